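"""Synthetic chain generator with planted binding-site structure.

Chains are drawn from a background residue composition; binding windows get
per-offset emission distributions (by default, the center residue is drawn
from a preferred set such as C/H/D/E with weight theta).  Optional per-class
secondary-structure categoricals and multi-modal relative-solvent-
accessibility mixtures give the annotation channels a planted signal too.
Everything is reproducible from the spec's master seed, and datasets
round-trip through the package's FASTA/TSV dialects.

The generator is a testing stand-in, not a model of real proteins: positions
are independent given the planted emissions, and sites are isolated centers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .pwsm import build_matrix
from .segio import (
    AA20,
    RESIDUE_ALPHABET,
    ProteinChain,
    Segment,
    WindowConfig,
    extract_segments,
    write_annotations,
    write_fasta,
    write_sites,
)

__all__ = [
    "BACKGROUND_FREQS",
    "SimulationSpec",
    "generate_dataset",
    "expected_positive_profile",
    "recover_pwm",
    "shuffle_labels",
    "write_dataset",
    "strong_signal_spec",
    "staged_signal_spec",
]

#: approximate vertebrate background residue frequencies (normalized below).
BACKGROUND_FREQS = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.56, "T": 5.34, "W": 1.08, "Y": 2.92, "V": 6.87,
}

_DEFAULT_SS_POS = {"H": 0.10, "E": 0.10, "C": 0.80}
_DEFAULT_SS_NEG = {"H": 0.35, "E": 0.25, "C": 0.40}
# binding RSA concentrates in narrow modes; non-binding is broader
_DEFAULT_RSA_POS = ((0.25, 0.04, 0.4), (0.35, 0.04, 0.3), (0.45, 0.04, 0.3))
_DEFAULT_RSA_NEG = ((0.12, 0.08, 0.3), (0.45, 0.15, 0.4), (0.70, 0.08, 0.3))


@dataclass
class SimulationSpec:
    """Parameters of the planted-signal generator."""

    n_chains: int = 50
    chain_length: int | tuple[int, int] = 100
    site_density: float = 2.0  # expected binding sites per chain
    L: int = 7
    theta: float = 0.9  # preferred-set weight at the binding center
    preferred: str = "CHDE"
    #: extra per-offset emissions: offset -> (letters, weight)
    flank_emissions: dict[int, tuple[str, float]] = field(default_factory=dict)
    background: Mapping[str, float] | None = None
    with_annotations: bool = True
    ss_pos: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_SS_POS))
    ss_neg: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_SS_NEG))
    rsa_pos: Sequence[tuple[float, float, float]] = _DEFAULT_RSA_POS
    rsa_neg: Sequence[tuple[float, float, float]] = _DEFAULT_RSA_NEG
    rsa_max: float = 0.85  # rejection bound; set > 0.85 to exercise clamping
    margin: int = 0  # keep centers at least this far from the termini
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.L % 2 == 0 or self.L < 5:
            raise ValueError("L must be odd and >= 5")
        for _, (letters, w) in self.flank_emissions.items():
            if not letters or not 0.0 <= w <= 1.0:
                raise ValueError("flank emission needs letters and weight in [0,1]")
        min_len = (
            self.chain_length
            if isinstance(self.chain_length, int)
            else self.chain_length[0]
        )
        if 2 * self.margin >= min_len:
            raise ValueError("margin leaves no room for binding centers")
        if self.site_density > min_len - 2 * self.margin:
            raise ValueError("site density exceeds chain capacity")

    def background_vector(self) -> np.ndarray:
        freqs = dict(self.background) if self.background else dict(BACKGROUND_FREQS)
        vec = np.array([freqs.get(aa, 0.0) for aa in AA20], dtype=float)
        if vec.sum() <= 0:
            raise ValueError("background frequencies sum to zero")
        return vec / vec.sum()


def _categorical(rng: np.random.Generator, probs: Mapping[str, float], n: int) -> str:
    letters = list(probs)
    p = np.array([probs[c] for c in letters], dtype=float)
    p = p / p.sum()
    return "".join(rng.choice(letters, size=n, p=p))


def _sample_rsa_mixture(
    rng: np.random.Generator,
    modes: Sequence[tuple[float, float, float]],
    n: int,
    upper: float,
) -> np.ndarray:
    """Mixture of Gaussian bumps, rejection-truncated to [0, upper]."""
    means = np.array([m for m, _, _ in modes])
    sds = np.array([s for _, s, _ in modes])
    ws = np.array([w for _, _, w in modes], dtype=float)
    ws = ws / ws.sum()
    out = np.empty(n)
    remaining = np.arange(n)
    hard_cap = min(upper, 1.0)
    while remaining.size:
        comp = rng.choice(len(modes), size=remaining.size, p=ws)
        vals = rng.normal(means[comp], sds[comp])
        ok = (vals >= 0.0) & (vals <= hard_cap)
        out[remaining[ok]] = vals[ok]
        remaining = remaining[~ok]
    return out


def generate_dataset(
    spec: SimulationSpec,
) -> tuple[list[ProteinChain], dict]:
    """Generate chains plus a ground-truth record of the planted parameters."""
    rng = np.random.default_rng(spec.seed)
    bg = spec.background_vector()
    aa = np.array(list(AA20))
    chains: list[ProteinChain] = []
    sites_truth: dict[str, list[int]] = {}

    for c in range(spec.n_chains):
        if isinstance(spec.chain_length, int):
            length = spec.chain_length
        else:
            lo, hi = spec.chain_length
            length = int(rng.integers(lo, hi + 1))
        lo_center = 1 + spec.margin
        hi_center = length - spec.margin
        capacity = hi_center - lo_center + 1
        n_sites = min(int(rng.poisson(spec.site_density)), capacity)
        centers = sorted(
            int(v)
            for v in rng.choice(
                np.arange(lo_center, hi_center + 1), size=n_sites, replace=False
            )
        )
        seq = rng.choice(aa, size=length, p=bg)

        # flanks first so that overlapping windows never clobber a center
        for center in centers:
            for offset, (letters, weight) in spec.flank_emissions.items():
                pos = center + offset
                if 1 <= pos <= length and rng.random() < weight:
                    seq[pos - 1] = letters[int(rng.integers(len(letters)))]
        for center in centers:
            if rng.random() < spec.theta:
                seq[center - 1] = spec.preferred[
                    int(rng.integers(len(spec.preferred)))
                ]

        ss = rsa = None
        if spec.with_annotations:
            binding = set(centers)
            ss_chars = []
            rsa_vals = np.empty(length)
            pos_mask = np.zeros(length, dtype=bool)
            for p in binding:
                pos_mask[p - 1] = True
            ss_pos_str = _categorical(rng, spec.ss_pos, int(pos_mask.sum()))
            ss_neg_str = _categorical(rng, spec.ss_neg, int((~pos_mask).sum()))
            it_pos, it_neg = iter(ss_pos_str), iter(ss_neg_str)
            ss_chars = [next(it_pos) if m else next(it_neg) for m in pos_mask]
            rsa_vals[pos_mask] = _sample_rsa_mixture(
                rng, spec.rsa_pos, int(pos_mask.sum()), spec.rsa_max
            )
            rsa_vals[~pos_mask] = _sample_rsa_mixture(
                rng, spec.rsa_neg, int((~pos_mask).sum()), spec.rsa_max
            )
            ss = "".join(ss_chars)
            rsa = tuple(round(float(v), 4) for v in rsa_vals)

        chain_id = f"synth_{c:04d}"
        chains.append(
            ProteinChain(
                id=chain_id,
                sequence="".join(seq),
                binding_positions=frozenset(centers),
                ss=ss,
                rsa=rsa,
            )
        )
        sites_truth[chain_id] = centers

    truth = {
        "spec": _spec_to_json(spec),
        "sites": sites_truth,
        "n_positive": sum(len(v) for v in sites_truth.values()),
        "center_distribution": expected_center_distribution(spec).tolist(),
    }
    return chains, truth


def _spec_to_json(spec: SimulationSpec) -> dict:
    d = asdict(spec)
    d["flank_emissions"] = {
        str(k): list(v) for k, v in spec.flank_emissions.items()
    }
    d["rsa_pos"] = [list(m) for m in spec.rsa_pos]
    d["rsa_neg"] = [list(m) for m in spec.rsa_neg]
    return d


def expected_center_distribution(spec: SimulationSpec) -> np.ndarray:
    """True residue distribution at the binding center, over the 21 letters."""
    bg = spec.background_vector()
    dist = np.zeros(len(RESIDUE_ALPHABET))
    dist[: len(AA20)] = (1.0 - spec.theta) * bg
    for letter in spec.preferred:
        dist[RESIDUE_ALPHABET.index(letter)] += spec.theta / len(spec.preferred)
    return dist


def expected_positive_profile(spec: SimulationSpec) -> np.ndarray:
    """True (L, 21) per-position residue distribution of positive windows.

    Valid when ``spec.margin >= (L-1)/2`` (no padding inside positive
    windows) and site density is low enough that window collisions are
    negligible.
    """
    L = spec.L
    half = (L - 1) // 2
    bg = spec.background_vector()
    profile = np.zeros((L, len(RESIDUE_ALPHABET)))
    profile[:, : len(AA20)] = bg[None, :]
    for offset, (letters, weight) in spec.flank_emissions.items():
        if abs(offset) > half:
            continue
        row = (1.0 - weight) * np.concatenate([bg, [0.0]])
        for letter in letters:
            row[RESIDUE_ALPHABET.index(letter)] += weight / len(letters)
        profile[half + offset] = row
    profile[half] = expected_center_distribution(spec)
    return profile


def recover_pwm(
    chains: Sequence[ProteinChain], L: int, spec: SimulationSpec
) -> dict:
    """Estimate the positive-class PWSM from the true positive segments and
    compare with the pseudocount-adjusted planted profile.

    Returns the estimated matrix, the adjusted truth and the max absolute
    per-cell deviation.
    """
    cfg = WindowConfig(L)
    positives = [
        s.residues
        for chain in chains
        for s in extract_segments(chain, cfg)
        if s.is_positive
    ]
    matrix = build_matrix(positives, RESIDUE_ALPHABET, background="uniform")
    truth = expected_positive_profile(spec)
    n = len(positives)
    a = len(RESIDUE_ALPHABET)
    root = np.sqrt(n)
    truth_pc = (n * truth + root / a) / (n + root)
    dev = float(np.abs(matrix.probs - truth_pc).max())
    return {
        "matrix": matrix,
        "n_positive": n,
        "truth": truth,
        "truth_with_pseudocount": truth_pc,
        "max_abs_dev": dev,
    }


def shuffle_labels(segments: Sequence[Segment], seed: int) -> list[Segment]:
    """Permute labels across segments (the permutation-null control)."""
    rng = np.random.default_rng(seed)
    labels = [s.label for s in segments]
    perm = rng.permutation(len(labels))
    return [
        Segment(
            residues=s.residues,
            label=labels[perm[i]],
            chain_id=s.chain_id,
            center=s.center,
            channels=dict(s.channels),
        )
        for i, s in enumerate(segments)
    ]


def write_dataset(
    chains: Sequence[ProteinChain],
    outdir: str | Path,
    truth: dict | None = None,
    ligand: str = "site",
) -> dict[str, Path]:
    """Emit FASTA + sites TSV (+ annotations TSV, truth JSON) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "chains.fasta",
        "sites": outdir / "sites.tsv",
    }
    write_fasta({c.id: c.sequence for c in chains}, paths["fasta"])
    write_sites(
        {c.id: c.binding_positions for c in chains}, paths["sites"], ligand=ligand
    )
    if any(c.ss is not None or c.rsa is not None for c in chains):
        paths["annotations"] = outdir / "annotations.tsv"
        write_annotations(
            {c.id: (c.ss, c.rsa) for c in chains}, paths["annotations"]
        )
    if truth is not None:
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return paths


# ---------------------------------------------------------------------------
# presets used by the test-suite and the acceptance harness
# ---------------------------------------------------------------------------

def strong_signal_spec(
    seed: int = 0, n_chains: int = 60, theta: float = 0.95
) -> SimulationSpec:
    """Strongly planted signal: preferred center plus distinctive flanks."""
    return SimulationSpec(
        n_chains=n_chains,
        chain_length=100,
        site_density=2.0,
        L=7,
        theta=theta,
        preferred="CHDE",
        flank_emissions={
            -2: ("W", 0.75),
            -1: ("P", 0.75),
            1: ("P", 0.75),
            2: ("W", 0.75),
        },
        with_annotations=False,
        seed=seed,
    )


def staged_signal_spec(seed: int = 0, n_chains: int = 80) -> SimulationSpec:
    """Moderate residue signal with informative SS and RSA channels."""
    return SimulationSpec(
        n_chains=n_chains,
        chain_length=100,
        site_density=2.0,
        L=7,
        theta=0.4,
        preferred="CHDE",
        with_annotations=True,
        ss_pos={"H": 0.05, "E": 0.05, "C": 0.90},
        ss_neg={"H": 0.40, "E": 0.30, "C": 0.30},
        rsa_pos=((0.25, 0.03, 0.4), (0.35, 0.03, 0.3), (0.45, 0.03, 0.3)),
        rsa_neg=((0.10, 0.06, 0.4), (0.55, 0.12, 0.4), (0.75, 0.06, 0.2)),
        seed=seed,
    )
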