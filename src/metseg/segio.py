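"""Sequence/annotation I/O, sliding-window segment extraction, and residue recodings.

Coordinates are 1-based and inclusive at every public interface.  Sequences are
normalized to the 20 standard residues plus the padding/catch-all letter ``X``;
derived channel strings (hydropathy, charge, secondary structure, solvent
accessibility) use their own small alphabets with a dedicated lowercase ``x``
padding letter so padding is an observed category, never missing data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "AA20",
    "PAD",
    "RESIDUE_ALPHABET",
    "CHANNEL_PAD",
    "HYDRO_ALPHABET",
    "CHARGE_ALPHABET",
    "SS_ALPHABET",
    "SA_ALPHABET",
    "ION_WINDOWS",
    "InvalidResidueError",
    "InvalidValueError",
    "ProteinChain",
    "Segment",
    "WindowConfig",
    "normalize_sequence",
    "pad_sequence",
    "extract_segments",
    "recode_hydro",
    "recode_charge",
    "recode_sa",
    "read_fasta",
    "write_fasta",
    "read_sites",
    "write_sites",
    "read_annotations",
    "write_annotations",
    "load_chains",
    "write_segments_tsv",
    "read_segments_tsv",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
PAD = "X"
#: residue alphabet: 20 standard residues followed by the padding letter.
RESIDUE_ALPHABET = AA20 + PAD

#: padding letter shared by the derived channel alphabets (distinct from each
#: alphabet's informative letters, and distinct from the residue pad ``X``).
CHANNEL_PAD = "x"
HYDRO_ALPHABET = "123456" + CHANNEL_PAD
CHARGE_ALPHABET = "+-0" + CHANNEL_PAD
SS_ALPHABET = "HEC" + CHANNEL_PAD
SA_ALPHABET = "IJMN" + CHANNEL_PAD

#: per-ion default window lengths.
ION_WINDOWS = {
    "zn": 7,
    "cu": 13,
    "fe2": 9,
    "fe3": 9,
    "co": 11,
    "mn": 7,
    "ca": 9,
    "mg": 9,
    "k": 11,
    "na": 9,
}

# hydropathy classes: strongly hydrophilic / weakly hydrophilic /
# strongly hydrophobic / proline / glycine / cysteine
_HYDRO_GROUPS = {
    "1": "RDENQKH",
    "2": "LIVAMF",
    "3": "STYW",
    "4": "P",
    "5": "G",
    "6": "C",
}
_HYDRO_MAP = {aa: cls for cls, group in _HYDRO_GROUPS.items() for aa in group}
_HYDRO_MAP[PAD] = CHANNEL_PAD

_CHARGE_MAP = {aa: "0" for aa in AA20}
_CHARGE_MAP.update({aa: "+" for aa in "KRP"})
_CHARGE_MAP.update({aa: "-" for aa in "DE"})
_CHARGE_MAP[PAD] = CHANNEL_PAD


class InvalidResidueError(ValueError):
    """A letter outside the expected alphabet was encountered."""


class InvalidValueError(ValueError):
    """A numeric annotation value is outside its legal range."""


def normalize_sequence(seq: str) -> str:
    """Uppercase ``seq`` and map every non-standard letter (B, Z, U, O, J, ...)
    to the catch-all ``X``.  Non-alphabetic characters raise."""
    out = []
    for ch in seq.upper():
        if ch in RESIDUE_ALPHABET:
            out.append(ch)
        elif ch.isalpha():
            out.append(PAD)
        else:
            raise InvalidResidueError(f"non-alphabetic character {ch!r} in sequence")
    return "".join(out)


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window length.  ``L`` must be odd and at least 5."""

    L: int

    def __post_init__(self) -> None:
        if self.L % 2 == 0 or self.L < 5:
            raise ValueError(f"window length must be odd and >= 5, got {self.L}")

    @property
    def half(self) -> int:
        return (self.L - 1) // 2

    @classmethod
    def for_ion(cls, ion: str) -> "WindowConfig":
        try:
            return cls(ION_WINDOWS[ion.lower()])
        except KeyError:
            raise KeyError(
                f"unknown ion {ion!r}; known ions: {sorted(ION_WINDOWS)}"
            ) from None


@dataclass
class ProteinChain:
    """A protein chain with its binding positions and optional annotations.

    ``binding_positions`` are 1-based indices into ``sequence``; ``ss`` is a
    string over ``HEC`` and ``rsa`` a tuple of reals in [0, 1], both of
    sequence length when present.
    """

    id: str
    sequence: str
    binding_positions: frozenset[int] = field(default_factory=frozenset)
    ss: str | None = None
    rsa: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"chain {self.id}: empty sequence")
        self.sequence = normalize_sequence(self.sequence)
        self.binding_positions = frozenset(int(p) for p in self.binding_positions)
        n = len(self.sequence)
        for p in self.binding_positions:
            if not 1 <= p <= n:
                raise ValueError(
                    f"chain {self.id}: binding position {p} outside [1, {n}]"
                )
        if self.ss is not None:
            if len(self.ss) != n:
                raise ValueError(f"chain {self.id}: ss length != sequence length")
            bad = set(self.ss) - set("HEC")
            if bad:
                raise InvalidResidueError(
                    f"chain {self.id}: ss letters {sorted(bad)} not in H/E/C"
                )
        if self.rsa is not None:
            self.rsa = tuple(float(v) for v in self.rsa)
            if len(self.rsa) != n:
                raise ValueError(f"chain {self.id}: rsa length != sequence length")
            for v in self.rsa:
                if not 0.0 <= v <= 1.0:
                    raise InvalidValueError(
                        f"chain {self.id}: rsa value {v} outside [0, 1]"
                    )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Segment:
    """One fixed-length window centered on a residue of a source chain."""

    residues: str
    label: str  # "positive" | "negative"
    chain_id: str
    center: int  # 1-based index into the source chain
    channels: dict[str, str] = field(default_factory=dict)

    @property
    def is_positive(self) -> bool:
        return self.label == "positive"


def pad_sequence(seq: str, L: int) -> str:
    """Return ``seq`` flanked by ``(L-1)/2`` padding letters on each side."""
    if L < 1 or L % 2 == 0:
        raise ValueError(f"window length must be a positive odd integer, got {L}")
    if not seq:
        raise ValueError("empty sequence")
    flank = PAD * ((L - 1) // 2)
    return flank + seq + flank


def recode_hydro(seq: str) -> str:
    """Recode residues into the 6-class hydropathy alphabet (``X`` -> pad)."""
    try:
        return "".join(_HYDRO_MAP[ch] for ch in seq)
    except KeyError as exc:
        raise InvalidResidueError(f"unknown residue {exc.args[0]!r}") from None


def recode_charge(seq: str) -> str:
    """Recode residues into the 3-class polarization-charge alphabet."""
    try:
        return "".join(_CHARGE_MAP[ch] for ch in seq)
    except KeyError as exc:
        raise InvalidResidueError(f"unknown residue {exc.args[0]!r}") from None


def recode_sa(rsa: Sequence[float]) -> str:
    """Discretize relative solvent accessibilities into the four-letter
    alphabet I/J/M/N.

    Bins: (0, 0.2] -> I, (0.2, 0.45] -> J, (0.45, 0.6] -> M, (0.6, 0.85] -> N.
    RSA of exactly 0 falls in the buried bin I; values above 0.85 are clamped
    to N.  Negative values raise.
    """
    out = []
    for v in rsa:
        v = float(v)
        if v < 0:
            raise InvalidValueError(f"negative RSA value {v}")
        if v <= 0.2:
            out.append("I")
        elif v <= 0.45:
            out.append("J")
        elif v <= 0.6:
            out.append("M")
        else:
            out.append("N")
    return "".join(out)


def extract_segments(chain: ProteinChain, cfg: WindowConfig) -> list[Segment]:
    """Slide a window of length ``cfg.L`` over ``chain`` and return one
    :class:`Segment` per residue.

    The padded coordinate system guarantees exactly ``len(chain)`` segments;
    the segment centered on residue ``i`` (1-based) covers padded positions
    ``[i, i + L - 1]``.  Channel strings are produced for the recodings that
    are always available (hydro6, charge3) and for whichever annotations the
    chain carries (ss3, sa4), padded with the channel padding letter.
    """
    L = cfg.L
    half = cfg.half
    padded = pad_sequence(chain.sequence, L)
    tracks: dict[str, str] = {
        "hydro6": recode_hydro(padded),
        "charge3": recode_charge(padded),
    }
    cpad = CHANNEL_PAD * half
    if chain.ss is not None:
        tracks["ss3"] = cpad + chain.ss + cpad
    if chain.rsa is not None:
        tracks["sa4"] = cpad + recode_sa(chain.rsa) + cpad

    segments = []
    for i in range(1, len(chain) + 1):
        lo = i - 1  # 0-based start in the padded string
        window = padded[lo : lo + L]
        label = "positive" if i in chain.binding_positions else "negative"
        channels = {name: track[lo : lo + L] for name, track in tracks.items()}
        segments.append(
            Segment(
                residues=window,
                label=label,
                chain_id=chain.id,
                center=i,
                channels=channels,
            )
        )
    return segments


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq)
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_sites(path: str | Path, ligand: str | None = None) -> dict[str, set[int]]:
    """Read a binding-annotation TSV: ``chain_id<TAB>ligand<TAB>positions``.

    ``positions`` is a comma-separated list of 1-based integers.  Rows for the
    same chain are unioned.  If ``ligand`` is given, only matching rows (case
    insensitive) are kept.
    """
    sites: dict[str, set[int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"malformed sites row: {line!r}")
            chain_id, lig, positions = parts
            if ligand is not None and lig.lower() != ligand.lower():
                continue
            pos = set()
            if positions.strip():
                pos = {int(p) for p in positions.split(",")}
            sites.setdefault(chain_id, set()).update(pos)
    return sites


def write_sites(
    sites: Mapping[str, Iterable[int]], path: str | Path, ligand: str = "site"
) -> None:
    with open(path, "w") as fh:
        for chain_id, positions in sites.items():
            pos = ",".join(str(p) for p in sorted(positions))
            fh.write(f"{chain_id}\t{ligand}\t{pos}\n")


def read_annotations(path: str | Path) -> dict[str, tuple[str, tuple[float, ...]]]:
    """Read per-residue annotations: ``chain_id<TAB>ss_string<TAB>rsa_csv``.

    Either field may be ``-`` to mark it absent.
    """
    out: dict[str, tuple[str, tuple[float, ...]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chain_id, ss, rsa_csv = line.split("\t")
            ss_val = None if ss == "-" else ss
            rsa_val = (
                None
                if rsa_csv == "-"
                else tuple(float(v) for v in rsa_csv.split(","))
            )
            out[chain_id] = (ss_val, rsa_val)
    return out


def write_annotations(
    annotations: Mapping[str, tuple[str | None, Sequence[float] | None]],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        for chain_id, (ss, rsa) in annotations.items():
            ss_field = ss if ss is not None else "-"
            rsa_field = (
                ",".join(f"{v:.4f}" for v in rsa) if rsa is not None else "-"
            )
            fh.write(f"{chain_id}\t{ss_field}\t{rsa_field}\n")


def load_chains(
    fasta_path: str | Path,
    sites_path: str | Path | None = None,
    annotations_path: str | Path | None = None,
    ligand: str | None = None,
) -> list[ProteinChain]:
    """Assemble :class:`ProteinChain` objects from the on-disk dialects."""
    sequences = read_fasta(fasta_path)
    sites = read_sites(sites_path, ligand=ligand) if sites_path else {}
    annotations = read_annotations(annotations_path) if annotations_path else {}
    chains = []
    for chain_id, seq in sequences.items():
        ss, rsa = annotations.get(chain_id, (None, None))
        chains.append(
            ProteinChain(
                id=chain_id,
                sequence=seq,
                binding_positions=frozenset(sites.get(chain_id, set())),
                ss=ss,
                rsa=rsa,
            )
        )
    return chains


_CHANNEL_ORDER = ("hydro6", "charge3", "ss3", "sa4")


def write_segments_tsv(segments: Iterable[Segment], path: str | Path) -> None:
    """Write segments as TSV: ``chain_id  center  label  residues  [channels]``."""
    segments = list(segments)
    present = [
        name
        for name in _CHANNEL_ORDER
        if segments and name in segments[0].channels
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["chain_id", "center", "label", "residues", *present])
        for seg in segments:
            writer.writerow(
                [seg.chain_id, seg.center, seg.label, seg.residues]
                + [seg.channels[name] for name in present]
            )


def read_segments_tsv(path: str | Path) -> list[Segment]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        channel_names = header[4:]
        segments = []
        for row in reader:
            chain_id, center, label, residues = row[:4]
            channels = dict(zip(channel_names, row[4:]))
            segments.append(
                Segment(
                    residues=residues,
                    label=label,
                    chain_id=chain_id,
                    center=int(center),
                    channels=channels,
                )
            )
    return segments
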