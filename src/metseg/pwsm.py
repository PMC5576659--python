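"""Conservation-weighted position weight scoring matrices.

A matrix is built per class (binding / non-binding) from equal-length
segments over an arbitrary alphabet.  Per-position probabilities use a
square-root pseudocount, p[i][j] = (n_ij + sqrt(N_i)/A) / (N_i + sqrt(N_i)),
weights are natural-log odds against a background composition, and each
position carries a conservation index C_i in [0, 100] (100 minus the
normalized Shannon entropy, scaled).  A segment scores

    S = sum_i C_i (w[i][a_i] - w_min[i]) / sum_i C_i (w_max[i] - w_min[i])

which lies in [0, 1]; classification takes the larger of the two class
scores, with ties resolved to the negative (majority) class.

Note: the pseudocount reading (n + sqrt(N)/A over N + sqrt(N)) is the
standard square-root rule with a uniform prior; ``pseudocount=False`` gives
plain frequencies for degenerate-column testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PositionWeightMatrix",
    "PwsmPair",
    "conservation_index",
    "build_matrix",
    "build_pair",
    "pooled_background",
    "score_segment",
    "classify_segment",
    "save_matrix",
    "load_matrix",
]

_NORM_TOL = 1e-6


def _encode(segments: Sequence[str], alphabet: str) -> np.ndarray:
    """Map equal-length strings to an (n, L) array of alphabet indices."""
    lut = np.full(128, -1, dtype=np.int16)
    for idx, ch in enumerate(alphabet):
        lut[ord(ch)] = idx
    arr = np.frombuffer("".join(segments).encode("ascii"), dtype=np.uint8)
    codes = lut[arr]
    if (codes < 0).any():
        bad = chr(int(arr[np.argmax(codes < 0)]))
        raise ValueError(f"letter {bad!r} not in alphabet {alphabet!r}")
    return codes.reshape(len(segments), -1).astype(np.intp)


def conservation_index(p_column: Sequence[float]) -> float:
    """Conservation of a probability column: 100·(1 − H(p)/log A).

    0 for the uniform distribution, 100 for a degenerate one; base-invariant.
    """
    p = np.asarray(p_column, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    if (p < 0).any():
        raise ValueError("negative probability")
    a = p.size
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    c = 100.0 * (1.0 - entropy / np.log(a))
    return float(np.clip(c, 0.0, 100.0))


@dataclass
class PositionWeightMatrix:
    """Per-class counts, probabilities, log-odds weights and conservation."""

    alphabet: str
    counts: np.ndarray  # (L, A) int
    n_segments: int  # N_i, identical at every position
    probs: np.ndarray  # (L, A)
    background: np.ndarray  # (A,)
    weights: np.ndarray  # (L, A) log(p / p0)
    conservation: np.ndarray  # (L,) in [0, 100]
    w_min: np.ndarray  # (L,)
    w_max: np.ndarray  # (L,)

    @property
    def L(self) -> int:
        return self.counts.shape[0]

    @property
    def A(self) -> int:
        return len(self.alphabet)

    def score_many(self, codes: np.ndarray) -> np.ndarray:
        """Vectorized scoring of pre-encoded segments, shape (n, L)."""
        pos = np.arange(self.L)
        w = self.weights[pos[None, :], codes]
        num = (self.conservation * (w - self.w_min)).sum(axis=1)
        denom = float((self.conservation * (self.w_max - self.w_min)).sum())
        if denom == 0.0:
            # no informative column: score carries no evidence either way
            return np.full(codes.shape[0], 0.5)
        return np.clip(num / denom, 0.0, 1.0)


def _column_counts(codes: np.ndarray, a: int) -> np.ndarray:
    L = codes.shape[1]
    counts = np.zeros((L, a), dtype=np.int64)
    for i in range(L):
        counts[i] = np.bincount(codes[:, i], minlength=a)
    return counts


def _estimate_probs(counts: np.ndarray, n: int, pseudocount: bool) -> np.ndarray:
    a = counts.shape[-1]
    if pseudocount:
        root = np.sqrt(n)
        return (counts + root / a) / (n + root)
    return counts / n


def pooled_background(
    segment_groups: Iterable[Sequence[str]], alphabet: str, pseudocount: bool = True
) -> np.ndarray:
    """Background composition pooled over several segment collections,
    estimated with the same square-root pseudocount as the matrices."""
    a = len(alphabet)
    totals = np.zeros(a, dtype=np.int64)
    for group in segment_groups:
        if not group:
            continue
        codes = _encode(group, alphabet)
        totals += np.bincount(codes.ravel(), minlength=a)
    n = int(totals.sum())
    if n == 0:
        raise ValueError("no letters to estimate a background from")
    return _estimate_probs(totals, n, pseudocount)


def build_matrix(
    segments: Sequence[str],
    alphabet: str,
    background: np.ndarray | str | None = None,
    pseudocount: bool = True,
) -> PositionWeightMatrix:
    """Build a :class:`PositionWeightMatrix` from equal-length segments.

    ``background`` is a probability vector over ``alphabet``; ``"uniform"``
    or ``None`` uses 1/A everywhere.
    """
    if len(segments) < 2:
        raise ValueError("need at least 2 segments to build a matrix")
    lengths = {len(s) for s in segments}
    if len(lengths) != 1:
        raise ValueError(f"ragged segment lengths: {sorted(lengths)}")
    a = len(alphabet)
    codes = _encode(segments, alphabet)
    n = len(segments)
    counts = _column_counts(codes, a)
    probs = _estimate_probs(counts, n, pseudocount)

    if background is None or (isinstance(background, str) and background == "uniform"):
        p0 = np.full(a, 1.0 / a)
    else:
        p0 = np.asarray(background, dtype=float)
        if p0.shape != (a,) or abs(p0.sum() - 1.0) > _NORM_TOL or (p0 <= 0).any():
            raise ValueError("background must be a positive probability vector over the alphabet")

    with np.errstate(divide="ignore"):
        weights = np.where(probs > 0, np.log(np.maximum(probs, 1e-300) / p0), -np.inf)

    conservation = np.array([conservation_index(row) for row in probs])
    # extremes over finite weights only; -inf (zero count, pseudocount
    # disabled) never defines the per-position range
    finite = np.where(np.isfinite(weights), weights, np.nan)
    w_min = np.nanmin(finite, axis=1)
    w_max = np.nanmax(finite, axis=1)

    return PositionWeightMatrix(
        alphabet=alphabet,
        counts=counts,
        n_segments=n,
        probs=probs,
        background=p0,
        weights=weights,
        conservation=conservation,
        w_min=w_min,
        w_max=w_max,
    )


def score_segment(matrix: PositionWeightMatrix, segment: str) -> float:
    """Score one segment in [0, 1] under ``matrix``."""
    if len(segment) != matrix.L:
        raise ValueError(f"segment length {len(segment)} != matrix length {matrix.L}")
    codes = _encode([segment], matrix.alphabet)
    return float(matrix.score_many(codes)[0])


@dataclass
class PwsmPair:
    """Positive and negative matrices sharing alphabet, length and background."""

    positive: PositionWeightMatrix
    negative: PositionWeightMatrix

    def __post_init__(self) -> None:
        if self.positive.alphabet != self.negative.alphabet:
            raise ValueError("matrices have different alphabets")
        if self.positive.L != self.negative.L:
            raise ValueError("matrices have different window lengths")

    def score_pair_many(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self.positive.score_many(codes), self.negative.score_many(codes)


def build_pair(
    positive_segments: Sequence[str],
    negative_segments: Sequence[str],
    alphabet: str,
    background: np.ndarray | str = "pooled",
    pseudocount: bool = True,
) -> PwsmPair:
    """Build the positive/negative matrix pair with a shared background.

    ``background="pooled"`` (default) estimates the background from the
    pooled composition of both training classes; ``"uniform"`` forces 1/A.
    """
    if isinstance(background, str) and background == "pooled":
        p0 = pooled_background(
            [positive_segments, negative_segments], alphabet, pseudocount
        )
    else:
        p0 = background
    return PwsmPair(
        positive=build_matrix(positive_segments, alphabet, p0, pseudocount),
        negative=build_matrix(negative_segments, alphabet, p0, pseudocount),
    )


def classify_segment(pair: PwsmPair, segment: str) -> tuple[str, float, float]:
    """Classify by the larger class score; ties go to the negative class.

    Returns ``(label, s_positive, s_negative)`` so the two scores can feed
    downstream feature vectors.
    """
    s_pos = score_segment(pair.positive, segment)
    s_neg = score_segment(pair.negative, segment)
    label = "positive" if s_pos > s_neg else "negative"
    return label, s_pos, s_neg


# ---------------------------------------------------------------------------
# plain-text serialization
# ---------------------------------------------------------------------------

def save_matrix(matrix: PositionWeightMatrix, path: str | Path) -> None:
    """Write a matrix in an inspectable tabular text format."""
    with open(path, "w") as fh:
        fh.write(f"#alphabet\t{matrix.alphabet}\n")
        fh.write(f"#n_segments\t{matrix.n_segments}\n")
        fh.write(
            "#background\t"
            + "\t".join(repr(float(v)) for v in matrix.background)
            + "\n"
        )
        for section, arr, fmt in (
            ("counts", matrix.counts, lambda v: str(int(v))),
            ("probs", matrix.probs, lambda v: repr(float(v))),
            ("weights", matrix.weights, lambda v: repr(float(v))),
        ):
            fh.write(f"#{section}\n")
            for row in arr:
                fh.write("\t".join(fmt(v) for v in row) + "\n")
        fh.write(
            "#conservation\t"
            + "\t".join(repr(float(v)) for v in matrix.conservation)
            + "\n"
        )


def load_matrix(path: str | Path) -> PositionWeightMatrix:
    alphabet = None
    n_segments = None
    background = None
    sections: dict[str, list[list[float]]] = {}
    current = None
    conservation = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#alphabet"):
                alphabet = line.split("\t", 1)[1]
            elif line.startswith("#n_segments"):
                n_segments = int(line.split("\t", 1)[1])
            elif line.startswith("#background"):
                background = np.array([float(v) for v in line.split("\t")[1:]])
            elif line.startswith("#conservation"):
                conservation = np.array([float(v) for v in line.split("\t")[1:]])
            elif line.startswith("#"):
                current = line[1:]
                sections[current] = []
            else:
                sections[current].append([float(v) for v in line.split("\t")])
    counts = np.array(sections["counts"], dtype=np.int64)
    probs = np.array(sections["probs"])
    weights = np.array(sections["weights"])
    finite = np.where(np.isfinite(weights), weights, np.nan)
    return PositionWeightMatrix(
        alphabet=alphabet,
        counts=counts,
        n_segments=n_segments,
        probs=probs,
        background=background,
        weights=weights,
        conservation=conservation,
        w_min=np.nanmin(finite, axis=1),
        w_max=np.nanmax(finite, axis=1),
    )
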