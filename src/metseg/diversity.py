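"""Increment-of-Diversity (ID) measure over composition count vectors.

D(X) = N log N − Σ n_i log n_i (natural log, 0·log 0 = 0) and
ID(X, Y) = D(X+Y) − D(X) − D(Y), a nonnegative, symmetric dissimilarity
between count vectors.  A segment's 21-letter composition against the
positive and negative training sources yields the 2-dimensional ID feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DiversitySource",
    "diversity",
    "increment_of_diversity",
    "id_features",
    "composition_counts",
]


def _xlogx(n: np.ndarray) -> np.ndarray:
    out = np.zeros_like(n, dtype=float)
    mask = n > 0
    out[mask] = n[mask] * np.log(n[mask])
    return out


@dataclass
class DiversitySource:
    """A nonnegative count vector over a fixed alphabet."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-d vector")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.sum() == 0:
            raise ValueError("all-zero count vector")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def dimension(self) -> int:
        return self.counts.size


def diversity(source: DiversitySource | Sequence[int]) -> float:
    """The diversity measure D(X) = N log N − Σ n_i log n_i, in nats."""
    if not isinstance(source, DiversitySource):
        source = DiversitySource(np.asarray(source))
    n = source.counts
    total = source.total
    return float(total * np.log(total) - _xlogx(n).sum())


def increment_of_diversity(
    x: DiversitySource | Sequence[int], y: DiversitySource | Sequence[int]
) -> float:
    """ID(X, Y) = D(X+Y) − D(X) − D(Y); symmetric, nonnegative, 0 at X = Y."""
    if not isinstance(x, DiversitySource):
        x = DiversitySource(np.asarray(x))
    if not isinstance(y, DiversitySource):
        y = DiversitySource(np.asarray(y))
    if x.dimension != y.dimension:
        raise ValueError(
            f"dimension mismatch: {x.dimension} vs {y.dimension}"
        )
    mixed = DiversitySource(x.counts + y.counts)
    val = diversity(mixed) - diversity(x) - diversity(y)
    # analytically ≥ 0; guard floating-point drift
    return max(val, 0.0)


def composition_counts(segment: str, alphabet: str) -> np.ndarray:
    """Letter counts of ``segment`` over ``alphabet`` (error on strangers)."""
    if not segment:
        raise ValueError("empty segment")
    counts = np.zeros(len(alphabet), dtype=np.int64)
    index = {ch: i for i, ch in enumerate(alphabet)}
    for ch in segment:
        try:
            counts[index[ch]] += 1
        except KeyError:
            raise ValueError(f"letter {ch!r} not in alphabet {alphabet!r}") from None
    return counts


def id_features(
    segment_counts: np.ndarray | Sequence[int],
    positive_source: DiversitySource,
    negative_source: DiversitySource,
) -> np.ndarray:
    """The 2-vector (ID(segment, positive), ID(segment, negative))."""
    seg = DiversitySource(np.asarray(segment_counts))
    return np.array(
        [
            increment_of_diversity(seg, positive_source),
            increment_of_diversity(seg, negative_source),
        ]
    )


def id_features_many(
    counts_matrix: np.ndarray,
    positive_source: DiversitySource,
    negative_source: DiversitySource,
) -> np.ndarray:
    """Vectorized :func:`id_features` for an (n, S) matrix of segment counts."""
    counts_matrix = np.asarray(counts_matrix, dtype=np.int64)
    out = np.empty((counts_matrix.shape[0], 2))
    seg_totals = counts_matrix.sum(axis=1)
    if (seg_totals == 0).any():
        raise ValueError("zero-length segment composition")
    d_seg = seg_totals * np.log(seg_totals) - _xlogx(counts_matrix).sum(axis=1)
    for col, src in ((0, positive_source), (1, negative_source)):
        if src.dimension != counts_matrix.shape[1]:
            raise ValueError("dimension mismatch with source")
        mixed = counts_matrix + src.counts[None, :]
        totals = seg_totals + src.total
        d_mixed = totals * np.log(totals) - _xlogx(mixed).sum(axis=1)
        out[:, col] = np.maximum(d_mixed - d_seg - diversity(src), 0.0)
    return out
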