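"""Staged multi-channel feature assembly.

Each enabled channel contributes a fixed block to the fused vector, in the
canonical order ``id_aa, s_p, ss_freq, s_ss, s_h, s_c, s_sa``:

========  ===  =========================================================
channel   dim  content
========  ===  =========================================================
id_aa      2   increment of diversity of the segment's 21-letter
               composition against the positive / negative sources
s_p        2   PWSM pair scores on the residue window
ss_freq    3   H/E/C frequencies over non-padding positions
s_ss       2   PWSM pair scores on the 3-state secondary structure window
s_h        2   PWSM pair scores on the 6-class hydropathy recoding
s_c        2   PWSM pair scores on the 3-class charge recoding
s_sa       2   PWSM pair scores on the 4-letter solvent-accessibility
               recoding
========  ===  =========================================================

Dropping channels removes their blocks and leaves the rest of the layout
untouched, which is what makes staged ablation runs comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import pwsm as _pwsm
from .diversity import DiversitySource, composition_counts, id_features, id_features_many
from .pwsm import PwsmPair, build_pair
from .segio import (
    CHANNEL_PAD,
    CHARGE_ALPHABET,
    HYDRO_ALPHABET,
    RESIDUE_ALPHABET,
    SA_ALPHABET,
    SS_ALPHABET,
    Segment,
)

__all__ = [
    "CHANNELS",
    "CHANNEL_DIMS",
    "FeatureConfig",
    "ChannelModels",
    "FeatureVector",
    "ChannelConfigError",
    "fit_channels",
    "featurize",
    "featurize_batch",
    "write_dense_tsv",
    "write_svmlight",
]

#: canonical channel order; vector layout follows this order always.
CHANNELS = ("id_aa", "s_p", "ss_freq", "s_ss", "s_h", "s_c", "s_sa")

CHANNEL_DIMS = {
    "id_aa": 2,
    "s_p": 2,
    "ss_freq": 3,
    "s_ss": 2,
    "s_h": 2,
    "s_c": 2,
    "s_sa": 2,
}

#: PWSM channels: (segment string source, alphabet).  ``None`` source means
#: the raw residue window.
_PWSM_CHANNELS = {
    "s_p": (None, RESIDUE_ALPHABET),
    "s_ss": ("ss3", SS_ALPHABET),
    "s_h": ("hydro6", HYDRO_ALPHABET),
    "s_c": ("charge3", CHARGE_ALPHABET),
    "s_sa": ("sa4", SA_ALPHABET),
}

#: channels that require an annotation carried by the chain.
_ANNOTATION_OF = {"ss_freq": "ss3", "s_ss": "ss3", "s_sa": "sa4"}


class ChannelConfigError(ValueError):
    """A requested channel is missing the annotation it needs."""


@dataclass(frozen=True)
class FeatureConfig:
    """An enabled-channel set plus window length; order is canonicalized."""

    channels: tuple[str, ...]
    L: int

    def __post_init__(self) -> None:
        unknown = set(self.channels) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")
        if not self.channels:
            raise ValueError("at least one channel must be enabled")
        ordered = tuple(c for c in CHANNELS if c in set(self.channels))
        object.__setattr__(self, "channels", ordered)

    @property
    def dimension(self) -> int:
        return sum(CHANNEL_DIMS[c] for c in self.channels)

    def layout(self) -> dict[str, tuple[int, int]]:
        """Channel -> half-open (start, stop) index range in the vector."""
        out = {}
        offset = 0
        for c in self.channels:
            out[c] = (offset, offset + CHANNEL_DIMS[c])
            offset += CHANNEL_DIMS[c]
        return out


@dataclass
class FeatureVector:
    values: np.ndarray
    layout: dict[str, tuple[int, int]]
    label: str


@dataclass
class ChannelModels:
    """Fitted per-channel models (PWSM pairs and/or ID sources)."""

    config: FeatureConfig
    pairs: dict[str, PwsmPair] = field(default_factory=dict)
    id_positive: DiversitySource | None = None
    id_negative: DiversitySource | None = None


def _channel_string(segment: Segment, channel: str) -> str:
    source, _ = _PWSM_CHANNELS[channel]
    if source is None:
        return segment.residues
    try:
        return segment.channels[source]
    except KeyError:
        raise ChannelConfigError(
            f"channel {channel!r} needs the {source!r} annotation, "
            f"absent on segment {segment.chain_id}:{segment.center}"
        ) from None


def _require_annotations(segments: Sequence[Segment], cfg: FeatureConfig) -> None:
    for channel in cfg.channels:
        track = _ANNOTATION_OF.get(channel)
        if track is None:
            continue
        missing = [s for s in segments if track not in s.channels]
        if missing:
            raise ChannelConfigError(
                f"channel {channel!r} requires the {track!r} annotation but "
                f"{len(missing)} segments lack it (e.g. "
                f"{missing[0].chain_id}:{missing[0].center})"
            )


def fit_channels(
    training_segments: Sequence[Segment],
    cfg: FeatureConfig,
    background: str = "pooled",
) -> ChannelModels:
    """Fit every enabled channel on labeled training segments.

    PWSM pairs are fitted per channel alphabet; ID sources pool the residue
    composition of each class.  ``ss_freq`` needs no fitting (but does need
    the annotation).
    """
    _require_annotations(training_segments, cfg)
    pos = [s for s in training_segments if s.is_positive]
    neg = [s for s in training_segments if not s.is_positive]
    if not pos or not neg:
        raise ValueError("training segments must include both classes")

    models = ChannelModels(config=cfg)
    for channel in cfg.channels:
        if channel in _PWSM_CHANNELS:
            _, alphabet = _PWSM_CHANNELS[channel]
            pos_strings = [_channel_string(s, channel) for s in pos]
            neg_strings = [_channel_string(s, channel) for s in neg]
            models.pairs[channel] = build_pair(
                pos_strings, neg_strings, alphabet, background=background
            )
    if "id_aa" in cfg.channels:
        pos_counts = sum(
            (composition_counts(s.residues, RESIDUE_ALPHABET) for s in pos),
            np.zeros(len(RESIDUE_ALPHABET), dtype=np.int64),
        )
        neg_counts = sum(
            (composition_counts(s.residues, RESIDUE_ALPHABET) for s in neg),
            np.zeros(len(RESIDUE_ALPHABET), dtype=np.int64),
        )
        models.id_positive = DiversitySource(pos_counts)
        models.id_negative = DiversitySource(neg_counts)
    return models


def _ss_freq(segment: Segment) -> np.ndarray:
    try:
        ss = segment.channels["ss3"]
    except KeyError:
        raise ChannelConfigError(
            "channel 'ss_freq' needs the 'ss3' annotation"
        ) from None
    informative = [c for c in ss if c != CHANNEL_PAD]
    if not informative:
        return np.zeros(3)
    n = len(informative)
    return np.array(
        [informative.count("H") / n, informative.count("E") / n, informative.count("C") / n]
    )


def featurize(segment: Segment, models: ChannelModels) -> FeatureVector:
    """Assemble one segment's fused feature vector under ``models.config``."""
    cfg = models.config
    blocks = []
    for channel in cfg.channels:
        if channel == "id_aa":
            counts = composition_counts(segment.residues, RESIDUE_ALPHABET)
            blocks.append(id_features(counts, models.id_positive, models.id_negative))
        elif channel == "ss_freq":
            blocks.append(_ss_freq(segment))
        else:
            pair = models.pairs[channel]
            string = _channel_string(segment, channel)
            _, s_pos, s_neg = _pwsm.classify_segment(pair, string)
            blocks.append(np.array([s_pos, s_neg]))
    values = np.concatenate(blocks)
    if not np.isfinite(values).all():
        raise ValueError("non-finite feature value")
    return FeatureVector(values=values, layout=cfg.layout(), label=segment.label)


def featurize_batch(
    segments: Sequence[Segment], models: ChannelModels
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized featurization: returns ``(X, y)`` with y in {0, 1}."""
    cfg = models.config
    n = len(segments)
    X = np.empty((n, cfg.dimension))
    layout = cfg.layout()
    for channel in cfg.channels:
        lo, hi = layout[channel]
        if channel == "id_aa":
            counts = np.stack(
                [composition_counts(s.residues, RESIDUE_ALPHABET) for s in segments]
            )
            X[:, lo:hi] = id_features_many(
                counts, models.id_positive, models.id_negative
            )
        elif channel == "ss_freq":
            X[:, lo:hi] = np.stack([_ss_freq(s) for s in segments])
        else:
            pair = models.pairs[channel]
            _, alphabet = _PWSM_CHANNELS[channel]
            strings = [_channel_string(s, channel) for s in segments]
            codes = _pwsm._encode(strings, alphabet)
            s_pos, s_neg = pair.score_pair_many(codes)
            X[:, lo] = s_pos
            X[:, lo + 1] = s_neg
    y = np.array([1 if s.is_positive else 0 for s in segments])
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature value in batch")
    return X, y


def write_dense_tsv(
    X: np.ndarray, y: np.ndarray, cfg: FeatureConfig, path: str | Path
) -> None:
    """Dense TSV with a header naming each column by channel and offset."""
    header = ["label"]
    for channel in cfg.channels:
        header += [f"{channel}_{k}" for k in range(CHANNEL_DIMS[channel])]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for label, row in zip(y, X):
            fh.write("\t".join([str(int(label))] + [repr(float(v)) for v in row]) + "\n")


def write_svmlight(X: np.ndarray, y: np.ndarray, path: str | Path) -> None:
    """libsvm sparse text format."""
    from sklearn.datasets import dump_svmlight_file

    dump_svmlight_file(X, y, str(path), zero_based=False)
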