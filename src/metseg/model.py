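"""Training, prediction and the balanced-subsampling cross-validation protocol.

The evaluation protocol: negatives are randomly subsampled to the positive
count (ten repetitions), each balanced set is split into five folds, channel
models + feature scaling + the SVM are fitted on the four training folds
only, and the held-out fold is scored.  Metrics are averaged per fold
(pooled counts are reported alongside).  All randomness flows from one
master seed recorded in the report.

The SVM is C-SVC with an RBF kernel at the libsvm defaults (cost 1,
gamma = 1 / n_features); a PWSM-only mode classifies directly by the larger
of the two residue-matrix scores, which is the route of choice for ions
whose binding sites are strongly position-conserved.
"""

from __future__ import annotations

import json
import math
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .features import (
    CHANNELS,
    ChannelModels,
    FeatureConfig,
    featurize_batch,
    fit_channels,
)
from .pwsm import PwsmPair, build_pair, load_matrix, save_matrix
from .diversity import DiversitySource
from .segio import (
    RESIDUE_ALPHABET,
    ProteinChain,
    Segment,
    WindowConfig,
    extract_segments,
)
from . import pwsm as _pwsm

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "EvaluationReport",
    "FoldResult",
    "FeatureScaler",
    "ModelBundle",
    "metrics",
    "balanced_subsample",
    "cross_validate",
    "train_final",
    "predict_chain",
    "save_bundle",
    "load_bundle",
]

UNDEFINED = float("nan")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.tn, self.fp, self.fn):
            if v < 0:
                raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class Metrics:
    sn: float  # percent
    sp: float  # percent
    acc: float  # percent
    mcc: float  # [-1, 1]


def metrics(c: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity and accuracy in percent, plus Matthews
    correlation.  A metric whose denominator is zero is NaN, never 0."""
    sn = 100.0 * c.tp / (c.tp + c.fn) if c.tp + c.fn > 0 else UNDEFINED
    sp = 100.0 * c.tn / (c.tn + c.fp) if c.tn + c.fp > 0 else UNDEFINED
    acc = 100.0 * (c.tp + c.tn) / c.total if c.total > 0 else UNDEFINED
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom > 0:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    else:
        mcc = UNDEFINED
    return Metrics(sn=sn, sp=sp, acc=acc, mcc=mcc)


def confusion_from_labels(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> ConfusionCounts:
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("label vectors differ in length")
    return ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
    )


def balanced_subsample(
    negatives: Sequence, n_positives: int, rep_seed: int
) -> list:
    """Uniform sample of ``n_positives`` negatives without replacement,
    reproducible from ``rep_seed``."""
    if len(negatives) < n_positives:
        raise ValueError(
            f"need at least {n_positives} negatives, have {len(negatives)}"
        )
    rng = np.random.default_rng(rep_seed)
    idx = rng.choice(len(negatives), size=n_positives, replace=False)
    return [negatives[i] for i in idx]


class FeatureScaler:
    """Per-feature affine map of the training range onto [lo, hi].

    Order-preserving; constant training features map to the range midpoint.
    Transformed arrays are tagged so that scaling an already-scaled matrix
    raises instead of silently compounding.
    """

    class _Scaled(np.ndarray):
        pass

    def __init__(self, feature_range: tuple[float, float] = (-1.0, 1.0)):
        self.lo, self.hi = feature_range
        if not self.lo < self.hi:
            raise ValueError("empty feature range")
        self.data_min_: np.ndarray | None = None
        self.data_max_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if isinstance(X, FeatureScaler._Scaled):
            raise ValueError("matrix is already scaled; refusing to scale twice")
        if self.data_min_ is None:
            raise ValueError("scaler not fitted")
        X = np.asarray(X, dtype=float)
        span = self.data_max_ - self.data_min_
        mid = 0.5 * (self.lo + self.hi)
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = self.lo + (X - self.data_min_) * (self.hi - self.lo) / span
        scaled = np.where(span == 0, mid, scaled)
        return scaled.view(FeatureScaler._Scaled)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def to_dict(self) -> dict:
        return {
            "lo": self.lo,
            "hi": self.hi,
            "data_min": self.data_min_.tolist(),
            "data_max": self.data_max_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        scaler = cls((d["lo"], d["hi"]))
        scaler.data_min_ = np.asarray(d["data_min"], dtype=float)
        scaler.data_max_ = np.asarray(d["data_max"], dtype=float)
        return scaler


@dataclass(frozen=True)
class FoldResult:
    rep: int
    fold: int
    counts: ConfusionCounts


@dataclass
class EvaluationReport:
    """Per-fold confusion counts plus fold-averaged and pooled metrics."""

    folds: list[FoldResult]
    metadata: dict = field(default_factory=dict)

    def fold_metrics(self) -> list[Metrics]:
        return [metrics(f.counts) for f in self.folds]

    @property
    def mean_metrics(self) -> Metrics:
        ms = self.fold_metrics()
        return Metrics(
            sn=float(np.mean([m.sn for m in ms])),
            sp=float(np.mean([m.sp for m in ms])),
            acc=float(np.mean([m.acc for m in ms])),
            mcc=float(np.mean([m.mcc for m in ms])),
        )

    @property
    def pooled_counts(self) -> ConfusionCounts:
        total = ConfusionCounts(0, 0, 0, 0)
        for f in self.folds:
            total = total + f.counts
        return total

    @property
    def pooled_metrics(self) -> Metrics:
        return metrics(self.pooled_counts)

    def per_rep_mcc(self) -> np.ndarray:
        """Mean per-fold MCC within each repetition."""
        reps = sorted({f.rep for f in self.folds})
        ms = {f: m for f, m in zip(self.folds, self.fold_metrics())}
        return np.array(
            [
                np.mean([ms[f].mcc for f in self.folds if f.rep == r])
                for r in reps
            ]
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for f, m in zip(self.folds, self.fold_metrics()):
            rows.append(
                {
                    "rep": f.rep,
                    "fold": f.fold,
                    "tp": f.counts.tp,
                    "tn": f.counts.tn,
                    "fp": f.counts.fp,
                    "fn": f.counts.fn,
                    "sn": m.sn,
                    "sp": m.sp,
                    "acc": m.acc,
                    "mcc": m.mcc,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        """Canonical (byte-stable) JSON rendering of the full report."""
        mean = self.mean_metrics
        pooled = self.pooled_metrics
        payload = {
            "metadata": self.metadata,
            "folds": [
                {
                    "rep": f.rep,
                    "fold": f.fold,
                    "tp": f.counts.tp,
                    "tn": f.counts.tn,
                    "fp": f.counts.fp,
                    "fn": f.counts.fn,
                }
                for f in self.folds
            ],
            "mean_metrics": {
                "sn": repr(mean.sn),
                "sp": repr(mean.sp),
                "acc": repr(mean.acc),
                "mcc": repr(mean.mcc),
            },
            "pooled_metrics": {
                "sn": repr(pooled.sn),
                "sp": repr(pooled.sp),
                "acc": repr(pooled.acc),
                "mcc": repr(pooled.mcc),
            },
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":"))


def _fold_assignments(
    n: int, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.asarray(part) for part in np.array_split(perm, n_folds)]


def _grouped_fold_assignments(
    chain_ids: Sequence[str], n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Fold assignment keeping all segments of one chain in one fold."""
    chains = sorted(set(chain_ids))
    order = rng.permutation(len(chains))
    fold_of_chain = {}
    for k, ci in enumerate(order):
        fold_of_chain[chains[ci]] = k % n_folds
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for i, cid in enumerate(chain_ids):
        folds[fold_of_chain[cid]].append(i)
    return [np.asarray(f, dtype=int) for f in folds]


def _fit_and_eval_fold(
    train: list[Segment],
    test: list[Segment],
    cfg: FeatureConfig,
    mode: str,
    background: str,
    svm_c: float,
    svm_gamma,
) -> ConfusionCounts:
    if mode == "pwsm":
        pos = [s.residues for s in train if s.is_positive]
        neg = [s.residues for s in train if not s.is_positive]
        pair = build_pair(pos, neg, RESIDUE_ALPHABET, background=background)
        codes = _pwsm._encode([s.residues for s in test], RESIDUE_ALPHABET)
        s_pos, s_neg = pair.score_pair_many(codes)
        y_pred = (s_pos > s_neg).astype(int)
    elif mode == "svm":
        models = fit_channels(train, cfg, background=background)
        X_train, y_train = featurize_batch(train, models)
        X_test, _ = featurize_batch(test, models)
        scaler = FeatureScaler()
        X_train_s = scaler.fit_transform(X_train)
        X_test_s = scaler.transform(X_test)
        gamma = svm_gamma if svm_gamma is not None else 1.0 / X_train.shape[1]
        clf = SVC(C=svm_c, kernel="rbf", gamma=gamma)
        clf.fit(np.asarray(X_train_s), y_train)
        y_pred = clf.predict(np.asarray(X_test_s))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    y_true = np.array([1 if s.is_positive else 0 for s in test])
    return confusion_from_labels(y_true, y_pred)


def cross_validate(
    segments: Sequence[Segment],
    cfg: FeatureConfig,
    *,
    mode: str = "svm",
    n_folds: int = 5,
    n_reps: int = 10,
    seed: int = 0,
    background: str = "pooled",
    svm_c: float = 1.0,
    svm_gamma=None,
    group_by_chain: bool = False,
) -> EvaluationReport:
    """Balanced-subsampling repeated k-fold cross-validation.

    For each repetition, negatives are subsampled to the positive count,
    the balanced set is shuffled and split into ``n_folds`` folds, and every
    model component (channel models, scaling, SVM) is refitted inside each
    training split.  Metrics are reported per fold.
    """
    positives = [s for s in segments if s.is_positive]
    negatives = [s for s in segments if not s.is_positive]
    if len(positives) < n_folds:
        raise ValueError(f"need at least {n_folds} positive segments")
    master = np.random.default_rng(seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=n_reps)
    fold_seeds = master.integers(0, 2**31 - 1, size=n_reps)

    folds: list[FoldResult] = []
    for rep in range(n_reps):
        sampled = balanced_subsample(negatives, len(positives), int(rep_seeds[rep]))
        data = positives + sampled
        rng = np.random.default_rng(int(fold_seeds[rep]))
        if group_by_chain:
            assignments = _grouped_fold_assignments(
                [s.chain_id for s in data], n_folds, rng
            )
        else:
            assignments = _fold_assignments(len(data), n_folds, rng)
        for k, test_idx in enumerate(assignments):
            test_mask = np.zeros(len(data), dtype=bool)
            test_mask[test_idx] = True
            train = [s for i, s in enumerate(data) if not test_mask[i]]
            test = [s for i, s in enumerate(data) if test_mask[i]]
            counts = _fit_and_eval_fold(
                train, test, cfg, mode, background, svm_c, svm_gamma
            )
            folds.append(FoldResult(rep=rep, fold=k, counts=counts))

    return EvaluationReport(
        folds=folds,
        metadata={
            "mode": mode,
            "channels": list(cfg.channels),
            "L": cfg.L,
            "n_folds": n_folds,
            "n_reps": n_reps,
            "seed": seed,
            "background": background,
            "svm_c": svm_c,
            "svm_gamma": "auto" if svm_gamma is None else svm_gamma,
            "group_by_chain": group_by_chain,
        },
    )


@dataclass
class ModelBundle:
    """Everything prediction needs: channel models, scaling, SVM, config."""

    mode: str  # "svm" | "pwsm"
    config: FeatureConfig
    window: WindowConfig
    ion: str | None = None
    channel_models: ChannelModels | None = None
    scaler: FeatureScaler | None = None
    svm: SVC | None = None
    pwsm_pair: PwsmPair | None = None


def train_final(
    segments: Sequence[Segment],
    cfg: FeatureConfig,
    *,
    mode: str = "svm",
    seed: int = 0,
    background: str = "pooled",
    svm_c: float = 1.0,
    svm_gamma=None,
    balance: bool = True,
    ion: str | None = None,
) -> ModelBundle:
    """Train a deployable model on (by default) a balanced training set."""
    if not segments:
        raise ValueError("empty training set")
    positives = [s for s in segments if s.is_positive]
    negatives = [s for s in segments if not s.is_positive]
    if not positives or not negatives:
        raise ValueError("training set must contain both classes")
    if balance and len(negatives) > len(positives):
        negatives = balanced_subsample(negatives, len(positives), seed)
    data = positives + negatives

    window = WindowConfig(cfg.L)
    bundle = ModelBundle(mode=mode, config=cfg, window=window, ion=ion)
    if mode == "pwsm":
        bundle.pwsm_pair = build_pair(
            [s.residues for s in positives],
            [s.residues for s in negatives],
            RESIDUE_ALPHABET,
            background=background,
        )
    elif mode == "svm":
        models = fit_channels(data, cfg, background=background)
        X, y = featurize_batch(data, models)
        scaler = FeatureScaler()
        Xs = scaler.fit_transform(X)
        gamma = svm_gamma if svm_gamma is not None else 1.0 / X.shape[1]
        clf = SVC(C=svm_c, kernel="rbf", gamma=gamma)
        clf.fit(np.asarray(Xs), y)
        bundle.channel_models = models
        bundle.scaler = scaler
        bundle.svm = clf
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return bundle


def predict_chain(bundle: ModelBundle, chain: ProteinChain) -> pd.DataFrame:
    """Window every residue of ``chain`` and call each one.

    Returns a frame with columns ``chain_id, position, residue, call,
    s_pos, s_neg, svm_decision`` (decision NaN in PWSM-only mode).
    """
    segments = extract_segments(chain, bundle.window)
    if bundle.mode == "pwsm":
        codes = _pwsm._encode([s.residues for s in segments], RESIDUE_ALPHABET)
        s_pos, s_neg = bundle.pwsm_pair.score_pair_many(codes)
        calls = (s_pos > s_neg).astype(int)
        decision = np.full(len(segments), np.nan)
    else:
        models = bundle.channel_models
        X, _ = featurize_batch(segments, models)
        Xs = bundle.scaler.transform(X)
        calls = bundle.svm.predict(np.asarray(Xs))
        decision = bundle.svm.decision_function(np.asarray(Xs))
        if "s_p" in models.pairs:
            codes = _pwsm._encode([s.residues for s in segments], RESIDUE_ALPHABET)
            s_pos, s_neg = models.pairs["s_p"].score_pair_many(codes)
        else:
            s_pos = np.full(len(segments), np.nan)
            s_neg = np.full(len(segments), np.nan)
    return pd.DataFrame(
        {
            "chain_id": chain.id,
            "position": [s.center for s in segments],
            "residue": list(chain.sequence),
            "call": ["positive" if c else "negative" for c in calls],
            "s_pos": s_pos,
            "s_neg": s_neg,
            "svm_decision": decision,
        }
    )


# ---------------------------------------------------------------------------
# bundle persistence
# ---------------------------------------------------------------------------

def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    """Serialize to a directory: JSON manifest, text PWSMs, joblib SVM."""
    path = Path(path)
    if path.exists():
        shutil.rmtree(path)
    path.mkdir(parents=True)
    manifest = {
        "mode": bundle.mode,
        "channels": list(bundle.config.channels),
        "L": bundle.config.L,
        "ion": bundle.ion,
    }
    if bundle.mode == "pwsm":
        save_matrix(bundle.pwsm_pair.positive, path / "pwsm_positive.txt")
        save_matrix(bundle.pwsm_pair.negative, path / "pwsm_negative.txt")
    else:
        models = bundle.channel_models
        for channel, pair in models.pairs.items():
            save_matrix(pair.positive, path / f"{channel}_positive.txt")
            save_matrix(pair.negative, path / f"{channel}_negative.txt")
        if models.id_positive is not None:
            manifest["id_sources"] = {
                "positive": models.id_positive.counts.tolist(),
                "negative": models.id_negative.counts.tolist(),
            }
        manifest["scaler"] = bundle.scaler.to_dict()
        joblib.dump(bundle.svm, path / "svm.joblib")
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_bundle(path: str | Path) -> ModelBundle:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    cfg = FeatureConfig(tuple(manifest["channels"]), manifest["L"])
    window = WindowConfig(manifest["L"])
    bundle = ModelBundle(
        mode=manifest["mode"], config=cfg, window=window, ion=manifest.get("ion")
    )
    if manifest["mode"] == "pwsm":
        bundle.pwsm_pair = PwsmPair(
            positive=load_matrix(path / "pwsm_positive.txt"),
            negative=load_matrix(path / "pwsm_negative.txt"),
        )
    else:
        models = ChannelModels(config=cfg)
        for channel in cfg.channels:
            pos_file = path / f"{channel}_positive.txt"
            if pos_file.exists():
                models.pairs[channel] = PwsmPair(
                    positive=load_matrix(pos_file),
                    negative=load_matrix(path / f"{channel}_negative.txt"),
                )
        if "id_sources" in manifest:
            models.id_positive = DiversitySource(
                np.asarray(manifest["id_sources"]["positive"])
            )
            models.id_negative = DiversitySource(
                np.asarray(manifest["id_sources"]["negative"])
            )
        bundle.channel_models = models
        bundle.scaler = FeatureScaler.from_dict(manifest["scaler"])
        bundle.svm = joblib.load(path / "svm.joblib")
    return bundle
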