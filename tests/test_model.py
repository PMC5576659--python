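import math

import numpy as np
import pytest

from metseg.features import CHANNELS, FeatureConfig
from metseg.model import (
    ConfusionCounts,
    FeatureScaler,
    balanced_subsample,
    confusion_from_labels,
    cross_validate,
    load_bundle,
    metrics,
    predict_chain,
    save_bundle,
    train_final,
)
from metseg.segio import ProteinChain, WindowConfig, extract_segments
from metseg.synthetic import (
    SimulationSpec,
    generate_dataset,
    shuffle_labels,
    strong_signal_spec,
)


def brute_force_counts(y_true, y_pred):
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 0:
            tn += 1
        elif t == 0 and p == 1:
            fp += 1
        else:
            fn += 1
    return ConfusionCounts(tp, tn, fp, fn)


class TestMetrics:
    def test_worked_value(self):
        m = metrics(ConfusionCounts(tp=8, tn=7, fp=3, fn=2))
        assert m.sn == pytest.approx(80.0)
        assert m.sp == pytest.approx(70.0)
        assert m.acc == pytest.approx(75.0)
        assert m.mcc == pytest.approx(50 / math.sqrt(9900))
        assert m.mcc == pytest.approx(0.5025, abs=1e-4)

    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert (m.sn, m.sp, m.acc) == (100.0, 100.0, 100.0)
        assert m.mcc == pytest.approx(1.0)

    def test_undefined_metrics_are_nan_not_zero(self):
        m = metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert math.isnan(m.sn)
        assert math.isnan(m.mcc)
        assert m.sp == pytest.approx(100.0)

    def test_random_labels_mcc_near_zero(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 2, size=10_000)
        y_pred = rng.integers(0, 2, size=10_000)
        m = metrics(confusion_from_labels(y_true, y_pred))
        assert abs(m.mcc) < 0.05

    def test_oracle_equivalence_random_cases(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            n = int(rng.integers(4, 50))
            y_true = rng.integers(0, 2, size=n)
            y_pred = rng.integers(0, 2, size=n)
            mine = confusion_from_labels(y_true, y_pred)
            oracle = brute_force_counts(y_true, y_pred)
            assert mine == oracle
            assert mine.total == n


class TestBalancedSubsample:
    def test_deterministic(self):
        negs = list(range(100))
        a = balanced_subsample(negs, 10, rep_seed=3)
        b = balanced_subsample(negs, 10, rep_seed=3)
        assert a == b
        assert len(a) == 10
        assert len(set(a)) == 10

    def test_different_seeds_differ_and_cover(self):
        negs = list(range(100))
        union = set()
        draws = [tuple(balanced_subsample(negs, 10, rep_seed=s)) for s in range(10)]
        for d in draws:
            union.update(d)
        assert len(set(draws)) > 1
        assert len(union) > 10

    def test_too_few_negatives(self):
        with pytest.raises(ValueError):
            balanced_subsample([1, 2], 5, rep_seed=0)


class TestFeatureScaler:
    def test_range_and_order_preserved(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 4))
        scaler = FeatureScaler()
        Xs = scaler.fit_transform(X)
        assert np.asarray(Xs).min() >= -1.0 - 1e-12
        assert np.asarray(Xs).max() <= 1.0 + 1e-12
        col = X[:, 0]
        scaled_col = np.asarray(Xs)[:, 0]
        assert (np.argsort(col) == np.argsort(scaled_col)).all()

    def test_constant_feature_maps_to_midpoint(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        Xs = FeatureScaler().fit_transform(X)
        assert np.allclose(np.asarray(Xs)[:, 0], 0.0)

    def test_double_scaling_rejected(self):
        X = np.random.default_rng(3).normal(size=(20, 3))
        scaler = FeatureScaler()
        Xs = scaler.fit_transform(X)
        with pytest.raises(ValueError, match="already scaled"):
            scaler.transform(Xs)

    def test_round_trip_dict(self):
        X = np.random.default_rng(4).normal(size=(20, 3))
        scaler = FeatureScaler().fit(X)
        back = FeatureScaler.from_dict(scaler.to_dict())
        np.testing.assert_allclose(
            np.asarray(back.transform(X)), np.asarray(scaler.transform(X))
        )


@pytest.fixture(scope="module")
def strong_segments():
    chains, _ = generate_dataset(strong_signal_spec(seed=1, n_chains=100))
    return [s for c in chains for s in extract_segments(c, WindowConfig(7))]


class TestCrossValidate:
    def test_pwsm_strong_signal(self, strong_segments):
        cfg = FeatureConfig(("s_p",), 7)
        report = cross_validate(
            strong_segments, cfg, mode="pwsm", n_reps=3, seed=5
        )
        assert report.mean_metrics.mcc >= 0.9
        assert len(report.folds) == 15

    def test_label_shuffle_null(self, strong_segments):
        cfg = FeatureConfig(("s_p",), 7)
        shuffled = shuffle_labels(strong_segments, seed=3)
        report = cross_validate(shuffled, cfg, mode="pwsm", n_reps=3, seed=5)
        assert abs(report.mean_metrics.mcc) <= 0.1

    def test_reproducible_from_seed(self, strong_segments):
        cfg = FeatureConfig(("s_p",), 7)
        a = cross_validate(strong_segments, cfg, mode="pwsm", n_reps=2, seed=9)
        b = cross_validate(strong_segments, cfg, mode="pwsm", n_reps=2, seed=9)
        assert a.to_json() == b.to_json()

    def test_requires_enough_positives(self):
        chain = ProteinChain(id="c", sequence="ACDEFGHIKL", binding_positions={2})
        segs = extract_segments(chain, WindowConfig(7))
        with pytest.raises(ValueError):
            cross_validate(segs, FeatureConfig(("s_p",), 7), mode="pwsm")

    def test_group_by_chain_respects_chains(self, strong_segments):
        cfg = FeatureConfig(("s_p",), 7)
        report = cross_validate(
            strong_segments, cfg, mode="pwsm", n_reps=1, seed=2,
            group_by_chain=True,
        )
        assert len(report.folds) == 5
        assert report.mean_metrics.mcc > 0.8

    def test_uninformative_data_near_zero(self):
        spec = SimulationSpec(
            n_chains=60, chain_length=100, site_density=2.0, theta=0.0,
            with_annotations=False, seed=8,
        )
        chains, _ = generate_dataset(spec)
        segs = [s for c in chains for s in extract_segments(c, WindowConfig(7))]
        report = cross_validate(
            segs, FeatureConfig(("s_p",), 7), mode="pwsm", n_reps=3, seed=1
        )
        assert abs(report.mean_metrics.mcc) < 0.15

    def test_report_accessors(self, strong_segments):
        cfg = FeatureConfig(("s_p",), 7)
        report = cross_validate(strong_segments, cfg, mode="pwsm", n_reps=2, seed=5)
        df = report.to_dataframe()
        assert set(df.columns) >= {"rep", "fold", "tp", "tn", "fp", "fn", "mcc"}
        assert len(df) == 10
        pooled = report.pooled_counts
        assert pooled.total == sum(f.counts.total for f in report.folds)
        assert report.per_rep_mcc().shape == (2,)


class TestTrainPredict:
    def test_pwsm_bundle_recovers_planted_sites(self, strong_segments):
        cfg = FeatureConfig(("s_p",), 7)
        bundle = train_final(strong_segments, cfg, mode="pwsm", seed=0)
        chains, _ = generate_dataset(strong_signal_spec(seed=1, n_chains=100))
        hits = total = 0
        for chain in chains[:20]:
            calls = predict_chain(bundle, chain)
            called = set(
                calls.loc[calls["call"] == "positive", "position"].tolist()
            )
            hits += len(called & chain.binding_positions)
            total += len(chain.binding_positions)
        assert total > 0
        assert hits / total >= 0.9

    def test_svm_bundle_round_trip(self, tmp_path):
        spec = SimulationSpec(n_chains=30, chain_length=80, seed=6)
        chains, _ = generate_dataset(spec)
        segs = [s for c in chains for s in extract_segments(c, WindowConfig(7))]
        cfg = FeatureConfig(CHANNELS, 7)
        bundle = train_final(segs, cfg, mode="svm", seed=0)
        out = predict_chain(bundle, chains[0])
        save_bundle(bundle, tmp_path / "bundle")
        loaded = load_bundle(tmp_path / "bundle")
        out2 = predict_chain(loaded, chains[0])
        np.testing.assert_allclose(out["svm_decision"], out2["svm_decision"])
        assert (out["call"] == out2["call"]).all()
        np.testing.assert_allclose(out["s_pos"], out2["s_pos"])

    def test_pwsm_bundle_round_trip(self, strong_segments, tmp_path):
        cfg = FeatureConfig(("s_p",), 7)
        bundle = train_final(strong_segments, cfg, mode="pwsm", seed=0)
        save_bundle(bundle, tmp_path / "bundle")
        loaded = load_bundle(tmp_path / "bundle")
        chains, _ = generate_dataset(strong_signal_spec(seed=1, n_chains=2))
        a = predict_chain(bundle, chains[0])
        b = predict_chain(loaded, chains[0])
        np.testing.assert_allclose(a["s_pos"], b["s_pos"])
        assert (a["call"] == b["call"]).all()

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            train_final([], FeatureConfig(("s_p",), 7), mode="pwsm")

    def test_prediction_output_schema(self, strong_segments):
        cfg = FeatureConfig(("s_p",), 7)
        bundle = train_final(strong_segments, cfg, mode="pwsm", seed=0)
        chain = ProteinChain(id="c", sequence="ACDEFGHIKL")
        out = predict_chain(bundle, chain)
        assert list(out.columns) == [
            "chain_id", "position", "residue", "call", "s_pos", "s_neg",
            "svm_decision",
        ]
        assert len(out) == 10
        assert (out["position"] == np.arange(1, 11)).all()
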