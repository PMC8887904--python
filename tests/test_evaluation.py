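"""Evaluation protocol: splits, grid search, metrics, null, worked examples."""

import numpy as np
import pytest

from tlemri.evaluation import (
    ConfusionMatrix,
    HyperGrid,
    MetricsSummary,
    OptimalParams,
    StudyProtocol,
    evaluate_on_test,
    grid_search,
    majority_baseline_accuracy,
    p_value,
    pooled_t,
    run_permutation_null,
    run_protocol,
    stratified_split,
)
from tlemri.exceptions import ConfigurationError
from tlemri.models import CNNSpec, TrainConfig

from .conftest import toy_dataset

FAST_GRID = HyperGrid(learning_rates=(0.05,), epochs=(15,), validation_frequencies=(5,))
FAST_CFG = TrainConfig(learning_rate=0.05, epochs=15, validation_frequency=5)


def auc_brute_force(y_true, scores):
    """All-pairs concordance count; ties count one half."""
    pos = [s for s, y in zip(scores, y_true) if y == 1]
    neg = [s for s, y in zip(scores, y_true) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestStratifiedSplit:
    def test_study_scale_floor_rule(self):
        ds = toy_dataset(n_tle=95, n_hc=202)
        train_val, test = stratified_split(ds, 0.2, rng=0)
        assert test.class_counts() == {"TLE": 19, "HC": 40}
        assert train_val.class_counts() == {"TLE": 76, "HC": 162}

    def test_partitions_disjoint_and_exhaustive(self):
        ds = toy_dataset(n_tle=12, n_hc=20)
        train_val, test = stratified_split(ds, 0.25, rng=5)
        ids = set(train_val.subject_ids) | set(test.subject_ids)
        assert len(ids) == len(ds)
        assert not set(train_val.subject_ids) & set(test.subject_ids)

    def test_zero_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            stratified_split(toy_dataset(10, 10), 0.0, rng=0)

    def test_deterministic_for_fixed_rng(self):
        ds = toy_dataset(n_tle=15, n_hc=25)
        a = stratified_split(ds, 0.2, rng=3)
        b = stratified_split(ds, 0.2, rng=3)
        assert a[1].subject_ids == b[1].subject_ids


class TestMetrics:
    def test_printed_formula_example(self):
        cm = ConfusionMatrix(tp=82, fn=18, tn=87, fp=13)
        m = MetricsSummary.compute(cm)
        assert m.sen == pytest.approx(0.82)
        assert m.spc == pytest.approx(0.87)
        assert m.acc == pytest.approx(0.845)
        assert m.ppv == pytest.approx(82 / 95)
        assert m.npv == pytest.approx(87 / 105)

    def test_majority_prediction_on_study_test_split(self):
        # all-controls prediction on a 19 TLE / 40 HC test set
        cm = ConfusionMatrix(tp=0, fn=19, fp=0, tn=40)
        m = MetricsSummary.compute(cm)
        assert m.acc == pytest.approx(40 / 59)
        assert m.sen == 0.0
        assert np.isnan(m.ppv) and "ppv" in m.undefined

    def test_perfect_separation_gives_auc_one(self):
        y = [0, 0, 0, 1, 1]
        s = [0.1, 0.2, 0.3, 0.8, 0.9]
        cm = ConfusionMatrix.from_predictions(y, [x >= 0.5 for x in s])
        assert MetricsSummary.compute(cm, y, s).auc == 1.0

    def test_identities_hold_on_random_confusions(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(0, 30, 4)
            if tp + fp + fn + tn == 0:
                continue
            m = MetricsSummary.compute(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
            total = tp + fp + fn + tn
            assert m.acc == pytest.approx((tp + tn) / total)
            for val, num, den in [
                (m.sen, tp, tp + fn), (m.spc, tn, tn + fp),
                (m.ppv, tp, tp + fp), (m.npv, tn, tn + fn),
            ]:
                if den == 0:
                    assert np.isnan(val)
                else:
                    assert val == pytest.approx(num / den)

    def test_auc_equals_brute_force_concordance(self):
        rng = np.random.default_rng(1)
        for n in (20, 57, 200):
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            pred = (scores >= 0.5).astype(int)
            m = MetricsSummary.compute(ConfusionMatrix.from_predictions(y, pred), y, scores)
            assert m.auc == pytest.approx(auc_brute_force(y, scores), abs=1e-12)


class TestWorkedExamples:
    def test_age_pooled_t(self):
        assert pooled_t(39.4, 18.7, 95, 42.3, 14.5, 202) == pytest.approx(1.46, abs=0.005)

    def test_pooled_t_symmetry_and_hand_example(self):
        assert pooled_t(5.0, 1.0, 10, 5.0, 2.0, 10) == 0.0
        assert pooled_t(0, 1, 2, 1, 1, 2) == pytest.approx(1.00)

    def test_pooled_t_degenerate_n_rejected(self):
        with pytest.raises(ConfigurationError):
            pooled_t(0, 1, 1, 1, 1, 10)

    def test_majority_baseline(self):
        assert majority_baseline_accuracy(95, 202) == pytest.approx(0.680, abs=0.0005)
        assert majority_baseline_accuracy(50, 50) == 0.5
        assert majority_baseline_accuracy(0, 10) == 1.0
        with pytest.raises(ConfigurationError):
            majority_baseline_accuracy(0, 0)

    def test_p_value_definition(self):
        null = np.arange(100) / 100.0  # 0.00, 0.01, ..., 0.99
        assert p_value(0.98, null) == pytest.approx(0.02)
        assert p_value(2.0, null) == 0.0
        assert p_value(-1.0, null) == 1.0
        assert p_value(0.85, [0.4, 0.5, 0.9]) == pytest.approx(1 / 3)
        with pytest.raises(ValueError):
            p_value(0.5, [])


class TestGridSearch:
    def test_single_combination_returned(self, strong_cohort):
        gs = grid_search(strong_cohort, FAST_GRID, k=5, rng=0)
        assert gs.optimal.spec.conv_layers == CNNSpec.scaled().conv_layers
        assert len(gs.fold_accuracies) == 5
        assert gs.best_accuracy == max(gs.fold_accuracies)

    def test_unbuildable_combination_skipped_with_log(self, strong_cohort):
        grid = HyperGrid(
            conv_layer_options=(
                ((8, 70), (8, 2), (8, 2)),  # kernel exceeds 64-pixel image
                CNNSpec.scaled().conv_layers,
            ),
            learning_rates=(0.05,), epochs=(15,), validation_frequencies=(5,),
        )
        gs = grid_search(strong_cohort, grid, k=5, rng=0)
        assert gs.optimal.spec.conv_layers == CNNSpec.scaled().conv_layers
        assert len(gs.skipped) == 1

    def test_too_few_per_class_for_folds_rejected(self):
        ds = toy_dataset(n_tle=6, n_hc=20)
        with pytest.raises(ConfigurationError):
            grid_search(ds, FAST_GRID, k=10, rng=0)


class TestProtocol:
    def test_repeats_reproducible_and_metrics_recomputable(self, strong_cohort):
        a = run_protocol(strong_cohort, FAST_GRID, repeats=2, seed=4, k=5)
        b = run_protocol(strong_cohort, FAST_GRID, repeats=2, seed=4, k=5)
        assert [(c.tp, c.fp, c.fn, c.tn) for c in a.confusions] == [
            (c.tp, c.fp, c.fn, c.tn) for c in b.confusions
        ]
        # summary statistics recompute from the stored per-repeat values
        vals = np.array(a.metrics.values["acc"])
        assert a.metrics.mean("acc") == pytest.approx(np.nanmean(vals))

    def test_subgroup_metrics_reported_for_flagged_cohorts(self, strong_cohort):
        res = run_protocol(strong_cohort, FAST_GRID, repeats=2, seed=0, k=5)
        assert "lesional" in res.subgroup_metrics
        assert "seizure_free" in res.subgroup_metrics

    def test_leakage_guard_audit(self, strong_cohort):
        res = run_protocol(strong_cohort, FAST_GRID, repeats=2, seed=1, k=5)
        for entry in res.audit:
            assert not entry["test_ids"] & entry["train_ids"]
            assert not entry["test_ids"] & entry["smote_parent_ids"]

    def test_strong_effect_recovery(self, strong_cohort):
        res = run_protocol(strong_cohort, FAST_GRID, repeats=3, seed=2, k=5)
        assert res.metrics.mean("acc") >= 0.9

    def test_summary_table_lists_all_metrics(self, strong_cohort):
        res = run_protocol(strong_cohort, FAST_GRID, repeats=2, seed=0, k=5)
        text = res.summary()
        for m in ("PPV", "NPV", "SEN", "SPC", "AUC", "ACC"):
            assert m in text


class TestPermutationNull:
    def test_null_reproducible_and_near_chance(self, strong_cohort):
        opt = OptimalParams(spec=CNNSpec.scaled(), cfg=FAST_CFG)
        a = run_permutation_null(strong_cohort, opt, repeats=4, seed=6, k=5)
        b = run_permutation_null(strong_cohort, opt, repeats=4, seed=6, k=5)
        assert a.metrics.values["auc"] == b.metrics.values["auc"]
        assert 0.25 <= a.metrics.mean("auc") <= 0.75

    def test_null_accuracy_overlaps_majority_proportion(self, strong_cohort):
        opt = OptimalParams(spec=CNNSpec.scaled(), cfg=FAST_CFG)
        res = run_permutation_null(strong_cohort, opt, repeats=4, seed=0, k=5)
        majority = 30 / 50
        assert abs(res.metrics.mean("acc") - majority) < 0.3

    def test_correct_model_beats_null(self, strong_cohort):
        correct = run_protocol(strong_cohort, FAST_GRID, repeats=3, seed=2, k=5)
        opt = OptimalParams(spec=CNNSpec.scaled(), cfg=FAST_CFG)
        null = run_permutation_null(strong_cohort, opt, repeats=5, seed=2, k=5)
        pvals = correct.p_values(null)
        assert pvals["acc"] <= 0.2
        text = correct.summary(null)
        assert "p" in text


class TestStudyProtocolFacade:
    def test_fit_and_fit_null_roundtrip(self, strong_cohort, tmp_path):
        protocol = StudyProtocol(strong_cohort, grid=FAST_GRID, family="cnn", n_folds=5)
        res = protocol.fit(repeats=2, seed=0)
        assert len(res.metrics) == 2
        res.to_json(tmp_path / "results.json")
        import json

        payload = json.loads((tmp_path / "results.json").read_text())
        assert payload["metrics"]["acc"]["mean"] == pytest.approx(res.metrics.mean("acc"))

    def test_unknown_family_rejected(self, strong_cohort):
        with pytest.raises(ConfigurationError):
            StudyProtocol(strong_cohort, family="mlp")
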