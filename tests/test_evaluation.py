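"""Metric suite, ROC/PR areas, cross-validation, sweeps and grouped summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve

from phenoforest.classifier import ModelConfig, Prediction
from phenoforest.errors import ValidationError
from phenoforest.evaluation import (
    ConfusionMatrix,
    confusion,
    cross_validate,
    f1_from_precision_recall,
    grouped_performance,
    metric_report,
    paired_confidence_table,
    pr_auc,
    roc_auc,
    sweep_boundaries,
    sweep_table,
)
from phenoforest.synthetic_data import TemperatureSpec, generate_temperature_panel


def preds(calls_confs, trait="t"):
    return [
        Prediction(f"S{i}", trait, conf, "positive" if conf >= 0.5 else "negative")
        for i, conf in enumerate(calls_confs)
    ]


class TestConfusion:
    def test_all_correct(self):
        p = preds([0.9] * 5 + [0.1] * 5)
        truth = {f"S{i}": i < 5 for i in range(10)}
        assert confusion(p, truth) == ConfusionMatrix(5, 0, 0, 5)

    def test_all_inverted(self):
        p = preds([0.9] * 5 + [0.1] * 5)
        truth = {f"S{i}": i >= 5 for i in range(10)}
        assert confusion(p, truth) == ConfusionMatrix(0, 5, 5, 0)

    def test_hand_count(self):
        p = preds([0.8, 0.7, 0.2])  # pos, pos, neg
        truth = {"S0": True, "S1": False, "S2": True}
        assert confusion(p, truth) == ConfusionMatrix(1, 1, 1, 0)

    def test_missing_truth_label(self):
        with pytest.raises(ValidationError, match="S0"):
            confusion(preds([0.9]), {})


def brute_force_metrics(tp, fp, fn, tn):
    """Independent direct evaluation of the eight confusion-matrix formulas."""
    n = tp + fp + fn + tn
    out = {"accuracy": (tp + tn) / n if n else None}
    out["precision"] = tp / (tp + fp) if tp + fp else None
    out["recall"] = tp / (tp + fn) if tp + fn else None
    out["specificity"] = tn / (tn + fp) if tn + fp else None
    out["npv"] = tn / (tn + fn) if tn + fn else None
    out["f1"] = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else None
    den = math.sqrt((tp + fp) * (fn + tn) * (tp + fn) * (fp + tn))
    out["mcc"] = (tp * tn - fp * fn) / den if den else None
    out["norm_mcc"] = (out["mcc"] + 1) / 2 if out["mcc"] is not None else None
    return out


class TestMetricReport:
    def test_hand_derived_values(self):
        rep = metric_report(ConfusionMatrix(3, 1, 2, 4))
        assert rep.accuracy == pytest.approx(0.7)
        assert rep.precision == pytest.approx(0.75)
        assert rep.recall == pytest.approx(0.6)
        assert rep.specificity == pytest.approx(0.8)
        assert rep.npv == pytest.approx(2 / 3)
        assert rep.f1 == pytest.approx(2 / 3)
        assert rep.mcc == pytest.approx(0.40825, abs=1e-5)
        assert rep.norm_mcc == pytest.approx(0.70412, abs=1e-5)

    def test_perfect_classifier(self):
        rep = metric_report(
            ConfusionMatrix(5, 0, 0, 5),
            y_true=[True] * 5 + [False] * 5,
            y_score=[0.9] * 5 + [0.1] * 5,
        )
        for name in ("accuracy", "precision", "recall", "specificity", "npv",
                     "f1", "norm_mcc", "auc", "aupr"):
            assert getattr(rep, name) == 1.0

    def test_random_midpoint(self):
        rep = metric_report(ConfusionMatrix(1, 1, 1, 1))
        assert rep.mcc == 0.0
        assert rep.norm_mcc == 0.5

    def test_zero_denominators_flagged_not_zeroed(self):
        rep = metric_report(ConfusionMatrix(0, 0, 5, 5))
        assert rep.precision is None
        assert "precision" in rep.undefined
        assert rep.f1 == 0.0  # 2TP+FP+FN = 5 > 0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            metric_report(ConfusionMatrix(0, 0, 0, 0))

    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        fn=st.integers(0, 50), tn=st.integers(0, 50),
    )
    @settings(max_examples=300)
    def test_oracle_equivalence(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        rep = metric_report(ConfusionMatrix(tp, fp, fn, tn))
        for name, expected in brute_force_metrics(tp, fp, fn, tn).items():
            got = getattr(rep, name)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    @given(
        tp=st.integers(0, 30), fp=st.integers(0, 30),
        fn=st.integers(0, 30), tn=st.integers(0, 30),
    )
    @settings(max_examples=200)
    def test_call_swap_antisymmetry(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        rep = metric_report(ConfusionMatrix(tp, fp, fn, tn))
        swapped = metric_report(ConfusionMatrix(fn, tn, tp, fp))
        if rep.mcc is not None and swapped.mcc is not None:
            assert swapped.mcc == pytest.approx(-rep.mcc, abs=1e-12)
            assert swapped.norm_mcc == pytest.approx(1 - rep.norm_mcc, abs=1e-12)

    def test_accuracy_blind_to_imbalance_f1_not(self):
        # a 2%-prevalence set where the model misses half the positives
        rep = metric_report(ConfusionMatrix(tp=5, fp=30, fn=5, tn=460))
        assert rep.accuracy > 0.9
        assert rep.f1 < 0.5


class TestF1Identity:
    def test_equal_precision_recall(self):
        assert f1_from_precision_recall(0.7, 0.7) == pytest.approx(0.7)

    def test_imbalanced_rows(self):
        assert f1_from_precision_recall(0.130, 0.750) == pytest.approx(0.22, abs=0.005)
        assert f1_from_precision_recall(0.062, 0.857) == pytest.approx(0.12, abs=0.005)

    def test_degenerate_undefined(self):
        assert f1_from_precision_recall(0.0, 0.0) is None

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            f1_from_precision_recall(1.2, 0.5)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([True, True, False, False], [0.9, 0.8, 0.3, 0.1]) == 1.0

    def test_brute_force_half(self):
        # pairs: (.8,.6)+, (.8,.4)+, (.2,.6)-, (.2,.4)- → 2/4
        assert roc_auc([True, True, False, False], [0.8, 0.2, 0.6, 0.4]) == 0.5

    def test_all_ties(self):
        assert roc_auc([True, False], [0.7, 0.7]) == 0.5

    def test_single_class_undefined(self):
        assert roc_auc([True, True], [0.2, 0.4]) is None

    def test_rank_form_equals_trapezoid(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(5, 200)
            y = rng.random(n) < 0.4
            if y.all() or not y.any():
                continue
            s = np.round(rng.random(n), 2)  # rounding forces ties
            fpr, tpr, _ = roc_curve(y, s)
            assert roc_auc(y, s) == pytest.approx(sk_auc(fpr, tpr), abs=1e-12)


class TestPrAuc:
    def test_perfect_separation(self):
        assert pr_auc([True, False], [0.9, 0.1]) == 1.0

    def test_constant_scores_give_prevalence(self):
        y = [True] * 2 + [False] * 8
        assert pr_auc(y, [0.5] * 10) == pytest.approx(0.2)

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(1)
        y = rng.random(5000) < 0.1
        s = rng.random(5000)
        assert pr_auc(y, s) == pytest.approx(0.1, abs=0.03)

    def test_no_positives_undefined(self):
        assert pr_auc([False, False], [0.3, 0.2]) is None


class TestCrossValidate:
    def test_mean_report_on_separable_panel(self, separable_panel):
        matrix, dataset, _ = separable_panel
        cv = cross_validate(matrix, dataset, ModelConfig(seed=0), k=5)
        assert len(cv.fold_reports) == 5
        assert cv.mean.f1 == pytest.approx(1.0)

    def test_determinism(self, separable_panel):
        matrix, dataset, _ = separable_panel
        cv1 = cross_validate(matrix, dataset, ModelConfig(seed=4), k=3)
        cv2 = cross_validate(matrix, dataset, ModelConfig(seed=4), k=3)
        assert cv1.fold_reports == cv2.fold_reports

    def test_class_smaller_than_k_rejected(self, separable_panel):
        matrix, dataset, _ = separable_panel
        from phenoforest.trait_curation import BinaryTraitDataset

        small = BinaryTraitDataset(
            "t", frozenset(sorted(dataset.positives)[:3]), dataset.negatives
        )
        with pytest.raises(ValidationError):
            cross_validate(matrix, small, k=5)


@pytest.fixture(scope="module")
def temp_panel():
    return generate_temperature_panel(
        TemperatureSpec(n_strains=250, n_features=80, discordant_fraction=0, seed=0)
    )


class TestSweep:

    def test_one_row_per_boundary(self, temp_panel):
        matrix, records, _ = temp_panel
        rows = sweep_boundaries(matrix, records, [35, 40, 45], gap_width=5,
                                config=ModelConfig(seed=0), k=3)
        assert [r.boundary_low for r in rows] == [35, 40, 45]
        for r in rows:
            assert r.n_pos + r.n_neg + r.n_excluded == 250

    def test_out_of_range_boundary_flagged(self, temp_panel):
        matrix, records, _ = temp_panel
        rows = sweep_boundaries(matrix, records, [40, 500], gap_width=5,
                                config=ModelConfig(seed=0), k=3)
        assert rows[1].flagged and rows[1].report is None
        assert not rows[0].flagged

    def test_table_export_and_determinism(self, temp_panel):
        matrix, records, _ = temp_panel
        rows1 = sweep_boundaries(matrix, records, [40, 45], 5, ModelConfig(seed=1), k=3)
        rows2 = sweep_boundaries(matrix, records, [40, 45], 5, ModelConfig(seed=1), k=3)
        assert sweep_table(rows1).equals(sweep_table(rows2))

    def test_too_few_boundaries_rejected(self, temp_panel):
        matrix, records, _ = temp_panel
        with pytest.raises(ValidationError):
            sweep_boundaries(matrix, records, [40], 5)


class TestGroupedPerformance:
    def test_low_n_flag_and_accuracy(self):
        p = preds([0.9] * 6 + [0.8] * 12)
        truth = {f"S{i}": True for i in range(18)}
        groups = {f"S{i}": "rare" if i < 6 else "common" for i in range(18)}
        res = grouped_performance(p, truth, groups)
        by_name = {g.group: g for g in res.groups}
        assert by_name["rare"].low_n_flag and by_name["rare"].n_annotations == 6
        assert not by_name["common"].low_n_flag
        assert by_name["common"].accuracy == 1.0

    def test_groups_computed_independently(self):
        p = preds([0.9, 0.1])
        truth = {"S0": True, "S1": True}
        groups = {"S0": "a", "S1": "b"}
        res = grouped_performance(p, truth, groups)
        accs = {g.group: g.accuracy for g in res.groups}
        assert accs == {"a": 1.0, "b": 0.0}

    def test_negative_call_certainty_used(self):
        p = preds([0.1])  # negative call, certainty 0.9
        res = grouped_performance(p, {"S0": False}, {"S0": "g"})
        assert res.groups[0].median_confidence == pytest.approx(0.9)


class TestPairedConfidenceTable:
    def test_pass_through(self):
        a = preds([0.9, 0.2, 0.7], trait="A")
        b = preds([0.1, 0.8, 0.3], trait="B")
        table = paired_confidence_table(a, b, {"S0": "aerobe"})
        assert len(table) == 3
        assert table.loc[table.strain_id == "S0", "conf_a"].item() == 0.9
        assert table.loc[table.strain_id == "S0", "true_state"].item() == "aerobe"

    def test_coverage_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            paired_confidence_table(preds([0.9, 0.1]), preds([0.9]), {})
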