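"""Confusion-matrix metric suite, ROC/PR analyses, cross-validation and sweeps.

Imbalanced trait datasets are the norm in genotype-to-phenotype work: a
model that predicts "negative" for everything can score 97% accuracy on a
2%-prevalence trait. The suite therefore reports, besides accuracy, the
class-conditional rates (precision, recall, specificity, NPV), the F1 score
(2TP/(2TP+FP+FN)), the Matthews correlation coefficient and its min-max
rescaling normMCC = (MCC+1)/2, plus threshold-free summaries (ROC-AUC and
the area under the precision–recall curve, whose baseline equals the class
prevalence).

Any metric with a zero denominator is reported as *undefined* (None, with
the name recorded in ``MetricReport.undefined``) rather than silently set
to 0 — silent zeros distort exactly the imbalanced comparisons the suite
exists for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedKFold

from .annotations_io import FeatureMatrix
from .classifier import ModelConfig, Prediction, TraitRandomForest, _design
from .errors import ValidationError
from .trait_curation import (
    BinaryTraitDataset,
    GapBinarizerConfig,
    TraitLabelRecord,
    binarize_with_gap,
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of true/false positive/negative calls."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


_METRIC_NAMES = (
    "accuracy", "precision", "recall", "specificity", "npv",
    "f1", "mcc", "norm_mcc", "auc", "aupr",
)


@dataclass(frozen=True)
class MetricReport:
    """The full metric suite; undefined metrics are None and listed by name."""

    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    specificity: float | None = None
    npv: float | None = None
    f1: float | None = None
    mcc: float | None = None
    norm_mcc: float | None = None
    auc: float | None = None
    aupr: float | None = None
    undefined: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in _METRIC_NAMES}


def confusion(
    predictions: Iterable[Prediction],
    truth: Mapping[str, bool],
) -> ConfusionMatrix:
    """Count the four confusion-matrix cells for a set of calls.

    ``truth`` maps strain id → actual positive/negative. Every predicted
    strain must have a truth label.
    """
    tp = fp = fn = tn = 0
    for pred in predictions:
        if pred.strain_id not in truth:
            raise ValidationError(f"no truth label for strain {pred.strain_id!r}")
        actual = bool(truth[pred.strain_id])
        called = pred.call == "positive"
        if called and actual:
            tp += 1
        elif called and not actual:
            fp += 1
        elif not called and actual:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp, fp, fn, tn)


def _ratio(num: float, den: float) -> float | None:
    return num / den if den else None


def metric_report(
    cm: ConfusionMatrix,
    y_true: Sequence[bool] | None = None,
    y_score: Sequence[float] | None = None,
) -> MetricReport:
    """Compute the full metric suite from a confusion matrix.

    ``y_true``/``y_score`` (per-strain truth and confidence) are needed only
    for the threshold-free AUC and AUPR; when omitted those two are
    undefined.
    """
    if cm.total < 1:
        raise ValidationError("confusion matrix must count at least one strain")
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    vals: dict[str, float | None] = {
        "accuracy": _ratio(tp + tn, cm.total),
        "precision": _ratio(tp, tp + fp),
        "recall": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "npv": _ratio(tn, tn + fn),
        "f1": _ratio(2 * tp, 2 * tp + fp + fn),
    }
    mcc_den = math.sqrt(
        float(tp + fp) * float(fn + tn) * float(tp + fn) * float(fp + tn)
    )
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den else None
    vals["mcc"] = mcc
    vals["norm_mcc"] = (mcc + 1) / 2 if mcc is not None else None
    vals["auc"] = roc_auc(y_true, y_score) if y_true is not None else None
    vals["aupr"] = pr_auc(y_true, y_score) if y_true is not None else None
    undefined = frozenset(name for name, v in vals.items() if v is None)
    return MetricReport(**vals, undefined=undefined)


def f1_from_precision_recall(p: float, r: float) -> float | None:
    """Harmonic mean 2pr/(p+r) of precision and recall; None when p = r = 0."""
    if not (0 <= p <= 1 and 0 <= r <= 1):
        raise ValidationError("precision and recall must lie in [0, 1]")
    if p + r == 0:
        return None
    return 2 * p * r / (p + r)


def roc_auc(
    y_true: Sequence[bool], y_score: Sequence[float]
) -> float | None:
    """Area under the ROC curve via the rank (Mann–Whitney) formulation.

    Equals the probability that a uniformly random positive outscores a
    uniformly random negative, with ties counted 1/2; identical to
    trapezoidal integration of the ROC curve. Undefined (None) when either
    class is empty.
    """
    y = np.asarray(y_true, dtype=bool)
    s = np.asarray(y_score, dtype=float)
    if y.shape != s.shape:
        raise ValidationError("y_true and y_score must have the same length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def pr_auc(
    y_true: Sequence[bool], y_score: Sequence[float]
) -> float | None:
    """Area under the precision–recall curve (non-interpolated step estimator).

    Uses the standard step-wise estimator Σ (R_k − R_{k−1}) · P_k (average
    precision); the curve's baseline equals the class prevalence. Undefined
    when there are no positives.
    """
    y = np.asarray(y_true, dtype=bool)
    s = np.asarray(y_score, dtype=float)
    if y.shape != s.shape:
        raise ValidationError("y_true and y_score must have the same length")
    if not y.any():
        return None
    return float(average_precision_score(y, s))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossValidationResult:
    """Per-fold metric reports plus their mean (over folds where defined)."""

    fold_reports: tuple[MetricReport, ...]
    mean: MetricReport
    k: int


def _mean_report(reports: Sequence[MetricReport]) -> MetricReport:
    vals: dict[str, float | None] = {}
    for name in _METRIC_NAMES:
        defined = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        vals[name] = float(np.mean(defined)) if defined else None
    undefined = frozenset(n for n, v in vals.items() if v is None)
    return MetricReport(**vals, undefined=undefined)


def cross_validate(
    matrix: FeatureMatrix,
    dataset: BinaryTraitDataset,
    config: ModelConfig = ModelConfig(),
    k: int = 5,
) -> CrossValidationResult:
    """Stratified k-fold cross-validation of a trait model.

    Folds partition the dataset's classified strains with per-fold class
    ratios within one strain of the global ratio; deterministic for a given
    ``config.seed``. Metrics are averaged across folds.
    """
    if min(dataset.n_pos, dataset.n_neg) < k:
        raise ValidationError(
            f"each class needs at least k={k} strains "
            f"(pos={dataset.n_pos}, neg={dataset.n_neg})"
        )
    X, y = _design(matrix, dataset)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    reports = []
    for train_idx, test_idx in skf.split(X, y):
        est = TraitRandomForest(
            n_estimators=config.n_trees,
            max_depth=config.max_depth,
            decision_threshold=config.decision_threshold,
            random_state=config.seed,
            class_weight=config.class_weight,
        ).fit(X.iloc[train_idx], y[train_idx])
        conf = est.confidence(X.iloc[test_idx])
        called = conf >= config.decision_threshold
        actual = y[test_idx]
        cm = ConfusionMatrix(
            tp=int((called & actual).sum()),
            fp=int((called & ~actual).sum()),
            fn=int((~called & actual).sum()),
            tn=int((~called & ~actual).sum()),
        )
        reports.append(metric_report(cm, y_true=actual, y_score=conf))
    return CrossValidationResult(tuple(reports), _mean_report(reports), k)


# ---------------------------------------------------------------------------
# Boundary sweep for continuous traits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepRow:
    """One boundary interval of a gap-binarization sweep."""

    boundary_low: float
    n_pos: int
    n_neg: int
    n_excluded: int
    flagged: bool
    report: MetricReport | None

    def __post_init__(self) -> None:
        if min(self.n_pos, self.n_neg, self.n_excluded) < 0:
            raise ValidationError("sweep counts must be non-negative")


def sweep_boundaries(
    matrix: FeatureMatrix,
    records: Sequence[TraitLabelRecord],
    boundaries: Sequence[float],
    gap_width: float = 5.0,
    config: ModelConfig = ModelConfig(),
    k: int = 5,
) -> list[SweepRow]:
    """Gap-binarize and cross-validate at each candidate class boundary.

    A boundary whose resulting classes are empty or smaller than ``k`` is
    reported as a flagged row (no metrics) rather than aborting the sweep.
    """
    if len(boundaries) < 2:
        raise ValidationError("need at least two boundaries to sweep")
    rows = []
    for b in boundaries:
        ds = binarize_with_gap(records, GapBinarizerConfig(b, gap_width))
        n_excluded = len(ds.excluded)
        if min(ds.n_pos, ds.n_neg) < k:
            rows.append(SweepRow(b, ds.n_pos, ds.n_neg, n_excluded, True, None))
            continue
        cv = cross_validate(matrix, ds, config, k=k)
        rows.append(SweepRow(b, ds.n_pos, ds.n_neg, n_excluded, False, cv.mean))
    return rows


def sweep_table(rows: Sequence[SweepRow]) -> pd.DataFrame:
    """Tabulate a sweep as a DataFrame (undefined metrics become NA)."""
    data = []
    for r in rows:
        rec = {
            "boundary_low": r.boundary_low,
            "n_pos": r.n_pos,
            "n_neg": r.n_neg,
            "n_excluded": r.n_excluded,
            "flagged": r.flagged,
        }
        rep = r.report.as_dict() if r.report else {m: None for m in _METRIC_NAMES}
        rec.update(rep)
        data.append(rec)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Grouped performance and paired-confidence export
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupPerformance:
    """Per-group accuracy and confidence summary (e.g. per phylum)."""

    group: str
    n_annotations: int
    accuracy: float
    median_confidence: float
    low_n_flag: bool

    def __post_init__(self) -> None:
        if self.low_n_flag != (self.n_annotations < 10):
            raise ValidationError("low_n_flag must equal (n_annotations < 10)")


@dataclass(frozen=True)
class GroupedPerformanceResult:
    groups: tuple[GroupPerformance, ...]
    overall_median_accuracy: float
    overall_median_confidence: float


def grouped_performance(
    predictions: Iterable[Prediction],
    truth: Mapping[str, bool],
    groups: Mapping[str, str],
) -> GroupedPerformanceResult:
    """Summarize call accuracy and confidence per strain group.

    The per-call confidence is the certainty of the accepted call
    (confidence for positive calls, 1 − confidence for negative calls).
    Groups with fewer than 10 annotations are flagged as statistically
    uncertain.
    """
    per_group: dict[str, list[tuple[bool, float]]] = {}
    for pred in predictions:
        if pred.strain_id not in groups:
            raise ValidationError(f"no group for strain {pred.strain_id!r}")
        if pred.strain_id not in truth:
            raise ValidationError(f"no truth label for strain {pred.strain_id!r}")
        correct = (pred.call == "positive") == bool(truth[pred.strain_id])
        certainty = pred.confidence if pred.call == "positive" else 1 - pred.confidence
        per_group.setdefault(groups[pred.strain_id], []).append((correct, certainty))
    results = []
    for group in sorted(per_group):
        entries = per_group[group]
        n = len(entries)
        results.append(
            GroupPerformance(
                group=group,
                n_annotations=n,
                accuracy=float(np.mean([c for c, _ in entries])),
                median_confidence=float(np.median([q for _, q in entries])),
                low_n_flag=n < 10,
            )
        )
    if results:
        overall_acc = float(np.median([g.accuracy for g in results]))
        overall_conf = float(np.median([g.median_confidence for g in results]))
    else:
        overall_acc = overall_conf = float("nan")
    return GroupedPerformanceResult(tuple(results), overall_acc, overall_conf)


def paired_confidence_table(
    predictions_a: Iterable[Prediction],
    predictions_b: Iterable[Prediction],
    truth_states: Mapping[str, str],
) -> pd.DataFrame:
    """One row per strain with both models' confidences and the true state.

    The table is the tabular form of the paired-confidence density analysis
    (suitable for external 2D-KDE plotting). Both prediction sets must cover
    exactly the same strains.
    """
    conf_a = {p.strain_id: p.confidence for p in predictions_a}
    conf_b = {p.strain_id: p.confidence for p in predictions_b}
    if set(conf_a) != set(conf_b):
        diff = set(conf_a) ^ set(conf_b)
        raise ValidationError(
            f"prediction sets cover different strains (e.g. {sorted(diff)[:5]})"
        )
    rows = []
    for strain in sorted(conf_a):
        rows.append(
            {
                "strain_id": strain,
                "conf_a": conf_a[strain],
                "conf_b": conf_b[strain],
                "true_state": truth_states.get(strain),
            }
        )
    return pd.DataFrame(rows, columns=["strain_id", "conf_a", "conf_b", "true_state"])
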