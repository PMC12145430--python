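"""Apply accepted models across a genome panel and audit against known data.

Only models that clear an F1 quality gate (default 0.8) are used to generate
predictions for a database. Predictions for (strain, trait) pairs that
already have curated annotations are compared against them — agreements
corroborate the curation, contradictions flag either model errors or
literature errors worth re-testing — while the remainder constitute entirely
new phenotype information. Exported records carry an explicit ``predicted``
provenance flag, the model version and the confidence, so downstream
consumers can distinguish computed from experimentally determined data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotations_io import FeatureMatrix
from .classifier import Prediction, TraitModel, predict
from .errors import ValidationError
from .evaluation import MetricReport

logger = logging.getLogger(__name__)

DEFAULT_F1_MIN = 0.8
DEFAULT_HIGH_CONF_BAR = 0.9


@dataclass(frozen=True)
class ModelAcceptance:
    """Outcome of the F1 quality gate over a set of candidate models."""

    accepted: tuple[str, ...]
    rejected: Mapping[str, str]


def accept_models(
    reports: Mapping[str, MetricReport | float],
    f1_min: float = DEFAULT_F1_MIN,
) -> ModelAcceptance:
    """Apply the F1 ≥ ``f1_min`` acceptance gate (inclusive boundary).

    ``reports`` maps trait name → MetricReport (or a bare F1 value). Models
    with an undefined F1 are rejected with an explicit reason.
    """
    accepted: list[str] = []
    rejected: dict[str, str] = {}
    for trait in sorted(reports):
        report = reports[trait]
        f1 = report if isinstance(report, (int, float)) else report.f1
        if f1 is None:
            rejected[trait] = "f1 undefined"
        elif f1 >= f1_min:
            accepted.append(trait)
        else:
            rejected[trait] = f"f1 {f1:.3f} below gate {f1_min}"
    return ModelAcceptance(tuple(accepted), rejected)


def predict_panel(
    models: Sequence[TraitModel],
    matrix: FeatureMatrix,
    zero_fill_missing: bool = False,
) -> pd.DataFrame:
    """Apply every accepted model to every strain of a genome panel.

    Returns exactly ``len(models) × n_strains`` rows with columns
    strain_id, trait, call, confidence.
    """
    if not models:
        logger.warning("no accepted models; returning an empty prediction table")
        return pd.DataFrame(columns=["strain_id", "trait", "call", "confidence"])
    rows = []
    for model in models:
        for pred in predict(model, matrix, zero_fill_missing=zero_fill_missing):
            rows.append(
                {
                    "strain_id": pred.strain_id,
                    "trait": pred.trait,
                    "call": pred.call,
                    "confidence": pred.confidence,
                }
            )
    return pd.DataFrame(rows, columns=["strain_id", "trait", "call", "confidence"])


@dataclass(frozen=True)
class EnrichmentAudit:
    """Bookkeeping of predictions against pre-existing annotations.

    Invariants: ``n_new = n_predicted − n_overlapping`` and
    ``n_agree + n_contradict = n_overlapping``.
    """

    n_predicted: int
    n_overlapping: int
    n_new: int
    n_agree: int
    n_contradict: int
    n_high_conf_contradict: int

    def __post_init__(self) -> None:
        if self.n_new != self.n_predicted - self.n_overlapping:
            raise ValidationError("n_new must equal n_predicted - n_overlapping")
        if self.n_agree + self.n_contradict != self.n_overlapping:
            raise ValidationError("n_agree + n_contradict must equal n_overlapping")

    @property
    def pct_new(self) -> float:
        """Share of predictions that are new information, in percent."""
        return 100 * self.n_new / self.n_predicted if self.n_predicted else 0.0

    @property
    def pct_agree(self) -> float:
        """Share of all predictions agreeing with existing data, in percent."""
        return 100 * self.n_agree / self.n_predicted if self.n_predicted else 0.0

    @property
    def pct_contradict(self) -> float:
        """Share of all predictions contradicting existing data, in percent."""
        return 100 * self.n_contradict / self.n_predicted if self.n_predicted else 0.0

    @property
    def consensus_of_overlap(self) -> float:
        """Agreements as a fraction of the overlapping records."""
        return self.n_agree / self.n_overlapping if self.n_overlapping else float("nan")


def audit(
    predictions: pd.DataFrame,
    existing: pd.DataFrame,
    high_conf_bar: float = DEFAULT_HIGH_CONF_BAR,
) -> EnrichmentAudit:
    """Compare a prediction table with pre-existing binary annotations.

    ``predictions`` needs columns strain_id, trait, call, confidence;
    ``existing`` needs strain_id, trait, state (``positive``/``negative``),
    deduplicated per (strain, trait). A contradiction counts as
    high-confidence when the certainty of the call (confidence for positive
    calls, 1 − confidence for negative calls) exceeds ``high_conf_bar``.
    """
    key_cols = ["strain_id", "trait"]
    dup = existing.duplicated(subset=key_cols)
    if dup.any():
        first = existing.loc[dup, key_cols].iloc[0].tolist()
        raise ValidationError(
            f"existing annotations contain duplicate (strain, trait) pairs, "
            f"e.g. {first}; deduplicate before auditing"
        )
    known = {
        (str(r.strain_id), str(r.trait)): str(r.state)
        for r in existing.itertuples(index=False)
    }
    n_predicted = len(predictions)
    n_overlap = n_agree = n_contradict = n_high = 0
    for r in predictions.itertuples(index=False):
        state = known.get((str(r.strain_id), str(r.trait)))
        if state is None:
            continue
        n_overlap += 1
        if str(r.call) == state:
            n_agree += 1
        else:
            n_contradict += 1
            certainty = (
                float(r.confidence)
                if str(r.call) == "positive"
                else 1 - float(r.confidence)
            )
            if certainty > high_conf_bar:
                n_high += 1
    return EnrichmentAudit(
        n_predicted=n_predicted,
        n_overlapping=n_overlap,
        n_new=n_predicted - n_overlap,
        n_agree=n_agree,
        n_contradict=n_contradict,
        n_high_conf_contradict=n_high,
    )


def export_predictions(
    predictions: pd.DataFrame,
    path: str | Path,
    fmt: str = "tsv",
    model_version: str = "0",
) -> None:
    """Write database-ready prediction records as TSV or JSON.

    Every record carries trait, call, confidence, the model version and a
    ``provenance`` flag of ``"predicted"``; reading the file back with
    :func:`read_predictions` reproduces the table.
    """
    table = predictions.copy()
    table["model_version"] = model_version
    table["provenance"] = "predicted"
    path = Path(path)
    if fmt == "tsv":
        table.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(table.to_dict(orient="records"), fh, indent=1)
    else:
        raise ValidationError(f"unknown export format {fmt!r} (use 'tsv' or 'json')")


def read_predictions(path: str | Path, fmt: str = "tsv") -> pd.DataFrame:
    """Read a prediction export written by :func:`export_predictions`."""
    path = Path(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"strain_id": str, "trait": str})
        # header-only files: enforce the column set
        return df
    if fmt == "json":
        with open(path, "rt", encoding="utf-8") as fh:
            return pd.DataFrame(json.load(fh))
    raise ValidationError(f"unknown export format {fmt!r} (use 'tsv' or 'json')")
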