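"""Turn raw, possibly contradictory trait annotations into binary training sets.

Literature-derived trait labels are noisy: different publications disagree,
multi-state traits (oxygen requirement) do not fit a binary scheme, continuous
measurements (growth temperature) have no natural class boundary, and some
"negative" strains carry the complete genetic machinery for the positive
phenotype. The functions here implement the corresponding curation steps:

* ambiguous-label removal (a strain with both positive and negative records
  is excluded rather than guessed),
* multi-state decomposition into complementary one-vs-rest datasets
  (intermediate states become negatives),
* gap binarization of continuous values (a guard band around the class
  boundary is excluded from training),
* knowledge-guided negative filtering (negatives carrying ≥ ``min_count`` of
  a marker gene set are removed as probable mislabels),
* a per-trait low-variance feature filter and a stratified train/test split.

Every operation is conservative: strains are only ever moved into the
``excluded`` mapping with a recorded reason, never silently dropped, so
``positives ∪ negatives ∪ excluded`` always equals the input strain set.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations_io import FeatureMatrix
from .errors import ValidationError

logger = logging.getLogger(__name__)

# Exclusion reasons
AMBIGUOUS = "ambiguous"
IN_GAP = "in_gap"
MARKER_CONFLICT = "marker_conflict"
NO_SINGLE_VALUE = "no_single_value"

_RANGE_RE = re.compile(r"^\s*-?\d+(\.\d+)?\s*[-–]\s*-?\d+(\.\d+)?\s*$")


@dataclass(frozen=True)
class TraitLabelRecord:
    """One literature-reported trait annotation for one strain.

    Exactly one of ``state`` (categorical) or ``value`` (numeric) is set.
    """

    strain_id: str
    trait: str
    state: str | None = None
    value: float | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        if (self.state is None) == (self.value is None):
            raise ValidationError(
                f"record for {self.strain_id!r} must carry exactly one of a "
                f"categorical state or a numeric value"
            )


@dataclass(frozen=True)
class BinaryTraitDataset:
    """Curated positive/negative strain sets for one trait.

    ``excluded`` maps each removed strain to the reason it was removed
    (``ambiguous``, ``in_gap``, ``marker_conflict`` or ``no_single_value``).
    """

    trait: str
    positives: frozenset[str]
    negatives: frozenset[str]
    excluded: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise ValidationError(f"strains in both classes: {sorted(overlap)[:5]}")
        inside = (self.positives | self.negatives) & set(self.excluded)
        if inside:
            raise ValidationError(
                f"excluded strains also assigned a class: {sorted(inside)[:5]}"
            )

    @property
    def strains(self) -> frozenset[str]:
        """All strains the dataset accounts for, including excluded ones."""
        return self.positives | self.negatives | frozenset(self.excluded)

    @property
    def n_pos(self) -> int:
        return len(self.positives)

    @property
    def n_neg(self) -> int:
        return len(self.negatives)

    def labels(self, order: Sequence[str] | None = None) -> pd.Series:
        """Boolean label series over the classified strains.

        ``order`` fixes the row order (default: sorted positives then sorted
        negatives); excluded strains are never included.
        """
        if order is None:
            order = sorted(self.positives) + sorted(self.negatives)
        vals = []
        for s in order:
            if s in self.positives:
                vals.append(True)
            elif s in self.negatives:
                vals.append(False)
            else:
                raise KeyError(f"strain {s!r} is not classified in this dataset")
        return pd.Series(vals, index=list(order), name=self.trait)


@dataclass(frozen=True)
class GapBinarizerConfig:
    """Boundary and guard-band width (same units as the values, e.g. °C)."""

    boundary_low: float
    gap_width: float = 5.0

    def __post_init__(self) -> None:
        if not self.gap_width > 0:
            raise ValidationError("gap_width must be positive")


@dataclass(frozen=True)
class MarkerFilterConfig:
    """Marker gene set and the minimum count that flags a conflicting negative."""

    marker_features: frozenset[str]
    min_count: int = 19

    def __post_init__(self) -> None:
        if self.min_count < 0 or self.min_count > len(self.marker_features):
            raise ValidationError(
                "min_count must lie between 0 and the number of marker features"
            )


# ---------------------------------------------------------------------------
# Oxygen-requirement vocabulary
# ---------------------------------------------------------------------------

#: Canonical groups for oxygen requirement. Obligate forms collapse onto
#: their parent group; both facultative forms collapse to ``facultative``;
#: microaerophiles and (micro)aerotolerant strains form ``other``.
OXYGEN_VOCABULARY: dict[str, str] = {
    "aerobe": "aerobe",
    "aerobic": "aerobe",
    "obligate aerobe": "aerobe",
    "obligately aerobic": "aerobe",
    "anaerobe": "anaerobe",
    "anaerobic": "anaerobe",
    "obligate anaerobe": "anaerobe",
    "obligately anaerobic": "anaerobe",
    "facultative aerobe": "facultative",
    "facultative anaerobe": "facultative",
    "facultatively aerobic": "facultative",
    "facultatively anaerobic": "facultative",
    "facultative": "facultative",
    "microaerophile": "other",
    "microaerophilic": "other",
    "aerotolerant": "other",
    "microaerotolerant": "other",
}

OXYGEN_GROUPS = ("aerobe", "anaerobe", "facultative", "other")


def canonicalize_oxygen_state(raw_state: str) -> str:
    """Map a literature oxygen-requirement term onto its canonical group.

    Matching is case-insensitive and whitespace-tolerant.
    """
    key = " ".join(str(raw_state).strip().lower().split())
    try:
        return OXYGEN_VOCABULARY[key]
    except KeyError:
        accepted = ", ".join(sorted(OXYGEN_VOCABULARY))
        raise ValidationError(
            f"unrecognized oxygen-requirement term {raw_state!r}; "
            f"accepted terms: {accepted}"
        ) from None


# ---------------------------------------------------------------------------
# Curation operations
# ---------------------------------------------------------------------------

def remove_ambiguous(
    records: Iterable[TraitLabelRecord],
    positive_states: Iterable[str],
    negative_states: Iterable[str] | None = None,
) -> BinaryTraitDataset:
    """Build a binary dataset, excluding strains with contradictory labels.

    Each record's categorical state is mapped to a class: states in
    ``positive_states`` are positive; states in ``negative_states`` (or, when
    that is None, any other state) are negative. A strain whose records map
    to more than one class is excluded with reason ``ambiguous``; duplicate
    concordant records collapse.
    """
    records = list(records)
    pos_states = {s.lower() for s in positive_states}
    neg_states = (
        {s.lower() for s in negative_states} if negative_states is not None else None
    )
    trait = records[0].trait if records else ""
    per_strain: dict[str, set[bool]] = {}
    for rec in records:
        if rec.state is None:
            raise ValidationError(
                f"record for {rec.strain_id!r} has no categorical state"
            )
        state = rec.state.lower()
        if state in pos_states:
            label = True
        elif neg_states is None or state in neg_states:
            label = False
        else:
            raise ValidationError(
                f"state {rec.state!r} for strain {rec.strain_id!r} is in "
                f"neither the positive nor the negative vocabulary"
            )
        per_strain.setdefault(rec.strain_id, set()).add(label)
    positives, negatives, excluded = set(), set(), {}
    for strain, labels in per_strain.items():
        if len(labels) > 1:
            excluded[strain] = AMBIGUOUS
        elif labels == {True}:
            positives.add(strain)
        else:
            negatives.add(strain)
    return BinaryTraitDataset(trait, frozenset(positives), frozenset(negatives), excluded)


def decompose_multistate(
    records: Iterable[TraitLabelRecord],
    target_group: str,
    canonicalize=canonicalize_oxygen_state,
) -> BinaryTraitDataset:
    """One-vs-rest decomposition of a multi-state trait.

    Positives are strains whose sole canonical group equals ``target_group``;
    strains of any other single group (including intermediate states such as
    facultative anaerobes) are negatives; strains reported in more than one
    group are excluded as ambiguous.
    """
    if target_group not in ("aerobe", "anaerobe"):
        raise ValidationError(
            f"target_group must be 'aerobe' or 'anaerobe', got {target_group!r}"
        )
    records = list(records)
    trait = records[0].trait if records else ""
    per_strain: dict[str, set[str]] = {}
    for rec in records:
        if rec.state is None:
            raise ValidationError(
                f"record for {rec.strain_id!r} has no categorical state"
            )
        per_strain.setdefault(rec.strain_id, set()).add(canonicalize(rec.state))
    positives, negatives, excluded = set(), set(), {}
    for strain, groups in per_strain.items():
        if len(groups) > 1:
            excluded[strain] = AMBIGUOUS
        elif groups == {target_group}:
            positives.add(strain)
        else:
            negatives.add(strain)
    return BinaryTraitDataset(
        f"{trait}:{target_group}" if trait else target_group,
        frozenset(positives),
        frozenset(negatives),
        excluded,
    )


def _value_outcome(value: float, cfg: GapBinarizerConfig) -> str:
    if value < cfg.boundary_low:
        return "negative"
    if value >= cfg.boundary_low + cfg.gap_width:
        return "positive"
    return IN_GAP


def binarize_with_gap(
    records: Iterable[TraitLabelRecord],
    cfg: GapBinarizerConfig,
) -> BinaryTraitDataset:
    """Binarize a continuous trait with a guard band at the class boundary.

    value < ``boundary_low`` → negative; value ≥ ``boundary_low + gap_width``
    → positive (closed edge); values inside the half-open band
    [boundary_low, boundary_low + gap_width) → excluded with reason
    ``in_gap``. Strains whose multiple values fall into different outcomes
    are excluded as ambiguous; strains reporting only a range (a categorical
    ``"a-b"`` record) are excluded with reason ``no_single_value``.
    """
    per_strain: dict[str, set[str]] = {}
    range_only: dict[str, bool] = {}
    trait = ""
    for rec in records:
        trait = trait or rec.trait
        if rec.value is None:
            if rec.state is not None and _RANGE_RE.match(rec.state):
                range_only.setdefault(rec.strain_id, True)
                per_strain.setdefault(rec.strain_id, set())
                continue
            raise ValidationError(
                f"non-numeric value {rec.state!r} for strain {rec.strain_id!r} "
                f"cannot be binarized"
            )
        range_only[rec.strain_id] = False
        per_strain.setdefault(rec.strain_id, set()).add(
            _value_outcome(float(rec.value), cfg)
        )
    positives, negatives, excluded = set(), set(), {}
    for strain, outcomes in per_strain.items():
        if not outcomes:  # only range records seen
            excluded[strain] = NO_SINGLE_VALUE
        elif len(outcomes) > 1:
            excluded[strain] = AMBIGUOUS
        elif outcomes == {"positive"}:
            positives.add(strain)
        elif outcomes == {"negative"}:
            negatives.add(strain)
        else:
            excluded[strain] = IN_GAP
    return BinaryTraitDataset(trait, frozenset(positives), frozenset(negatives), excluded)


def filter_marker_conflicts(
    dataset: BinaryTraitDataset,
    matrix: FeatureMatrix,
    cfg: MarkerFilterConfig,
) -> BinaryTraitDataset:
    """Exclude negatives that carry ≥ ``min_count`` of the marker features.

    A strain labeled negative in the literature while encoding nearly the
    complete marker gene set (e.g. ≥ 19 of 21 flagellar families for a
    reportedly non-motile strain) is a probable mislabel; it is moved to
    ``excluded`` with reason ``marker_conflict``. Positives are never
    touched. Marker features absent from the matrix are warned about and
    treated as absent in every strain.
    """
    missing_strains = (dataset.positives | dataset.negatives) - set(matrix.strain_ids)
    if missing_strains:
        raise ValidationError(
            f"dataset strains missing from matrix: {sorted(missing_strains)[:5]}"
        )
    present_markers = [m for m in sorted(cfg.marker_features) if m in matrix.feature_ids]
    absent = sorted(cfg.marker_features - set(present_markers))
    if absent:
        logger.warning(
            "marker features absent from matrix (treated as absent everywhere): %s",
            absent,
        )
    excluded = dict(dataset.excluded)
    negatives = set(dataset.negatives)
    if present_markers and negatives:
        order = sorted(negatives)
        counts = matrix.subset(strains=order, features=present_markers).values.sum(axis=1)
        for strain, count in zip(order, counts):
            if count >= cfg.min_count:
                negatives.discard(strain)
                excluded[strain] = MARKER_CONFLICT
    elif cfg.min_count == 0:
        # Degenerate: every negative trivially carries ≥ 0 markers.
        for strain in sorted(negatives):
            excluded[strain] = MARKER_CONFLICT
        negatives.clear()
    return BinaryTraitDataset(
        dataset.trait, dataset.positives, frozenset(negatives), excluded
    )


def variance_filter(
    matrix: FeatureMatrix,
    dataset: BinaryTraitDataset,
    t: float = 0.2,
) -> FeatureMatrix:
    """Drop features with low variance among the dataset's classified strains.

    For a binary feature the variance is a function of its presence fraction
    ``p``; a feature is retained iff ``t ≤ p ≤ 1 − t`` (boundary values
    retained), computed over the dataset's positives and negatives. Column
    order is preserved; all rows of the input matrix are kept.
    """
    if t >= 0.5:
        raise ValidationError("variance-filter threshold t must be < 0.5")
    strains = sorted(dataset.positives | dataset.negatives)
    missing = set(strains) - set(matrix.strain_ids)
    if missing:
        raise ValidationError(
            f"dataset strains missing from matrix: {sorted(missing)[:5]}"
        )
    sub = matrix.subset(strains=strains)
    p = sub.values.mean(axis=0)
    keep = [f for f, pf in zip(sub.feature_ids, p) if t <= pf <= 1 - t]
    return matrix.subset(features=keep)


def train_test_split(
    dataset: BinaryTraitDataset,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[BinaryTraitDataset, BinaryTraitDataset]:
    """Stratified split of a dataset into train and test partitions.

    Each class contributes ``round(n_class * test_fraction)`` strains to the
    test set, so the per-class test share is within one strain of
    ``test_fraction``. Deterministic for a given seed. The ``excluded``
    mapping stays with the training dataset (it documents curation, not a
    holdout).
    """
    if not 0 <= test_fraction < 1:
        raise ValidationError("test_fraction must be in [0, 1)")
    for name, cls in (("positive", dataset.positives), ("negative", dataset.negatives)):
        if len(cls) < 2:
            raise ValidationError(
                f"{name} class has {len(cls)} strains; need at least 2 to split"
            )
    rng = np.random.default_rng(seed)
    train_pos, test_pos = _split_class(sorted(dataset.positives), test_fraction, rng)
    train_neg, test_neg = _split_class(sorted(dataset.negatives), test_fraction, rng)
    train = BinaryTraitDataset(
        dataset.trait, frozenset(train_pos), frozenset(train_neg), dict(dataset.excluded)
    )
    test = BinaryTraitDataset(dataset.trait, frozenset(test_pos), frozenset(test_neg))
    return train, test


def _split_class(
    members: list[str], test_fraction: float, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    n_test = int(round(len(members) * test_fraction))
    perm = rng.permutation(len(members))
    test_idx = set(perm[:n_test].tolist())
    test = [m for i, m in enumerate(members) if i in test_idx]
    train = [m for i, m in enumerate(members) if i not in test_idx]
    return train, test


# ---------------------------------------------------------------------------
# Label-table IO
# ---------------------------------------------------------------------------

def read_trait_table(
    path: str | Path,
    numeric_traits: Iterable[str] = (),
) -> list[TraitLabelRecord]:
    """Read a trait label table (TSV: strain_id, trait, value, source).

    Values for traits listed in ``numeric_traits`` are parsed as numbers;
    unparsable entries (e.g. a reported range ``"4-65"``) are kept as
    categorical records so that downstream curation can exclude them with an
    explicit reason.
    """
    numeric = set(numeric_traits)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"strain_id", "trait", "value"}
    if not required <= set(df.columns):
        raise ValidationError(
            f"trait table must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    records = []
    for row in df.itertuples(index=False):
        source = getattr(row, "source", None)
        source = None if source is None or pd.isna(source) else str(source)
        raw = str(row.value)
        if row.trait in numeric:
            try:
                records.append(
                    TraitLabelRecord(str(row.strain_id), str(row.trait),
                                     value=float(raw), source_id=source)
                )
                continue
            except ValueError:
                pass
        records.append(
            TraitLabelRecord(str(row.strain_id), str(row.trait),
                             state=raw, source_id=source)
        )
    return records


def write_exclusion_report(dataset: BinaryTraitDataset, path: str | Path) -> None:
    """Write the exclusion provenance of a dataset as TSV (strain_id, reason)."""
    pd.DataFrame(
        sorted(dataset.excluded.items()), columns=["strain_id", "reason"]
    ).to_csv(path, sep="\t", index=False)
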