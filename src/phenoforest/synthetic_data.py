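"""Seedable synthetic genotype–phenotype panels for testing every stage.

The generators emulate the statistical regimes the curation and modeling
procedures are built for, without any download:

* binary feature matrices with thousands of Pfam-like columns whose
  background presence rates are drawn from a Beta distribution (so the
  low-variance filter has realistic work to do),
* planted causal feature sets acting through presence *or* absence of the
  family, with configurable penetrance,
* strong class imbalance (e.g. a 2% prevalence trait),
* label noise: random flips, contradictory multi-source records (a second
  record with the opposite state), and "cryptic" negatives that carry the
  complete positive marker set while keeping their negative label,
* continuous per-strain growth temperatures drawn from two overlapping
  class distributions, with optional discordant second reports.

What the panels deliberately do **not** model: phylogenetic correlation
among strains, realistic Pfam co-occurrence structure, or genome sequences.
All generators are bit-reproducible under a fixed seed and return the
ground truth needed for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations_io import FeatureMatrix
from .errors import ValidationError
from .trait_curation import TraitLabelRecord

PRESENCE = "presence"
ABSENCE = "absence"


@dataclass(frozen=True)
class CausalSet:
    """A group of features that jointly carry the trait signal.

    ``feature_indices`` index into the generated feature list; ``direction``
    says whether the features are *present* (``"presence"``) or *absent*
    (``"absence"``) in positives with probability ``penetrance``. Negatives
    carry each feature at its background rate.
    """

    feature_indices: tuple[int, ...]
    direction: str = PRESENCE
    penetrance: float = 0.9

    def __post_init__(self) -> None:
        if self.direction not in (PRESENCE, ABSENCE):
            raise ValidationError("direction must be 'presence' or 'absence'")
        if not 0 <= self.penetrance <= 1:
            raise ValidationError("penetrance must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic binary-trait panel."""

    n_strains: int = 1000
    n_features: int = 500
    causal_sets: tuple[CausalSet, ...] = ()
    prevalence: float = 0.5
    label_flip_noise: float = 0.0
    contradiction_rate: float = 0.0
    cryptic_negative_fraction: float = 0.0
    background_beta: tuple[float, float] = (2.0, 6.0)
    absence_background_beta: tuple[float, float] = (6.0, 2.0)
    background_rate: float | None = None  # fixes all background rates exactly
    trait: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 1 or self.n_features < 1:
            raise ValidationError("n_strains and n_features must be positive")
        for name in ("prevalence", "label_flip_noise", "contradiction_rate",
                     "cryptic_negative_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for cs in self.causal_sets:
            if any(j < 0 or j >= self.n_features for j in cs.feature_indices):
                raise ValidationError("causal feature index out of range")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    labels: pd.Series  # true latent class per strain (bool)
    causal_directions: dict[str, str]  # feature id -> presence|absence
    flipped: frozenset[str] = frozenset()
    contradicted: frozenset[str] = frozenset()
    cryptic: frozenset[str] = frozenset()


def _strain_ids(n: int) -> list[str]:
    return [f"S{i:05d}" for i in range(n)]


def _feature_ids(m: int) -> list[str]:
    return [f"PF{i + 1:05d}" for i in range(m)]


def generate_binary_panel(
    spec: SyntheticSpec,
) -> tuple[FeatureMatrix, list[TraitLabelRecord], GroundTruth]:
    """Generate one binary-trait panel with planted causal structure.

    The latent class is drawn at ``spec.prevalence``. Causal features follow
    their direction and penetrance in positives and their background rate in
    negatives; all other features are i.i.d. at per-feature background rates
    drawn from ``background_beta``. Label records are then corrupted: a
    ``label_flip_noise`` fraction of strains get the wrong state, a
    ``contradiction_rate`` fraction get a *second* record with the opposite
    state, and a ``cryptic_negative_fraction`` of negative-labeled strains
    have every presence-direction causal feature forced to present.
    """
    rng = np.random.default_rng(spec.seed)
    strains = _strain_ids(spec.n_strains)
    features = _feature_ids(spec.n_features)
    y = rng.random(spec.n_strains) < spec.prevalence

    causal: dict[int, tuple[str, float]] = {}
    for cs in spec.causal_sets:
        for j in cs.feature_indices:
            causal[j] = (cs.direction, cs.penetrance)

    a, b = spec.background_beta
    aa, ab = spec.absence_background_beta
    X = np.empty((spec.n_strains, spec.n_features), dtype=np.int8)
    for j in range(spec.n_features):
        if spec.background_rate is not None:
            p_bg = spec.background_rate
        elif j in causal and causal[j][0] == ABSENCE:
            p_bg = rng.beta(aa, ab)
        else:
            p_bg = rng.beta(a, b)
        col = rng.random(spec.n_strains) < p_bg
        if j in causal:
            direction, pen = causal[j]
            p_pos = pen if direction == PRESENCE else 1 - pen
            col[y] = rng.random(int(y.sum())) < p_pos
        X[:, j] = col

    # label corruption
    labels = y.copy()
    n_flip = int(round(spec.label_flip_noise * spec.n_strains))
    flip_idx = rng.choice(spec.n_strains, size=n_flip, replace=False) if n_flip else []
    for i in flip_idx:
        labels[i] = ~labels[i]
    flipped = frozenset(strains[i] for i in flip_idx)

    n_contra = int(round(spec.contradiction_rate * spec.n_strains))
    contra_idx = (
        rng.choice(spec.n_strains, size=n_contra, replace=False) if n_contra else []
    )
    contradicted = frozenset(strains[i] for i in contra_idx)

    # cryptic negatives: negative-labeled strains given the full positive
    # marker set (presence-direction causal features)
    presence_markers = [j for j, (d, _) in causal.items() if d == PRESENCE]
    neg_idx = np.flatnonzero(~labels)
    n_cryptic = int(round(spec.cryptic_negative_fraction * neg_idx.size))
    if n_cryptic > neg_idx.size:
        raise ValidationError("cryptic fraction exceeds the negative pool")
    cryptic_idx = (
        rng.choice(neg_idx, size=n_cryptic, replace=False) if n_cryptic else []
    )
    for i in cryptic_idx:
        X[i, presence_markers] = 1
    cryptic = frozenset(strains[i] for i in cryptic_idx)

    records = []
    for i, strain in enumerate(strains):
        state = "positive" if labels[i] else "negative"
        records.append(TraitLabelRecord(strain, spec.trait, state=state))
        if strain in contradicted:
            other = "negative" if labels[i] else "positive"
            records.append(
                TraitLabelRecord(strain, spec.trait, state=other, source_id="alt")
            )

    matrix = FeatureMatrix(
        pd.DataFrame(X, index=strains, columns=features), validate=False
    )
    truth = GroundTruth(
        labels=pd.Series(y, index=strains, name=spec.trait),
        causal_directions={features[j]: d for j, (d, _) in causal.items()},
        flipped=flipped,
        contradicted=contradicted,
        cryptic=cryptic,
    )
    return matrix, records, truth


@dataclass(frozen=True)
class TemperatureSpec:
    """Study conditions for a continuous growth-temperature panel.

    Two latent classes (mesophile-like and thermophile-like) with Normal
    temperature distributions whose tails overlap around the class boundary;
    the genotype carries ``n_causal`` presence-direction features tied to the
    thermophile class. A ``discordant_fraction`` of strains report a second
    temperature drawn from the *other* class, exercising the ambiguity rule.
    """

    n_strains: int = 600
    n_features: int = 300
    n_causal: int = 12
    penetrance: float = 0.9
    mesophile_mean: float = 33.0
    mesophile_sd: float = 5.0
    thermophile_mean: float = 55.0
    thermophile_sd: float = 6.0
    thermophile_fraction: float = 0.35
    discordant_fraction: float = 0.05
    background_beta: tuple[float, float] = (2.0, 6.0)
    trait: str = "growth_temperature"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mesophile_sd <= 0 or self.thermophile_sd <= 0:
            raise ValidationError("temperature standard deviations must be positive")
        if not 0 < self.thermophile_fraction < 1:
            raise ValidationError("thermophile_fraction must lie in (0, 1)")
        if self.n_causal > self.n_features:
            raise ValidationError("n_causal cannot exceed n_features")


def generate_temperature_panel(
    spec: TemperatureSpec,
) -> tuple[FeatureMatrix, list[TraitLabelRecord], GroundTruth]:
    """Generate a genotype panel with per-strain temperature reports."""
    rng = np.random.default_rng(spec.seed)
    strains = _strain_ids(spec.n_strains)
    features = _feature_ids(spec.n_features)
    thermo = rng.random(spec.n_strains) < spec.thermophile_fraction

    a, b = spec.background_beta
    X = np.empty((spec.n_strains, spec.n_features), dtype=np.int8)
    for j in range(spec.n_features):
        p_bg = rng.beta(a, b)
        col = rng.random(spec.n_strains) < p_bg
        if j < spec.n_causal:
            col[thermo] = rng.random(int(thermo.sum())) < spec.penetrance
        X[:, j] = col

    temps = np.where(
        thermo,
        rng.normal(spec.thermophile_mean, spec.thermophile_sd, spec.n_strains),
        rng.normal(spec.mesophile_mean, spec.mesophile_sd, spec.n_strains),
    )
    n_disc = int(round(spec.discordant_fraction * spec.n_strains))
    disc_idx = rng.choice(spec.n_strains, size=n_disc, replace=False) if n_disc else []
    discordant = frozenset(strains[i] for i in disc_idx)

    records = []
    for i, strain in enumerate(strains):
        records.append(
            TraitLabelRecord(strain, spec.trait, value=float(temps[i]))
        )
        if strain in discordant:
            # second report drawn from the other class distribution
            if thermo[i]:
                second = rng.normal(spec.mesophile_mean, spec.mesophile_sd)
            else:
                second = rng.normal(spec.thermophile_mean, spec.thermophile_sd)
            records.append(
                TraitLabelRecord(strain, spec.trait, value=float(second),
                                 source_id="alt")
            )

    matrix = FeatureMatrix(
        pd.DataFrame(X, index=strains, columns=features), validate=False
    )
    truth = GroundTruth(
        labels=pd.Series(thermo, index=strains, name=spec.trait),
        causal_directions={features[j]: PRESENCE for j in range(spec.n_causal)},
        contradicted=discordant,
    )
    return matrix, records, truth


def inject_cryptic_negatives(
    matrix: FeatureMatrix,
    records: Sequence[TraitLabelRecord],
    marker_features: Sequence[str],
    fraction: float,
    seed: int = 0,
) -> tuple[FeatureMatrix, list[TraitLabelRecord], frozenset[str]]:
    """Force the full marker set present in a fraction of negative strains.

    Emulates literature mislabels: strains carrying the complete positive
    marker gene set but reported negative. Labels are untouched; the matrix
    is modified; the affected strain ids are returned as ground truth.
    """
    if not 0 <= fraction <= 1:
        raise ValidationError("fraction must lie in [0, 1]")
    missing = set(marker_features) - set(matrix.feature_ids)
    if missing:
        raise ValidationError(
            f"marker features not in matrix: {sorted(missing)[:5]}"
        )
    negatives = sorted(
        {r.strain_id for r in records if r.state == "negative"}
        - {r.strain_id for r in records if r.state == "positive"}
    )
    n_inject = int(round(fraction * len(negatives)))
    if n_inject > len(negatives):
        raise ValidationError("fraction exceeds the negative pool")
    rng = np.random.default_rng(seed)
    chosen = (
        sorted(rng.choice(negatives, size=n_inject, replace=False).tolist())
        if n_inject
        else []
    )
    frame = matrix.frame
    frame.loc[chosen, list(marker_features)] = 1
    return (
        FeatureMatrix(frame, validate=False),
        list(records),
        frozenset(chosen),
    )


# ---------------------------------------------------------------------------
# 4-state oxygen-like panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultistatePanelSpec:
    """Study conditions for a synthetic 4-state oxygen-like panel.

    Three feature blocks carry the signal: block A is the state-A machinery
    (present in state-A strains and, mimicking facultative organisms that
    harbor most of the aerobic inventory, at a high rate in intermediates);
    block B is the state-B machinery; block C is machinery distinctive of
    the intermediate state, which lets the two one-vs-rest models reject
    intermediates despite the shared blocks.
    """

    n_strains: int = 1200
    n_features: int = 400
    block_size: int = 15
    state_probs: tuple[float, float, float, float] = (0.35, 0.30, 0.25, 0.10)
    penetrance: float = 0.92
    intermediate_block_a_rate: float = 0.80
    intermediate_block_b_rate: float = 0.45
    background_beta: tuple[float, float] = (2.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.state_probs) - 1.0) > 1e-9:
            raise ValidationError("state_probs must sum to 1")
        if 3 * self.block_size > self.n_features:
            raise ValidationError("feature space too small for three blocks")


MULTISTATE_GROUPS = ("state_a", "state_b", "intermediate", "other")


def generate_multistate_panel(
    spec: MultistatePanelSpec,
) -> tuple[FeatureMatrix, pd.Series]:
    """Generate a 4-state panel; returns the matrix and true state per strain."""
    rng = np.random.default_rng(spec.seed)
    strains = _strain_ids(spec.n_strains)
    features = _feature_ids(spec.n_features)
    states = rng.choice(
        len(MULTISTATE_GROUPS), size=spec.n_strains, p=spec.state_probs
    )
    state_names = np.array(MULTISTATE_GROUPS)[states]

    bs = spec.block_size
    blocks = {
        "A": range(0, bs),
        "B": range(bs, 2 * bs),
        "C": range(2 * bs, 3 * bs),
    }
    # presence rate of each block per true state
    low = 0.05
    rates = {
        "A": {"state_a": spec.penetrance, "state_b": low,
              "intermediate": spec.intermediate_block_a_rate, "other": 0.3},
        "B": {"state_a": low, "state_b": spec.penetrance,
              "intermediate": spec.intermediate_block_b_rate, "other": 0.2},
        "C": {"state_a": low, "state_b": low,
              "intermediate": spec.penetrance, "other": 0.1},
    }
    a, b = spec.background_beta
    X = np.empty((spec.n_strains, spec.n_features), dtype=np.int8)
    for j in range(spec.n_features):
        block = next((name for name, rng_ in blocks.items() if j in rng_), None)
        if block is None:
            p_bg = rng.beta(a, b)
            X[:, j] = rng.random(spec.n_strains) < p_bg
        else:
            p = np.array([rates[block][s] for s in state_names])
            X[:, j] = rng.random(spec.n_strains) < p
    matrix = FeatureMatrix(
        pd.DataFrame(X, index=strains, columns=features), validate=False
    )
    return matrix, pd.Series(state_names, index=strains, name="state")
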