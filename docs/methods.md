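# Methods

## The problem and the model

`phenoforest` predicts binary phenotypic traits of prokaryotic strains
(Gram-stain response, spore formation, motility, oxygen requirement,
thermophily, ...) from their protein-family inventory. The genotype
representation is deliberately simple: a strain is a binary vector over Pfam
family accessions, where entry *j* is 1 iff the genome has at least one
annotation hit against family *j* with e-value ≤ 10⁻²⁰. Hit multiplicity and
gene order are discarded; the assumption is that the *presence or absence*
of functional modules (terminal oxidases, flagellar machinery, ribosome
quality-control domains, ...) carries the trait signal.

Each trait is modeled by a random forest with a fixed configuration shared
across all traits:

| parameter | default | rationale |
|---|---|---|
| number of trees | 200 | stable Gini-importance estimates without excessive cost |
| maximum depth | 10 | guards against memorizing strain-specific noise |
| decision threshold | 0.5 | a confidence ≥ 50% is called positive (tie inclusive) |
| class weighting | none | imbalance effects are reported, not dampened |
| bootstrap / feature subsampling | library defaults | recorded in the serialized model |

The *confidence* of a prediction is the forest's positive-class probability:
the mean over trees of the proportion of positive training samples in the
leaf the strain reaches. Confidence is a per-prediction quantity, distinct
from the per-model quality metrics.

Feature importances are reported as **signed Gini importances**: magnitude
is the forest's normalized mean impurity decrease; the sign is +1 when the
family is at least as frequent among training positives as among negatives
and −1 otherwise (its absence drives positive calls — typical for the
anaerobe model, where missing oxidative-metabolism families are the
signal). On binary features this presence-fraction comparison agrees in
sign with the point-biserial correlation. Ties (equal fractions) take the
positive sign.

## Training-set curation

Literature-derived labels are contradictory and multi-modal; the curation
pipeline is conservative — strains are only ever *excluded*, each with a
recorded reason, never reassigned:

* **Ambiguity removal.** A strain with both positive and negative records
  (different publications, unclear tests) is excluded (`ambiguous`).
  Duplicated concordant records collapse.
* **Multi-state decomposition.** Oxygen requirement is decomposed into two
  complementary one-vs-rest datasets (AEROBE, ANAEROBE). Obligate forms
  collapse onto their parent group; both facultative forms collapse to
  `facultative`; microaerophiles and (micro)aerotolerant strains form
  `other`. Intermediates are *negatives* for both models; strains listed in
  more than one group are ambiguous. Vocabulary matching is
  case-insensitive over a documented synonym table.
* **Gap binarization.** Continuous values (growth temperature, °C) are
  binarized at a boundary *b* with a guard band of width *w* (default 5):
  value < *b* → negative, value ≥ *b* + *w* → positive, values in
  [*b*, *b* + *w*) → excluded (`in_gap`). The half-open convention means a
  value exactly at *b* + *w* is positive. Strains reporting only ranges are
  excluded (`no_single_value`); strains with multiple single values in
  different outcome regions are ambiguous; multiple concordant values are
  kept. The shipped thermophily configuration uses the 40–45 °C band.
* **Marker-conflict filtering.** A negative strain carrying ≥ `min_count`
  of a trait's marker families (default: 19 of the 21 flagellar families
  for motility) is excluded (`marker_conflict`) as a probable literature
  mislabel — motility genes may simply not be expressed under the tested
  conditions. Positives are never touched, so the filter can only shrink
  the negative class.
* **Variance filter.** Per trait, features whose presence fraction *p*
  among the curated strains falls outside [*t*, 1 − *t*] (default
  *t* = 0.2, boundaries retained) are dropped. For Bernoulli features this
  is the standard reading of a "low variance" cutoff: a literal variance
  threshold of 0.2 would remove every feature, since a binary feature's
  variance is at most 0.25. The filter is computed on the full curated
  dataset by default (a train-only option exists).
* **Splitting.** Stratified 80/20 train/test split and stratified k-fold
  cross-validation, both deterministic under a seed. k defaults to 5, with
  a documented option for 10 — both conventions appear in practice and the
  package does not privilege one beyond the default.

## Evaluation

All confusion-matrix metrics are computed directly from their defining
ratios; any metric with a zero denominator is reported as *undefined* and
printed as NA, never silently as 0 — with imbalanced data a silent zero is
indistinguishable from genuinely poor performance. F1 is
2TP/(2TP + FP + FN), the precision–recall harmonic mean. The Matthews
correlation coefficient is min-max rescaled to normMCC = (MCC + 1)/2 so that
0.5 marks random performance on the same [0, 1] scale as the other metrics.

ROC-AUC is computed by the rank (Mann–Whitney) formulation with ties
counted 1/2; this equals trapezoidal integration of the ROC curve, and the
test suite verifies the equivalence to 1e-12 against an independent curve
integration. The PR-AUC uses the non-interpolated step estimator
Σ (R_k − R_{k−1}) P_k (average precision); its baseline equals the class
prevalence, which is why it is preferred over ROC-AUC for rare traits.

Models clear a quality gate of F1 ≥ 0.8 (inclusive) before their
predictions are exported. Exports carry trait, call, confidence, model
version and a `predicted` provenance flag. Audits against pre-existing
annotations report raw counts plus two ratios — agreements as a share of
all predictions and as a share of the overlapping records — because the two
denominators answer different questions and conflating them changes the
headline percentage by several points.

For the paired oxygen models, each strain's calls form a vector:
[1 0] aerobe, [0 1] anaerobe, [0 0] neither (facultative/other expected),
[1 1] conflict. Conflicts are impossible in truth, so their rate is a
quality diagnostic; conflicting strains are withheld from export by
default.

## Synthetic data: what it does and does not show

The generators produce the regimes the pipeline must handle: per-feature
background presence rates drawn from a Beta(2, 6) distribution (so the
variance filter has realistic work), planted causal feature sets acting
through presence or absence with configurable penetrance, strong class
imbalance, label flips, contradictory second records, "cryptic" negatives
carrying the full positive marker set, and bimodal growth-temperature
values with overlapping tails and occasional discordant second reports.
Absence-direction causal features draw their background from Beta(6, 2) so
that absence is informative.

They deliberately do **not** model phylogenetic correlation among strains,
Pfam co-occurrence structure, or annotation pipeline artifacts. Passing the
synthetic studies therefore shows that the *procedures* behave as designed
(signals are recovered, filters remove what they should, metrics expose
imbalance); it does not certify performance on real genome panels, where
phylogenetic confounding can inflate apparent accuracy.

## Validation studies (study conditions)

The `validation` module fixes the conditions under which the package checks
itself; `scripts/acceptance.py` re-runs all of them. Problem sizes were
chosen as the smallest that give stable averages on a single CPU:

* **Planted-feature recovery** — 1,500 strains, 2,000 features, 10 causal
  (7 presence- and 3 absence-direction, penetrance 0.9), balanced classes,
  20 replicates. Success: ≥ 8 of 10 planted features in the top 20 by
  importance magnitude with correct signs.
* **Gap-binarization benefit** — 600 strains, 300 features, mesophile-like
  N(33, 5²) vs thermophile-like N(55, 6²) temperatures, 5% discordant
  second reports; 5-fold CV F1 with the 40–45 °C band vs a hard threshold
  at the 42.5 °C midpoint, 20 replicates.
* **Marker-filter rescue** — 800 strains, 300 features, a 21-family marker
  set (penetrance 0.95) as the causal block, 10% of negatives made
  cryptic; filtering at `min_count = 21`, 10 replicates.
* **Paired-model separation** — 1,200 strains, 400 features, four latent
  states (35/30/25/10%); the intermediate state carries the state-A block
  at rate 0.8 (facultative organisms harbor most aerobic machinery) plus
  its own distinctive block, which is what lets both models reject it.
  Evaluated on the intersection of the two models' 20% holdouts,
  20 replicates.
* **Imbalance demonstration** — 2,500 strains at 2% prevalence, five causal
  features at penetrance 0.8 over a 0.3 background: a weak, rare signal.
  Cross-validated accuracy stays ≈ 98% while F1 collapses (≈ 0 at these
  conditions — at the 0.5 threshold the forest almost never calls a
  positive), which is precisely the argument against accuracy as a gate
  for imbalanced traits.

## Numerical choices and degenerate inputs

* Confidence exactly at the threshold is called positive.
* A feature matrix with zero strains is valid (header-only table);
  building a matrix from zero hits is an error.
* Training requires both classes non-empty; cross-validation requires each
  class ≥ k; splitting requires each class ≥ 2.
* Marker features absent from a matrix are warned about and treated as
  absent everywhere, so an incomplete marker list degrades gracefully.
* Serialized models embed a format version; loading a different major
  version fails loudly rather than risking silently wrong predictions.
* Per-replicate seeds in validation studies are `base_seed + i`; every
  stochastic component (generators, splits, forests) receives an explicit
  seed derived from it.

## Known limitations

* The sign rule for importances is a population-level heuristic; a feature
  with strong interactions could in principle receive a counter-intuitive
  sign while its magnitude remains correct.
* The variance filter interpretation (presence fraction outside
  [0.2, 0.8]) is the standard Bernoulli idiom but is one of several
  readings of a "<20% variance" rule; the threshold is configurable.
* Gap binarization treats every reported value as equally trustworthy;
  values that are test temperatures rather than optima add label noise the
  procedure cannot distinguish.
* No correction for phylogenetic non-independence is attempted; grouped
  performance summaries (per phylum, with an n < 10 flag) are the provided
  diagnostic for taxon-specific failure modes.
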