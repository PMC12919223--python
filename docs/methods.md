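# Methods

This note records the modelling choices behind `adrdscreen`: the cohort
and feature model, the ensemble, the screening arithmetic, the
misclassification-corrected odds ratio, the synthetic-data generator, and
the numerical conventions. Where the design was genuinely open we state
the choice made and why.

## Time model and cohort construction

Time is measured in integer weeks since a patient's first recorded DX
code; a year is 52 weeks for all window arithmetic. Ages are converted
from week spans with 52.1775 calendar weeks per year (the mean over the
Gregorian cycle) and carried as `age_at_index = (index_week −
birth_week) / 52.1775`.

A patient is a **case** on any ADRD diagnosis code or any anti-dementia
prescription (prefix matching against externally supplied code lists, so a
three-character list entry covers its whole family); a **control** only if
additionally free of every listed dementia-associated exclusion
condition. The case index date is `max(1, h)·52` weeks before the first
qualifying event for a horizon of `h` years, so the model never sees the
diagnostic run-up it is asked to predict; where both an ADRD diagnosis and
an anti-dementia prescription occur, the *earlier* qualifying event
anchors the index (an explicit assumption — the alternative of always
using the first diagnosis would let prescriptions precede the anchor).
Control indices sit `max(buffer, h+1)·52` weeks before end-of-record,
generalizing the 2-year confirmation buffer to horizons above one year.

Exclusions: cases with under 3 years of history before the first ADRD
code; controls with under 4 years of total history; anyone younger than 50
at the index or with under 3 years of record span. "Continuous history" is
operationalized as record span (first event to end-of-record) with no
enrollment-gap analysis, since gap rules cannot be inferred from span data
alone. Every decision is tallied by reason, and inclusion plus per-reason
exclusion counts always equal the input count.

The observation window is the `2·52` weeks before the index,
half-open on the right (the index week itself is excluded).

## Feature embeddings

**Prefix scheme.** Codes are normalized (uppercased, dots stripped; the
`rx` marker stays lowercase) and expanded into prefixes at fixed lengths —
DX 1/2/3/5/6, RX 3/4/5/8, PROC 1/2/3/4/5. A full code whose own length is
untracked is still a vocabulary entry in its own right: presence tests
membership of codes *and* prefixes, so dropping untracked-length full
codes would discard resolution for no saving.

**Presence vectors** are binary over the augmented vocabulary built from
the training ("code inference") split only. Out-of-vocabulary codes
contribute through whatever of their prefixes the vocabulary knows —
this is the generalization the hierarchy buys.

**Odds-ratio dictionaries** are estimated per *full* code (prefixes
excluded by default, configurable): the ratio of the case patient-fraction
carrying the code to the control patient-fraction, cubed. Fractions use
additive smoothing `(k + s)/(n + 2s)` with `s = 0.5`
(Haldane–Anscombe-style), so codes absent from one class yield finite,
nonzero ratios; cubing is monotone and therefore preserves the ranking of
codes while stretching the dynamic range seen by the tree models.
Membership semantics throughout: a code repeated within one window counts
once (the dictionary's probabilities are per-patient, not per-event), so
presence and OR embeddings are invariant to event order and duplication.

**Aggregations.** The 12 summaries of a window's OR multiset are min, max,
mean, median, standard deviation (population), sum, count, the
10/25/75/90th percentiles (linear interpolation), and the geometric mean
(0 if any value is 0). They span location, scale, extremes and tails of
the multiset; the set is overridable. An empty window maps to 0 in every
coordinate — neutral under tree models, which learn their own split for
"no dictionary code present".

**Leakage contract.** Vocabularies and dictionaries carry a fingerprint of
the patient ids they were fitted on; feature assembly for an evaluation
patient refuses a dictionary fitted on that patient. Nothing is ever
refit on evaluation data.

## Risk ensemble

Six LightGBM binary classifiers — presence and OR blocks for DX, RX,
PROC — are trained with 5-fold stratified out-of-fold stacking: the meta
learner only ever sees scores from folds the base model did not train on.
Per-fold early stopping (25 rounds patience) picks the iteration count;
the final refit on all training rows uses the median of per-fold best
iterations. Base hyperparameters: at most 300 rounds, learning rate 0.1,
31 leaves, depth ≤ 6, minimum 20 samples per leaf, positive-class
weighting via `is_unbalance` (weighting rather than resampling, so
probability ordering is preserved and no data is duplicated). The meta
learner is a smaller model of the same family (depth ≤ 3, 7 leaves, 150
rounds) over the 8 inputs: six base scores, sex, age; sex and age enter
only at the meta stage. All randomness flows from a single explicit seed
recorded in the model manifest; training runs single-threaded and
deterministic, so fixed seed and data give bit-identical scores. Models
persist as plain-text LightGBM dumps plus a manifest with per-file
checksums; loading verifies both the format version and the checksums.

## Screening metrics

A patient screens positive when their score strictly exceeds the
threshold; ties push toward fewer false positives. The threshold at target
specificity `t` over `n` controls is the `⌈t·n⌉`-th smallest control score
(the smallest threshold whose empirical specificity meets the target).
Discrimination metrics are prevalence-invariant; predictive values are
standardized to a fixed prevalence (default π = 0.109) rather than the
cohort's own case fraction, making sites with different case mixes
directly comparable. Accuracy at the standardized prevalence is
`se·π + sp·(1−π)` — the weighting must be stated because empirical
accuracy at the cohort prevalence would be dominated by controls.
Horizon decay is reported two ways: the endpoint estimate
`(AUC_min − AUC_max)/span` and an OLS slope over all horizons, both in
percent per year. Uncertainty half-widths come from a percentile
bootstrap over patients, stratified by label, B = 200 by default, seeded;
subgroups with fewer than 10 cases or 10 controls are suppressed with a
reason rather than reported unstably.

## The corrected odds ratio

For a 2×2 exposure table under noisy labels with known sensitivity `p` and
specificity `q` (exposure on rows, label status on columns), the noise
process maps true to observed counts by the row-stochastic matrix
`K = [[p, 1−p], [1−q, q]]` acting on the label axis: `T̃ = T·K` in
expectation. (Note the direction: the *columns* of T̃ blend the true
columns by the probability each true label is observed as that column.
Writing the product with `Kᵀ` instead is only equivalent when `p = q` and
yields an inconsistent estimator otherwise — the asymmetric worked example
in the module docstring makes the convention testable.)

The plain inverse `T̃K⁻¹` can produce negative cells; the estimator uses
`T(λ) = T̃(K + λI)⁻¹` with the smallest λ ≥ 0 at which all four recovered
cells reach a floor ε. Defaults and conventions:

- ε = 0.5, the midpoint of the typical [0.1, 1] range;
- λ search by bisection on [0, 10·max(T̃)] to relative tolerance 1e−9,
  after a 4096-point scan locates a feasible point (each cell rises
  through its zero then decays like 1/λ, so the feasible set is an
  interval and bisection against its left edge is well-posed); an empty
  feasible set is a reported state (`feasible=False`), not an exception;
- degeneracy guard: |p + q − 1| < 1e−3 is refused — K is then nearly
  singular and no useful inversion exists;
- the classical variance `1/a + 1/b + 1/c + 1/d` is evaluated on the
  *corrected* counts (the ordering is a choice; the corrected counts are
  the estimator's currency);
- when `(p, q)` were estimated on an independent validation cohort of size
  `n_val`, an extra delta-method component is added:
  `[(1−q)/(p+q−1)²]²·2p(1−p)/n_val + [(1−p)/(p+q−1)²]²·2q(1−q)/n_val`
  (zero when `(p, q)` are known; vanishes as `n_val → ∞` and at
  `p = q = 1`);
- Wald z, two-sided normal p-value, and `log Λ-OR ± z_{α/2}·√Var_total`
  intervals; Benjamini–Hochberg q-values across codes in the volcano
  export (raw and adjusted are both reported).

**Known limitation — anticonservative intervals under strong noise.** The
closed-form total variance above ignores how the inversion amplifies the
sampling noise of the observed cells (by roughly `1/(p+q−1)²`). The point
estimate is consistent — simulation recovery in the test suite shows mean
bias below 0.01 in log-OR across the noise grid — but 95% intervals built
from the closed form undercover when `p + q` is small (the acceptance
suite measures coverage as low as ~60% at `p = q = 0.8`). A full
delta-method propagation of the observed-cell noise through the inverse,
which restores near-nominal coverage in the same simulations, is exposed
on every result as `var_propagated` for users who need calibrated
intervals; the reported test statistic keeps the closed form.

For model-based attribution, tables are built by stratifying patients at a
risk-score threshold (high stratum = score ≥ threshold, playing the role
of the noisy case label) and cross-tabulating exposure against stratum;
`(p, q)` then default to the score's validation-split sensitivity and
specificity at that threshold.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes, not
real claims data. Each patient gets: an anchor DX event at week 0 (the
time origin); an index placed 4–10 years into the record (uniform);
planted codes included in the observation window with per-code
class-conditional rates (defaults: control rates log-uniform on
[0.03, 0.30], case/control ratios uniform on [2, 4] — the range of
common-comorbidity prevalence contrasts); background codes at
channel-specific Poisson rates scattered uniformly over the record span;
sex (55% female) and age at index (normal, case mean 74, control mean 68,
sd 8, clipped to [52, 95] — ADRD risk is strongly age-graded, and
keeping the clip above 50 separates the age-eligibility rule from
generator noise); and, for true cases, an ADRD-defining code placed
exactly `max(1, h)` years after the index, so the cohort module recovers
the planted label and index without slack. Default class mix is 3.8%
cases, matching large administrative-claims cohorts. Label noise, when
requested, flips each label independently with the stated sensitivity and
specificity.

Planted codes are placed *inside* the observation window so that the
configured class-conditional window rates are exact by construction —
they are the ground truth the recovery tests check; background events are
uniform over the whole record. Codes are sampled independently given
class; an optional shared latent severity factor adds block correlation
for robustness checks. What the generator does **not** emulate: real ICD
marginal frequencies, billing seasonality, care-pathway and ascertainment
effects, enrollment gaps, or correlated comorbidity clusters. Passing
tests on these cohorts therefore establishes the *mechanics* (labeling,
windowing, embedding, stacking, correction and their contracts), and
parameter recovery under the stated noise model — not clinical performance
on any real population.

## Problem sizes in tests

The test and acceptance workloads are sized for a single CPU: the
ensemble check trains on a 2,000-case / 20,000-control cohort with 30
planted contrast codes (held-out AUC floor 0.85, permutation null within
[0.45, 0.55]); odds-ratio recovery uses 200 replicates of n = 50,000 per
cell over the 45-cell grid of true log OR ∈ {0, ±log 2, ±log 4} ×
p, q ∈ {0.8, 0.9, 0.95}; the λ-search oracle comparison covers 1,000
infeasible-at-zero tables; the AUC oracle 100 fixtures up to n = 200.
The acceptance script's screening run uses a 1,000 / 10,000 cohort.
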