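# Methods

This note documents the models and procedures implemented in `icfmon`,
the defaults chosen where the underlying methodology is genuinely open,
and what the synthetic cohorts do and do not establish.

## ICF data model

ICF categories are coded as a component letter (b body functions, s body
structures, d activities/participation, e environmental factors)
followed by 1 (chapter), 3 (second level), 4 (third level) or 5 (fourth
level) digits; two-digit forms do not exist. The parent of a non-chapter
code is fully determined by its text (drop to 1, 3 or 4 digits
respectively), so the hierarchy used for rollups is derived from code
structure alone and no external taxonomy file is required. Well-formed
codes absent from the published taxonomy — notably the "-8 other
specified" codes such as d5308 — are accepted and attached under their
textual parent, and they participate in parent averaging like any other
child. Rollup stops at chapter level; chapters have no parent.

Each category carries the generic qualifier: an ordinal severity 0 (no
problem) … 4 (complete problem) plus the sentinels 8 (not specified) and
9 (not applicable). Sentinels have no position on the severity order —
comparing them raises rather than silently ordering — and they are
excluded from every mean, aggregation and inference. A category whose
only evidence is sentinels records 8.

## Standardization pipeline

One person-year is standardized in four steps: (1) attribute
normalization (instrument item → ICF category), (2) value normalization
(raw score → qualifier) via an explicit, total value map, (3)
aggregation when several items target one category, (4) hierarchical
inference of missing parents from rated children.

Decisions where the method is under-determined:

* **Aggregation policy.** The default combines ordered qualifiers by
  arithmetic mean with halves rounded toward worse; `worst` (max) and
  `best` (min) are selectable. The mean matches the inference rule
  (parents are child averages), and rounding toward worse is the
  clinically conservative tie-break. Non-half fractions round to the
  nearest integer; the whole rule is implemented in exact integer
  arithmetic as ⌊(2·Σq + n) / 2n⌋.
* **Inference.** Applied bottom-up (fourth → third → second → chapter)
  using *immediate* children only at each pass, so lower-level
  inferences feed higher ones without skipping levels. Measured and
  aggregated values are never overwritten (measured > aggregated >
  inferred precedence). Inference is idempotent and every inferred value
  lies within [min, max] of its contributing children; the test suite
  checks both, plus equivalence with an independent brute-force
  recomputation by recursive descendant enumeration.
* **Duplicates.** Repeated observations of one (person, year, item) keep
  the last by input order and emit a warning. Unmapped items and
  out-of-domain raw values are collected as warnings and skipped, never
  fatal.

### Crosswalk

Crosswalks are YAML documents (one block per instrument; rule entries of
item / icf_code / values) validated field-by-field at load time. Raw
value keys are exact matches or closed intervals `"lo..hi"`; intervals
within an item must not overlap, and every mapped qualifier must be on
the 0–4/8/9 scale. Direction is always explicit in the value map:
instruments scored "higher = better" (Barthel) invert there, never by
inference. Only the Barthel feeding row (10/5/0 → 0/2/4 onto d550) is
asserted as ground truth; the other bundled rows are plausible,
clearly-labeled illustrative fixtures that let the pipeline run
end-to-end, not clinically validated crosswalks.

## Monitoring representations

The individual view is a categories × years matrix of qualifiers with
the fixed severity color code (blue/0, green/1, yellow/2, orange/3,
red/4; grey for sentinels, white for missing). Population views report,
per category and year, the percentage of the population at each
qualifier level. Membership in a year's denominator requires an
evaluation (snapshot) that year; members without an ordered value for
the category fall into an explicit `missing` bin, and a complete-case
flag restricts the denominator instead (the published figures do not
disclose their convention, so both are offered and the explicit bin is
the default because it never hides data). Distributions always sum to
100% within 1e-9. All representations are produced as data; PNG export
is a thin optional layer and nothing is asserted about pixels.

## Prognosis benchmark

The task is 5-class classification of a target category's qualifier at
the label year (each cohort's last evaluation year). Eligibility
requires at least `min_series_length` (default 3) distinct measurement
years and an ordered target value at the label year — the last
measurement is what validates the prediction.

* **Representations.** *Full time-series*: one numeric feature per
  (category, predictor year) pair, over all categories with an ordered
  value in at least one eligible profile and all years before the label
  year; pairs never observed in any eligible profile are dropped.
  *Previous state*: one feature per category — its most recent ordered
  pre-label value (chosen over "strictly previous calendar year", which
  the real missingness pattern would leave mostly empty). Label-year
  values are never used as features; sentinels count as missing. Five
  demographic features (age, gender, years from diagnosis, disease,
  origin) are always included.
* **Learners.** KNN (k = 7), Gaussian naive Bayes, an RBF-kernel SVM and
  a CART decision tree standing in for C4.5/J48.
* **Protocol.** Stratified k-fold cross-validation (default k = 10,
  shuffled under the run seed; k reduced to the smallest class support
  when needed and recorded in the report metadata). Median/mode
  imputation and one-hot encoding are fitted inside training folds only.
  All learners of one representation share identical folds, so their
  confusion totals agree, and a fixed seed makes reports bit-identical
  across runs.
* **Metrics.** accuracy = (TP+TN)/(TP+FP+FN+TN), precision = TP/(TP+FP),
  recall = TP/(TP+FN), specificity = TN/(TN+FP), computed one-vs-rest
  per class. The published report style prints single values for a
  5-class problem without naming the averaging; the default here is
  support-weighted averaging (the summary convention of the Weka
  toolkit), under which weighted recall is algebraically the overall
  accuracy — the reported accuracy is exactly that overall fraction.
  Macro averaging is available by flag, and a binary mode applies the
  formulas verbatim to a designated positive class. A per-class ratio
  with a zero denominator is reported as 0 and flagged with a warning.
* **Attribute importance.** Impurity-based importances from a 300-tree
  random forest, with one-hot columns folded back onto their source
  feature, reported as percentages of the top-k (≤ 10 by default)
  renormalized to 100 and sorted descending. This is this package's own
  ranking method; it is not claimed to reproduce any external service's
  importance percentages.

## Economics

No published mapping from ICF qualifiers to health-state utilities
exists for this setting, so the utility policy is explicit and
pluggable; the default is linear disutility u = 1 − mean(q)/4 over a
configurable category set. QALYs gained = (u_after − u_before) × years
(signed, antisymmetric); DALYs averted = QALYs × factor (default 1:1);
savings = DALYs × cost-per-DALY − rehabilitation cost. Discounting and
age-weighting of DALYs are off by default and configurable. Every output
of this module is policy-dependent and labeled as such.

## Synthetic cohorts

The generator emulates the published marginal structure of a real ABI
prognosis cohort, per preset (emotional functions, target b152, n = 419;
executive functions, target b164, n = 477):

* ages truncated-normal in (17, 90) with mean 46.7/47.2, sd ≈ 15.5;
  male fraction 274/419 resp. 313/477; disease and origin drawn from the
  published frequency tables; years from diagnosis truncated-normal in
  the published ranges;
* series of 3–7 consecutive annual evaluations ending in 2013, lengths
  drawn from {3: .28, 4: .38, 5: .22, 6: .08, 7: .04} (mean 4.22,
  sd ≈ 1.06 — the closest simple law to the published mean 4.2, sd 1.0);
* a latent target severity following a sticky ±1 random walk (stay
  probability 0.6) started from the published 5-class label
  distribution;
* per-year target missingness following the published schedules (e.g.
  99% → 0% over 2007–2013 for emotional functions). Missingness is
  realized by **per-year quota sampling**: exactly round(rate · n_year)
  of the people evaluated that year are marked missing, chosen uniformly
  at random. Uniform selection is exchangeable, hence still
  missing-completely-at-random, but it pins the empirical per-year rate
  to the schedule up to rounding at any seed — i.i.d. Bernoulli draws
  would scatter by several points in the sparsely measured early years
  (only ~4% of the cohort is evaluated in 2007). An informative mode
  instead biases selection toward severe states for robustness
  experiments.

Observations are emitted at the instrument level (the target item plus
correlated context items from Barthel/CIQ/PCRS/DRS, whose severity
tracks the latent state with ±1 jitter; coarse 3-point items snap to the
nearest representable qualifier, ties toward worse) and pushed through
the bundled crosswalk, so generated profiles exercise normalization,
aggregation and inference exactly as real data would. Generation is
deterministic given (config, seed).

**Planted signals.** `plant_signal` rewrites each profile's label-year
target from an explicit transition: with probability `noise` uniform
over 0–4, otherwise stay/up/down around the previous state with clipping
at the boundaries. Profiles lacking any ordered pre-label target first
receive one (uniform over 0–4) in their most recent pre-label year, so
the transition defines every label and the Bayes-optimal accuracy has a
closed form used by the recovery tests. Only the target category is
rewritten; ancestor values inferred at generation time are left as they
were.

What passing tests on these cohorts establish: that the pipeline's
logic, metrics and learners behave correctly under a realistic
missingness/series-length regime, and that planted dependence of the
stated strength is recovered. What they do not establish: any benchmark
number for real clinical populations — the generator reproduces
published *marginals*, not the joint distribution, instrument response
patterns or true temporal dynamics of clinical data, and the published
benchmark values themselves are not reproducible without the original
730-person dataset.

## Problem sizes and numerical choices

Default test and acceptance runs use cohorts of 120–500 people, 1,000
random tables/snapshots for the oracle-equivalence checks and 3–10 CV
folds; these sizes give stable statistics (binomial sampling error
≈ ±2 points on a 5-class accuracy at n = 500) while keeping the full
suite under a minute of compute. Qualifier arithmetic is exact integer
arithmetic throughout; percentage sums are asserted to 1e-9; seeds flow
from a single per-run integer and every CLI run writes its seed and a
configuration hash to `run_metadata.json`.

## Known limitations

* Crosswalk content beyond the Barthel feeding row is illustrative; real
  deployments must supply validated instrument mappings (the format and
  validation are the deliverable, not the clinical content).
* Global staged instruments (Rancho, GOSE) are mapped to single
  categories here; how such global scores should fan out into multi-code
  ICF profiles is an open clinical question.
* The utility and QALY→DALY policies in the economics module are
  explicit defaults, not validated health-economic mappings.
* Multi-level inference (chapter values inferred from inferred
  second-level values) is a choice; a system that fills only one level
  would produce sparser profiles.
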