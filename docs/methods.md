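# Methods

This note documents the statistical machinery in `phenotree`, the defaults
and why they were chosen, what the synthetic cohorts do and do not emulate,
and the numerical conventions that make runs exactly reproducible.

## Patient representation

A patient is a document over clinical codes: event order and dates are
discarded and the cohort becomes a sparse non-negative integer matrix
`counts[i, j]` = number of events of code *j* for patient *i*, with an
aligned binary outcome vector. Patients present in the label table but
absent from the events keep an all-zero row — "no recorded code" is
informative in primary care and must not silently drop controls.

Two representation choices are deliberately configurable because source
records do not determine them:

* **Same-day duplicates** are kept by default (`dedup_same_day=True`
  collapses identical (patient, code, date) rows). Repeated same-day
  coding is usually genuine repeated care activity.
* **Vocabulary scope** defaults to the full dataset before splitting,
  mirroring how the patient-term matrix is normally built in this
  setting; building from the training part only is available for strictly
  leakage-free protocols. Note that the vocabulary only fixes the column
  set — all association scores are computed on the training part.

Splits are stratified by outcome using per-class largest-remainder
allocation, so each part's class count is within one patient of the exact
proportion. With ~2% prevalence an unstratified split can easily leave a
part with almost no positives, which makes validation accuracy
uninterpretable; stratification is therefore the default and the package
does not offer an unstratified mode.

## Association indices

All five indices operate on the 2×2 table of code *presence* (count ≥ 1)
against outcome: A/B = positives/negatives with the code, C/D = without.
Binarization is used for *ranking only*; the trees downstream consume raw
counts. Rationale: the five indices are contingency-table statistics, and
presence/absence is the scale on which they are standardly defined, while
count thresholds are better exploited by the tree's split search.

* χ²: `N(AD−BC)² / ((A+B)(C+D)(A+C)(B+D))`.
* Gini gain: impurity decrease with `Gini(q) = 2q(1−q)` on the
  positive-class proportion. Satisfies `gini_gain = χ² · Gini(parent)/N`
  exactly (verified to 1e-12 over random tables), hence identical rankings.
* Information gain: Shannon mutual information, base 2 with `0·log 0 = 0`.
  Base is a ranking-invariant convention; bits are reported.
* DKM gain: same gain structure with impurity `2√(q(1−q))`. The gain form
  makes DKM commensurable with Gini/entropy while preserving its sharper
  penalty near purity.
* Binomial: `−log10 P(X ≥ A)` with `X ~ Binomial(A+B, (A+C)/N)` — the
  exact one-sided enrichment tail of the code among positives under the
  class-prevalence null, computed in log space (`binom.logsf`) so strongly
  enriched codes do not underflow to equal scores. This is the standard
  binomial term-scoring construction from text categorization; other
  binomial variants exist, and this one is documented as the package's
  interpretation.

Degenerate codes (present in everyone or no one) score 0 under all five
indices: they cannot discriminate. Ties rank lexicographically by code so
rankings are reproducible regardless of row order.

## Forward selection

Features are added in ranking order, Σᵢ = Σᵢ₋₁ ∪ Ω(i); at each step a
fresh classifier is fitted on the training part restricted to Σᵢ and
scored on the validation part. The sweep stops early when validation
error ≤ `tolerance`, else runs to `i_max`. The cut-off ordering is
lexicographic (accuracy, then F1, then *fewer* features), and both the
best and the second-best cut-offs go to the tuning phase, so a near-tie
between a compact and a larger feature set is resolved by the final
model selection rather than discarded early.

Defaults and why:

* `tolerance = 0`: stops only on a perfect validation score. On noisy
  data the full curve up to `i_max` is observed, which is what the
  interior-optimum cut-offs require; on noise-free fixtures the early
  exit fires at the first perfect step.
* `i_max = 400`: generous relative to cut-offs seen in practice
  (single digits to a few hundred) while capping compute at `i_max`
  fits — against K(K+1)/2 for exhaustive wrapper search. The fit counter
  is recorded and asserted in the tests.
* Inner learner: an entropy-criterion tree with default parameters and no
  cost weighting. The inner model only has to order feature subsets, not
  be the final classifier; it is injectable (`learner=` / `estimator=`)
  for protocols that want the Phase-3 learner here too.
* F1 at a step can be undefined (no positive calls); it is stored as NaN
  and sorts below any defined F1, never coerced to 0.

## The tree engine

Binary splits on count thresholds, with candidates at midpoints between
consecutive distinct observed counts and the left branch taking
`count ≤ threshold`. Search is exhaustive over (feature, threshold) at
each node; ties break to the lowest feature index, then the smallest
threshold — determinism is a design requirement, since exported rules are
clinical artifacts that must not vary between runs.

Cost sensitivity: each positive training patient carries weight
`fn_cost` (false-positive cost fixed at 1) in every count, impurity and
leaf label. A leaf predicts the class with the smaller expected cost,
ties to positive; e.g. 1 positive + 3 negatives with `fn_cost = 4`
predicts positive (cost 3 < 4). At fixed structure, raising `fn_cost`
can only flip leaves from negative to positive, which is the monotone
sensitivity behaviour the tests assert.

Profiles:

* `cart`: Gini criterion, `min_split` gate, cost-complexity pruning. The
  pruning measure is the weakest-link value
  `g(t) = (R(t) − R(T_t)) / (|leaves(T_t)| − 1) / R(root)` with R the
  weighted misclassification cost; nodes are collapsed while `g < cp`.
  `cp = 0` is the identity. `cp ≥ 1` collapses to the root leaf (a
  perfect split attains `g = 1` exactly, so the boundary case is handled
  explicitly rather than left to strict inequality).
* `c50`: entropy criterion, `min_child` (smallest patient count allowed
  in each side of a split), instance-weight cost handling. This is an
  approximation of the C5.0 family's observable levers — minimum cases
  and asymmetric cost — without winnowing, boosting or rule
  post-simplification, which are proprietary internals out of scope here.
* `ci`: growth continues only while the chosen split's χ² association
  p-value (computed on the same weighted counts as the impurity search,
  df = 1), Bonferroni-corrected over the candidate features at the node,
  satisfies `1 − p ≥ mincriterion`. This reproduces the
  significance-stopped behaviour of conditional-inference trees without
  their permutation-test machinery; the node-size knob is mapped to
  `min_split` on raw patient counts, a documented approximation.

Counts are never missing (absence of a code is count 0), so there is no
surrogate-split or missing-value machinery.

## Grid search and model selection

The default grids cover the standard tuning ranges of the three
profiles: c50 `min_child` ∈ {5,…,30} step 5 and `fn_cost` ∈ {1, 2.25, …,
19.75} (step 1.25 from 1; the literal arithmetic tops out at 19.75);
cart `min_split` ∈ {10,…,40} step 5 and `cp` ∈ {0.001,…,0.1} step 0.001;
ci `mincriterion` ∈ {0.1,…,0.9} step 0.1 plus 0.99 and `min_split` ∈
{35,40,45}.

Each grid point is scored by the overall agreement rate — plain held-out
accuracy averaged over stratified k-fold cross-validation (k = 10 by
default). Cost weighting shapes the *fitted trees*, not the selection
metric. Folds are stratified because at ~2% prevalence unstratified folds
routinely contain no positives; fold assignment is derived from the seed
on canonically (patient-id) ordered rows, so the cross-validation score
is invariant to incidental row order. Ties between grid points resolve to
the earliest point in axis order.

Final selection refits each candidate's best parameters on the training
part, ranks candidates by validation accuracy (F1, then fewer features,
as tie-breaks) and reports the winner exactly once on the test part.

## Metrics

Accuracy, sensitivity, specificity, PPV, NPV, and F1 =
2·recall·precision/(recall+precision). Any metric with a zero denominator
is NaN, never 0 — and F1 is NaN whenever either component is zero or
undefined, so a degenerate all-negative classifier cannot masquerade as
"F1 = 0 but accuracy high" in a sortable score.

`reconstruct_cm` inverts printed sensitivity/specificity and class sizes
back to integer confusion counts with half-up rounding; composing it with
`performance` recovers the input rates to within the half-count bound
0.5/n. This is the mechanism used to check published performance tables
for internal consistency: four independent printed columns are
reproduced to two decimals, which also pins down the rounding convention.

## Synthetic cohorts

`generate_cohort` draws labels ~ Bernoulli(prevalence), per-patient event
counts ~ Poisson(`mean_events`), and event codes from a categorical
distribution: Zipf(`zipf_exponent`) background weights, with each planted
code's weight set to `base_rate` in negatives and `base_rate · rate_ratio`
in positives (renormalized). One seeded stream, labels drawn before
events, makes cohorts byte-reproducible.

What it emulates: dimensional shape (10³–10⁴ patients, hundreds to
thousands of codes), heavy-tailed code popularity, low prevalence, and
count-level (not just presence-level) enrichment of informative codes.
What it does not: code-hierarchy correlations, temporal structure,
differential record completeness, and label noise in the gold standard.
Passing tests on these cohorts therefore demonstrate that the pipeline
recovers planted count-level signal under imbalance — not that it handles
coding-practice artifacts of real primary-care data.

Fixture cohorts (`golden_fixture`) are deterministic: two hand-written
tiny cohorts (a perfectly separable 12-patient one and a 50-patient one
with 2 positives for cost-sweep behaviour) and two generated ones —
`as_like` (2000 patients, 2% prevalence, two planted codes named
`N100.`/`F440.` at rate ratio 8) and `ra_like` (2000 patients, 14%
prevalence, ten planted codes at rate ratio 4). In `as_like`,
`mean_events = 100` so that count thresholds separate the Poisson(~1)
background from the enriched positives: each planted code alone is a
mediocre classifier but the pair is near-decisive, making the fixture a
genuine test of multi-feature forward selection rather than of a single
dominant code.

## Problem sizes used in the checks

The recovery study runs 20 seeded cohorts of 2000 patients × 500 codes
with 5 planted codes at rate ratio 4 and prevalence 0.1; ranking must
place ≥ 4/5 planted codes in its top 20 for all five indices and forward
selection's best cut-off must be ≤ 20 (swept to `i_max = 25` so the bound
is falsifiable). Oracle-equivalence checks enumerate all 2-feature
datasets of up to 4 patients and a 300-dataset pseudo-random sample of
the 6-patient × 3-feature space. The null-calibration check uses
2000-patient cohorts so that even the rarest Zipf-tail code appears in
~15 patients, keeping the asymptotic χ² null valid. These sizes are the
package's standing study conditions, chosen to make each property
statistically meaningful at small simulation cost.

## Known limitations

* The c50 and ci profiles reproduce the *levers* of their namesakes, not
  their numerical output; no claim of agreement with external R
  implementations is made or tested.
* The binomial index is one specific (exact, one-sided, −log10) reading
  of "binomial scoring"; alternatives (two-sided, normal-approximate)
  would change scores but rarely the ranking of strongly enriched codes.
* Ranking uses presence binarization; codes whose signal lives purely in
  count magnitude with near-universal presence will rank low even though
  the trees could exploit them.
* Forward selection never revisits the ranking (no floating search, no
  backward elimination) — by design, for transparency and the `i_max`
  fit bound.
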