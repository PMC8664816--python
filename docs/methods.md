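# Methods

## Problem setting

Two longitudinal aging cohorts are pooled into one long-format table (one
row per subject-visit). The cohorts differ in visit schedule (study A:
18-month grid; study B: a 3-month visit then a 6-month grid), in
demographic composition, and — crucially — in battery: each administers
only one of two closely related list-learning episodic-memory tests. In
the joined table that test's column is therefore *systematically missing*
for one study, alongside ordinary scattered missingness. All missing
cells are treated identically by the imputation engine; the
systematically missing columns are the harmonization targets.

## Joined-table construction

The canonical layout (default schema) has 39 columns: participant and
dataset identifiers, months since baseline, age, sex, 4-level education,
APOE ε4 allele count, clinical class (CN/MCI/AD), CDR and MMSE, 14
bounded integer cognitive scores, and 15 rate-of-change columns (MMSE and
every cognitive score). The CDR's rate is not derived: the global CDR is
a coarse 0.5-step staging ordinal whose between-visit difference is
almost always exactly zero, which makes a per-month rate degenerate. An
auxiliary Centiloid-scale amyloid value rides along outside the layout;
it is never shown to the imputation forests and exists only for the case
study.

Inclusion rules, applied in this order per study before joining:

1. a clinical/cognitive variable measured in both studies is dropped from
   both when ≥ 50% of its values are missing in either study
   (single-study harmonization targets are exempt — their wholesale
   absence is the point);
2. a visit with missing clinical class inherits a class when its
   immediately preceding and following visits agree, or when it has
   exactly one adjacent visit with a known class; otherwise the visit is
   dropped. Ambiguity (disagreeing neighbours) drops the visit —
   the conservative reading of "use an adjacent timepoint";
3. visits with fewer than 3 completed cognitive tests are dropped;
4. visit times are re-baselined so each subject's earliest retained visit
   is month 0 (rates are differences, so this does not affect them);
5. rate-of-change columns are derived *after* the row filters so that no
   rate is anchored on an excluded visit: the rate at visit *t* is
   `(x_t − x_prev)/(months_t − months_prev)` using the nearest previous
   visit where the score is non-missing; it is missing at the first visit.
   The filter-then-derive order is a package decision; deriving first
   would only change rates adjacent to excluded visits.

Education bins are read as [0,9), [9,13), [13,16), ≥16 → `<9`, `9-12`,
`13-15`, `15+`, so integer year counts land in the literally labelled bin
(the printed labels overlap at 15; this is the assumption we log).
Every dropped row or variable is recorded with exactly one primary reason
in an `ExclusionLog`, and retained + dropped row counts always reconcile
with the input.

## Imputation engine

A chained per-variable random-forest loop (MissForest scheme):

* **Initialization** — column median for continuous/discrete variables,
  modal category for categoricals (ties broken by the lexicographically
  smallest category, for determinism).
* **Sweep** — variables with originally missing cells are visited in
  ascending order of missing count (the reference convention; a
  `schema_order` policy is available). For each, a
  `RandomForestRegressor` (or `RandomForestClassifier` for categoricals)
  with 100 trees (default), `max_features="sqrt"`, and minimum leaf size
  5 for regression / 1 for classification is fit on the observed rows and
  predicts the originally missing rows, which are overwritten
  immediately, so later variables in the same sweep see the update.
* **Predictors** — every non-identifier layout column except the target,
  in its current imputed state. Ordered categoricals (education) enter as
  integer codes; unordered ones (sex, clinical class) as one-of-K
  indicators; both encodings are invertible. The dataset identifier is
  never shown to the forests, and evaluation runs additionally withhold
  the clinical class so that class-discrimination results cannot be
  circular. A config flag can also withhold the target's own
  rate-of-change column (off by default: the default predictor set is
  exactly "all other columns").
* **Stopping** — after each sweep,
  `Δ_num = Σ(X_new − X_old)² / Σ X_new²` over imputed numeric cells and
  the disagreement fraction over imputed categorical cells. The loop
  stops the first time either Δ exceeds its previous value, *returning
  the previous sweep's imputation*, or after 10 sweeps. A fully observed
  table returns unchanged with zero sweeps.
* **Post-processing** — integer-valued scores are rounded to the nearest
  integer (half away from zero) and clipped to their valid range.
  Clipping is a formal safety net: forest predictions are averages of
  observed responses and therefore already lie inside the observed range
  (asserted internally before rounding).
* **Determinism** — every forest's seed derives from
  `SeedSequence([rng_seed, sweep, variable_index])`, so results are
  bit-reproducible and independent of any execution interleaving.

Observed cells are never touched: the completed table is bit-identical to
the input everywhere a value was measured.

Deliberate non-goals, matching the method's scope: a single completed
dataset (no multiple imputation or uncertainty bands), and no
subject-level random effects — every row is treated as an independent
observation, which understates within-subject correlation in longitudinal
data. Mixed-effects forests are the natural extension.

## Synthetic cohort generator

The generator emulates the two-cohort structure the analysis assumes, at
configurable scale. Defaults mirror the reported characteristics of the
cohorts being emulated: 1805 + 2122 subjects; class mixes ≈ (66/17/18)%
and (37/41/22)%; baseline age ≈ 72.4 ± 7.6 and 73.3 ± 7.2 years;
per-study sex, APOE (0/1/2) and education mixes renormalized over
subjects with non-missing values; 18-month vs 3-then-6-month visit
grids to 90 months. A per-visit retention probability of 0.85 (geometric
dropout, baseline always observed) yields a B:A observation-count ratio
of about 1.7. Dropout is non-informative in v1.

Scores follow

    score(i, v, t) = mean[v, class] + decline[v, class]·t
                     + loading[v]·latent(i, t) + shift[study, v] + ε

with `latent(i, t) = b_i + slope_class·t + e_it` a shared latent memory
factor (`b_i ~ N(0, 0.7)`, visit noise SD 0.25, mean zero per class at
baseline so class means are identifiable), integer scores rounded
half-away-from-zero then clipped. The two list-learning tests carry the
largest loadings (9 and 8 score units per latent unit against noise SDs
of 4.0 and 3.8), which under the default class mix gives a complete-data
correlation ≈ 0.93 between them — the generative signal that makes
cross-study recovery of a never-measured test possible at all. Amyloid is
generated directly on a Centiloid-like scale (no image simulation):
class-dependent mean (25/55/85), +12 per ε4 allele, and a negative
coupling to the latent factor that strengthens with clinical severity and
ε4 dose, giving the MCI ε4/ε4 subgroup an amyloid–memory correlation
around −0.35.

Masking: the systematically missing columns are fully masked per study;
MCAR masking at a configurable rate (default 5%) applies to clinical and
cognitive scores; clinical class is masked at 2% to exercise the
adjacent-visit resolution rule. Ground truth for every masked cell, and
the latent factors, are returned alongside the released tables.

What the generator does **not** emulate: informative dropout,
practice/learning effects, class transitions over time (a subject's class
is constant), floor/ceiling-induced skew beyond clipping, site effects
within a study, and measurement error correlated across tests beyond the
single latent factor. Passing tests therefore demonstrate that the
pipeline's logic and statistics behave as intended under a favourable but
structurally realistic data-generating process — not that any particular
accuracy level will be attained on real cohort data.

## Validation experiments

Both experiments mask an outcome actually measured in both studies
(LMII-like by default), impute, and score MAE and Pearson r on the held
out cells over replicates (mean ± SE, with SE = sd/√replicates). The
single-study list-learning tests are excluded from these runs, as are the
rate-of-change columns at demo scale (see below).

* **Within vs cross** — per replicate the test study is size-matched to
  the smaller study, 25% of it is masked, and the identical masked cells
  are imputed once with same-study training rows and once with an equally
  sized sample of the other study. The experiment wrapper generates the
  two cohorts *fully exchangeable* (same schedule, class mix and
  demographics) so the no-shift comparison is a true null; an injected
  additive shift on study B's correlated predictors is then the only
  systematic difference. Splits are drawn at the subject level here:
  observation-level splits put a test subject's other visits into the
  within-study training set, whose shared subject effect gives the within
  arm a genuine advantage that has nothing to do with study differences.
  The row-level unit remains the default elsewhere, matching the
  long-format framing.
* **Missingness grid** — test fractions 10%…100% crossed with training
  fractions {10%, 50%, 100%} of the size-matched training study, the
  sub-sample redrawn every replicate.

## Evaluation

Class discrimination uses the classical Student pooled-variance
two-sample t (a Welch flag exists) and Cohen's d with the pooled-SD,
(n₁+n₂−2)-denominator form; p-values are reported raw, with no
multiplicity correction. The case study computes the Pearson r, two-sided
p and least-squares slope of memory score on Centiloid amyloid in the
MCI ε4/ε4 subgroup, for the measuring study alone and for the harmonized
pool; the analysis unit is the observation (subject-visit), unadjusted
for within-subject correlation and without covariates. Subgroups under 3
observations are flagged undefined rather than raising.

## Problem sizes and numerical choices

Library defaults are full scale (1805 + 2122 subjects, 100 trees, rates
included). The packaged experiments (`cogimpute.experiments`, used by the
test suite and `scripts/acceptance.py`) run at demo scale as the
package's own choice of a laptop-friendly operating point: 60–300
subjects per study, 25–50 trees, 10–50 replicates, MCAR confined to the
masked outcome and rate columns omitted so each sweep fits forests only
for the variables under study. The power case study enriches MCI
prevalence and ε4-homozygote frequency so the subgroup sizes echo the
small-single-study vs pooled contrast (≈ 9 vs ≈ 95 observations).

Tie-breaks and tolerances: modal-category ties go to the smallest label;
sweep order ties follow column order; forest predictions are checked
against the observed response range with 1e-8 slack; equality tests on
observed-cell preservation are exact (bit-identical). Degenerate inputs:
a column with zero observed values anywhere in the joined table is an
error (it must be dropped upstream); duplicate visit times for a subject
are an error; an empty mask in the simulated-missing wrapper reduces to a
plain imputation run.

## Known limitations

* Rows are independent to the imputer; within-subject correlation is
  exploited only indirectly through the rate-of-change predictors.
* A single completed dataset understates uncertainty; downstream p-values
  do not account for imputation variability.
* The two-cohort design is hard-coded in the experiment wrappers
  (the engine itself is study-count agnostic).
* Real-data accuracy claims are out of reach by construction — the
  experiments quantify behaviour under the synthetic generative process
  only.
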