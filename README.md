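# cogimpute

Cross-cohort **harmonization of longitudinal neuropsychological test
scores by iterative random-forest imputation**.

Observational aging cohorts administer overlapping but not identical
cognitive batteries: one study measures a 16-word structured list-learning
test (CVLT-II style), another a 15-word unstructured one (RAVLT style).
Pooling such cohorts for better-powered analyses of Alzheimer's disease
requires putting every subject-visit on a common set of variables.
`cogimpute` treats the scores a study never measured as *systematically
missing* cells of one joined long-format table and fills them — together
with ordinary randomly missing values — with a MissForest-style chained
random-forest imputer, then provides the simulation experiments and
effect-size analyses needed to decide whether the imputed scores can be
trusted.

It is aimed at biostatisticians and cohort-data managers who need a
tested, reproducible pipeline rather than a one-off script; every stage
runs on a bundled synthetic two-cohort generator, so the whole analysis is
exercisable without access to any restricted data.

## The method

Let `X = (X_1, …, X_p)` be the joined `r × p` table (default layout:
39 columns — identifiers, months since baseline, demographics including
clinical class CN/MCI/AD and APOE ε4 count, CDR and MMSE, 14 cognitive
scores, and per-score rate-of-change predictors
`(x_t − x_prev)/(t − t_prev)`). For a variable `X_k` with observed values
`y_obs` (rows `i_obs`) and missing values `y_mis` (rows `i_mis`):

1. initialize every missing cell with the column's median (numeric) or
   modal category;
2. for each `X_k` with missing cells, in order of ascending missingness:
   fit a random forest with response `y_obs` and predictors `X_obs` (all
   other columns in their current imputed state, identifiers excluded),
   predict `y_mis`, overwrite;
3. after each full sweep compute
   `Δ_num = Σ(X_new − X_old)² / Σ X_new²` over imputed numeric cells and
   the disagreement fraction over imputed categorical cells; stop the
   first time either Δ rises, returning the previous sweep's values
   (at most 10 sweeps);
4. round bounded integer scores to the nearest integer and clip to their
   valid range.

Imputation quality is scored on held-out cells with
`MAE = (1/N) Σ |x_actual − x_imputed|` and the Pearson correlation;
class separation uses Student's pooled-variance t and Cohen's d with
pooled SD.

## Worked example

```python
from cogimpute import (default_schema, generate_cohorts, harmonize_studies,
                       MissForest, ImputationConfig, case_study,
                       compare_actual_vs_imputed)
from cogimpute.synthetic import demo_config

schema = default_schema()
cfg = demo_config(seed=7, n_a=300, n_b=300).with_overrides(
    mcar_rate=0.0, class_missing_rate=0.0)
tables, truth = generate_cohorts(cfg, schema)     # study B never measures CVLT
joined, log = harmonize_studies(tables, schema, include_rates=False)

model = MissForest(joined, schema, ImputationConfig(
    n_trees=50, rng_seed=7,
    excluded_predictors=frozenset({"dataset_id", "clinical_class"})))
res = model.fit()
print(res.summary())
```

```
Iterative random-forest imputation
============================================
Columns imputed                            2
Cells imputed                           2623
Trees per forest                          50
Sweeps run                                 5
Stopped by                         criterion
--------------------------------------------
 sweep       delta_numeric delta_categorical
     1            0.161118                 0
     2          0.00318136                 0
     3         0.000545809                 0
     4         0.000514901                 0
     5         0.000590058                 0
```

The engine imputed the two never-measured list-learning columns (2623
cells), converging when the sweep-to-sweep change rose at sweep 5 (the
sweep-4 values are kept). Do the imputed scores behave like measured
ones?

```python
disc, boxes = compare_actual_vs_imputed(joined, res.completed,
                                        "cvlt_immediate", schema)
print(disc[["pair", "source", "t_statistic", "p_value", "cohens_d"]])
```

```
  pair  source  t_statistic  p_value  cohens_d
CN-MCI  actual       21.482      0.0     1.946
 CN-AD  actual       40.916      0.0     3.791
MCI-AD  actual       15.002      0.0     1.757
CN-MCI imputed       42.441      0.0     2.359
 CN-AD imputed       68.839      0.0     4.528
MCI-AD imputed       35.578      0.0     2.265
```

Imputed study-B scores separate the clinical classes as strongly as the
measured study-A scores (all p < 0.001, |d| > 1). The pooled table then
powers an analysis neither cohort supports alone — the amyloid–memory
association in MCI APOE ε4 homozygotes:

```python
cs = case_study(res.completed, "cvlt_immediate", "amyloid_centiloid", schema)
for arm, r in cs.items():
    print(f"{arm}: n={r.n_observations} r={r.pearson_r:.3f} p={r.p_value:.4f}")
```

```
single_study: n=14 r=-0.296 p=0.3036
harmonized: n=90 r=-0.383 p=0.0002
```

The negative amyloid–memory correlation is invisible in the 14
measuring-study observations but clearly significant in the 90
harmonized ones.

## Command line

```bash
cogimpute simulate  --seed 1 --out run/                 # synthetic cohorts + truth
cogimpute harmonize --study A=run/study_A.csv --study B=run/study_B.csv \
                    --out run/joined.csv
cogimpute impute    --in run/joined.csv --trees 100 --seed 1 \
                    --out run/completed.csv
cogimpute validate  --mode within-cross --outcome lm_ii \
                    --study A=run/study_A.csv --study B=run/study_B.csv \
                    --reps 100 --seed 1 --out run/validation.csv
cogimpute evaluate  --joined run/joined.csv --completed run/completed.csv \
                    --variable cvlt_immediate --out run/discrimination.csv
cogimpute run-all   --config demo.yaml                  # all stages + manifest
```

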