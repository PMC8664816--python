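"""Simulation-based validation of the imputation engine.

Two experiment families, each masking an outcome variable (an LMII-like or
MMSE-like score measured by both studies) on rows where it is actually
observed, imputing, and scoring the imputed against the held-out values
with the mean absolute error

    MAE = (1/N) * sum_i |actual_i - imputed_i|

and the Pearson correlation:

* within vs cross: is imputing a study's missing scores from its own
  remaining rows more accurate than imputing from the other study's rows?
  Per replicate the test study is size-matched to the smaller study, a
  test fraction (default 25%) of its rows is masked, and the same masked
  cells are imputed once with same-study training rows ("within") and once
  with an equally sized training sample from the other study ("cross").
* missingness grid: how do accuracy metrics move as the masked fraction of
  the test study (10%..100%) and the size of the training study (10%, 50%,
  100%) vary?

The list-learning scores measured by only one study are excluded from both
experiments, as are (optionally) the rate-of-change columns; the dataset
identifier is never shown to the forests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .missforest import ImputationConfig, MissForest
from .schema import Schema

__all__ = [
    "ValidationConfig",
    "ValidationReport",
    "mae",
    "pearson_r",
    "subsample_to_match",
    "run_within_vs_cross",
    "run_missingness_grid",
]


def mae(actual: Sequence[float], imputed: Sequence[float]) -> float:
    """Mean absolute error between held-out actual and imputed values."""
    a = np.asarray(actual, float)
    b = np.asarray(imputed, float)
    if a.size == 0:
        raise ValueError("empty input")
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing entries in metric input")
    return float(np.mean(np.abs(a - b)))


def pearson_r(actual: Sequence[float], imputed: Sequence[float]) -> float:
    """Pearson correlation between held-out actual and imputed values."""
    a = np.asarray(actual, float)
    b = np.asarray(imputed, float)
    if a.size != b.size:
        raise ValueError("length mismatch")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    return float(stats.pearsonr(a, b)[0])


@dataclass(frozen=True)
class ValidationConfig:
    """Experiment parameters.

    ``resample_unit`` chooses whether random splits draw observation rows
    (subject-visits, the default) or whole subjects.  ``include_rates``
    keeps/drops the rate-of-change predictor columns; dropping them (and
    using tables free of other missingness) confines the forest fits to the
    outcome variable, which is how the demo-scale experiments stay fast.
    """

    outcome_variable: str = "lm_ii"
    n_replicates: int = 100
    test_fraction: float = 0.25
    test_fractions_grid: tuple[float, ...] = tuple(
        round(0.1 * k, 1) for k in range(1, 11))
    train_fractions_grid: tuple[float, ...] = (0.1, 0.5, 1.0)
    seed: int = 0
    resample_unit: str = "observation"
    include_rates: bool = False
    imputation: ImputationConfig = field(
        default_factory=lambda: ImputationConfig(n_trees=100))

    def __post_init__(self) -> None:
        fracs = (self.test_fraction, *self.test_fractions_grid,
                 *self.train_fractions_grid)
        if any(not (0.0 < f <= 1.0) for f in fracs):
            raise ValueError("fractions must lie in (0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.resample_unit not in ("observation", "subject"):
            raise ValueError("resample_unit must be 'observation' or 'subject'")

    def with_overrides(self, **kwargs) -> "ValidationConfig":
        return replace(self, **kwargs)


@dataclass
class ValidationReport:
    """Per-replicate records plus mean ± standard-error summaries."""

    records: pd.DataFrame
    outcome_variable: str

    _GROUP_CANDIDATES = ("arm", "test_fraction", "train_fraction")

    def summarize(self) -> pd.DataFrame:
        keys = [k for k in self._GROUP_CANDIDATES if k in self.records.columns]
        g = self.records.groupby(keys, sort=True)
        out = g.agg(
            n_replicates=("mae", "size"),
            mae_mean=("mae", "mean"),
            mae_se=("mae", lambda s: s.std(ddof=1) / np.sqrt(len(s))
                    if len(s) > 1 else 0.0),
            pearson_mean=("pearson_r", "mean"),
            pearson_se=("pearson_r", lambda s: s.std(ddof=1) / np.sqrt(len(s))
                        if len(s) > 1 else 0.0),
        ).reset_index()
        return out

    def summary(self) -> str:
        s = self.summarize()
        lines = [f"Imputation validation — outcome: {self.outcome_variable}",
                 "=" * 66]
        keys = [k for k in self._GROUP_CANDIDATES if k in s.columns]
        header = "".join(f"{k:>16}" for k in keys)
        lines.append(header + f"{'MAE':>16}{'Pearson r':>16}")
        for _, row in s.iterrows():
            cell = "".join(
                f"{row[k]:>16}" if isinstance(row[k], str)
                else f"{row[k]:>16.2f}" for k in keys)
            lines.append(cell + f"{row['mae_mean']:>10.3f} ± "
                         f"{row['mae_se']:.3f}"
                         f"{row['pearson_mean']:>10.3f} ± "
                         f"{row['pearson_se']:.3f}")
        return "\n".join(lines)


def _observed_rows(df: pd.DataFrame, outcome: str) -> pd.DataFrame:
    return df.loc[df[outcome].notna()].reset_index(drop=True)


def subsample_to_match(larger: pd.DataFrame, target_size: int,
                       seed: int, outcome: str | None = None) -> pd.DataFrame:
    """Uniform row subsample without replacement, seeded.

    When ``outcome`` is given, sampling is restricted to rows where the
    outcome is observed — size-matching counts observations with the
    outcome measured, not raw rows.
    """
    pool = _observed_rows(larger, outcome) if outcome else larger
    if target_size > len(pool):
        raise ValueError(
            f"target_size {target_size} exceeds available rows {len(pool)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=target_size, replace=False)
    return pool.iloc[np.sort(idx)].reset_index(drop=True)


def _validation_columns(schema: Schema, df: pd.DataFrame,
                        cfg: ValidationConfig) -> list[str]:
    drop = set(schema.systematic_targets()) | set(schema.auxiliary_names())
    if not cfg.include_rates:
        drop |= set(schema.rate_names)
    else:
        drop |= {v.canonical_name for v in schema
                 if v.rate_of in schema.systematic_targets()}
    return [c for c in df.columns if c not in drop]


def _split_sizes(n: int, frac: float) -> int:
    return max(1, int(round(n * frac)))


def _draw(rng: np.random.Generator, df: pd.DataFrame, size: int,
          unit: str) -> np.ndarray:
    """Row positions of a random sample, by observation or by subject."""
    if unit == "observation":
        return rng.choice(len(df), size=size, replace=False)
    subjects = df["participant_id"].unique()
    order = rng.permutation(subjects)
    counts = df["participant_id"].value_counts()
    chosen: list[str] = []
    total = 0
    for s in order:
        chosen.append(s)
        total += int(counts[s])
        if total >= size:
            break
    sel = df["participant_id"].isin(chosen)
    return np.flatnonzero(sel.to_numpy())


def run_within_vs_cross(
    study_test: pd.DataFrame,
    study_other: pd.DataFrame,
    schema: Schema,
    config: ValidationConfig | None = None,
) -> ValidationReport:
    """First validation experiment: same-study vs cross-study training.

    Per replicate, the two arms share an identical test mask; "within"
    trains on the remaining rows of the test study, "cross" on an equally
    sized random sample of the other study.
    """
    cfg = config or ValidationConfig()
    outcome = cfg.outcome_variable
    test_all = _observed_rows(study_test, outcome)
    other_all = _observed_rows(study_other, outcome)
    if test_all.empty or other_all.empty:
        raise ValueError(f"outcome {outcome!r} unobserved in one study")
    cols = _validation_columns(schema, test_all, cfg)
    imp_cfg = cfg.imputation.with_overrides(
        excluded_predictors=frozenset(cfg.imputation.excluded_predictors)
        | {"dataset_id"})

    records = []
    for rep in range(cfg.n_replicates):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(cfg.seed) % (2**31), 11, rep]))
        m = min(len(test_all), len(other_all))
        test_pool = test_all.iloc[
            np.sort(rng.choice(len(test_all), m, replace=False))]
        test_pool = test_pool.reset_index(drop=True)
        n_test = _split_sizes(m, cfg.test_fraction)
        test_pos = _draw(rng, test_pool, n_test, cfg.resample_unit)
        is_test = np.zeros(m, bool)
        is_test[test_pos] = True
        test_rows = test_pool.loc[is_test, cols].reset_index(drop=True)
        train_within = test_pool.loc[~is_test, cols].reset_index(drop=True)
        n_train = len(train_within)
        cross_pos = rng.choice(len(other_all), min(n_train, len(other_all)),
                               replace=False)
        train_cross = other_all.iloc[np.sort(cross_pos)][cols]
        train_cross = train_cross.reset_index(drop=True)

        actual = test_rows[outcome].to_numpy(float)
        for arm, train in (("within", train_within), ("cross", train_cross)):
            masked = test_rows.copy()
            masked[outcome] = np.nan
            table = pd.concat([train, masked], ignore_index=True)
            seed = int(np.random.SeedSequence(
                [int(cfg.seed) % (2**31), 13, rep,
                 0 if arm == "within" else 1]).generate_state(1)[0] % (2**31))
            res = MissForest(table, schema.subset(cols),
                             imp_cfg.with_overrides(rng_seed=seed)).fit()
            imputed = res.completed[outcome].to_numpy(float)[len(train):]
            records.append({"replicate": rep, "arm": arm,
                            "mae": mae(actual, imputed),
                            "pearson_r": pearson_r(actual, imputed)})
    return ValidationReport(pd.DataFrame(records), outcome)


def run_missingness_grid(
    train_study: pd.DataFrame,
    test_study: pd.DataFrame,
    schema: Schema,
    config: ValidationConfig | None = None,
) -> ValidationReport:
    """Second validation experiment: vary test missingness and training size.

    For every (test_fraction, train_fraction) grid cell and replicate, a
    ``test_fraction`` of the test study's outcome values is masked and the
    training data is a ``train_fraction`` sample of the size-matched
    training study; both studies' rows are joined before imputing.
    """
    cfg = config or ValidationConfig()
    outcome = cfg.outcome_variable
    test_all = _observed_rows(test_study, outcome)
    train_all = _observed_rows(train_study, outcome)
    if test_all.empty or train_all.empty:
        raise ValueError(f"outcome {outcome!r} unobserved in one study")
    cols = _validation_columns(schema, test_all, cfg)
    sub_schema = schema.subset(cols)
    imp_cfg = cfg.imputation.with_overrides(
        excluded_predictors=frozenset(cfg.imputation.excluded_predictors)
        | {"dataset_id"})

    m = min(len(test_all), len(train_all))
    records = []
    for rep in range(cfg.n_replicates):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(cfg.seed) % (2**31), 17, rep]))
        train_pool = train_all.iloc[
            np.sort(rng.choice(len(train_all), m, replace=False))]
        train_pool = train_pool.reset_index(drop=True)
        for tf, trf in product(cfg.test_fractions_grid,
                               cfg.train_fractions_grid):
            n_test = _split_sizes(len(test_all), tf)
            test_pos = _draw(rng, test_all, n_test, cfg.resample_unit)
            test_rows = test_all.iloc[np.sort(test_pos)][cols]
            test_rows = test_rows.reset_index(drop=True)
            n_train = _split_sizes(m, trf)
            train_pos = rng.choice(m, n_train, replace=False)
            train = train_pool.iloc[np.sort(train_pos)][cols]
            train = train.reset_index(drop=True)

            actual = test_rows[outcome].to_numpy(float)
            masked = test_rows.copy()
            masked[outcome] = np.nan
            table = pd.concat([train, masked], ignore_index=True)
            seed = int(np.random.SeedSequence(
                [int(cfg.seed) % (2**31), 19, rep,
                 int(tf * 100), int(trf * 100)]
            ).generate_state(1)[0] % (2**31))
            res = MissForest(table, sub_schema,
                             imp_cfg.with_overrides(rng_seed=seed)).fit()
            imputed = res.completed[outcome].to_numpy(float)[len(train):]
            records.append({"replicate": rep, "test_fraction": tf,
                            "train_fraction": trf,
                            "mae": mae(actual, imputed),
                            "pearson_r": pearson_r(actual, imputed)})
    return ValidationReport(pd.DataFrame(records), outcome)
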