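"""Iterative random-forest imputation of mixed-type tables.

The engine fills every missing cell of a joined long-format table by
cycling over variables: for each variable with missing values it fits a
random forest on the rows where that variable is observed (response
``y_obs``, predictors = all other columns in their current imputed state)
and predicts the missing rows, repeating full sweeps until the change
between successive sweeps starts increasing — at which point the previous
sweep's values are returned — or a maximum number of sweeps is reached.

Mixed types are handled natively by the forest base learner: bounded
integer test scores are treated as regression targets and rounded to the
nearest integer afterwards; categorical variables use classification
forests.  Ordered categoricals (the education bins) enter predictors as
integer codes, unordered ones (sex, clinical class) as one-of-K
indicators; both encodings are invertible.

Usage follows the model/results idiom::

    model = MissForest(joined, schema, ImputationConfig(n_trees=100))
    res = model.fit()
    res.completed          # table with no missing cells
    res.delta_trace        # per-sweep convergence deltas
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .schema import Schema, VariableSchema

__all__ = [
    "ImputationConfig",
    "MissForest",
    "MissForestResults",
    "ImputationError",
    "UnimputableColumnError",
    "initialize",
    "impute",
    "impute_with_simulated_missing",
    "stop_index",
]


class ImputationError(ValueError):
    pass


class UnimputableColumnError(ImputationError):
    """A column to impute has no observed values at all."""


@dataclass(frozen=True)
class ImputationConfig:
    """Tuning knobs of the imputation engine.

    ``n_trees=100`` and ``max_iterations=10`` are the full-scale defaults;
    demo runs typically use 25 trees.  ``excluded_predictors`` always
    contains the two identifiers — extend it (e.g. with ``clinical_class``)
    to keep a variable out of every forest while still imputing it.
    ``visit_order_policy`` selects the sweep order over variables:
    ``ascending_missingness`` (fewest originally-missing cells first, the
    reference convention) or ``schema_order``.
    """

    n_trees: int = 100
    max_iterations: int = 10
    excluded_predictors: frozenset[str] = frozenset()
    rng_seed: int = 0
    visit_order_policy: str = "ascending_missingness"
    bootstrap: bool = True
    max_features: float | str = "sqrt"
    min_samples_leaf: int | None = None  # None -> 5 regression, 1 classification
    exclude_target_rate: bool = False

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ImputationError("n_trees must be >= 1")
        if self.max_iterations < 1:
            raise ImputationError("max_iterations must be >= 1")
        if self.visit_order_policy not in ("ascending_missingness", "schema_order"):
            raise ImputationError(
                f"unknown visit_order_policy {self.visit_order_policy!r}")

    def with_overrides(self, **kwargs) -> "ImputationConfig":
        return replace(self, **kwargs)


def stop_index(delta_trace: Sequence[tuple[float, float]]) -> int | None:
    """First-increase stopping rule on a sweep-delta trace.

    Given per-sweep ``(delta_numeric, delta_categorical)`` pairs, return the
    index of the sweep whose values should be kept — the sweep before the
    first one where either delta increased — or ``None`` if the trace never
    increases.  A trace ``[0.50, 0.20, 0.30]`` stops after the third sweep
    and keeps the second (index 1).
    """
    for i in range(1, len(delta_trace)):
        if (delta_trace[i][0] > delta_trace[i - 1][0]
                or delta_trace[i][1] > delta_trace[i - 1][1]):
            return i - 1
    return None


def _mode_smallest(s: pd.Series):
    counts = s.value_counts()
    top = counts[counts == counts.max()]
    return sorted(top.index)[0]


def initialize(table: pd.DataFrame, schema: Schema,
               columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Fill missing cells with column medians (numeric) or modes (categorical).

    The median/mode is taken over the whole joined table, mirroring the
    initialization of the iterative scheme.  A column with zero observed
    values cannot be initialized and raises.
    """
    out = table.copy()
    cols = columns if columns is not None else [
        c for c in table.columns
        if c in schema and schema[c].role not in ("identifier", "auxiliary")
    ]
    for c in cols:
        col = out[c]
        if not col.isna().any():
            continue
        obs = col.dropna()
        if obs.empty:
            raise UnimputableColumnError(
                f"column {c!r} has no observed values; drop it upstream")
        if schema[c].is_numeric:
            fill = float(obs.median())
        else:
            fill = _mode_smallest(obs)
        out[c] = col.fillna(fill)
    return out


@dataclass
class MissForestResults:
    """Completed table plus convergence diagnostics.

    ``iterations_run`` counts the forest sweeps executed; when the stopping
    criterion fires at sweep *k*, sweep *k-1*'s values are the ones kept.
    """

    completed: pd.DataFrame
    iterations_run: int
    delta_trace: pd.DataFrame
    stopped_by: str
    imputed_mask: pd.DataFrame
    config: ImputationConfig

    @property
    def completed_table(self) -> pd.DataFrame:  # spec-facing alias
        return self.completed

    def imputed_values(self, column: str) -> pd.Series:
        """The imputed (originally missing) entries of one column."""
        return self.completed.loc[self.imputed_mask[column], column]

    def summary(self) -> str:
        n_cells = int(self.imputed_mask.to_numpy().sum())
        lines = [
            "Iterative random-forest imputation",
            "=" * 44,
            f"{'Columns imputed':<28}{int((self.imputed_mask.sum() > 0).sum()):>16}",
            f"{'Cells imputed':<28}{n_cells:>16}",
            f"{'Trees per forest':<28}{self.config.n_trees:>16}",
            f"{'Sweeps run':<28}{self.iterations_run:>16}",
            f"{'Stopped by':<28}{self.stopped_by:>16}",
            "-" * 44,
            f"{'sweep':>6}{'delta_numeric':>20}{'delta_categorical':>18}",
        ]
        for _, row in self.delta_trace.iterrows():
            lines.append(f"{int(row['sweep']):>6}{row['delta_numeric']:>20.6g}"
                         f"{row['delta_categorical']:>18.6g}")
        return "\n".join(lines)


class MissForest:
    """Chained random-forest imputation model for one canonical table.

    Parameters
    ----------
    data : DataFrame
        Canonical-column table (typically the joined two-study dataset).
        Identifier and auxiliary columns are never used as predictors nor
        imputed.
    schema : Schema
        Variable definitions (types, ranges, roles).
    config : ImputationConfig, optional
    """

    def __init__(self, data: pd.DataFrame, schema: Schema,
                 config: ImputationConfig | None = None):
        self.data = data
        self.schema = schema
        self.config = config or ImputationConfig()
        unknown = [c for c in data.columns if c not in schema]
        if unknown:
            raise ImputationError(f"columns not in schema: {unknown}")
        self._model_cols = [
            c for c in data.columns
            if schema[c].role not in ("identifier", "auxiliary")
        ]
        self._excluded = (set(schema.identifier_names)
                          | set(self.config.excluded_predictors)
                          | set(schema.auxiliary_names()))

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, schema: Schema,
                       **config_kwargs) -> "MissForest":
        return cls(data, schema, ImputationConfig(**config_kwargs))

    # -- encoding ----------------------------------------------------------

    def _levels(self, var: VariableSchema, values: pd.Series) -> list:
        if var.levels and var.levels != ("*",):
            return list(var.levels)
        return sorted(values.dropna().unique())

    def _encode_block(self, values: pd.Series, var: VariableSchema) -> np.ndarray:
        """Encode one fully-observed column as a 2-D float block."""
        if var.is_numeric:
            return values.to_numpy(float)[:, None]
        levels = self._levels(var, values)
        if var.ordered:
            codes = values.map({lv: i for i, lv in enumerate(levels)})
            return codes.to_numpy(float)[:, None]
        return np.column_stack(
            [(values == lv).to_numpy(float) for lv in levels])

    # -- fitting -----------------------------------------------------------

    def fit(self) -> MissForestResults:
        cfg = self.config
        schema = self.schema
        work = self.data.copy()
        miss = {c: self.data[c].isna().to_numpy() for c in self._model_cols}
        imputable = [c for c in self._model_cols if miss[c].any()]
        mask_frame = pd.DataFrame(
            {c: miss.get(c, np.zeros(len(work), bool))
             for c in self.data.columns}, index=self.data.index)

        if not imputable:
            trace = pd.DataFrame(
                columns=["sweep", "delta_numeric", "delta_categorical"])
            return MissForestResults(work, 0, trace, "criterion",
                                     mask_frame, cfg)

        work = initialize(work, schema, self._model_cols)

        if cfg.visit_order_policy == "ascending_missingness":
            order = sorted(imputable,
                           key=lambda c: (int(miss[c].sum()),
                                          self._model_cols.index(c)))
        else:
            order = [c for c in self._model_cols if c in imputable]

        num_targets = [c for c in imputable if schema[c].is_numeric]
        cat_targets = [c for c in imputable if not schema[c].is_numeric]

        blocks = {c: self._encode_block(work[c], schema[c])
                  for c in self._model_cols}

        def predictor_matrix(target: str) -> np.ndarray:
            drop = {target} | self._excluded
            if cfg.exclude_target_rate:
                drop |= {v.canonical_name for v in schema
                         if v.rate_of == target}
            cols = [c for c in self._model_cols if c not in drop]
            return np.hstack([blocks[c] for c in cols])

        trace: list[tuple[float, float]] = []
        prev_state = {c: work[c].to_numpy()[miss[c]].copy() for c in imputable}
        kept_state = None
        stopped_by = "max_iterations"
        iterations_run = 0

        for sweep in range(1, cfg.max_iterations + 1):
            iterations_run = sweep
            before = {c: work[c].to_numpy()[miss[c]].copy() for c in imputable}
            for k, col in enumerate(order):
                var = schema[col]
                seed = int(np.random.SeedSequence(
                    [int(cfg.rng_seed) % (2**31), sweep, k]
                ).generate_state(1)[0] % (2**31))
                X = predictor_matrix(col)
                obs = ~miss[col]
                y_obs = work.loc[obs, col]
                if var.is_numeric:
                    leaf = cfg.min_samples_leaf or 5
                    forest = RandomForestRegressor(
                        n_estimators=cfg.n_trees, bootstrap=cfg.bootstrap,
                        max_features=cfg.max_features,
                        min_samples_leaf=leaf, random_state=seed, n_jobs=1)
                    forest.fit(X[obs], y_obs.to_numpy(float))
                    pred = forest.predict(X[miss[col]])
                    lo, hi = float(y_obs.min()), float(y_obs.max())
                    if pred.size and (pred.min() < lo - 1e-8
                                      or pred.max() > hi + 1e-8):
                        raise ImputationError(
                            f"{col!r}: forest prediction escaped the observed "
                            f"response range [{lo}, {hi}]")
                    work.loc[miss[col], col] = pred
                else:
                    leaf = cfg.min_samples_leaf or 1
                    forest = RandomForestClassifier(
                        n_estimators=cfg.n_trees, bootstrap=cfg.bootstrap,
                        max_features=cfg.max_features,
                        min_samples_leaf=leaf, random_state=seed, n_jobs=1)
                    forest.fit(X[obs], y_obs.astype(str).to_numpy())
                    pred = forest.predict(X[miss[col]])
                    work.loc[miss[col], col] = pred
                blocks[col] = self._encode_block(work[col], var)

            d_num = 0.0
            if num_targets:
                new_sq = 0.0
                diff_sq = 0.0
                for c in num_targets:
                    new = work[c].to_numpy(float)[miss[c]]
                    old = before[c].astype(float)
                    diff_sq += float(((new - old) ** 2).sum())
                    new_sq += float((new ** 2).sum())
                d_num = diff_sq / new_sq if new_sq > 0 else 0.0
            d_cat = 0.0
            if cat_targets:
                n_cells = sum(int(miss[c].sum()) for c in cat_targets)
                dis = sum(int((work[c].to_numpy()[miss[c]]
                               != before[c]).sum()) for c in cat_targets)
                d_cat = dis / n_cells if n_cells else 0.0
            trace.append((d_num, d_cat))

            keep = stop_index(trace)
            if keep is not None:
                # the state before this sweep is the sweep-(k-1) imputation
                kept_state = before
                stopped_by = "criterion"
                break
            prev_state = {c: work[c].to_numpy()[miss[c]].copy()
                          for c in imputable}

        if kept_state is None:
            kept_state = prev_state
        for c in imputable:
            col_vals = work[c].copy()
            col_vals.iloc[np.flatnonzero(miss[c])] = kept_state[c]
            work[c] = col_vals

        # final integer rounding and range clipping on imputed cells only
        for c in imputable:
            var = schema[c]
            if not var.is_numeric:
                continue
            vals = work[c].to_numpy(float)
            imp = vals[miss[c]]
            if var.integer_valued:
                imp = np.sign(imp) * np.floor(np.abs(imp) + 0.5)
            if var.valid_range is not None:
                imp = np.clip(imp, var.valid_range[0], var.valid_range[1])
            vals[miss[c]] = imp
            work[c] = vals

        trace_df = pd.DataFrame(
            [(i + 1, d[0], d[1]) for i, d in enumerate(trace)],
            columns=["sweep", "delta_numeric", "delta_categorical"])
        return MissForestResults(work, iterations_run, trace_df,
                                 stopped_by, mask_frame, cfg)


def impute(table: pd.DataFrame, schema: Schema,
           config: ImputationConfig | None = None) -> MissForestResults:
    """Convenience wrapper: build a :class:`MissForest` model and fit it."""
    return MissForest(table, schema, config).fit()


def impute_with_simulated_missing(
    table: pd.DataFrame,
    target_variable: str,
    mask: np.ndarray | pd.Series | Sequence,
    config: ImputationConfig | None = None,
    schema: Schema | None = None,
) -> tuple[MissForestResults, pd.Series]:
    """Mask observed cells of one variable, impute, return result + truth.

    ``mask`` is a boolean vector aligned to ``table`` (or a sequence of row
    labels).  Every masked cell must be observed in the input; the held-out
    actual values are returned for scoring.
    """
    if schema is None:
        raise ImputationError("schema is required")
    if isinstance(mask, (pd.Series, np.ndarray)) and np.asarray(mask).dtype == bool:
        mask_bool = pd.Series(np.asarray(mask), index=table.index)
    else:
        mask_bool = pd.Series(False, index=table.index)
        mask_bool.loc[list(mask)] = True
    masked_vals = table.loc[mask_bool, target_variable]
    if masked_vals.isna().any():
        raise ImputationError(
            f"mask references cells of {target_variable!r} that are already "
            "missing")
    simulated = table.copy()
    simulated.loc[mask_bool, target_variable] = np.nan
    result = MissForest(simulated, schema, config).fit()
    return result, masked_vals
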