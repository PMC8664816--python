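"""Build the joined long-format two-cohort dataset.

Pipeline (in this order): drop common variables too sparse in either study,
resolve or drop visits with missing clinical classification, drop visits
with fewer than three completed cognitive tests, re-baseline visit times,
derive rate-of-change predictors, and concatenate the studies into a single
table with a fixed canonical column layout (39 columns under the default
schema).  Every dropped row or variable is recorded with one primary reason
in an :class:`ExclusionLog`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import EDUCATION_LEVELS, Schema, TableValidationError

__all__ = [
    "ExclusionLog",
    "drop_sparse_variables",
    "resolve_classification",
    "drop_sparse_visits",
    "bin_education",
    "compute_rate_of_change",
    "join_studies",
    "harmonize_studies",
]


@dataclass
class ExclusionLog:
    """Audit trail of the inclusion/exclusion rules."""

    dropped_variables: list[tuple[str, str, float]] = field(default_factory=list)
    dropped_rows: list[tuple[str, str, float, str]] = field(default_factory=list)

    def add_variable(self, name: str, study: str, missing_fraction: float) -> None:
        self.dropped_variables.append((name, study, missing_fraction))

    def add_row(self, study: str, participant: str, months: float, reason: str) -> None:
        self.dropped_rows.append((study, participant, months, reason))

    def variables_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dropped_variables,
                            columns=["variable", "study", "missing_fraction"])

    def rows_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dropped_rows,
                            columns=["study", "participant_id",
                                     "months_since_baseline", "reason"])

    def n_rows_dropped(self, study: str | None = None) -> int:
        if study is None:
            return len(self.dropped_rows)
        return sum(1 for r in self.dropped_rows if r[0] == study)


def drop_sparse_variables(
    tables: dict[str, pd.DataFrame],
    schema: Schema,
    threshold: float = 0.5,
    log: ExclusionLog | None = None,
) -> tuple[dict[str, pd.DataFrame], ExclusionLog]:
    """Drop common variables with too much missing data in either study.

    A clinical/cognitive variable measured in both studies is removed from
    both when its missing fraction in either study reaches ``threshold``
    (default 50%).  Harmonization targets — variables measured in exactly
    one study — are exempt: their wholesale absence in the other study is
    the point of the exercise, not noise.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    log = log if log is not None else ExclusionLog()
    exempt = set(schema.systematic_targets())
    studies = list(tables)
    to_drop: dict[str, tuple[str, float]] = {}
    for var in schema:
        name = var.canonical_name
        if var.role not in ("clinical", "cognitive") or name in exempt:
            continue
        for study in studies:
            df = tables[study]
            if name not in df.columns or name not in schema.present_in(study):
                continue
            frac = float(df[name].isna().mean()) if len(df) else 0.0
            if frac >= threshold and name not in to_drop:
                to_drop[name] = (study, frac)
    out = {}
    for study in studies:
        out[study] = tables[study].drop(
            columns=[c for c in to_drop if c in tables[study].columns])
    for name, (study, frac) in to_drop.items():
        log.add_variable(name, study, frac)
    return out, log


def resolve_classification(
    table: pd.DataFrame,
    log: ExclusionLog | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Fill missing clinical classifications from adjacent visits, else drop.

    Within a subject's time-ordered visits, a visit with missing class
    inherits one only when its immediately preceding and following visits
    agree, or when it has exactly one adjacent visit whose class is known
    (first/last visit).  Ambiguous or unresolvable visits are dropped.
    """
    log = log if log is not None else ExclusionLog()
    keep_mask = np.ones(len(table), dtype=bool)
    filled = table["clinical_class"].copy()
    for (study, pid), idx in table.groupby(
            ["dataset_id", "participant_id"], sort=False).groups.items():
        idx = table.loc[idx].sort_values("months_since_baseline").index
        classes = table.loc[idx, "clinical_class"].tolist()
        months = table.loc[idx, "months_since_baseline"].tolist()
        for j, cls in enumerate(classes):
            if isinstance(cls, str):
                continue
            prev_c = classes[j - 1] if j > 0 else None
            next_c = classes[j + 1] if j + 1 < len(classes) else None
            prev_known = isinstance(prev_c, str)
            next_known = isinstance(next_c, str)
            if j > 0 and j + 1 < len(classes):
                if prev_known and next_known and prev_c == next_c:
                    filled.loc[idx[j]] = prev_c
                    continue
            elif prev_known != next_known and (prev_known or next_known):
                filled.loc[idx[j]] = prev_c if prev_known else next_c
                continue
            keep_mask[table.index.get_loc(idx[j])] = False
            log.add_row(study, pid, months[j], "unresolvable_classification")
    out = table.copy()
    out["clinical_class"] = filled
    out = out.loc[keep_mask].reset_index(drop=True)
    return out, log


def drop_sparse_visits(
    table: pd.DataFrame,
    schema: Schema,
    min_tests: int = 3,
    log: ExclusionLog | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop visits with fewer than ``min_tests`` completed cognitive tests."""
    log = log if log is not None else ExclusionLog()
    cog = [c for c in schema.cognitive_names if c in table.columns]
    n_done = table[cog].notna().sum(axis=1)
    bad = n_done < min_tests
    for _, row in table.loc[bad].iterrows():
        log.add_row(row["dataset_id"], row["participant_id"],
                    row["months_since_baseline"], "too_few_tests")
    return table.loc[~bad].reset_index(drop=True), log


def bin_education(years: float) -> str:
    """Map years of education to the four ordinal bins <9, 9-12, 13-15, 15+.

    Boundaries are read so integer year counts land in the literally labelled
    bin: [0,9) -> "<9", [9,13) -> "9-12", [13,16) -> "13-15", >=16 -> "15+".
    """
    y = float(years)
    if y < 0 or not np.isfinite(y):
        raise TableValidationError(f"invalid years of education: {years!r}")
    if y < 9:
        return EDUCATION_LEVELS[0]
    if y < 13:
        return EDUCATION_LEVELS[1]
    if y < 16:
        return EDUCATION_LEVELS[2]
    return EDUCATION_LEVELS[3]


def rebaseline(table: pd.DataFrame) -> pd.DataFrame:
    """Shift each subject's visit times so the earliest retained visit is 0."""
    out = table.copy()
    first = out.groupby(["dataset_id", "participant_id"])[
        "months_since_baseline"].transform("min")
    out["months_since_baseline"] = out["months_since_baseline"] - first
    return out


def compute_rate_of_change(
    table: pd.DataFrame,
    schema: Schema,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Add rate-of-change columns: (current − previous non-missing) / months.

    The rate at a visit uses the nearest previous visit where the score is
    non-missing; it is missing at the first visit and wherever no earlier
    non-missing value exists.
    """
    rate_vars = [v for v in schema if v.rate_of is not None]
    if variables is not None:
        rate_vars = [v for v in rate_vars if v.rate_of in variables]
    rate_vars = [v for v in rate_vars if v.rate_of in table.columns]
    out = table.copy()
    for v in rate_vars:
        out[v.canonical_name] = np.nan
    for _, idx in out.groupby(["dataset_id", "participant_id"],
                              sort=False).groups.items():
        sub = out.loc[idx].sort_values("months_since_baseline")
        months = sub["months_since_baseline"].to_numpy(float)
        if len(months) > 1 and np.any(np.diff(months) <= 0):
            raise TableValidationError(
                f"duplicate visit times for participant "
                f"{sub['participant_id'].iloc[0]!r}")
        for v in rate_vars:
            scores = sub[v.rate_of].to_numpy(float)
            rates = np.full(len(sub), np.nan)
            prev_val, prev_t = np.nan, np.nan
            for j in range(len(sub)):
                if j > 0 and np.isfinite(prev_val) and np.isfinite(scores[j]):
                    rates[j] = (scores[j] - prev_val) / (months[j] - prev_t)
                if np.isfinite(scores[j]):
                    prev_val, prev_t = scores[j], months[j]
            out.loc[sub.index, v.canonical_name] = rates
    return out


def join_studies(
    tables: dict[str, pd.DataFrame],
    schema: Schema,
    namespace_ids: bool = True,
) -> pd.DataFrame:
    """Concatenate per-study tables into the joined canonical layout.

    Participant IDs are namespaced by study to avoid cross-study collisions.
    Variables unmeasured in a study are present as all-missing columns.
    Auxiliary variables (e.g. the Centiloid amyloid value) ride along after
    the layout columns but are not part of the joined layout itself.
    """
    layout = schema.joined_layout()
    dropped = {
        name for name in layout
        if all(name not in df.columns for df in tables.values())
        and schema[name].role in ("clinical", "cognitive")
    }
    dropped |= {
        v.canonical_name for v in schema
        if v.rate_of is not None and v.rate_of in dropped
    }
    layout = [c for c in layout if c not in dropped]
    aux = [c for c in schema.auxiliary_names()
           if any(c in df.columns for df in tables.values())]
    parts = []
    for study, df in tables.items():
        part = df.copy()
        if namespace_ids:
            part["participant_id"] = study + "_" + part["participant_id"].astype(str)
        part["dataset_id"] = study
        for col in layout + aux:
            if col not in part.columns:
                part[col] = np.nan
        parts.append(part[layout + aux])
    joined = pd.concat(parts, ignore_index=True)
    return joined


def harmonize_studies(
    tables: dict[str, pd.DataFrame],
    schema: Schema,
    sparse_threshold: float = 0.5,
    min_tests: int = 3,
    include_rates: bool = True,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Run the full harmonization pipeline on per-study canonical tables."""
    log = ExclusionLog()
    tables, log = drop_sparse_variables(tables, schema, sparse_threshold, log)
    cleaned: dict[str, pd.DataFrame] = {}
    for study, df in tables.items():
        df, log = resolve_classification(df, log)
        df, log = drop_sparse_visits(df, schema, min_tests, log)
        df = rebaseline(df)
        if include_rates:
            df = compute_rate_of_change(df, schema)
        cleaned[study] = df
    joined = join_studies(cleaned, schema)
    if not include_rates:
        joined = joined.drop(columns=[c for c in schema.rate_names
                                      if c in joined.columns])
    return joined, log
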