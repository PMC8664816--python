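"""Canonical variable schema and study-table I/O.

Two longitudinal cohorts record overlapping neuropsychological batteries
under different variable names, types and codings.  Everything downstream
(harmonization, imputation, validation) works on a single canonical column
vocabulary defined here.  A :class:`VariableSchema` describes one canonical
variable — its type, valid range, role in the analysis and its source name
in each study — and a :class:`Schema` is the ordered collection of them.

Missingness is coded internally as NaN (``pandas`` missing); on disk a
missing cell is an empty string, and the literal token ``"NA"`` is accepted
on read, matching the convention of coding every missing value — randomly
missing or systematically unmeasured — as NA in the joined dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "TableValidationError",
    "VariableSchema",
    "Schema",
    "default_schema",
    "load_schema",
    "save_schema",
    "load_study_table",
    "write_table",
]

#: tokens interpreted as missing on read
MISSING_TOKENS = ("", "NA")

VAR_TYPES = ("continuous", "discrete", "categorical")
ROLES = ("identifier", "demographic", "clinical", "cognitive", "derived", "auxiliary")

CLINICAL_CLASSES = ("CN", "MCI", "AD")
EDUCATION_LEVELS = ("<9", "9-12", "13-15", "15+")
SEX_LEVELS = ("F", "M")


class SchemaError(ValueError):
    """Schema inconsistency or a table/header that contradicts the schema."""


class TableValidationError(ValueError):
    """A table cell violates its variable's type or range."""


@dataclass(frozen=True)
class VariableSchema:
    """Definition of one canonical variable.

    Parameters
    ----------
    canonical_name : str
        Name used in the joined dataset.
    var_type : {"continuous", "discrete", "categorical"}
    role : {"identifier", "demographic", "clinical", "cognitive", "derived", "auxiliary"}
    source_name_by_study : mapping study-id -> source column name
        Studies omitted here do not measure the variable at all
        (systematic missingness).
    valid_range : (low, high), optional
        Inclusive bounds in score units, required for bounded scores.
    integer_valued : bool
        Whether non-missing values must be integers (implies discrete).
    levels : tuple of str, optional
        Allowed categories, in order, for categorical variables.
    ordered : bool
        Whether the categorical levels are ordinal (e.g. education bins).
    rate_of : str, optional
        For derived rate-of-change columns, the canonical name of the score
        the rate is computed from.
    """

    canonical_name: str
    var_type: str
    role: str
    source_name_by_study: Mapping[str, str] = field(default_factory=dict)
    valid_range: tuple[float, float] | None = None
    integer_valued: bool = False
    levels: tuple[str, ...] | None = None
    ordered: bool = False
    rate_of: str | None = None

    def __post_init__(self) -> None:
        if self.var_type not in VAR_TYPES:
            raise SchemaError(f"{self.canonical_name}: bad var_type {self.var_type!r}")
        if self.role not in ROLES:
            raise SchemaError(f"{self.canonical_name}: bad role {self.role!r}")
        if self.integer_valued and self.var_type != "discrete":
            raise SchemaError(
                f"{self.canonical_name}: integer_valued requires var_type='discrete'"
            )
        if self.var_type == "categorical" and not self.levels:
            raise SchemaError(f"{self.canonical_name}: categorical variable needs levels")

    @property
    def is_numeric(self) -> bool:
        return self.var_type in ("continuous", "discrete")


class Schema:
    """Ordered collection of :class:`VariableSchema` records.

    The order of variables defines the joined-table column layout.
    """

    def __init__(self, variables: Iterable[VariableSchema]):
        self.variables: list[VariableSchema] = list(variables)
        names = [v.canonical_name for v in self.variables]
        if len(names) != len(set(names)):
            raise SchemaError("duplicate canonical names in schema")
        self._by_name = {v.canonical_name: v for v in self.variables}
        ids = [v for v in self.variables if v.role == "identifier"]
        if len(ids) != 2:
            raise SchemaError("schema must define exactly two identifier variables")
        for v in self.variables:
            if v.role in ("clinical", "cognitive") and v.valid_range is None:
                if v.var_type != "categorical":
                    raise SchemaError(
                        f"{v.canonical_name}: bounded score needs a valid_range"
                    )

    def __iter__(self):
        return iter(self.variables)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> VariableSchema:
        return self._by_name[name]

    def names(self, role: str | None = None) -> list[str]:
        if role is None:
            return [v.canonical_name for v in self.variables]
        return [v.canonical_name for v in self.variables if v.role == role]

    @property
    def identifier_names(self) -> list[str]:
        return self.names("identifier")

    @property
    def cognitive_names(self) -> list[str]:
        return self.names("cognitive")

    @property
    def rate_names(self) -> list[str]:
        return [v.canonical_name for v in self.variables if v.rate_of is not None]

    def joined_layout(self) -> list[str]:
        """Column order of the joined dataset (auxiliary columns excluded)."""
        return [v.canonical_name for v in self.variables if v.role != "auxiliary"]

    def auxiliary_names(self) -> list[str]:
        return self.names("auxiliary")

    def study_ids(self) -> list[str]:
        out: list[str] = []
        for v in self.variables:
            for s in v.source_name_by_study:
                if s not in out:
                    out.append(s)
        return out

    def present_in(self, study_id: str) -> list[str]:
        """Canonical names of variables the study measures (has a source name)."""
        return [
            v.canonical_name
            for v in self.variables
            if study_id in v.source_name_by_study
        ]

    def measuring_studies(self, name: str) -> list[str]:
        return sorted(self[name].source_name_by_study)

    def systematic_targets(self) -> list[str]:
        """Variables measured by exactly one study (harmonization targets)."""
        n_studies = len(self.study_ids())
        return [
            v.canonical_name
            for v in self.variables
            if v.source_name_by_study
            and len(v.source_name_by_study) == 1
            and n_studies > 1
        ]

    def subset(self, names: Sequence[str]) -> "Schema":
        keep = set(names) | set(self.identifier_names)
        return Schema([v for v in self.variables if v.canonical_name in keep])


# ---------------------------------------------------------------------------
# default schema
# ---------------------------------------------------------------------------

#: the 14 cognitive scores of the default battery: (name, range, A source, B source)
_COGNITIVE = [
    ("cvlt_immediate", (0, 80), "CVLT_TotImmRecall", None),
    ("ravlt_immediate", (0, 75), None, "RAVLT_IMMEDIATE"),
    ("lm_i", (0, 25), "LogMem_StoryA_Imm", "LIMMTOTAL"),
    ("lm_ii", (0, 25), "LogMem_StoryA_Del", "LDELTOTAL"),
    ("bnt", (0, 30), "BNT_Total", "BNTTOTAL"),
    ("digit_span_fwd", (0, 16), "DigitSpan_Fwd", "DSPANFOR"),
    ("digit_span_bwd", (0, 14), "DigitSpan_Bwd", "DSPANBAC"),
    ("digit_symbol", (0, 93), "DigitSymbol", "DIGITSCOR"),
    ("fluency_animal", (0, 40), "Fluency_Animals", "CATANIMSC"),
    ("fluency_letter", (0, 60), "Fluency_Letters", "CATVEGESC"),
    ("word_recognition", (0, 50), "WordRecog", "WRECOG"),
    ("word_list_delayed", (0, 10), "WordList_Del", "WLISTDEL"),
    ("clock_drawing", (0, 10), "Clock_Total", "CLOCKSCOR"),
    ("orientation", (0, 8), "Orientation", "ORIENTSC"),
]


def default_schema(study_a: str = "A", study_b: str = "B") -> Schema:
    """The shipped 39-column joined layout plus one auxiliary amyloid column.

    Study ``A`` is the 18-month-interval cohort (administers the CVLT-II-like
    list-learning test), study ``B`` the 6-month-interval cohort (administers
    the RAVLT-like test).  Source aliases are repo conventions standing in for
    the studies' native export names.
    """
    a, b = study_a, study_b
    vars_: list[VariableSchema] = [
        VariableSchema("participant_id", "categorical", "identifier",
                       {a: "SubjectID", b: "PTID"}, levels=("*",)),
        VariableSchema("dataset_id", "categorical", "identifier", {},
                       levels=("*",)),
        VariableSchema("months_since_baseline", "continuous", "derived",
                       {a: "MonthsSinceBL", b: "VISMONTH"},
                       valid_range=(0, math.inf)),
        VariableSchema("age", "continuous", "demographic",
                       {a: "AgeAtVisit", b: "AGE"}, valid_range=(40, 110)),
        VariableSchema("sex", "categorical", "demographic",
                       {a: "Sex", b: "PTGENDER"}, levels=SEX_LEVELS),
        VariableSchema("education", "categorical", "demographic",
                       {a: "EduLevel", b: "PTEDUCAT4"},
                       levels=EDUCATION_LEVELS, ordered=True),
        VariableSchema("apoe_e4", "discrete", "demographic",
                       {a: "ApoE4_Count", b: "APOE4"},
                       valid_range=(0, 2), integer_valued=True),
        VariableSchema("clinical_class", "categorical", "demographic",
                       {a: "Classification", b: "DX"}, levels=CLINICAL_CLASSES),
        VariableSchema("cdr", "discrete", "clinical",
                       {a: "CDR_Global", b: "CDGLOBAL"}, valid_range=(0, 3)),
        VariableSchema("mmse", "discrete", "clinical",
                       {a: "MMSE_Total", b: "MMSCORE"},
                       valid_range=(0, 30), integer_valued=True),
    ]
    for name, rng, src_a, src_b in _COGNITIVE:
        sources = {}
        if src_a:
            sources[a] = src_a
        if src_b:
            sources[b] = src_b
        vars_.append(
            VariableSchema(name, "discrete", "cognitive", sources,
                           valid_range=rng, integer_valued=True)
        )
    # rate-of-change columns: mmse plus every cognitive score (CDR excluded:
    # its 0.5-step staging scale makes between-visit differences degenerate)
    for base in ["mmse"] + [c[0] for c in _COGNITIVE]:
        vars_.append(
            VariableSchema(f"rate_{base}", "continuous", "derived", {},
                           rate_of=base)
        )
    vars_.append(
        VariableSchema("amyloid_centiloid", "continuous", "auxiliary",
                       {a: "Centiloid", b: "CENTILOIDS"},
                       valid_range=(-50, 300))
    )
    return Schema(vars_)


# ---------------------------------------------------------------------------
# schema file round-trip (flat YAML, one record per variable)
# ---------------------------------------------------------------------------

def save_schema(schema: Schema, path) -> None:
    records = []
    for v in schema:
        rec: dict = {
            "canonical_name": v.canonical_name,
            "var_type": v.var_type,
            "role": v.role,
            "source_name_by_study": dict(v.source_name_by_study),
            "integer_valued": v.integer_valued,
        }
        if v.valid_range is not None:
            lo, hi = v.valid_range
            rec["valid_range"] = [float(lo), None if math.isinf(hi) else float(hi)]
        if v.levels is not None:
            rec["levels"] = list(v.levels)
        if v.ordered:
            rec["ordered"] = True
        if v.rate_of is not None:
            rec["rate_of"] = v.rate_of
        records.append(rec)
    with open(path, "w") as fh:
        yaml.safe_dump(records, fh, sort_keys=False, allow_unicode=True)


def load_schema(path) -> Schema:
    with open(path) as fh:
        records = yaml.safe_load(fh)
    vars_ = []
    for rec in records:
        rng = rec.get("valid_range")
        if rng is not None:
            lo, hi = rng
            rng = (float(lo), math.inf if hi is None else float(hi))
        levels = rec.get("levels")
        vars_.append(
            VariableSchema(
                canonical_name=rec["canonical_name"],
                var_type=rec["var_type"],
                role=rec["role"],
                source_name_by_study=rec.get("source_name_by_study", {}) or {},
                valid_range=rng,
                integer_valued=bool(rec.get("integer_valued", False)),
                levels=tuple(levels) if levels else None,
                ordered=bool(rec.get("ordered", False)),
                rate_of=rec.get("rate_of"),
            )
        )
    return Schema(vars_)


# ---------------------------------------------------------------------------
# study-table I/O
# ---------------------------------------------------------------------------

def _coerce_column(s: pd.Series, var: VariableSchema, study_label: str) -> pd.Series:
    """Coerce a string column to its schema type, validating values."""
    if var.is_numeric:
        try:
            out = pd.to_numeric(s, errors="raise")
        except (ValueError, TypeError) as exc:
            raise TableValidationError(
                f"{study_label}: column {var.canonical_name!r} has a "
                f"non-numeric value ({exc})"
            ) from None
        out = out.astype(float)
        if var.valid_range is not None:
            lo, hi = var.valid_range
            bad = out.notna() & ((out < lo) | (out > hi))
            if bad.any():
                row = int(bad.idxmax())
                raise TableValidationError(
                    f"{study_label}: value {out.loc[row]} of "
                    f"{var.canonical_name!r} at row {row} outside "
                    f"valid_range [{lo}, {hi}]"
                )
        if var.integer_valued:
            frac = out.notna() & (out != np.round(out))
            if frac.any():
                row = int(frac.idxmax())
                raise TableValidationError(
                    f"{study_label}: non-integer value {out.loc[row]} of "
                    f"integer variable {var.canonical_name!r} at row {row}"
                )
        return out
    # categorical
    out = s.astype(object).where(s.notna(), np.nan)
    if var.levels and var.levels != ("*",):
        bad = s.notna() & ~s.isin(var.levels)
        if bad.any():
            row = int(bad.idxmax())
            raise TableValidationError(
                f"{study_label}: category {s.loc[row]!r} of "
                f"{var.canonical_name!r} at row {row} not in levels {var.levels}"
            )
    return out


def load_study_table(path, schema: Schema, study_id: str) -> pd.DataFrame:
    """Read one study's visit table, renaming source columns to canonical names.

    Accepts both the study's source names and canonical names in the header.
    Empty cells and the token ``"NA"`` become missing.  All rows are retained;
    any value that violates the schema raises rather than being dropped
    silently.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = raw.mask(raw.isin(MISSING_TOKENS))

    rename: dict[str, str] = {}
    known = set(schema.names())
    for var in schema:
        src = var.source_name_by_study.get(study_id)
        if src is not None:
            rename[src] = var.canonical_name
    seen: set[str] = set()
    cols: dict[str, str] = {}
    for col in raw.columns:
        canon = rename.get(col, col if col in known else None)
        if canon is None:
            raise SchemaError(f"{study_id}: unknown column {col!r}")
        if canon in seen:
            raise SchemaError(f"{study_id}: duplicate column for {canon!r}")
        seen.add(canon)
        cols[col] = canon
    df = raw.rename(columns=cols)

    required = [
        n for n in schema.present_in(study_id)
        if schema[n].rate_of is None and schema[n].role != "auxiliary"
    ]
    missing_cols = [n for n in required if n not in df.columns]
    if missing_cols:
        raise SchemaError(f"{study_id}: header lacks required columns {missing_cols}")

    for name in df.columns:
        var = schema[name]
        if var.canonical_name == "participant_id":
            continue
        if var.canonical_name == "dataset_id":
            mismatch = df[name].notna() & (df[name] != study_id)
            if mismatch.any():
                raise SchemaError(
                    f"{study_id}: dataset_id column disagrees with study id"
                )
            continue
        df[name] = _coerce_column(df[name], var, study_id)
    df["dataset_id"] = study_id

    if {"participant_id", "months_since_baseline"} <= set(df.columns):
        dup = df.duplicated(["participant_id", "months_since_baseline"])
        if dup.any():
            pid = df.loc[dup.idxmax(), "participant_id"]
            raise TableValidationError(
                f"{study_id}: duplicate (participant, visit-month) pair for "
                f"participant {pid!r}"
            )
    order = [n for n in schema.names() if n in df.columns]
    return df[order].reset_index(drop=True)


def write_table(table: pd.DataFrame, path) -> None:
    """Write a canonical-column table as CSV; missing cells become empty."""
    table.to_csv(path, index=False, na_rep="")
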