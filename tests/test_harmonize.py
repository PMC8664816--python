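"""Joined-dataset construction: filters, derived variables, the join."""

import numpy as np
import pandas as pd
import pytest

from cogimpute.harmonize import (
    bin_education,
    compute_rate_of_change,
    drop_sparse_variables,
    drop_sparse_visits,
    harmonize_studies,
    join_studies,
    rebaseline,
    resolve_classification,
)
from cogimpute.schema import TableValidationError

from conftest import make_visits


# -- sparse-variable filter --------------------------------------------------

def _two_study_tables(schema, missing_frac_a, missing_frac_b, var="bnt"):
    out = {}
    for study, frac in (("A", missing_frac_a), ("B", missing_frac_b)):
        subs = tuple((f"{study.lower()}{i}", [0.0, 18.0]) for i in range(20))
        df = make_visits(schema, study=study, subjects=subs)
        n_miss = int(round(frac * len(df)))
        df.loc[df.index[:n_miss], var] = np.nan
        out[study] = df
    return out


def test_variable_sparse_in_one_study_dropped_from_both(schema):
    tables = _two_study_tables(schema, 0.6, 0.1)
    out, log = drop_sparse_variables(tables, schema, 0.5)
    assert "bnt" not in out["A"].columns
    assert "bnt" not in out["B"].columns
    assert log.variables_frame()["variable"].tolist() == ["bnt"]


def test_fully_observed_variable_retained(schema):
    tables = _two_study_tables(schema, 0.0, 0.0)
    out, log = drop_sparse_variables(tables, schema, 0.5)
    assert "bnt" in out["A"].columns
    assert log.variables_frame().empty


def test_single_study_targets_exempt_from_sparsity_drop(schema):
    tables = _two_study_tables(schema, 0.0, 0.0)
    tables["A"]["cvlt_immediate"] = 30.0
    tables["A"]["ravlt_immediate"] = np.nan
    tables["B"]["ravlt_immediate"] = 28.0
    tables["B"]["cvlt_immediate"] = np.nan
    out, log = drop_sparse_variables(tables, schema, 0.5)
    assert "cvlt_immediate" in out["A"].columns
    assert "ravlt_immediate" in out["B"].columns


# -- classification resolution ----------------------------------------------

@pytest.mark.parametrize(
    "classes, expected_kept, expected_filled",
    [
        (["CN", np.nan, "CN"], 3, ["CN", "CN", "CN"]),
        (["CN", np.nan, "AD"], 2, ["CN", "AD"]),
        ([np.nan, "MCI"], 2, ["MCI", "MCI"]),
        (["MCI", np.nan], 2, ["MCI", "MCI"]),
        ([np.nan], 0, []),
    ],
)
def test_resolve_classification_rules(schema, classes, expected_kept,
                                      expected_filled):
    months = [18.0 * k for k in range(len(classes))]
    df = make_visits(schema, subjects=(("p1", months),))
    df["clinical_class"] = classes
    out, log = resolve_classification(df)
    assert len(out) == expected_kept
    assert out["clinical_class"].tolist() == expected_filled
    assert log.n_rows_dropped() == len(classes) - expected_kept


def test_resolution_accounting(schema):
    df = make_visits(schema, subjects=(("p1", [0.0, 18.0, 36.0]),
                                       ("p2", [0.0, 18.0]),))
    df.loc[1, "clinical_class"] = np.nan   # p1 middle: neighbors agree
    df.loc[3, "clinical_class"] = np.nan   # p2 last: single neighbor
    out, log = resolve_classification(df)
    assert len(out) + log.n_rows_dropped() == len(df)
    assert out["clinical_class"].notna().all()


# -- sparse-visit filter -----------------------------------------------------

@pytest.mark.parametrize("n_present, kept", [(2, False), (3, True), (14, True)])
def test_visit_kept_iff_enough_completed_tests(schema, n_present, kept):
    df = make_visits(schema, subjects=(("p1", [0.0]),))
    cogs = schema.cognitive_names
    for name in cogs[n_present:]:
        df[name] = np.nan
    out, log = drop_sparse_visits(df, schema, min_tests=3)
    assert (len(out) == 1) is kept
    assert log.n_rows_dropped() == (0 if kept else 1)


# -- education binning -------------------------------------------------------

@pytest.mark.parametrize("years, label", [
    (0, "<9"), (8, "<9"), (9, "9-12"), (12, "9-12"),
    (13, "13-15"), (15, "13-15"), (16, "15+"), (20, "15+"),
])
def test_bin_education(years, label):
    assert bin_education(years) == label


def test_bin_education_rejects_negative():
    with pytest.raises(TableValidationError):
        bin_education(-1)


# -- rate of change ----------------------------------------------------------

def test_rate_of_change_arithmetic(schema):
    df = make_visits(schema, subjects=(("p1", [0.0, 18.0]),))
    df["mmse"] = [28.0, 26.0]
    out = compute_rate_of_change(df, schema, variables=["mmse"])
    assert np.isnan(out.loc[0, "rate_mmse"])          # first visit
    assert out.loc[1, "rate_mmse"] == pytest.approx(-2 / 18)


def test_rate_skips_to_nearest_previous_nonmissing(schema):
    df = make_visits(schema, subjects=(("p1", [0.0, 18.0, 36.0]),))
    df["mmse"] = [30.0, np.nan, 24.0]
    out = compute_rate_of_change(df, schema, variables=["mmse"])
    assert np.isnan(out.loc[1, "rate_mmse"])
    assert out.loc[2, "rate_mmse"] == pytest.approx((24 - 30) / 36)


def test_rate_rejects_duplicate_times(schema):
    df = make_visits(schema, subjects=(("p1", [0.0, 18.0]),))
    df.loc[1, "months_since_baseline"] = 0.0
    with pytest.raises(TableValidationError, match="duplicate"):
        compute_rate_of_change(df, schema, variables=["mmse"])


def test_rates_reproducible_from_scores(schema, joined_small):
    """Derived rate columns recompute exactly from scores and times."""
    joined, _ = joined_small
    redone = compute_rate_of_change(
        joined.drop(columns=schema.rate_names), schema)
    for c in schema.rate_names:
        if c in joined.columns:
            pd.testing.assert_series_equal(redone[c], joined[c],
                                           check_names=False)


# -- join ---------------------------------------------------------------------

def test_join_concatenates_and_namespaces(schema):
    ta = make_visits(schema, study="A", subjects=(("p1", [0.0, 18.0]),))
    tb = make_visits(schema, study="B", subjects=(("p1", [0.0, 6.0, 12.0]),))
    joined = join_studies({"A": ta, "B": tb}, schema)
    assert len(joined) == 5
    assert set(joined["participant_id"]) == {"A_p1", "B_p1"}


def test_default_join_has_39_columns(schema, joined_small):
    joined, _ = joined_small
    layout = [c for c in joined.columns if schema[c].role != "auxiliary"]
    assert len(layout) == 39
    assert layout == schema.joined_layout()


def test_join_leaves_unmeasured_columns_missing(schema, joined_small):
    joined, _ = joined_small
    b = joined[joined["dataset_id"] == "B"]
    assert b["cvlt_immediate"].isna().all()
    a = joined[joined["dataset_id"] == "A"]
    assert a["ravlt_immediate"].isna().all()


def test_joined_rows_have_class_and_enough_tests(schema, joined_small):
    joined, _ = joined_small
    assert joined["clinical_class"].notna().all()
    cogs = [c for c in schema.cognitive_names if c in joined.columns]
    assert (joined[cogs].notna().sum(axis=1) >= 3).all()


def test_row_accounting(schema, small_cohorts, joined_small):
    tables, _ = small_cohorts
    joined, log = joined_small
    for study in tables:
        n_in = len(tables[study])
        n_kept = (joined["dataset_id"] == study).sum()
        assert n_kept + log.n_rows_dropped(study) == n_in


def test_pipeline_idempotent(schema, joined_small):
    """Re-applying the row filters to harmonized output changes nothing."""
    joined, _ = joined_small
    again, log2 = resolve_classification(joined)
    again, log2 = drop_sparse_visits(again, schema, 3, log2)
    again = rebaseline(again)
    assert log2.n_rows_dropped() == 0
    pd.testing.assert_frame_equal(again, joined.reset_index(drop=True))


def test_baseline_restored_after_drops(schema):
    df = make_visits(schema, subjects=(("p1", [0.0, 18.0, 36.0]),))
    df.loc[0, "clinical_class"] = np.nan   # baseline dropped (neighbor CN... )
    df.loc[0, schema.cognitive_names] = np.nan
    out, _ = harmonize_studies({"A": df}, schema, include_rates=False)
    assert out["months_since_baseline"].min() == 0.0
    assert len(out) == 2


# -- property tests -----------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, derandomize=True, max_examples=100)
@given(st.floats(0, 60, allow_nan=False))
def test_bin_education_total_and_monotone(years):
    order = ["<9", "9-12", "13-15", "15+"]
    label = bin_education(years)
    assert label in order
    # monotone: more years never maps to a lower bin
    assert order.index(bin_education(years + 1.0)) >= order.index(label)
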