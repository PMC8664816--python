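"""Evaluate harmonized (imputed) scores.

Two analyses:

* clinical-class discrimination: do imputed scores separate CN/MCI/AD as
  well as the measured scores do?  Student's pooled-variance two-sample
  t-tests and Cohen's d (pooled-SD) per class pair, for the "actual" arm
  (the study that measured the score) and the "imputed" arm (the study
  that did not).
* amyloid–memory case study: the Pearson correlation, two-sided p-value
  and least-squares slope between a Centiloid-scale amyloid burden and a
  list-learning memory score in the small MCI / APOE ε4-homozygote
  subgroup, contrasting the single measuring study against the harmonized
  (measured + imputed) dataset — the power argument for harmonization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .schema import Schema

__all__ = [
    "EffectSizeError",
    "class_discrimination",
    "compare_actual_vs_imputed",
    "case_study",
    "CaseStudyResult",
    "plot_class_boxes",
    "plot_case_study",
]

CLASS_PAIRS = (("CN", "MCI"), ("CN", "AD"), ("MCI", "AD"))


class EffectSizeError(ValueError):
    """Effect size undefined (zero pooled variance or too few observations)."""


def _pooled_sd(x: np.ndarray, y: np.ndarray) -> float:
    n1, n2 = len(x), len(y)
    s2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (
        n1 + n2 - 2)
    return float(np.sqrt(s2))


def cohens_d(x, y) -> float:
    """Cohen's d with pooled standard deviation; sign of mean(x) − mean(y)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sp = _pooled_sd(x, y)
    diff = float(np.mean(x) - np.mean(y))
    if sp == 0:
        if diff == 0:
            return 0.0
        raise EffectSizeError("zero pooled variance with unequal means")
    return diff / sp


def class_discrimination(
    scores,
    classes,
    source_label: str = "actual",
    pairs=CLASS_PAIRS,
    welch: bool = False,
) -> pd.DataFrame:
    """Pairwise class discrimination of one score.

    Returns one row per class pair with the Student (pooled-variance, or
    Welch when requested) t-statistic, its two-sided p-value and Cohen's d,
    plus group sizes, means and SDs.  P-values are reported raw — no
    multiplicity correction.
    """
    s = pd.Series(np.asarray(scores, float))
    c = pd.Series(np.asarray(classes, object)).reset_index(drop=True)
    keep = s.notna() & c.notna()
    s, c = s[keep], c[keep]
    rows = []
    for g1, g2 in pairs:
        x = s[c == g1].to_numpy()
        y = s[c == g2].to_numpy()
        if len(x) < 2 or len(y) < 2:
            raise EffectSizeError(
                f"need >= 2 observations per class for pair {g1}-{g2}")
        if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
            if np.mean(x) != np.mean(y):
                raise EffectSizeError(
                    f"zero pooled variance for pair {g1}-{g2}")
            t, p, d = 0.0, 1.0, 0.0
        else:
            t, p = stats.ttest_ind(x, y, equal_var=not welch)
            d = cohens_d(x, y)
        rows.append({
            "pair": f"{g1}-{g2}", "source": source_label,
            "t_statistic": float(t), "p_value": float(p), "cohens_d": d,
            "n_1": len(x), "n_2": len(y),
            "mean_1": float(np.mean(x)), "mean_2": float(np.mean(y)),
            "sd_1": float(np.std(x, ddof=1)), "sd_2": float(np.std(y, ddof=1)),
        })
    return pd.DataFrame(rows)


def _boxplot_frame(scores: pd.Series, classes: pd.Series,
                   source: str) -> pd.DataFrame:
    rows = []
    for cls, grp in scores.groupby(classes.to_numpy()):
        g = grp.dropna().to_numpy(float)
        q1, med, q3 = np.percentile(g, [25, 50, 75])
        rows.append({"clinical_class": cls, "source": source, "n": len(g),
                     "q1": q1, "median": med, "q3": q3,
                     "whisker_low": float(g.min()),
                     "whisker_high": float(g.max()),
                     "mean": float(g.mean()), "sd": float(g.std(ddof=1))})
    return pd.DataFrame(rows)


def compare_actual_vs_imputed(
    joined: pd.DataFrame,
    completed: pd.DataFrame,
    variable: str,
    schema: Schema,
    welch: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Discrimination of measured vs imputed values of a one-study score.

    ``variable`` must be systematically missing in exactly one study: the
    "actual" arm uses the measuring study's observed values from ``joined``,
    the "imputed" arm the other study's imputed values from ``completed``.
    Returns (discrimination table, tidy boxplot-quantile table).
    """
    measuring = schema.measuring_studies(variable)
    studies = sorted(joined["dataset_id"].unique())
    if len(measuring) != 1 or len(studies) < 2:
        raise ValueError(
            f"{variable!r} is not a single-study harmonization target")
    src = measuring[0]
    actual_rows = joined["dataset_id"] == src
    actual = joined.loc[actual_rows & joined[variable].notna()]
    imputed_rows = completed["dataset_id"] != src
    imputed = completed.loc[imputed_rows]

    disc = pd.concat([
        class_discrimination(actual[variable], actual["clinical_class"],
                             "actual", welch=welch),
        class_discrimination(imputed[variable], imputed["clinical_class"],
                             "imputed", welch=welch),
    ], ignore_index=True)
    boxes = pd.concat([
        _boxplot_frame(actual[variable], actual["clinical_class"], "actual"),
        _boxplot_frame(imputed[variable], imputed["clinical_class"],
                       "imputed"),
    ], ignore_index=True)
    return disc, boxes


@dataclass
class CaseStudyResult:
    """Amyloid–memory association in one dataset arm."""

    dataset: str            # "single_study" or "harmonized"
    subgroup_filter: str
    n_observations: int
    pearson_r: float
    p_value: float
    slope: float            # score units per Centiloid
    defined: bool

    def rejects(self, alpha: float = 0.05) -> bool:
        return self.defined and self.p_value < alpha


def _fit_association(x: np.ndarray, y: np.ndarray, dataset: str,
                     subgroup: str) -> CaseStudyResult:
    n = len(x)
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return CaseStudyResult(dataset, subgroup, n, float("nan"),
                               float("nan"), float("nan"), defined=False)
    r, p = stats.pearsonr(x, y)
    slope = stats.linregress(x, y).slope
    return CaseStudyResult(dataset, subgroup, n, float(r), float(p),
                           float(slope), defined=True)


def case_study(
    completed: pd.DataFrame,
    memory_variable: str,
    amyloid_variable: str,
    schema: Schema,
    clinical_class: str = "MCI",
    apoe_count: int = 2,
) -> dict[str, CaseStudyResult]:
    """Amyloid–memory correlation in a small genotype/class subgroup.

    Observed cells are preserved by imputation, so the measuring study's
    rows of ``completed`` carry actual values: the ``single_study`` arm
    restricts to them, the ``harmonized`` arm pools measured and imputed
    rows.  Subgroups with fewer than 3 usable observations are flagged
    undefined rather than raising.
    """
    subgroup_desc = f"clinical_class == {clinical_class!r} and apoe_e4 == {apoe_count}"
    sub = completed.loc[
        (completed["clinical_class"] == clinical_class)
        & (completed["apoe_e4"] == apoe_count)
        & completed[amyloid_variable].notna()
        & completed[memory_variable].notna()
    ]
    measuring = schema.measuring_studies(memory_variable)
    if len(measuring) != 1:
        raise ValueError(f"{memory_variable!r} must be measured by one study")
    single = sub.loc[sub["dataset_id"] == measuring[0]]
    out = {}
    out["single_study"] = _fit_association(
        single[amyloid_variable].to_numpy(float),
        single[memory_variable].to_numpy(float),
        "single_study", subgroup_desc)
    out["harmonized"] = _fit_association(
        sub[amyloid_variable].to_numpy(float),
        sub[memory_variable].to_numpy(float),
        "harmonized", subgroup_desc)
    return out


# ---------------------------------------------------------------------------
# optional plotting (matplotlib)
# ---------------------------------------------------------------------------

def plot_class_boxes(boxes: pd.DataFrame, variable: str, ax=None):
    """Render the tidy boxplot table produced by compare_actual_vs_imputed."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    order = ["CN", "MCI", "AD"]
    width = 0.35
    for k, source in enumerate(("actual", "imputed")):
        part = boxes[boxes["source"] == source].set_index("clinical_class")
        stats_ = [
            {"med": part.loc[c, "median"], "q1": part.loc[c, "q1"],
             "q3": part.loc[c, "q3"], "whislo": part.loc[c, "whisker_low"],
             "whishi": part.loc[c, "whisker_high"], "label": c}
            for c in order if c in part.index
        ]
        ax.bxp(stats_, positions=np.arange(len(stats_)) + (k - 0.5) * width,
               widths=width * 0.9, showfliers=False,
               boxprops={"color": "C%d" % k})
    ax.set_xticks(range(len(order)), order)
    ax.set_ylabel(variable)
    ax.set_title(f"{variable}: actual (left) vs imputed (right) by class")
    return ax


def plot_case_study(completed: pd.DataFrame, memory_variable: str,
                    amyloid_variable: str, schema: Schema, ax=None,
                    clinical_class: str = "MCI", apoe_count: int = 2):
    """Scatter of amyloid vs memory in the subgroup, colored by study."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    sub = completed.loc[
        (completed["clinical_class"] == clinical_class)
        & (completed["apoe_e4"] == apoe_count)
        & completed[amyloid_variable].notna()
        & completed[memory_variable].notna()
    ]
    for k, (study, grp) in enumerate(sub.groupby("dataset_id")):
        ax.scatter(grp[amyloid_variable], grp[memory_variable],
                   s=16, label=str(study), color=f"C{k}")
    ax.set_xlabel(f"{amyloid_variable} (Centiloid)")
    ax.set_ylabel(memory_variable)
    ax.legend(title="study")
    return ax
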