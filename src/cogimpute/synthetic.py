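"""Synthetic paired-cohort generator.

Emulates the statistical structure the harmonization analysis relies on:
two observational aging cohorts with different visit schedules (one on an
18-month grid, one on a 3/6-month grid), clinical classes CN/MCI/AD with
class-dependent score levels and decline rates, a shared latent episodic-
memory factor driving two list-learning tests of which each study measures
only one (systematic missingness), bounded integer test scores, demographic
covariates (age, sex, 4-level education, APOE ε4 allele count), an amyloid
burden value on a Centiloid-like scale coupled negatively to the latent
memory factor, and configurable completely-at-random missingness.

Every masked cell's ground truth is retained in :class:`SyntheticTruth`, so
downstream imputation can be scored without any external data.

The generative model for a score ``v`` of subject ``i`` (class ``c``) at
month ``t`` is::

    score = mean[v, c] + decline[v, c] * t + loading[v] * latent(i, t)
            + shift[study, v] + Normal(0, noise_sd[v])

with ``latent(i, t) = b_i + slope_c * t + e_it`` a mean-zero-at-baseline
latent factor (subject intercept ``b_i``, class-dependent decline, visit
noise).  Integer scores are rounded half-away-from-zero then clipped to
their valid range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .schema import Schema, default_schema

__all__ = [
    "AmyloidParams",
    "SyntheticCohortConfig",
    "SyntheticTruth",
    "default_config",
    "generate_cohorts",
]

CLASSES = ("CN", "MCI", "AD")
EDU_LEVELS = ("<9", "9-12", "13-15", "15+")

#: score columns eligible for MCAR masking
SCORE_ROLES = ("clinical", "cognitive")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class AmyloidParams:
    """Centiloid-scale amyloid burden model.

    ``value = mean_by_class[c] + apoe_effect*n4
    - (coupling_by_class[c] + coupling_apoe*n4) * latent + Normal(0, sd)``

    Coupling coefficients are positive numbers; because higher latent means
    better memory, the generated amyloid–memory association is negative, and
    more strongly so in MCI/AD and in ε4 carriers.
    """

    mean_by_class: Mapping[str, float] = field(
        default_factory=lambda: {"CN": 25.0, "MCI": 55.0, "AD": 85.0})
    sd: float = 25.0
    apoe_effect: float = 12.0
    coupling_by_class: Mapping[str, float] = field(
        default_factory=lambda: {"CN": 4.0, "MCI": 10.0, "AD": 12.0})
    coupling_apoe: float = 4.0


# default per-class score means (baseline) and decline rates (units/month)
_SCORE_MEANS: dict[str, dict[str, float]] = {
    "mmse": {"CN": 28.8, "MCI": 27.0, "AD": 21.5},
    "cdr": {"CN": 0.05, "MCI": 0.5, "AD": 1.1},
    "cvlt_immediate": {"CN": 45.0, "MCI": 32.0, "AD": 20.0},
    "ravlt_immediate": {"CN": 42.0, "MCI": 30.0, "AD": 19.0},
    "lm_i": {"CN": 14.0, "MCI": 9.0, "AD": 5.0},
    "lm_ii": {"CN": 13.0, "MCI": 7.0, "AD": 3.0},
    "bnt": {"CN": 27.0, "MCI": 24.5, "AD": 20.0},
    "digit_span_fwd": {"CN": 10.5, "MCI": 9.5, "AD": 8.5},
    "digit_span_bwd": {"CN": 7.5, "MCI": 6.5, "AD": 5.0},
    "digit_symbol": {"CN": 45.0, "MCI": 36.0, "AD": 25.0},
    "fluency_animal": {"CN": 20.0, "MCI": 15.0, "AD": 10.0},
    "fluency_letter": {"CN": 40.0, "MCI": 33.0, "AD": 25.0},
    "word_recognition": {"CN": 44.0, "MCI": 38.0, "AD": 30.0},
    "word_list_delayed": {"CN": 7.0, "MCI": 4.0, "AD": 1.5},
    "clock_drawing": {"CN": 9.0, "MCI": 7.5, "AD": 5.5},
    "orientation": {"CN": 7.8, "MCI": 7.0, "AD": 5.0},
}

_DECLINE: dict[str, dict[str, float]] = {
    "mmse": {"CN": -0.004, "MCI": -0.03, "AD": -0.12},
    "cdr": {"CN": 0.0, "MCI": 0.004, "AD": 0.015},
    "cvlt_immediate": {"CN": -0.01, "MCI": -0.08, "AD": -0.15},
    "ravlt_immediate": {"CN": -0.01, "MCI": -0.07, "AD": -0.14},
    "lm_i": {"CN": -0.003, "MCI": -0.03, "AD": -0.06},
    "lm_ii": {"CN": -0.003, "MCI": -0.035, "AD": -0.06},
    "bnt": {"CN": -0.002, "MCI": -0.015, "AD": -0.05},
    "digit_span_fwd": {"CN": -0.001, "MCI": -0.005, "AD": -0.015},
    "digit_span_bwd": {"CN": -0.001, "MCI": -0.006, "AD": -0.02},
    "digit_symbol": {"CN": -0.01, "MCI": -0.04, "AD": -0.1},
    "fluency_animal": {"CN": -0.005, "MCI": -0.02, "AD": -0.05},
    "fluency_letter": {"CN": -0.005, "MCI": -0.02, "AD": -0.05},
    "word_recognition": {"CN": -0.003, "MCI": -0.03, "AD": -0.07},
    "word_list_delayed": {"CN": -0.002, "MCI": -0.02, "AD": -0.03},
    "clock_drawing": {"CN": -0.001, "MCI": -0.01, "AD": -0.03},
    "orientation": {"CN": -0.001, "MCI": -0.008, "AD": -0.025},
}

#: loading of each score on the shared latent memory factor (score units
#: per latent unit); the two list-learning tests load most heavily
_LOADINGS: dict[str, float] = {
    "mmse": 0.8,
    "cdr": -0.15,
    "cvlt_immediate": 9.0,
    "ravlt_immediate": 8.0,
    "lm_i": 3.0,
    "lm_ii": 3.5,
    "bnt": 0.8,
    "digit_span_fwd": 0.3,
    "digit_span_bwd": 0.4,
    "digit_symbol": 2.0,
    "fluency_animal": 1.5,
    "fluency_letter": 1.5,
    "word_recognition": 2.5,
    "word_list_delayed": 1.3,
    "clock_drawing": 0.4,
    "orientation": 0.3,
}

_NOISE_SD: dict[str, float] = {
    "mmse": 1.1,
    "cdr": 0.25,
    "cvlt_immediate": 4.0,
    "ravlt_immediate": 3.8,
    "lm_i": 2.2,
    "lm_ii": 2.0,
    "bnt": 2.0,
    "digit_span_fwd": 1.8,
    "digit_span_bwd": 1.7,
    "digit_symbol": 8.0,
    "fluency_animal": 3.5,
    "fluency_letter": 7.0,
    "word_recognition": 2.8,
    "word_list_delayed": 1.2,
    "clock_drawing": 1.1,
    "orientation": 0.7,
}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Generative parameters for a pair of synthetic cohorts.

    Defaults mirror the reported characteristics of the two large AIBL-
    and ADNI-style cohorts being emulated: 1805 and 2122 subjects; class
    mixes ~(66/17/18)% and ~(37/41/22)%; 18-month vs 3/6-month visit
    grids; per-study APOE, sex and education mixes (renormalized over
    subjects with non-missing values).
    """

    n_subjects_by_study: Mapping[str, int] = field(
        default_factory=lambda: {"A": 1805, "B": 2122})
    class_proportions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "A": {"CN": 0.6583, "MCI": 0.1653, "AD": 0.1764},
            "B": {"CN": 0.3695, "MCI": 0.4138, "AD": 0.2167},
        })
    visit_interval_months_by_study: Mapping[str, float] = field(
        default_factory=lambda: {"A": 18.0, "B": 6.0})
    early_visits_by_study: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {"B": (3.0,)})
    max_followup_months: float = 90.0
    retention_per_visit: float = 0.85
    score_means_by_class: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: _SCORE_MEANS)
    decline_rate_by_class: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: _DECLINE)
    latent_memory_loadings: Mapping[str, float] = field(
        default_factory=lambda: _LOADINGS)
    study_shift: Mapping[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: Mapping[str, float] = field(default_factory=lambda: _NOISE_SD)
    mcar_rate: float = 0.05
    class_missing_rate: float = 0.02
    systematically_missing: Mapping[str, frozenset] = field(
        default_factory=lambda: {
            "A": frozenset({"ravlt_immediate"}),
            "B": frozenset({"cvlt_immediate"}),
        })
    amyloid_params: AmyloidParams = field(default_factory=AmyloidParams)
    # demographics (per study)
    age_mean_by_study: Mapping[str, float] = field(
        default_factory=lambda: {"A": 72.42, "B": 73.32})
    age_sd_by_study: Mapping[str, float] = field(
        default_factory=lambda: {"A": 7.64, "B": 7.21})
    female_prob_by_study: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.5667, "B": 0.4680})
    apoe_probs_by_study: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "A": (0.6343, 0.3046, 0.0611),
            "B": (0.5442, 0.3611, 0.0947),
        })
    education_probs_by_study: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "A": (0.1066, 0.3781, 0.1988, 0.3164),
            "B": (0.0108, 0.1357, 0.1890, 0.6645),
        })
    # latent-factor dynamics
    latent_intercept_sd: float = 0.7
    latent_visit_sd: float = 0.25
    latent_slope_by_class: Mapping[str, float] = field(
        default_factory=lambda: {"CN": -0.004, "MCI": -0.012, "AD": -0.025})
    seed: int = 0

    def validate(self) -> None:
        for s, props in self.class_proportions.items():
            if abs(sum(props.values()) - 1.0) > 1e-6:
                raise ValueError(f"class proportions of study {s!r} must sum to 1")
        if not (0.0 <= self.mcar_rate < 1.0):
            raise ValueError("mcar_rate must be in [0, 1)")
        if not (0.0 < self.retention_per_visit <= 1.0):
            raise ValueError("retention_per_visit must be in (0, 1]")
        for sd in self.noise_sd.values():
            if sd < 0:
                raise ValueError("noise sds must be >= 0")

    def with_overrides(self, **kwargs) -> "SyntheticCohortConfig":
        return replace(self, **kwargs)

    @property
    def study_ids(self) -> list[str]:
        return list(self.n_subjects_by_study)


def default_config(seed: int = 0) -> SyntheticCohortConfig:
    """Full-scale default configuration (1805 + 2122 subjects).

    Under these defaults the two studies contribute observation counts in a
    ratio of about 1.7 (the denser 6-month grid of study B compensating its
    shorter per-visit retention horizon).
    """
    return SyntheticCohortConfig(seed=seed)


def demo_config(seed: int = 0, n_a: int = 200, n_b: int = 200,
                max_followup: float = 54.0) -> SyntheticCohortConfig:
    """Small configuration for tests and demos (same structure, fewer rows)."""
    return SyntheticCohortConfig(
        n_subjects_by_study={"A": n_a, "B": n_b},
        max_followup_months=max_followup,
        seed=seed,
    )


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated cohort pair.

    ``complete_tables``: per-study tables with zero missingness;
    ``mask``: one row per (study, participant, visit-month, variable)
    masked in the released tables; ``latent_factors``: the per-visit latent
    memory factor.
    """

    complete_tables: dict[str, pd.DataFrame]
    mask: pd.DataFrame
    latent_factors: pd.DataFrame

    def true_values(self, study_id: str, variable: str) -> pd.Series:
        """Ground-truth values of one variable, indexed like the released table."""
        return self.complete_tables[study_id][variable]


def _visit_schedule(cfg: SyntheticCohortConfig, study: str) -> np.ndarray:
    interval = cfg.visit_interval_months_by_study[study]
    grid = np.arange(0.0, cfg.max_followup_months + 1e-9, interval)
    extra = cfg.early_visits_by_study.get(study, ())
    times = np.unique(np.concatenate([grid, np.asarray(extra, float)]))
    return times[times <= cfg.max_followup_months + 1e-9]


def _generate_study(cfg: SyntheticCohortConfig, study: str, schema: Schema,
                    rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Complete (no-missing) table and latent factors for one study."""
    n = cfg.n_subjects_by_study[study]
    classes = np.array(CLASSES)
    p_class = np.array([cfg.class_proportions[study][c] for c in CLASSES])
    subj_class = rng.choice(classes, size=n, p=p_class / p_class.sum())
    age0 = np.clip(
        rng.normal(cfg.age_mean_by_study[study], cfg.age_sd_by_study[study], n),
        55.0, 95.0)
    sex = np.where(rng.random(n) < cfg.female_prob_by_study[study], "F", "M")
    apoe = rng.choice([0, 1, 2], size=n,
                      p=np.asarray(cfg.apoe_probs_by_study[study])
                      / sum(cfg.apoe_probs_by_study[study]))
    edu = rng.choice(list(EDU_LEVELS), size=n,
                     p=np.asarray(cfg.education_probs_by_study[study])
                     / sum(cfg.education_probs_by_study[study]))
    b_i = rng.normal(0.0, cfg.latent_intercept_sd, n)

    schedule = _visit_schedule(cfg, study)
    # geometric dropout: baseline always observed, then each successive
    # scheduled visit retained with probability retention_per_visit
    n_later = len(schedule) - 1
    keep_draw = rng.random((n, n_later)) < cfg.retention_per_visit
    n_visits = 1 + np.argmin(np.pad(keep_draw, ((0, 0), (0, 1)),
                                    constant_values=False), axis=1)

    score_vars = [v.canonical_name for v in schema
                  if v.role in SCORE_ROLES]
    rows: dict[str, list] = {k: [] for k in (
        ["participant_id", "dataset_id", "months_since_baseline", "age",
         "sex", "education", "apoe_e4", "clinical_class"]
        + score_vars + ["amyloid_centiloid", "_latent"])}
    width = len(str(max(n, 1)))
    amy = cfg.amyloid_params
    for i in range(n):
        c = subj_class[i]
        slope = cfg.latent_slope_by_class[c]
        times = schedule[: n_visits[i]]
        k = len(times)
        latent = b_i[i] + slope * times + rng.normal(0, cfg.latent_visit_sd, k)
        pid = f"S{i:0{width}d}"
        rows["participant_id"].extend([pid] * k)
        rows["dataset_id"].extend([study] * k)
        rows["months_since_baseline"].extend(times.tolist())
        rows["age"].extend((age0[i] + times / 12.0).tolist())
        rows["sex"].extend([sex[i]] * k)
        rows["education"].extend([edu[i]] * k)
        rows["apoe_e4"].extend([float(apoe[i])] * k)
        rows["clinical_class"].extend([c] * k)
        for v in score_vars:
            var = schema[v]
            mu = (cfg.score_means_by_class[v][c]
                  + cfg.decline_rate_by_class.get(v, {}).get(c, 0.0) * times
                  + cfg.latent_memory_loadings.get(v, 0.0) * latent
                  + cfg.study_shift.get((study, v), 0.0))
            val = mu + rng.normal(0, cfg.noise_sd.get(v, 1.0), k)
            if v == "cdr":  # staging scale: snap to its 0.5-step grid
                val = np.clip(_round_half_away(val * 2.0) / 2.0, 0.0, 3.0)
            elif var.integer_valued:
                lo, hi = var.valid_range
                val = np.clip(_round_half_away(val), lo, hi)
            elif var.valid_range is not None:
                val = np.clip(val, var.valid_range[0], var.valid_range[1])
            rows[v].extend(val.tolist())
        coupling = amy.coupling_by_class[c] + amy.coupling_apoe * apoe[i]
        a_val = (amy.mean_by_class[c] + amy.apoe_effect * apoe[i]
                 - coupling * latent + rng.normal(0, amy.sd, k))
        rows["amyloid_centiloid"].extend(a_val.tolist())
        rows["_latent"].extend(latent.tolist())

    df = pd.DataFrame(rows)
    latents = df[["participant_id", "months_since_baseline", "_latent"]].copy()
    latents.insert(0, "dataset_id", study)
    latents = latents.rename(columns={"_latent": "latent"})
    df = df.drop(columns=["_latent"])
    return df, latents


def generate_cohorts(
    config: SyntheticCohortConfig | None = None,
    schema: Schema | None = None,
) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Generate the released (masked) study tables plus ground truth.

    Masking applies, per study: (i) full masking of that study's
    systematically-missing variables, (ii) MCAR masking of clinical and
    cognitive score cells at ``mcar_rate``, (iii) MCAR masking of the
    clinical classification at ``class_missing_rate``.  Identical seeds
    produce identical output.
    """
    cfg = config or default_config()
    cfg.validate()
    schema = schema or default_schema()
    root = np.random.SeedSequence([int(cfg.seed) % (2**31), 982451653])
    study_seeds = root.spawn(len(cfg.study_ids) * 2)

    released: dict[str, pd.DataFrame] = {}
    complete: dict[str, pd.DataFrame] = {}
    mask_rows: list[tuple[str, str, float, str]] = []
    latent_parts: list[pd.DataFrame] = []
    score_vars = [v.canonical_name for v in schema if v.role in SCORE_ROLES]

    for j, study in enumerate(cfg.study_ids):
        gen_rng = np.random.default_rng(study_seeds[2 * j])
        mask_rng = np.random.default_rng(study_seeds[2 * j + 1])
        full, latents = _generate_study(cfg, study, schema, gen_rng)
        latent_parts.append(latents)
        complete[study] = full
        out = full.copy()

        sys_miss = set(cfg.systematically_missing.get(study, ()))
        for v in sorted(sys_miss):
            mask_rows.extend(
                (study, pid, t, v)
                for pid, t in zip(out["participant_id"],
                                  out["months_since_baseline"])
            )
            out[v] = np.nan
        if cfg.mcar_rate > 0:
            for v in score_vars:
                if v in sys_miss:
                    continue
                hit = mask_rng.random(len(out)) < cfg.mcar_rate
                if hit.any():
                    mask_rows.extend(
                        (study, pid, t, v)
                        for pid, t in zip(out.loc[hit, "participant_id"],
                                          out.loc[hit, "months_since_baseline"])
                    )
                    out.loc[hit, v] = np.nan
        if cfg.class_missing_rate > 0:
            hit = mask_rng.random(len(out)) < cfg.class_missing_rate
            if hit.any():
                mask_rows.extend(
                    (study, pid, t, "clinical_class")
                    for pid, t in zip(out.loc[hit, "participant_id"],
                                      out.loc[hit, "months_since_baseline"])
                )
                out.loc[hit, "clinical_class"] = np.nan
        released[study] = out

    mask = pd.DataFrame(
        mask_rows,
        columns=["dataset_id", "participant_id", "months_since_baseline",
                 "variable"],
    )
    truth = SyntheticTruth(
        complete_tables=complete,
        mask=mask,
        latent_factors=pd.concat(latent_parts, ignore_index=True),
    )
    return released, truth
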