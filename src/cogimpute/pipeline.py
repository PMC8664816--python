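"""End-to-end driver: simulate → harmonize → impute → validate → evaluate.

A run is described by a flat YAML/dict config; every stage writes CSV
outputs into the run directory and the driver records a manifest (config
snapshot, seeds, SHA-256 digests of all outputs, per-stage wall time).
Re-running the same config and seed reproduces byte-identical CSVs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .evaluation import case_study, compare_actual_vs_imputed
from .harmonize import harmonize_studies
from .missforest import ImputationConfig, MissForest
from .schema import Schema, default_schema, load_study_table, write_table
from .synthetic import SyntheticCohortConfig, demo_config, generate_cohorts
from .validation import ValidationConfig, run_missingness_grid, run_within_vs_cross

__all__ = ["PipelineError", "run_pipeline", "build_simulation_config"]

STAGES = ("simulate", "harmonize", "impute", "validate", "evaluate")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def build_simulation_config(options: dict, seed: int) -> SyntheticCohortConfig:
    """Translate the 'simulate' config section into generator parameters."""
    opts = dict(options or {})
    n = opts.pop("n_subjects", None)
    base = demo_config(seed=seed)
    if n:
        base = base.with_overrides(n_subjects_by_study=dict(n))
    known = set(SyntheticCohortConfig.__dataclass_fields__)
    bad = [k for k in opts if k not in known]
    if bad:
        raise PipelineError("simulate", f"unknown generator options {bad}")
    if "study_shift" in opts:
        opts["study_shift"] = {
            (study, var): float(v)
            for study, shifts in opts["study_shift"].items()
            for var, v in shifts.items()}
    if "systematically_missing" in opts:
        opts["systematically_missing"] = {
            s: frozenset(vs) for s, vs in opts["systematically_missing"].items()}
    return base.with_overrides(seed=seed, **opts)


def run_pipeline(config, out_dir=None) -> dict:
    """Execute the configured stages in order and return the run manifest.

    ``config`` is a dict or a path to a YAML file.  Stage outputs that a
    later stage needs but that was not itself run must already exist in the
    run directory (e.g. joined.csv for a bare 'impute' run).
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = dict(config)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out", "run"))
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg.get("stages", list(STAGES))
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise PipelineError(bad[0], "unknown stage")
    schema = default_schema()

    manifest: dict = {"version": __version__, "seed": seed,
                      "config": cfg, "stages": [], "outputs": {}}
    tables: dict[str, pd.DataFrame] | None = None
    joined = completed = None

    def record(stage: str, t0: float, files: list[Path]) -> None:
        manifest["stages"].append(
            {"stage": stage, "seconds": round(time.perf_counter() - t0, 3)})
        for f in files:
            manifest["outputs"][str(f.relative_to(out))] = _sha256(f)

    if "simulate" in stages:
        t0 = time.perf_counter()
        sim_cfg = build_simulation_config(cfg.get("simulate"), seed)
        tables, truth = generate_cohorts(sim_cfg, schema)
        files = []
        for study, df in tables.items():
            p = out / f"study_{study}.csv"
            write_table(df, p)
            files.append(p)
        p = out / "truth_mask.csv"
        truth.mask.to_csv(p, index=False)
        files.append(p)
        for study, df in truth.complete_tables.items():
            p = out / f"truth_complete_{study}.csv"
            write_table(df, p)
            files.append(p)
        record("simulate", t0, files)

    if "harmonize" in stages:
        t0 = time.perf_counter()
        if tables is None:
            tables = _load_tables(cfg, out, schema)
        joined, log = harmonize_studies(
            tables, schema,
            sparse_threshold=float(cfg.get("harmonize", {}).get(
                "sparse_threshold", 0.5)),
            min_tests=int(cfg.get("harmonize", {}).get("min_tests", 3)),
            include_rates=bool(cfg.get("harmonize", {}).get(
                "include_rates", True)))
        pj = out / "joined.csv"
        write_table(joined, pj)
        pl = out / "exclusions_rows.csv"
        log.rows_frame().to_csv(pl, index=False)
        pv = out / "exclusions_variables.csv"
        log.variables_frame().to_csv(pv, index=False)
        record("harmonize", t0, [pj, pl, pv])

    if "impute" in stages:
        t0 = time.perf_counter()
        if joined is None:
            pj = out / "joined.csv"
            if not pj.exists():
                raise PipelineError("impute", "missing input joined.csv")
            joined = _read_joined(pj, schema)
        iopts = cfg.get("impute", {}) or {}
        excl = {"clinical_class"} if iopts.get(
            "exclude_class_predictor", True) else set()
        imp_cfg = ImputationConfig(
            n_trees=int(iopts.get("n_trees", 25)),
            max_iterations=int(iopts.get("max_iterations", 10)),
            rng_seed=seed,
            excluded_predictors=frozenset(excl) | {"dataset_id"})
        res = MissForest(joined, schema, imp_cfg).fit()
        completed = res.completed
        pc = out / "completed.csv"
        write_table(completed, pc)
        pt = out / "impute_trace.csv"
        res.delta_trace.to_csv(pt, index=False)
        (out / "impute_summary.txt").write_text(res.summary() + "\n")
        record("impute", t0, [pc, pt, out / "impute_summary.txt"])

    if "validate" in stages:
        t0 = time.perf_counter()
        if tables is None:
            tables = _load_tables(cfg, out, schema)
        vopts = cfg.get("validate", {}) or {}
        vcfg = ValidationConfig(
            outcome_variable=vopts.get("outcome", "lm_ii"),
            n_replicates=int(vopts.get("n_replicates", 5)),
            seed=seed,
            test_fractions_grid=tuple(vopts.get(
                "test_fractions", (0.25, 0.5, 1.0))),
            train_fractions_grid=tuple(vopts.get(
                "train_fractions", (1.0,))),
            imputation=ImputationConfig(
                n_trees=int(vopts.get("n_trees", 25)), rng_seed=seed))
        per_study = {s: _strip_for_validation(df, schema)
                     for s, df in tables.items()}
        ids = sorted(per_study)
        mode = vopts.get("mode", "within-cross")
        if mode == "within-cross":
            report = run_within_vs_cross(per_study[ids[0]], per_study[ids[1]],
                                         schema, vcfg)
        elif mode == "grid":
            report = run_missingness_grid(per_study[ids[1]], per_study[ids[0]],
                                          schema, vcfg)
        else:
            raise PipelineError("validate", f"unknown mode {mode!r}")
        pr = out / "validation_records.csv"
        report.records.to_csv(pr, index=False)
        ps = out / "validation_summary.csv"
        report.summarize().to_csv(ps, index=False)
        record("validate", t0, [pr, ps])

    if "evaluate" in stages:
        t0 = time.perf_counter()
        if completed is None:
            pc = out / "completed.csv"
            if not pc.exists():
                raise PipelineError("evaluate", "missing input completed.csv")
            completed = _read_joined(pc, schema)
        if joined is None:
            joined = _read_joined(out / "joined.csv", schema)
        eopts = cfg.get("evaluate", {}) or {}
        variable = eopts.get("variable", "cvlt_immediate")
        disc, boxes = compare_actual_vs_imputed(joined, completed, variable,
                                                schema)
        pd_ = out / "discrimination.csv"
        disc.to_csv(pd_, index=False)
        pb = out / "boxplot_data.csv"
        boxes.to_csv(pb, index=False)
        files = [pd_, pb]
        if "amyloid_centiloid" in completed.columns:
            cs = case_study(completed, variable, "amyloid_centiloid", schema)
            pcs = out / "case_study.csv"
            pd.DataFrame([vars(v) for v in cs.values()]).to_csv(
                pcs, index=False)
            files.append(pcs)
        record("evaluate", t0, files)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _load_tables(cfg: dict, out: Path, schema: Schema) -> dict[str, pd.DataFrame]:
    inputs = cfg.get("studies")
    tables = {}
    if inputs:
        for study, path in inputs.items():
            tables[study] = load_study_table(path, schema, study)
    else:
        for study in ("A", "B"):
            p = out / f"study_{study}.csv"
            if not p.exists():
                raise PipelineError(
                    "harmonize", f"missing input {p.name} (run simulate "
                    "first or give 'studies' paths)")
            tables[study] = load_study_table(p, schema, study)
    return tables


def _read_joined(path, schema: Schema) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.mask(df.isin(["", "NA"]))
    for c in df.columns:
        if c in schema and schema[c].is_numeric:
            df[c] = pd.to_numeric(df[c])
    return df


def _strip_for_validation(df: pd.DataFrame, schema: Schema) -> pd.DataFrame:
    """Per-study table ready for the validation experiments.

    Missing classifications are resolved/dropped and only complete rows of
    the common battery are kept, so validation masks are the only
    missingness the forests see.
    """
    from .harmonize import drop_sparse_visits, rebaseline, resolve_classification

    out, _ = resolve_classification(df)
    out, _ = drop_sparse_visits(out, schema)
    out = rebaseline(out)
    drop = set(schema.systematic_targets()) | set(schema.auxiliary_names())
    out = out.drop(columns=[c for c in drop if c in out.columns])
    return out.dropna().reset_index(drop=True)
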