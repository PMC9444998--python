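"""File-based pipeline orchestration.

Stages (each idempotent, resumable from its input files):

    simulate -> quantify -> select -> fit (per age target) -> accelerate
             -> cluster -> report

All stage handoff is via CSV files in a working directory, so every stage
is independently inspectable and testable. All randomness derives from the
single config seed: each stage uses ``derive_seed(seed, stage_name)``
(SHA-256 of "seed:stage", reduced mod 2^31), so adding or reordering
stages never perturbs another stage's draws.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acceleration import build_acceleration_panel, correlation_matrix, read_panel, write_panel
from .clock import (ClockSpec, FittedClock, MODEL_FAMILIES, cross_validate, fit_final,
                    results_to_frame, select_optimal)
from .errors import CogClockError, ConfigError, DataError
from .patterns import (DEFAULT_K, DEFAULT_KERNEL_SD, DEFAULT_PATTERN_QUANTIFIERS,
                       DEFAULT_THRESHOLD_FACTOR, build_pattern_matrix, cluster_patterns,
                       test_group_acceleration)
from .quantifiers import (QuantifierMapping, build_quantifier_matrix, default_mapping,
                          read_quantifiers, write_quantifiers)
from .selection import (DEFAULT_ALPHA, ranked_quantifier_names, read_selection,
                        select_quantifiers, write_selection)
from .synthetic import (BioClockSpec, CohortConfig, IndexSpec, SubgroupSpec,
                        generate_cohort, read_cohort, write_cohort)

log = logging.getLogger(__name__)

#: CLI target keyword -> cohort-table column
TARGET_COLUMNS = {
    "chronological": "age",
    "phenoage": "PhenoAge",
    "dnamage": "DNAmAge",
    "hannum": "DNAmAgeHannum",
    "dnamphenoage": "DNAmPhenoAge",
    "grimage": "DNAmGrimAge",
}


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "workdir": "cogclock_run",
    "simulate": {},  # CohortConfig field overrides; omit stage if data provided
    "select": {"alpha": DEFAULT_ALPHA, "targets": ["chronological"]},
    "fit": {
        "targets": ["chronological"],
        "model_families": ["linear", "svr_rbf", "knn"],
        "top_k_range": [5, 10, 15, 20],
        "n_folds": 5,
        "objective": "mean_EV",
        "ranking_mode": "paper",
    },
    "accelerate": {"mode": "residual"},
    "cluster": {
        "k": DEFAULT_K,
        "kernel_sd": DEFAULT_KERNEL_SD,
        "threshold_factor": DEFAULT_THRESHOLD_FACTOR,
        "n_restarts": 50,
    },
}


def _merge(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), Mapping):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Load and validate a pipeline config (YAML), merged over defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    validate_config(cfg)
    return cfg


def validate_config(cfg: Mapping[str, Any]) -> None:
    """Fail fast, before any stage runs."""
    for fam in cfg["fit"].get("model_families", []):
        if fam not in MODEL_FAMILIES:
            raise ConfigError(f"fit.model_families: unknown model family {fam!r}; "
                              f"expected one of {MODEL_FAMILIES}")
    for tgt in list(cfg["select"].get("targets", [])) + list(cfg["fit"].get("targets", [])):
        if tgt not in TARGET_COLUMNS:
            raise ConfigError(f"unknown age target {tgt!r}; "
                              f"expected one of {tuple(TARGET_COLUMNS)}")
    if cfg["accelerate"].get("mode") not in ("difference", "residual"):
        raise ConfigError("accelerate.mode must be 'difference' or 'residual'")
    if int(cfg["cluster"].get("k", DEFAULT_K)) < 1:
        raise ConfigError("cluster.k must be >= 1")
    _cohort_config(cfg)  # raises ConfigError on bad simulate fields


def _cohort_config(cfg: Mapping[str, Any]) -> CohortConfig:
    sim = dict(cfg.get("simulate") or {})
    if "index_specs" in sim:
        sim["index_specs"] = tuple(IndexSpec(**s) for s in sim["index_specs"])
    if "bio_clock_specs" in sim:
        sim["bio_clock_specs"] = tuple(BioClockSpec(**s) for s in sim["bio_clock_specs"])
    if "subgroups" in sim:
        sim["subgroups"] = tuple(SubgroupSpec(**s) for s in sim["subgroups"])
    sim.setdefault("seed", derive_seed(int(cfg.get("seed", 0)), "simulate"))
    try:
        config = CohortConfig(**sim)
    except TypeError as exc:
        raise ConfigError(f"simulate: {exc}") from exc
    config.validate()
    return config


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: Mapping[str, Any], workdir: Path) -> dict[str, Path]:
    cohort = generate_cohort(_cohort_config(cfg))
    return write_cohort(cohort, workdir)


def _load_cohort(workdir: Path):
    cohort = read_cohort(workdir)
    if len(cohort) == 0:
        raise DataError(f"{workdir}: cohort is empty")
    return cohort


def stage_quantify(cfg: Mapping[str, Any], workdir: Path) -> Path:
    cohort = _load_cohort(workdir)
    mapping_path = (cfg.get("quantify") or {}).get("mapping")
    if mapping_path:
        mapping = QuantifierMapping.from_file(mapping_path)
    else:
        # derive the shipped default mapping from the configured index specs
        specs = _cohort_config(cfg).index_specs
        known = {s.name for s in specs}
        if set(cohort.index_names) <= known:
            mapping = default_mapping([s for s in specs if s.name in cohort.index_names])
        else:
            mapping = QuantifierMapping(tuple((n, "mean") for n in cohort.index_names))
    matrix = build_quantifier_matrix(cohort, mapping)
    out = workdir / "quantifiers.csv"
    write_quantifiers(matrix, out)
    log.info("quantify: %d participants x %d quantifiers", *matrix.shape)
    return out


def _target_vector(cohort_df: pd.DataFrame, target: str) -> np.ndarray:
    col = TARGET_COLUMNS[target]
    if col not in cohort_df.columns:
        raise DataError(f"cohort table lacks column {col!r} required for "
                        f"target {target!r}")
    return cohort_df[col].to_numpy(dtype=float)


def stage_select(cfg: Mapping[str, Any], workdir: Path, target: str) -> Path:
    matrix = read_quantifiers(workdir / "quantifiers.csv")
    cohort_df = pd.read_csv(workdir / "cohort.csv").set_index("id")
    cohort_df = cohort_df.loc[matrix.index]
    age = _target_vector(cohort_df, target)
    alpha = float(cfg["select"].get("alpha", DEFAULT_ALPHA))
    sel = select_quantifiers(matrix, age, alpha=alpha, target_name=target)
    out = workdir / f"selection_{target}.csv"
    write_selection(sel, out)
    log.info("select[%s]: %d/%d significant at BH-adjusted p < %g",
             target, int(sel["significant"].sum()), len(sel), alpha)
    return out


def stage_fit(cfg: Mapping[str, Any], workdir: Path, target: str) -> dict[str, Path]:
    matrix = read_quantifiers(workdir / "quantifiers.csv")
    cohort_df = pd.read_csv(workdir / "cohort.csv").set_index("id")
    cohort_df = cohort_df.loc[matrix.index]
    age = _target_vector(cohort_df, target)
    sel_path = workdir / f"selection_{target}.csv"
    if not sel_path.exists():
        raise DataError(f"missing {sel_path}; run the 'select' stage first")
    sel = read_selection(sel_path)
    ranked = ranked_quantifier_names(sel)

    fit_cfg = cfg["fit"]
    spec = ClockSpec(
        model_families=tuple(fit_cfg["model_families"]),
        grids=fit_cfg.get("grids"),
        top_k_range=tuple(int(k) for k in fit_cfg["top_k_range"]),
        n_folds=int(fit_cfg["n_folds"]),
        objective=fit_cfg["objective"],
        ranking_mode=fit_cfg["ranking_mode"],
        seed=derive_seed(int(cfg["seed"]), f"fit:{target}"),
    )
    keep = np.isfinite(age)
    results = cross_validate(spec, matrix.loc[keep], ranked, age[keep])
    winner = select_optimal(results, spec.objective)
    clock = fit_final(winner, matrix.loc[keep], ranked, age[keep],
                      target_name=target, seed=spec.seed)

    cv_path = workdir / f"cv_results_{target}.csv"
    results_to_frame(results).to_csv(cv_path, index=False)
    clock_path = workdir / f"clock_{target}.pkl"
    clock.save(clock_path)
    pred_path = workdir / f"predictions_{target}.csv"
    clock.predict(matrix).rename("predicted").to_frame().assign(
        target=target).to_csv(pred_path, index=True, index_label="id")
    log.info("fit[%s]: winner %s %s top_k=%d (mean EV %.3f, mean MAE %.2f y)",
             target, winner.family, winner.params, winner.top_k,
             winner.mean_ev, winner.mean_mae)
    return {"cv": cv_path, "clock": clock_path, "predictions": pred_path}


def stage_accelerate(cfg: Mapping[str, Any], workdir: Path) -> dict[str, Path]:
    cohort_df = pd.read_csv(workdir / "cohort.csv").set_index("id")
    ages = pd.DataFrame(index=cohort_df.index)
    for target in cfg["fit"]["targets"]:
        pred_path = workdir / f"predictions_{target}.csv"
        if pred_path.exists():
            pred = pd.read_csv(pred_path).set_index("id")["predicted"]
            ages[f"Cognitive[{target}]"] = pred.reindex(cohort_df.index)
    for col in cohort_df.columns:
        if col not in ("sex", "age"):
            ages[col] = cohort_df[col]
    if ages.shape[1] == 0:
        raise DataError("no clock-age columns available; run 'fit' first or "
                        "supply biological-age columns in cohort.csv")

    chrono = cohort_df["age"].to_numpy(dtype=float)
    mode = cfg["accelerate"]["mode"]
    panel = build_acceleration_panel(ages, chrono, mode=mode)
    acc_path = workdir / "accelerations.csv"
    write_panel(panel, acc_path)

    ages_all = ages.copy()
    ages_all.insert(0, "age", chrono)
    corr_ages = correlation_matrix(ages_all)
    corr_acc = correlation_matrix(panel)
    corr_ages_path = workdir / "correlations_ages.csv"
    corr_acc_path = workdir / "correlations_accelerations.csv"
    corr_ages.to_csv(corr_ages_path)
    corr_acc.to_csv(corr_acc_path)
    return {"accelerations": acc_path, "corr_ages": corr_ages_path,
            "corr_accelerations": corr_acc_path}


def stage_cluster(cfg: Mapping[str, Any], workdir: Path) -> dict[str, Path]:
    matrix = read_quantifiers(workdir / "quantifiers.csv")
    cohort_df = pd.read_csv(workdir / "cohort.csv").set_index("id")
    cohort_df = cohort_df.loc[matrix.index]
    ccfg = cfg["cluster"]
    patterns = build_pattern_matrix(
        matrix, cohort_df["age"].to_numpy(dtype=float),
        pattern_quantifiers=ccfg.get("pattern_quantifiers"),
        kernel_sd=float(ccfg["kernel_sd"]),
        threshold_factor=float(ccfg["threshold_factor"]))
    groups = cluster_patterns(patterns, k=int(ccfg["k"]),
                              seed=derive_seed(int(cfg["seed"]), "cluster"),
                              n_restarts=int(ccfg["n_restarts"]))

    panel = read_panel(workdir / "accelerations.csv")
    cog_cols = [c for c in panel.columns if c.startswith("Cognitive[")]
    if not cog_cols:
        raise DataError("accelerations.csv has no cognitive-clock column; "
                        "run 'fit' and 'accelerate' first")
    acc = panel[cog_cols[0]].reindex(patterns.index)
    keep = acc.notna()
    report = test_group_acceleration(acc[keep].to_numpy(),
                                     groups[keep].to_numpy())

    patterns_path = workdir / "patterns.csv"
    patterns.to_csv(patterns_path, index=True, index_label="id")
    clusters_path = workdir / "clusters.csv"
    groups.to_frame().to_csv(clusters_path, index=True, index_label="id")
    report_path = workdir / "cluster_report.csv"
    report.to_csv(report_path, index=False)
    return {"patterns": patterns_path, "clusters": clusters_path,
            "report": report_path}


def stage_report(cfg: Mapping[str, Any], workdir: Path) -> Path:
    """Aggregate prior outputs into summary.json without recomputation."""
    summary: dict[str, Any] = {"version": __version__}
    for target in cfg["fit"]["targets"]:
        sel_path = workdir / f"selection_{target}.csv"
        if sel_path.exists():
            sel = read_selection(sel_path)
            summary[f"n_significant[{target}]"] = int(sel["significant"].sum())
        cv_path = workdir / f"cv_results_{target}.csv"
        if cv_path.exists():
            cv = pd.read_csv(cv_path)
            best = cv.sort_values(["mean_ev", "top_k"],
                                  ascending=[False, True]).iloc[0]
            summary[f"best_model[{target}]"] = {
                "family": best["family"], "top_k": int(best["top_k"]),
                "mean_ev": float(best["mean_ev"]),
                "mean_mae": float(best["mean_mae"]),
                "mean_medae": float(best["mean_medae"])}
    rep_path = workdir / "cluster_report.csv"
    if rep_path.exists():
        rep = pd.read_csv(rep_path)
        summary["clusters"] = rep.to_dict(orient="records")
    corr_path = workdir / "correlations_accelerations.csv"
    if corr_path.exists():
        corr = pd.read_csv(corr_path, index_col=0)
        summary["acceleration_correlations"] = {
            c: (None if pd.isna(corr.iloc[0][c]) else float(corr.iloc[0][c]))
            for c in corr.columns}
    out = workdir / "summary.json"
    out.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config_path: str | Path | None = None,
                 overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Execute all stages; returns the run manifest (also written to disk)."""
    cfg = load_config(config_path, overrides)
    workdir = Path(cfg["workdir"])
    workdir.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, Any] = {
        "config": {k: v for k, v in cfg.items()},
        "seed": int(cfg["seed"]),
        "version": __version__,
        "stages": [],
        "outputs": {},
    }

    def run_stage(name: str, fn, *args):
        t0 = time.perf_counter()
        result = fn(cfg, workdir, *args)
        manifest["stages"].append({"stage": name,
                                   "seconds": round(time.perf_counter() - t0, 3)})
        return result

    if cfg.get("simulate") is not None:
        run_stage("simulate", stage_simulate)
    run_stage("quantify", stage_quantify)
    targets = list(dict.fromkeys(list(cfg["select"]["targets"])
                                 + list(cfg["fit"]["targets"])))
    for target in targets:
        run_stage(f"select:{target}", stage_select, target)
    for target in cfg["fit"]["targets"]:
        run_stage(f"fit:{target}", stage_fit, target)
    run_stage("accelerate", stage_accelerate)
    run_stage("cluster", stage_cluster)
    run_stage("report", stage_report)

    manifest["outputs"] = {p.name: _sha256(p) for p in sorted(workdir.glob("*.csv"))}
    (workdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return manifest
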