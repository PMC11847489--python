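"""End-to-end pipeline: configuration, orchestration and artifacts.

Stage order: clean → dedup → thin → mask to calibration region →
correlation/VIF pruning → contribution pruning → candidate grid →
evaluate/select → final bootstrap replicate fit → projection (+ MOP) →
MTSS threshold → binarize → change / centroid / protected-area summaries.
Every random stage draws its seed deterministically from the master seed,
so one integer reproduces the whole run.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration, changes, maxent, occurrences, predictors, projection, raster
from . import synthetic
from .raster import RasterLayer, RasterStack

_PARAM_SPEC: dict[str, tuple[type, object]] = {
    # name: (type, default) — the study's defaults
    "min_year": (int, 1965),
    "require_date": (bool, True),
    "min_dist_km": (float, 5.5),
    "thin_attempts": (int, 10),
    "r_threshold": (float, 0.7),
    "contribution_threshold": (float, 1.0),
    "contribution_runs": (int, 10),
    "classes": (str, "lqph"),
    "rm_values": (list, [0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0]),
    "train_frac": (float, 0.7),
    "E": (float, 0.05),
    "alpha": (float, 0.05),
    "d_aicc_max": (float, 2.0),
    "replicates": (int, 10),
    "background_max": (int, 10000),
    "hinge_knots": (int, 50),
    "max_iter": (int, 500),
    "tol": (float, 1e-5),
    "proc_iterations": (int, 500),
    "mop_subset_frac": (float, 0.10),
    "clamp": (bool, True),
}

_RANGES = {
    "train_frac": (0.0, 1.0, "exclusive"),
    "E": (0.0, 1.0, "half"),
    "alpha": (0.0, 1.0, "exclusive"),
    "mop_subset_frac": (0.0, 1.0, "half_upper"),
}


@dataclass
class PipelineConfig:
    occurrences: str
    predictors: dict[str, str]
    scenarios: dict[str, dict[str, str]] = field(default_factory=dict)
    m_area: str | None = None
    mpas: str | None = None
    seed: int = 0
    params: dict = field(default_factory=dict)

    def param(self, name: str):
        return self.params[name]


def validate_config(raw: dict) -> PipelineConfig:
    """Validate a raw config document, filling defaults.

    Unknown keys are rejected; every type/range violation is collected
    and reported together.
    """
    errors: list[str] = []
    known_top = {"occurrences", "predictors", "scenarios", "m_area", "mpas",
                 "seed", "params"}
    for key in raw:
        if key not in known_top:
            errors.append(f"unknown key {key!r}")
    params = dict(raw.get("params") or {})
    for key in params:
        if key not in _PARAM_SPEC:
            errors.append(f"unknown parameter {key!r}")
    merged = {}
    for name, (typ, default) in _PARAM_SPEC.items():
        val = params.get(name, default)
        try:
            if typ is bool and not isinstance(val, bool):
                raise TypeError
            val = typ(val) if typ is not list else list(val)
        except (TypeError, ValueError):
            errors.append(f"parameter {name!r} must be {typ.__name__}, got {val!r}")
            continue
        merged[name] = val
    if "rm_values" in merged and any(rm <= 0 for rm in merged["rm_values"]):
        errors.append("rm_values must all be positive")
    for name, (lo, hi, kind) in _RANGES.items():
        v = merged.get(name)
        if v is None:
            continue
        ok = {"exclusive": lo < v < hi, "half": lo <= v < hi,
              "half_upper": lo < v <= hi}[kind]
        if not ok:
            errors.append(f"parameter {name!r}={v} out of range")
    if merged.get("min_dist_km", 1) <= 0:
        errors.append("min_dist_km must be positive")
    if "occurrences" not in raw:
        errors.append("missing required key 'occurrences'")
    if not raw.get("predictors"):
        errors.append("missing required key 'predictors'")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return PipelineConfig(
        occurrences=raw["occurrences"], predictors=dict(raw["predictors"]),
        scenarios={k: dict(v) for k, v in (raw.get("scenarios") or {}).items()},
        m_area=raw.get("m_area"), mpas=raw.get("mpas"),
        seed=int(raw.get("seed", 0)), params=merged)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return (zlib.crc32(stage.encode()) ^ (master * 2654435761)) % (2 ** 31)


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage; write artifacts and return the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "warnings": []}
    p = cfg.param

    # --- occurrences: clean, dedup, thin
    occ = raster.read_occurrences_csv(cfg.occurrences)
    region = raster.read_polygons(cfg.m_area) if cfg.m_area else None
    clean_cfg = occurrences.CleaningConfig(min_year=p("min_year"),
                                           range_polygons=region,
                                           require_date=p("require_date"))
    occ, clean_report = occurrences.clean_occurrences(occ, clean_cfg)
    stack = raster.align_stack([raster.read_raster(path, name)
                                for name, path in cfg.predictors.items()])
    occ = occurrences.deduplicate(occ, stack.grid)
    occ = occurrences.thin(occ, occurrences.ThinConfig(
        min_dist_km=p("min_dist_km"), n_attempts=p("thin_attempts"),
        seed=stage_seed(cfg.seed, "thin")))
    occ.to_csv(outdir / "occurrences_clean.csv", index=False)
    manifest["stages"]["occurrences"] = {**clean_report, "final": len(occ)}

    # --- calibration region mask
    if region is not None:
        stack = raster.mask_to_region(stack, region)

    # --- predictor selection
    kept, corr_report = predictors.vifcor_prune(stack, p("r_threshold"))
    manifest["stages"]["vifcor"] = {"kept": kept,
                                    "dropped": [s["dropped"] for s in corr_report.steps]}
    stack = stack.subset(kept)
    occ_rows, occ_cols = stack.grid.cell_index(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    ok = ~stack.combined_mask[occ_rows, occ_cols]
    occ_env = stack.env_table(occ_rows[ok], occ_cols[ok])
    fit_opts = {"max_iter": p("max_iter"), "tol": p("tol"), "n_knots": p("hinge_knots")}
    kept, contrib = predictors.contribution_prune(
        occ_env, stack, p("contribution_threshold"), runs=p("contribution_runs"),
        seed=stage_seed(cfg.seed, "contribution"),
        background_max=p("background_max"), **fit_opts)
    contrib.per_run.to_csv(outdir / "contributions.csv", index=False)
    manifest["stages"]["contribution"] = {"kept": kept, "dropped": contrib.dropped}
    stack = stack.subset(kept)
    occ_env = occ_env[kept]

    # --- candidate evaluation and selection
    train_env, test_env = calibration.split_occurrences(
        occ_env, p("train_frac"), seed=stage_seed(cfg.seed, "split"))
    bg_env, _, _ = maxent.sample_background(stack, p("background_max"),
                                            seed=stage_seed(cfg.seed, "background"))
    all_rows, all_cols = stack.data_cells()
    all_env = stack.env_table(all_rows, all_cols)
    cands = calibration.generate_candidates(p("rm_values"), p("classes"))
    criteria = calibration.SelectionCriteria(p("alpha"), p("E"), p("d_aicc_max"))
    results = calibration.evaluate_candidates(
        cands, train_env, test_env, bg_env, all_env, criteria,
        seed=stage_seed(cfg.seed, "proc"), proc_iterations=p("proc_iterations"),
        **fit_opts)
    table = calibration.results_table(results)
    table.to_csv(outdir / "candidates.csv", index=False)
    selected = [r for r in results if r.selected]
    if not selected:
        manifest["warnings"].append("no candidate selected; using best ΔAICc model")
        finite = [r for r in results if not r.failed and np.isfinite(r.aicc)]
        selected = [min(finite, key=lambda r: r.aicc)]
    chosen = selected[0]
    manifest["stages"]["calibration"] = {
        "n_candidates": len(cands), "selected": chosen.label,
        "n_selected": len([r for r in results if r.selected])}

    # --- final model: bootstrap replicates on all occurrences
    reps = maxent.replicate_fit(occ_env, bg_env, chosen.spec, n=p("replicates"),
                                seed=stage_seed(cfg.seed, "replicates"), **fit_opts)
    current = projection.project(reps, stack, clamp=p("clamp"))
    raster.write_raster(current, outdir / "suitability_current.asc")
    mean_auc = float(np.mean([maxent.training_auc(m, occ_env) for m in reps.models]))
    manifest["stages"]["final_model"] = {"mean_training_auc": mean_auc,
                                         "replicates": len(reps.models)}

    # --- threshold from training presences vs background
    pres_scores, _ = reps.cloglog_stats(occ_env)
    bg_scores, _ = reps.cloglog_stats(bg_env)
    thr = changes.mtss_threshold(pres_scores, bg_scores)
    manifest["stages"]["threshold"] = {"mtss": thr.threshold,
                                       "sensitivity": thr.sensitivity,
                                       "specificity": thr.specificity}
    areas = raster.cell_areas(stack.grid)
    cur_bin = changes.binarize(current, thr.threshold)
    raster.write_raster(cur_bin.layer, outdir / "binary_current.asc")
    cur_total = float(areas.area_km2[cur_bin.suitable].sum())
    cur_centroid = changes.centroid(cur_bin, areas)

    mpas = raster.read_polygons(cfg.mpas) if cfg.mpas else None
    cur_inside = None
    overlap_rows = []
    if mpas is not None:
        ov = changes.mpa_overlap(cur_bin, mpas, areas, cur_total)
        cur_inside = ov.inside_km2
        overlap_rows.append({"scenario": "current", "total_km2": ov.total_km2,
                             "inside_km2": ov.inside_km2, "outside_km2": ov.outside_km2,
                             "pct_inside": ov.pct_inside, "pct_outside": ov.pct_outside,
                             "change_inside_km2": np.nan, "change_inside_pct": np.nan})

    # --- scenario projections
    change_rows, shift_rows = [], []
    for label, paths in cfg.scenarios.items():
        scen = raster.align_stack([raster.read_raster(path, name)
                                   for name, path in paths.items()])
        scen = scen.subset([n for n in stack.names])
        fut = projection.project(reps, scen, clamp=p("clamp"))
        raster.write_raster(fut, outdir / f"suitability_{label}.asc")
        mopmap = projection.mop(stack, scen, p("mop_subset_frac"),
                                sample_cap=p("background_max"),
                                seed=stage_seed(cfg.seed, f"mop_{label}"))
        raster.write_raster(mopmap.similarity, outdir / f"mop_{label}.asc")
        fut_bin = changes.binarize(fut, thr.threshold)
        cm = changes.change_map(cur_bin, fut_bin)
        raster.write_raster(cm.layer, outdir / f"change_{label}.asc")
        summ = changes.change_summary(cm, areas)
        change_rows.append({
            "scenario": label, "current_km2": summ.total_current_km2,
            "future_km2": summ.total_future_km2,
            "maintained_km2": summ.maintained_km2, "gained_km2": summ.gained_km2,
            "lost_km2": summ.lost_km2, "pct_maintained": summ.pct_maintained,
            "pct_gained": summ.pct_gained, "pct_lost": summ.pct_lost,
            "total_change_pct": summ.total_change_pct})
        fut_centroid = changes.centroid(fut_bin, areas)
        sh = changes.shift(cur_centroid, fut_centroid)
        shift_rows.append({"scenario": label, "from_lon": sh.from_lon,
                           "from_lat": sh.from_lat, "to_lon": sh.to_lon,
                           "to_lat": sh.to_lat, "distance_km": sh.distance_km,
                           "bearing_deg": sh.bearing_deg})
        if mpas is not None:
            ov = changes.mpa_overlap(fut_bin, mpas, areas, cur_total, cur_inside)
            overlap_rows.append({
                "scenario": label, "total_km2": ov.total_km2,
                "inside_km2": ov.inside_km2, "outside_km2": ov.outside_km2,
                "pct_inside": ov.pct_inside, "pct_outside": ov.pct_outside,
                "change_inside_km2": ov.change_inside_km2,
                "change_inside_pct": ov.change_inside_pct})

    if change_rows:
        pd.DataFrame(change_rows).to_csv(outdir / "change_summary.csv", index=False)
        pd.DataFrame(shift_rows).to_csv(outdir / "centroid_shifts.csv", index=False)
    if overlap_rows:
        pd.DataFrame(overlap_rows).to_csv(outdir / "mpa_overlap.csv", index=False)
    manifest["stages"]["outputs"] = {"current_km2": cur_total,
                                     "centroid": list(cur_centroid)}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def simulate_inputs(outdir: str | Path, seed: int = 0, *,
                    n_rows: int = 120, n_cols: int = 120, n_presences: int = 400,
                    d_lon: float = 1.0, mpa_coverage: float = 0.25,
                    scenario_label: str = "future") -> dict:
    """Write a complete synthetic input set (rasters, occurrences, polygons).

    Returns a config dict that :func:`run_pipeline` accepts after
    :func:`validate_config`.  The synthetic truth translates east by
    ``d_lon`` degrees in the future scenario.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = synthetic.LandscapeConfig(n_rows=n_rows, n_cols=n_cols, seed=seed)
    stack, truth = synthetic.make_landscape(cfg)
    truth_r = synthetic.true_suitability(truth, stack)
    occ = synthetic.sample_occurrences(truth_r, n_presences, seed=seed + 1)
    occ.to_csv(outdir / "occurrences.csv", index=False)
    pred_paths = {}
    for layer in stack.layers:
        path = outdir / f"{layer.name}.asc"
        raster.write_raster(layer, path)
        pred_paths[layer.name] = str(path)
    scen = synthetic.make_future(stack, synthetic.ScenarioConfig(d_lon=d_lon),
                                 truth=truth)
    scen_paths = {}
    for layer in scen.layers:
        path = outdir / f"{layer.name}_{scenario_label}.asc"
        raster.write_raster(layer, path)
        scen_paths[layer.name] = str(path)
    thr = float(np.quantile(truth_r.data_values, 0.8))
    mpas = synthetic.make_protected_areas(changes.binarize(truth_r, thr),
                                          mpa_coverage, seed=seed + 2)
    raster.write_polygons(mpas, outdir / "mpas.geojson")
    return {
        "occurrences": str(outdir / "occurrences.csv"),
        "predictors": pred_paths,
        "scenarios": {scenario_label: scen_paths},
        "mpas": str(outdir / "mpas.geojson"),
        "seed": seed,
    }
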