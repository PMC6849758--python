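"""End-to-end orchestration: simulate -> QC -> statistics -> outlier scan ->
GEA -> candidates -> connectivity -> MRDM -> risk assessment.

`run_pipeline` executes the stages in dependency order from a single
nested config dict (YAML-friendly), writes per-stage CSV/raster artifacts
into an output directory and finishes with a manifest (parameter echo,
seeds, file hashes).  Reruns with the same config and seed produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adaptive_candidates import intersect, orient_candidates, population_summary
from .exposure_risk import (ExposureRecord, adaptive_sensitivity, assess,
                            exposure_level, neutral_sensitivity)
from .genotype_qc import QcThresholds, apply_qc
from .landscape_connectivity import (build_cost_surface, connectivity_change,
                                     cumulative_current, euclidean_matrix,
                                     resistance_distance)
from .latent_factor_gea import broadcast_pop_values, run_two_scales
from .matrix import MISSING
from .mrdm import env_dissimilarity_matrix, ibe_test, stepwise_residual
from .outlier_scan import logistic_env_regression, scan, simulate_envelope
from .popgen_stats import amova, fst_matrix, heterozygosity, mean_multilocus_fst
from .synthetic_data import (FutureDelta, SimConfig, generate,
                             write_simulation)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},                      # SimConfig overrides
    "qc": {},                            # QcThresholds overrides
    "scan": {"alpha": 0.01, "n_sim_loci": 10_000},
    "gea": {"k_full": 3, "k_region": 2, "n_runs": 5, "fdr": 0.05},
    "candidates": {"logit_alpha": 0.05, "gea_scale": "region"},
    "connect": {"sea_cost": 200.0, "buffer_radius": 3, "tau": 0.5},
    "mrdm": {"n_permutations": 1000},
    "assess": {},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base.get(k, {}), v) if isinstance(v, dict) else v
    return out


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict | None = None, outdir="pipeline_out") -> dict:
    """Run every stage; returns the in-memory results keyed by stage."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    results: dict = {}

    # ---- simulate ----------------------------------------------------
    sim_kwargs = dict(cfg["simulate"])
    if "future_delta" in sim_kwargs and isinstance(sim_kwargs["future_delta"], dict):
        sim_kwargs["future_delta"] = FutureDelta(**sim_kwargs["future_delta"])
    if "grid_shape" in sim_kwargs:
        sim_kwargs["grid_shape"] = tuple(sim_kwargs["grid_shape"])
    sim_cfg = SimConfig(seed=seed, **sim_kwargs)
    sim = generate(sim_cfg)
    write_simulation(sim, outdir / "simulate")
    results["simulate"] = sim

    # ---- qc ----------------------------------------------------------
    gm, report = apply_qc(sim.genotypes, QcThresholds(**cfg["qc"]))
    report.to_frame().to_csv(outdir / "qc_report.csv", index=False)
    results["qc"] = (gm, report)
    stat_pops = report.pops_for_stats
    pops = sim.pops[sim.pops["pop"].isin(stat_pops)].reset_index(drop=True)
    main_pops = pops.loc[pops["region"] == "main", "pop"].tolist()

    # ---- outlier scan ------------------------------------------------
    sizes = [int(np.sum((np.asarray(gm.pop_ids) == p)
                        & np.any(gm.genotypes != MISSING, axis=1)))
             for p in stat_pops]
    target = mean_multilocus_fst(gm, stat_pops)
    envelope = simulate_envelope(
        len(stat_pops), sizes, target,
        n_sim_loci=int(cfg["scan"]["n_sim_loci"]), seed=seed)
    scan_df = scan(gm, envelope, alpha=float(cfg["scan"]["alpha"]),
                   pops=stat_pops)
    scan_df.to_csv(outdir / "outlier_scan.csv", index=False)
    results["scan"] = scan_df
    outlier_loci = scan_df.loc[scan_df["outlier"], "locus"].tolist()

    # ---- population statistics --------------------------------------
    gm_stats = gm.subset_pops(stat_pops)
    het_ind, het_pop = heterozygosity(gm_stats, exclude_loci=outlier_loci)
    het_ind.to_csv(outdir / "het_individual.csv", index=False)
    het_pop.to_csv(outdir / "het_population.csv", index=False)
    neutral_idx = np.array([l not in set(outlier_loci) for l in gm.locus_ids])
    fst_neutral = fst_matrix(gm, stat_pops, np.flatnonzero(neutral_idx),
                             name="fst_neutral")
    fst_neutral.to_csv(outdir / "fst_neutral.csv")
    amova_pops = amova(gm_stats, n_permutations=199, seed=seed)
    results["stats"] = {"het_pop": het_pop, "fst_neutral": fst_neutral,
                        "amova": amova_pops}

    # ---- GEA ---------------------------------------------------------
    gea = run_two_scales(
        gm, pops, {"temperature": "tmax_now", "rainfall": "rain_now"},
        K_full=int(cfg["gea"]["k_full"]), K_region=int(cfg["gea"]["k_region"]),
        n_runs=int(cfg["gea"]["n_runs"]), seed=seed,
        fdr=float(cfg["gea"]["fdr"]))
    pd.concat([s.table.assign(scale=s.scale, covariate=s.covariate)
               for s in gea.values()]).to_csv(outdir / "gea.csv", index=False)
    results["gea"] = gea

    # ---- candidate intersection -------------------------------------
    gm_region = gm.subset_pops(main_pops)
    logit_rows = []
    locus_index = {l: k for k, l in enumerate(gm_region.locus_ids)}
    for covariate, col in (("temperature", "tmax_now"), ("rainfall", "rain_now")):
        env = broadcast_pop_values(
            gm_region, pops[pops["pop"].isin(main_pops)], col)
        for locus in outlier_loci:
            dosage = gm_region.genotypes[:, locus_index[locus]]
            try:
                fit = logistic_env_regression(dosage, env)
            except ValueError:
                continue
            logit_rows.append({"locus": locus, "covariate": covariate,
                               "slope": fit.slope, "p": fit.p_value})
    logit_df = pd.DataFrame(logit_rows,
                            columns=["locus", "covariate", "slope", "p"])
    candidates = intersect(scan_df, gea, logit_df,
                           gea_scale=cfg["candidates"]["gea_scale"],
                           logit_alpha=float(cfg["candidates"]["logit_alpha"]))
    candidates = orient_candidates(candidates) if not candidates.empty \
        else candidates
    candidates.to_csv(outdir / "candidates.csv", index=False)
    results["candidates"] = candidates
    if not candidates.empty:
        adaptive_summary = population_summary(candidates, gm, stat_pops)
    else:
        adaptive_summary = pd.DataFrame(
            {"pop": stat_pops, "n_candidates": 0,
             "mean_adaptive_freq": np.nan, "n_below_025": 0,
             "fraction_below_025": np.nan})
    adaptive_summary.to_csv(outdir / "adaptive_summary.csv", index=False)

    # ---- connectivity ------------------------------------------------
    sea_cost = float(cfg["connect"]["sea_cost"])
    land = sim.landscape
    focal = list(zip(pops["row"], pops["col"]))
    labels = pops["pop"].tolist()
    surf_now = build_cost_surface(land["suitability_now"], "suitability",
                                  land.sea_mask, sea_cost)
    surf_fut = build_cost_surface(land["suitability_future"], "suitability",
                                  land.sea_mask, sea_cost)
    res_now = resistance_distance(surf_now, focal, labels)
    res_fut = resistance_distance(surf_fut, focal, labels)
    cur_now = cumulative_current(surf_now, focal)
    cur_fut = cumulative_current(surf_fut, focal)
    cur_now.write_ascii(outdir / "current_now.asc")
    cur_fut.write_ascii(outdir / "current_future.asc")
    res_now.to_csv(outdir / "resistance_now.csv")
    res_fut.to_csv(outdir / "resistance_future.csv")
    geo = euclidean_matrix(pops)
    range_flags = connectivity_change(
        cur_now, cur_fut, pops,
        buffer_radius=int(cfg["connect"]["buffer_radius"]),
        tau=float(cfg["connect"]["tau"]),
        resistance_now=res_now, resistance_future=res_fut)
    range_flags.to_csv(outdir / "range_shift.csv", index=False)
    results["connect"] = {"resistance_now": res_now, "resistance_future": res_fut,
                          "range_flags": range_flags, "geo": geo}

    # ---- MRDM --------------------------------------------------------
    n_perm = int(cfg["mrdm"]["n_permutations"])
    landscape_preds = {"suitability_resistance": res_now}
    step = stepwise_residual(fst_neutral, geo, landscape_preds,
                             n_permutations=n_perm, seed=seed)
    results["mrdm"] = step
    mrdm_rows = [{
        "model": "geography", "r2": step.stage1.r2, "f": step.stage1.f_stat,
        "p": step.stage1.p_overall,
    }]
    for subset, fit in step.stage2_fits.items():
        mrdm_rows.append({"model": "+".join(subset), "r2": fit.r2,
                          "f": fit.f_stat, "p": fit.p_overall})
    pd.DataFrame(mrdm_rows).to_csv(outdir / "mrdm.csv", index=False)

    ibe = None
    if not candidates.empty:
        cand_idx = np.flatnonzero(
            np.isin(np.asarray(gm.locus_ids), candidates["locus"]))
        try:
            fst_adaptive = fst_matrix(gm, stat_pops, cand_idx, "fst_adaptive")
            env_d = {
                "temperature": env_dissimilarity_matrix(pops, "tmax_now"),
                "rainfall": env_dissimilarity_matrix(pops, "rain_now"),
            }
            ibe = ibe_test(fst_adaptive, env_d, n_permutations=n_perm, seed=seed)
        except ValueError:
            ibe = None
    results["ibe"] = ibe

    # ---- risk assessment --------------------------------------------
    exp_rows, sens_rows = [], []
    het_lut = dict(zip(het_pop["pop"], het_pop["heterozygosity"]))
    for rec in pops.itertuples():
        er = ExposureRecord(
            pop=rec.pop, tmax_now=rec.tmax_now, tmax_future=rec.tmax_future,
            rain_now=rec.rain_now, rain_future=rec.rain_future,
            suit_now=100.0 * rec.suitability_now,
            suit_future=100.0 * rec.suitability_future,
            suitable_now=bool(rec.suitable_now),
            suitable_future=bool(rec.suitable_future))
        ea = exposure_level(er)
        exp_rows.append({"pop": rec.pop, "exposure": ea.level,
                         "rule_path": ea.rule_path,
                         "rule_mismatch": ea.rule_mismatch})
        summary = adaptive_summary[adaptive_summary["pop"] == rec.pop]
        if len(summary) and summary["n_candidates"].iloc[0] > 0:
            a_code = adaptive_sensitivity(
                float(summary["mean_adaptive_freq"].iloc[0]),
                float(summary["fraction_below_025"].iloc[0]))
        else:
            a_code = "-"  # no candidate loci: no adaptive-sensitivity signal
        het = float(np.clip(het_lut.get(rec.pop, np.nan), 0.0, 1.0))
        n_code = neutral_sensitivity(het)
        sens_rows.append({"pop": rec.pop, "adaptive_code": a_code,
                          "neutral_code": n_code})
    exposures = pd.DataFrame(exp_rows)
    sens = pd.DataFrame(sens_rows)
    risk = assess(exposures[["pop", "exposure"]], sens,
                  range_flags[["pop", "range_shift"]])
    risk.to_csv(outdir / "risk.csv", index=False)
    results["risk"] = risk

    # ---- manifest ----------------------------------------------------
    files = sorted(p for p in outdir.rglob("*") if p.is_file()
                   and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": _jsonable(cfg),
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, FutureDelta):
        return {"tmax_add": _jsonable(obj.tmax_add), "rain_mult": obj.rain_mult}
    return obj
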