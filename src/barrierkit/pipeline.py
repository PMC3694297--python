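"""End-to-end pipeline: generate or load each assay table, analyse, summarise.

Stages run in the study's order — TEER → QC gate → permeability → uptake →
ALP → qPCR → screen — skipping any assay with no input.  Each stage writes
its table under the configured output directory; a human-readable summary
and a machine-readable JSON land next to them.  All randomness derives from
the single root seed (per-assay seeds are fixed offsets), so a re-run with
the same config reproduces every output bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io as bio
from . import qpcr as bq
from . import screen as bscreen
from . import synthetic, teer, uptake
from .permeability import process_clearance_table
from .synthetic import SimulationConfig

_SEED_OFFSETS = {"teer": 0, "permeability": 1, "uptake": 2, "alp": 3, "qpcr": 4, "screen": 5}


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")


def run_pipeline(config: bio.PipelineConfig) -> dict[str, Any]:
    """Run every configured stage; returns (and writes) the summary bundle."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geom = config.geometry.build()
    bench = config.benchmark.build()
    summary: dict[str, Any] = {"skipped": [], "warnings": []}
    lines: list[str] = ["Blood-brain-barrier assay pipeline summary", ""]

    def seed_for(stage: str) -> int:
        return (config.seed + _SEED_OFFSETS[stage]) % (2**31)

    # --- TEER + QC gate ----------------------------------------------------
    teer_mean = None
    sec = config.teer
    if sec and (sec.path or sec.simulate):
        if sec.path:
            table = bio.read_teer_csv(sec.path)
        else:
            g = sec.simulate
            table = synthetic.simulate_teer_batch(
                g.n_inserts, g.mean_teer_ohm_cm2, g.sd_teer_ohm_cm2, g.blank_ohm,
                geom, seed=seed_for("teer"))
        res = teer.process_teer_table(table, bench)
        bio.write_table(res, out_dir / "teer_results.csv")
        teer_mean = float(res["teer_ohm_cm2"].mean())
        summary["teer"] = {
            "n": int(len(res)),
            "mean_teer_ohm_cm2": teer_mean,
            "sem_teer_ohm_cm2": _sem(res["teer_ohm_cm2"].to_numpy()),
            "qc_pass_n": int(res["qc_teer_pass"].sum()),
            "degenerate_n": int(res["degenerate"].sum()),
        }
        s = summary["teer"]
        lines.append(
            f"TEER: n={s['n']}, mean±SEM = {s['mean_teer_ohm_cm2']:.1f}"
            f"±{s['sem_teer_ohm_cm2']:.1f} Ω·cm², QC(> {bench.min_teer_ohm_cm2:g}) "
            f"pass {s['qc_pass_n']}/{s['n']}")
        if s["degenerate_n"]:
            summary["warnings"].append(f"{s['degenerate_n']} degenerate (negative) TEER records")
    else:
        summary["skipped"].append("teer")
        lines.append("TEER: not run")

    # --- permeability ------------------------------------------------------
    sec = config.permeability
    if sec and (sec.path or sec.simulate):
        if teer_mean is not None and teer_mean <= bench.min_teer_ohm_cm2:
            summary["warnings"].append(
                "batch mean TEER at or below the QC floor; permeability results "
                "computed but the batch fails the pre-assay gate")
        if sec.path:
            table = bio.read_clearance_csv(sec.path)
        else:
            g = sec.simulate
            table = synthetic.simulate_transwell(
                SimulationConfig(g.true_papp_cm_s, g.insert_cv, g.n_inserts,
                                 seed_for("permeability"), g.noise_model),
                geom, donor_sampling=g.donor_sampling,
                count_window_min=g.count_window_min)
        res = process_clearance_table(table, geom, through_origin=sec.through_origin)
        res["qc_papp_pass"] = res["papp_cm_s"] < bench.max_sucrose_papp_cm_s
        bio.write_table(res, out_dir / "papp_results.csv")
        summary["permeability"] = {
            "n": int(len(res)),
            "mean_papp_cm_s": float(res["papp_cm_s"].mean()),
            "sem_papp_cm_s": _sem(res["papp_cm_s"].to_numpy()),
            "qc_pass_n": int(res["qc_papp_pass"].sum()),
            "mean_r_squared": float(res["r_squared"].mean()),
        }
        s = summary["permeability"]
        lines.append(
            f"Papp: n={s['n']}, mean±SEM = {s['mean_papp_cm_s']:.3g}"
            f"±{s['sem_papp_cm_s']:.2g} cm/s, QC(< {bench.max_sucrose_papp_cm_s:g}) "
            f"pass {s['qc_pass_n']}/{s['n']}")
    else:
        summary["skipped"].append("permeability")
        lines.append("Papp: not run")

    # --- uptake / efflux ---------------------------------------------------
    sec = config.uptake
    if sec and (sec.path or sec.simulate):
        if sec.path:
            table = bio.read_uptake_csv(sec.path)
        else:
            g = sec.simulate
            table = synthetic.simulate_uptake_plate(
                g.n_control, g.n_test, g.vd_control_ul_mg, g.factor,
                g.nonspecific_vd_ul_mg, g.protein_mg, noise_sd=g.noise_sd,
                seed=seed_for("uptake"))
        res, factor = uptake.process_uptake_table(
            table, sec.substrate_background_dpm, sec.marker_background_dpm)
        bio.write_table(res, out_dir / "uptake_results.csv")
        summary["uptake"] = {
            "factor_increase": factor.factor,
            "mean_vd_control_ul_mg": factor.mean_control,
            "mean_vd_inhibitor_ul_mg": factor.mean_test,
            "n_control": factor.n_control,
            "n_inhibitor": factor.n_test,
            "negative_corrected_n": int(res["negative_corrected_vd"].sum()),
        }
        lines.append(
            f"P-gp: corrected Vd {factor.mean_control:.2f} (control) vs "
            f"{factor.mean_test:.2f} (verapamil) μl/mg → factor increase "
            f"{factor.factor:.3f}")
        if summary["uptake"]["negative_corrected_n"]:
            summary["warnings"].append("negative corrected Vd wells present")
    else:
        summary["skipped"].append("uptake")
        lines.append("P-gp uptake: not run")

    # --- ALP ---------------------------------------------------------------
    sec = config.alp
    if sec and (sec.path or sec.simulate):
        if sec.path:
            table = bio.read_alp_csv(sec.path)
        else:
            g = sec.simulate
            table = synthetic.simulate_alp_plate(
                g.group_activities_au_mg, g.n_wells, g.protein_mg,
                g.absorbance_sd, seed=seed_for("alp"))
        res = uptake.process_alp_table(table)
        bio.write_table(res, out_dir / "alp_results.csv")
        group_means = res.groupby("group")["activity_au_per_mg"].mean().to_dict()
        summary["alp"] = {"group_mean_au_per_mg": {k: float(v) for k, v in group_means.items()}}
        lines.append("ALP activity (AU/mg): " + ", ".join(
            f"{k}={v:.2f}" for k, v in group_means.items()))
    else:
        summary["skipped"].append("alp")
        lines.append("ALP: not run")

    # --- qPCR --------------------------------------------------------------
    sec = config.qpcr
    if sec and (sec.path or sec.simulate):
        if sec.path:
            plate = bio.read_qpcr_csv(sec.path)
            reference_gene = sec.reference_gene
        else:
            g = sec.simulate
            reference_gene = g.reference_gene
            quantities = {g.reference_gene: {}}
            for i in range(g.n_samples_per_group):
                quantities[g.reference_gene][f"{sec.calibrator_prefix}_{i}"] = 1.0
                quantities[g.reference_gene][f"{sec.test_prefix}_{i}"] = 1.0
            for gene, fold in g.gene_folds.items():
                quantities[gene] = {}
                for i in range(g.n_samples_per_group):
                    quantities[gene][f"{sec.calibrator_prefix}_{i}"] = 1.0
                    quantities[gene][f"{sec.test_prefix}_{i}"] = fold
            plate = synthetic.simulate_qpcr_plate(
                quantities, g.curve_slope, g.curve_intercept, g.n_standards,
                g.replicate_sd, seed=seed_for("qpcr"))
        bq.validate_controls(plate)
        quant = bq.quantify_plate(plate, reference_gene)
        bio.write_table(quant, out_dir / "qpcr_quantities.csv")
        folds = []
        for gene in sorted(set(quant["gene"]) - {reference_gene}):
            sub = quant[quant["gene"] == gene]
            is_test = sub["sample_id"].str.startswith(sec.test_prefix)
            is_cal = sub["sample_id"].str.startswith(sec.calibrator_prefix)
            if not is_test.any() or not is_cal.any():
                summary["warnings"].append(
                    f"qPCR gene {gene}: cannot split test/calibrator groups by prefix")
                continue
            fd = bq.normalized_fold_difference(
                sub.loc[is_test, "nt"], sub.loc[is_cal, "nt"], gene=gene)
            folds.append({"gene": gene, "fold": fd.fold, "significant": fd.significant})
        fold_df = pd.DataFrame(folds)
        if len(fold_df):
            bio.write_table(fold_df, out_dir / "qpcr_folds.csv")
        summary["qpcr"] = {"folds": folds}
        lines.append("qPCR fold differences (test/calibrator, 2-fold rule): " + ", ".join(
            f"{f['gene']}={f['fold']:.2f}{'*' if f['significant'] else ''}" for f in folds))
    else:
        summary["skipped"].append("qpcr")
        lines.append("qPCR: not run")

    # --- Log P screen ------------------------------------------------------
    sec = config.screen
    if sec and (sec.path or sec.simulate):
        if sec.path:
            table = bio.read_screen_csv(sec.path)
        else:
            g = sec.simulate
            table = synthetic.simulate_screen_table(
                g.slope_cm_s_per_logp, g.intercept_cm_s, g.ref_noise_sd_cm_s,
                g.offset_margins, k=sec.k, min_margin_frac=sec.min_margin_frac,
                seed=seed_for("screen"))
        line = bscreen.fit_passive_line(table, log_scale=sec.log_scale)
        res = bscreen.classify_transport(table, line, k=sec.k,
                                         min_margin_frac=sec.min_margin_frac)
        bio.write_table(res, out_dir / "screen_results.csv")
        summary["screen"] = {
            "slope": line.slope, "intercept": line.intercept,
            "r_squared": line.r_squared, "residual_scale": line.residual_scale,
            "classes": dict(zip(res["name"], res["transport_class"])),
        }
        lines.append(
            f"Screen: passive line R²={line.r_squared:.3f}; " + ", ".join(
                f"{n}:{c}" for n, c in summary["screen"]["classes"].items()))
    else:
        summary["skipped"].append("screen")
        lines.append("Screen: not run")

    if summary["warnings"]:
        lines.append("")
        lines.extend(f"WARNING: {w}" for w in summary["warnings"])

    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
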