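"""End-to-end reproduction pipeline on synthetic data.

``run_reproduce`` chains the stages — droplet contact angles per dish
type, multinucleation timecourse, nuclei-per-cell histogram, and the
mono-vs-multi morphometric comparison — entirely on generated images
with known ground truth, then writes CSV reports plus a machine-
readable summary comparing every recovered quantity with its configured
truth.  All randomness derives from the single config seed through
fixed per-stage offsets, so any stage can be rerun in isolation and two
runs with one seed produce byte-identical CSVs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import morphometry as mm
from . import nuclei as nu
from . import stats_report as sr
from . import synthetic as syn
from .config import PipelineConfig
from .contact_angle import aggregate_by_group, measure_droplet

logger = logging.getLogger("multinuc")

# fixed per-stage seed offsets (stage reruns are reproducible in isolation)
_SEED_DROPLETS = 101
_SEED_TIMECOURSE = 202
_SEED_MORPHO = 303


def _stage_seed(seed: int, offset: int) -> int:
    return int(np.random.SeedSequence((seed, offset)).generate_state(1)[0] % (2**31))


def run_droplet_stage(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Generate, measure and compare droplets per dish group.

    Returns (per-droplet table, per-group summary, Tukey comparisons).
    The per-group means come from noise-free droplets at the configured
    mean angle; the Tukey test uses a second, angle-jittered set whose
    per-droplet angles are drawn from N(mean, jitter SD).
    """
    dc = config.droplets
    rng = np.random.default_rng(_stage_seed(config.seed, _SEED_DROPLETS))
    rows = []
    obs_exact, labels = [], []
    jitter_samples: dict[str, list[float]] = {}
    for group in sorted(dc.angles_deg):
        mean_angle = dc.angles_deg[group]
        jitter_samples[group] = []
        for i in range(dc.n_per_group):
            spec = syn.DropletSpec(contact_angle_deg=mean_angle,
                                   base_radius_px=dc.base_radius_px)
            img, truth = syn.generate_droplet_image(spec)
            o = measure_droplet(img, baseline_row=truth.baseline_row,
                                   source_id=f"{group}-{i}")
            obs_exact.append(o)
            labels.append(group)
            rows.append({"group": group, "droplet": i, "true_theta_deg": mean_angle,
                         "h_px": o.h, "r_px": o.fit.r, "base_radius_px": o.base_radius,
                         "A": o.fit.A, "B": o.fit.B, "C": o.fit.C,
                         "theta_deg": o.theta_deg})
            # jittered replicate for the between-dish significance test
            th = float(np.clip(rng.normal(mean_angle, dc.jitter_sd_deg[group]),
                               5.0, 175.0))
            jimg, jtruth = syn.generate_droplet_image(
                syn.DropletSpec(contact_angle_deg=th, base_radius_px=dc.base_radius_px))
            jo = measure_droplet(jimg, baseline_row=jtruth.baseline_row)
            jitter_samples[group].append(jo.theta_deg)
    summary = aggregate_by_group(obs_exact, labels)
    comparisons = sr.tukey_all_pairs(jitter_samples)
    logger.info("droplet stage: %d groups, %d droplets each",
                len(dc.angles_deg), dc.n_per_group)
    return pd.DataFrame(rows), summary, comparisons


def run_timecourse_stage(config: PipelineConfig
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate condition × timepoint fields and measure R_multi on each.

    Returns (measured R_multi table, truth table, nuclei histogram of
    the final treatment field).
    """
    tc = config.timecourse
    seg = config.segmentation
    conditions = [syn.Condition(label=k, trajectory=v)
                  for k, v in sorted(tc.trajectories.items())]
    base = syn.CellFieldSpec(n_cells=tc.n_cells, pixel_size_um=config.pixel_size_um)
    fields = syn.generate_timecourse(conditions, base,
                                     seed=_stage_seed(config.seed, _SEED_TIMECOURSE))
    truth_table = syn.timecourse_truth_table(fields)
    rows = []
    hist = None
    last_key = max(fields, key=lambda k: (k[0] == conditions[0].label, k[1]))
    for (label, t), (img, cell_mask, nmask, truth) in sorted(fields.items()):
        # primary route: exact counting on the ground-truth nucleus mask
        recs = nu.records_from_label_mask(nmask, config.pixel_size_um)
        assignment = nu.assign_nuclei_to_cells(recs, cell_mask)
        summ = nu.count_multinucleated(assignment, condition=label, timepoint_h=t)
        # diagnostic route: full segmentation of the rendered fluorescence
        # channel (the debris filter may drop the smallest nuclei)
        seg_recs, _ = nu.segment_nuclei(img, threshold=seg.threshold,
                                        min_area_um2=seg.min_nucleus_area_um2,
                                        pixel_size_um=config.pixel_size_um,
                                        blur_sigma=seg.blur_sigma,
                                        exclude_border=seg.exclude_border)
        seg_summ = nu.count_multinucleated(
            nu.assign_nuclei_to_cells(seg_recs, cell_mask),
            condition=label, timepoint_h=t)
        rows.append({"condition": label, "timepoint_h": t, "n_all": summ.n_all,
                     "n_multi": summ.n_multi, "r_multi": summ.r_multi,
                     "r_multi_segmented": seg_summ.r_multi,
                     "true_r_multi": truth.r_multi})
        if (label, t) == last_key:
            hist = nu.nuclei_count_histogram(assignment)
    logger.info("timecourse stage: %d fields measured", len(fields))
    return pd.DataFrame(rows), truth_table, hist


def run_morphometry_stage(config: PipelineConfig
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list]:
    """Mono vs multi morphometric comparison on two generated fields.

    Returns (cells table, nuclei table, tidy group-summary table,
    comparison list).
    """
    mc = config.morphometry
    seed = _stage_seed(config.seed, _SEED_MORPHO)
    specs = {
        "mono": syn.CellFieldSpec(
            n_cells=mc.n_cells_per_group, frac_multinucleated=0.0,
            cell_area_um2=mc.mono_cell_area_um2,
            nucleus_eccentricity_range=mc.mono_nucleus_ecc,
            mono_ratio_pct=mc.mono_ratio_pct,
            pixel_size_um=config.pixel_size_um, seed=seed),
        "multi": syn.CellFieldSpec(
            n_cells=mc.n_cells_per_group, frac_multinucleated=1.0,
            cell_area_um2=mc.multi_cell_area_um2,
            nucleus_eccentricity_range=mc.multi_nucleus_ecc,
            per_nucleus_ratio_pct=mc.per_nucleus_ratio_pct,
            summed_ratio_pct=mc.summed_ratio_pct,
            ratio_mode=mc.ratio_mode,
            pixel_size_um=config.pixel_size_um, seed=seed + 1),
    }
    cells_parts, nuc_parts = [], []
    for name, spec in specs.items():
        _img, cell_mask, nucleus_mask, _truth = syn.generate_cell_field(spec)
        recs = nu.records_from_label_mask(nucleus_mask, config.pixel_size_um)
        assignment = nu.assign_nuclei_to_cells(recs, cell_mask)
        cells_df, nuclei_df = mm.compute_cell_metrics(
            cell_mask, nucleus_mask, assignment,
            pixel_size_um=config.pixel_size_um,
            convention=config.circularity_convention)
        cells_df.insert(0, "field", name)
        nuclei_df.insert(0, "field", name)
        cells_parts.append(cells_df)
        nuc_parts.append(nuclei_df)
    cells = pd.concat(cells_parts, ignore_index=True)
    nucs = pd.concat(nuc_parts, ignore_index=True)

    comparisons = []
    tidy_rows = []
    metric_tables = [
        ("S_nucleus_um2", nucs), ("alpha_nucleus", nucs), ("ratio_pct", nucs),
        ("S_cell_um2", cells), ("alpha_cell", cells), ("summed_ratio_pct", cells),
    ]
    for metric, table in metric_tables:
        res = mm.group_compare(table, metric)
        comparisons.append(sr.ComparisonResult(
            group_a=f"mono:{metric}", group_b=f"multi:{metric}",
            statistic=res.mean_a - res.mean_b, p=res.p, significant=res.significant))
        for g, mean, sd, n in [("mono", res.mean_a, res.sd_a, res.n_a),
                               ("multi", res.mean_b, res.sd_b, res.n_b)]:
            tidy_rows.append({"metric": metric, "group": g, "n": n,
                              "mean": mean, "sd": sd, "p": res.p,
                              "significant": res.significant})
    logger.info("morphometry stage: %d cells, %d nuclei", len(cells), len(nucs))
    return cells, nucs, pd.DataFrame(tidy_rows), comparisons


def _recovery_checks(config: PipelineConfig, droplet_summary: pd.DataFrame,
                     rmulti: pd.DataFrame, morpho_groups: pd.DataFrame) -> list[dict]:
    checks = []
    for _, row in droplet_summary.iterrows():
        true = config.droplets.angles_deg[row["group"]]
        checks.append({
            "name": f"contact_angle_mean_{row['group']}",
            "configured": true, "recovered": row["mean_theta_deg"],
            "tolerance": 1.0,
            "pass": bool(abs(row["mean_theta_deg"] - true) <= 1.0),
        })
    for _, row in rmulti.iterrows():
        checks.append({
            "name": f"r_multi_{row['condition']}_{row['timepoint_h']}h",
            "configured": row["true_r_multi"], "recovered": row["r_multi"],
            "tolerance": 0.0,
            "pass": bool(row["r_multi"] == row["true_r_multi"]),
        })
    mc = config.morphometry
    ratio_targets = {("ratio_pct", "mono"): mc.mono_ratio_pct,
                     ("ratio_pct", "multi"): mc.per_nucleus_ratio_pct}
    for (metric, group), (mean, sd) in ratio_targets.items():
        sub = morpho_groups[(morpho_groups["metric"] == metric)
                            & (morpho_groups["group"] == group)]
        rec = float(sub["mean"].iloc[0])
        n = int(sub["n"].iloc[0])
        tol = 2.0 * sd / np.sqrt(n)
        checks.append({"name": f"wilson_ratio_{group}", "configured": mean,
                       "recovered": rec, "tolerance": tol,
                       "pass": bool(abs(rec - mean) <= tol)})
    return checks


def run_reproduce(config: PipelineConfig | None = None,
                  out_dir: Path | str = "reproduce_out") -> dict:
    """Run every stage on synthetic data and write reports to ``out_dir``.

    Writes per-stage CSVs, plots, and ``acceptance_summary.json`` whose
    ``all_pass`` flag states whether every recovered quantity matched
    its configured truth within tolerance.  Returns the summary dict.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    try:
        logger.info("config: %s", config.model_dump())
        droplets, droplet_summary, droplet_comp = run_droplet_stage(config)
        rmulti, rmulti_truth, hist = run_timecourse_stage(config)
        cells, nucs, morpho_groups, morpho_comp = run_morphometry_stage(config)

        tables = {
            "droplets": droplets,
            "droplet_summary": droplet_summary,
            "r_multi_timecourse": rmulti,
            "r_multi_truth": rmulti_truth,
            "nuclei_histogram": hist,
            "morphometry_cells": cells,
            "morphometry_nuclei": nucs,
            "morphometry_groups": morpho_groups,
        }
        sr.build_report(out_dir, tables, list(droplet_comp) + list(morpho_comp))

        checks = _recovery_checks(config, droplet_summary, rmulti, morpho_groups)
        summary = {
            "seed": config.seed,
            "checks": checks,
            "all_pass": bool(all(c["pass"] for c in checks)),
            "tukey_all_pairs_significant":
                bool(all(c.significant for c in droplet_comp)),
        }
        with open(out_dir / "acceptance_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        logger.info("reproduce finished: all_pass=%s", summary["all_pass"])
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
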