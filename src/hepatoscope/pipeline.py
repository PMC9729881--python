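"""End-to-end pipeline: simulate -> spatial stats -> lobules -> classify -> group stats.

Every stage writes its tables under the configured output directory; the
run log records per-stage counts, the seed and a hash of the configuration
so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import groupstats, lobules, nuclei, patterns, synthetic
from .io import RunConfig, write_nuclei_csv, write_points_csv

log = logging.getLogger("hepatoscope")

__all__ = ["run_pipeline"]


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.model_dump_json().encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on synthetic tissue; returns the report dict.

    Stage failures propagate with the stage name prepended so a broken run
    names its culprit.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "config_hash": _config_hash(config)}
    rng = np.random.default_rng(config.seed)

    # --- simulate vascular sections ---------------------------------------
    stage = "simulate"
    try:
        all_patterns: list[patterns.MarkedPointPattern] = []
        for gspec in config.groups:
            for s in range(gspec.n_sections):
                cfg = synthetic.SyntheticTissueConfig(
                    lattice_radius_r0=gspec.lattice_radius_r0,
                    jitter_sd=gspec.jitter_sd,
                    portal_occupancy=gspec.portal_occupancy,
                    occupancy_fraction=gspec.occupancy_fraction,
                    window_width=gspec.window_width,
                    window_height=gspec.window_height,
                    seed=int(rng.integers(2**31)),
                )
                pat = synthetic.generate_lobular_lattice(cfg)
                pat.section_id = f"{gspec.group}_{s}"
                pat.group = gspec.group
                all_patterns.append(pat)
        write_points_csv(all_patterns, out / "points.csv")
        report[stage] = {
            "n_sections": len(all_patterns),
            "n_points": int(sum(len(p) for p in all_patterns)),
        }
        log.info("simulate: %d sections", len(all_patterns))
    except Exception as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- spatial statistics -------------------------------------------------
    stage = "spatial"
    try:
        w0 = all_patterns[0].window
        r_grid = patterns.default_r_grid(w0, config.spatial.n_r)
        summaries = [
            patterns.ripley_L(
                p, None, r_grid, correction=config.spatial.correction
            )
            for p in all_patterns
        ]
        pd.DataFrame(
            {
                "r_um": r_grid,
                **{
                    p.section_id: s.values
                    for p, s in zip(all_patterns, summaries)
                },
            }
        ).to_csv(out / "ripley_L.csv", index=False)
        grouped = patterns.GroupedPatterns(
            patterns=all_patterns,
            groups=[p.group for p in all_patterns],
            summaries=summaries,
        )
        perm = patterns.grouped_studentized_permutation_test(
            grouped,
            n_permutations=config.spatial.n_permutations,
            seed=int(rng.integers(2**31)),
        )
        report[stage] = {
            "statistic_T": perm.statistic_T,
            "p_value": perm.p_value,
            "n_permutations": perm.n_permutations,
        }
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- lobule metrics -----------------------------------------------------
    stage = "lobule"
    try:
        rows = []
        for p in all_patterns:
            prof = lobules.step_profile(p, config.lobule.k_max)
            step = lobules.detect_step(prof)
            est = lobules.lobule_estimates(
                p, exclude_boundary=config.lobule.exclude_boundary
            )
            rows.append(
                {
                    "section_id": p.section_id,
                    "group": p.group,
                    "portal_density_per_mm2": lobules.portal_density(p),
                    "mean_lobule_area_um2": est.section_mean_area,
                    "k_star": step.k_star,
                }
            )
        lob_df = pd.DataFrame(rows)
        lob_df.to_csv(out / "lobule_summary.csv", index=False)
        report[stage] = {
            "k_star_mode": int(lob_df.k_star.mode()[0]),
            "mean_lobule_area_um2": float(lob_df.mean_lobule_area_um2.mean()),
        }
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- nuclear classification ----------------------------------------------
    stage = "classify"
    try:
        ncfg = synthetic.NucleusPopulationConfig(
            n_hepatocyte=config.classify.n_hepatocyte,
            n_binuclear=config.classify.n_binuclear,
            n_other=config.classify.n_other,
            touching_distance=config.classify.touching_distance,
            seed=int(rng.integers(2**31)),
        )
        records = synthetic.generate_nuclei(ncfg)
        tcfg = nuclei.TreeConfig(
            max_depth=config.classify.max_depth,
            min_samples_per_leaf=config.classify.min_samples_per_leaf,
            cv_folds=config.classify.cv_folds,
            train_fraction=config.classify.train_fraction,
            seed=int(rng.integers(2**31)),
        )
        train, test = nuclei.stratified_split(records, tcfg)
        model = nuclei.train_tree(train, tcfg)
        test_pred = model.predict(test)
        em = nuclei.error_matrix(
            [nuclei.binary_label(r.true_class) for r in test],
            [r.predicted_class for r in test_pred],
        )
        all_pred = model.predict(records)
        reclassified, audit = nuclei.reclassify_binuclear(
            all_pred,
            nuclei.BinuclearRules(touching_distance=config.classify.touching_distance),
        )
        write_nuclei_csv(reclassified, out / "nuclei.csv")
        area_mm2 = ncfg.window_width * ncfg.window_height / 1e6
        dens = nuclei.class_density(reclassified, area_mm2)
        report[stage] = {
            "n_nuclei": len(records),
            "cv_accuracy": model.cv_mean,
            "test_error_matrix": em.rounded(),
            "binuclear_audit": audit,
            "class_density_per_mm2": dens,
        }
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- group statistics -----------------------------------------------------
    stage = "stats"
    try:
        samples = {
            g: sub.portal_density_per_mm2.tolist()
            for g, sub in lob_df.groupby("group")
        }
        anova = groupstats.one_way_anova(samples)
        tukey = groupstats.tukey_hsd(samples)
        areas = {
            g: sub.mean_lobule_area_um2.tolist() for g, sub in lob_df.groupby("group")
        }
        kw = groupstats.kruskal_wallis(areas)
        report[stage] = {
            "portal_density_anova": {
                "F": anova.statistic,
                "df": anova.df,
                "p": anova.p_value,
            },
            "portal_density_tukey_min_p": tukey.p_value,
            "lobule_area_kruskal": {"H": kw.statistic, "p": kw.p_value},
        }
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
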