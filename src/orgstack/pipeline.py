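"""End-to-end driver: simulate wells, image them, quantify, report.

One :func:`run_pipeline` call emulates a complete plate experiment: per
well it plants a scene, images it at d0 (stained, untreated), applies the
group's treatment, stains and images again at dN, and quantifies both
composites on the live (green) channel.  Survival rates, size-change
ratios, chemosensitivity calls and treated-vs-control statistics are
written as CSV/Markdown, together with the resolved configuration and a
log, so a run is reproducible from its output directory alone.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .acquisition import plan_zstack
from .analytics import (DEFAULT_CUTOFF, TimepointPair, classify_chemosensitivity,
                        compare_groups, size_change_ratio, survival_rate)
from .edf import fuse_stack
from .errors import InvalidParameterError
from .quantify import (DEFAULT_MIN_AREA, segment_objects, summarize_well)
from .scene import (OpticalModel, StainingModel, TreatmentEffect, apply_staining,
                    apply_treatment, generate_scene, render_stack)
from .stacks import write_stack

__all__ = ["DEFAULT_CONFIG", "resolve_config", "run_pipeline"]

logger = logging.getLogger("orgstack")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "scene": {
        "n_objects": 50,
        "diameter": [30.0, 80.0],
        "gel_depth": 1100.0,
        "xy_extent": [512.0, 512.0],
        "xy_margin": 45.0,
    },
    "plan": {"z_range": 1100.0, "n_layers": 7, "round_to": 10.0},
    "optics": {
        "pixel_size": 1.0,
        "blur_coeff": 0.05,
        "dof_half_depth": 80.0,
        "noise_sd": 0.01,
        "background_base": 0.05,
    },
    "staining": {
        "concentration": 2.0,
        "time": 60.0,
        "saturation_constant": 120.0,
        "cu_concentration": 0.1,
        "background_rate": 0.003,
        "quench_reference": 0.1,
    },
    "groups": {
        "control": {
            "n_wells": 3,
            "treatment": {"kill_fraction": 0.0, "shrink_factor": 1.0,
                          "dead_shell_width": 0.0},
        },
        "treated": {
            "n_wells": 3,
            "treatment": {"kill_fraction": 0.6, "shrink_factor": 0.7,
                          "dead_shell_width": 10.0},
        },
    },
    "day": 10,
    "thresholds": {
        "min_area": DEFAULT_MIN_AREA,
        "green_threshold": None,  # None -> background_base + 3 * noise_sd
        "cutoff": DEFAULT_CUTOFF,
    },
    "save_stacks": False,
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def resolve_config(config: dict | None = None) -> dict:
    """Merge a partial config over the defaults.

    Nested blocks merge key-by-key, except ``groups``, which replaces the
    default plate layout wholesale (half-merged group tables would silently
    resurrect default treatment arms).
    """
    config = config or {}
    resolved = _deep_merge(DEFAULT_CONFIG, config)
    if "groups" in config:
        resolved["groups"] = config["groups"]
    return resolved


def _quantify_composite(composite, thresholds, optics):
    green_thr = thresholds["green_threshold"]
    if green_thr is None:
        green_thr = optics.background_base + 3 * optics.noise_sd
    _, records = segment_objects(
        composite, channel="green", min_area=thresholds["min_area"],
        green_threshold=green_thr)
    return summarize_well(records, labeling_threshold=green_thr)


def run_pipeline(config: dict | None = None, outdir="orgstack_run") -> Path:
    """Run the full simulate → fuse → quantify → assay pipeline.

    Returns the output directory, which contains ``well_summary.csv``,
    ``group_comparison.csv``, ``assay_report.md``, ``resolved_config.yaml``
    and ``run.log`` (plus the stacks and composites when ``save_stacks``).
    Deterministic for a fixed ``seed``.
    """
    cfg = resolve_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    try:
        t0 = time.perf_counter()
        plan = plan_zstack(cfg["plan"]["z_range"], cfg["plan"]["n_layers"],
                           round_to=cfg["plan"].get("round_to", 10.0))
        optics = OpticalModel(**cfg["optics"])
        staining = StainingModel(**cfg["staining"])
        scn = cfg["scene"]
        thresholds = cfg["thresholds"]
        logger.info("plan: %d layers, step %.0f um over %.0f um",
                    plan.n_layers, plan.step, plan.z_range)
        logger.info("optics: %s | staining: %s", optics, staining)

        root_rng = np.random.default_rng(cfg["seed"])
        rows = []
        pairs_by_group: dict[str, list[TimepointPair]] = {}
        for group_name, group_cfg in cfg["groups"].items():
            effect = TreatmentEffect(**group_cfg["treatment"])
            pairs_by_group[group_name] = []
            for well in range(group_cfg["n_wells"]):
                seed = int(root_rng.integers(0, 2**31 - 1))
                stage = f"{group_name}/well{well}"
                try:
                    scene = generate_scene(
                        scn["n_objects"], tuple(scn["diameter"])
                        if isinstance(scn["diameter"], (list, tuple))
                        else scn["diameter"],
                        gel_depth=scn["gel_depth"],
                        xy_extent=tuple(scn["xy_extent"]),
                        seed=seed, xy_margin=scn.get("xy_margin", 0.0))
                    d0_scene = apply_staining(scene, staining, seed=seed)
                    d0_stack = render_stack(d0_scene, plan, optics,
                                            staining=staining, seed=seed)
                    d0_comp = fuse_stack(d0_stack)
                    d0_summary = _quantify_composite(d0_comp, thresholds, optics)

                    treated = apply_treatment(scene, effect, seed=seed + 1)
                    dn_scene = apply_staining(treated, staining, seed=seed + 2)
                    dn_stack = render_stack(dn_scene, plan, optics,
                                            staining=staining, seed=seed + 2)
                    dn_comp = fuse_stack(dn_stack)
                    dn_summary = _quantify_composite(dn_comp, thresholds, optics)
                except Exception as exc:
                    raise RuntimeError(f"pipeline stage {stage} failed: {exc}") from exc

                pair = TimepointPair(d0=d0_summary, dN=dn_summary, day=cfg["day"])
                pairs_by_group[group_name].append(pair)
                surv = survival_rate(pair)
                ratio = size_change_ratio(pair)
                call = classify_chemosensitivity(ratio, thresholds["cutoff"])
                rows.append({
                    "group": group_name, "well": well, "seed": seed,
                    "d0_count": d0_summary.n_objects,
                    "dN_count": dn_summary.n_objects,
                    "d0_area_um2": d0_summary.total_area,
                    "dN_area_um2": dn_summary.total_area,
                    "survival_pct_of_d0": surv,
                    "size_change_ratio_pct": ratio,
                    "chemo_call": call.call,
                })
                logger.info("%s: d0=%d dN=%d survival=%.1f%% ratio=%.1f%% (%s)",
                            stage, d0_summary.n_objects, dn_summary.n_objects,
                            surv, ratio, call.call)
                if cfg["save_stacks"]:
                    stack_dir = outdir / "stacks"
                    stack_dir.mkdir(exist_ok=True)
                    write_stack(d0_stack, stack_dir / f"{group_name}_w{well}_d0.tif")
                    write_stack(dn_stack, stack_dir / f"{group_name}_w{well}_dN.tif")
                per_obj = pd.DataFrame([{
                    "id": r.id, "x_um": r.centroid[0], "y_um": r.centroid[1],
                    "area_um2": r.area, "short_diameter_um": r.short_diameter,
                    "mean_green": r.mean_green, "mean_red": r.mean_red,
                    "live": r.live} for r in dn_summary.records],
                    columns=["id", "x_um", "y_um", "area_um2",
                             "short_diameter_um", "mean_green", "mean_red",
                             "live"])
                obj_dir = outdir / "objects"
                obj_dir.mkdir(exist_ok=True)
                per_obj.to_csv(obj_dir / f"{group_name}_w{well}_dN.csv", index=False)

        summary = pd.DataFrame(rows)
        summary.to_csv(outdir / "well_summary.csv", index=False)

        treated_groups = {k: v for k, v in pairs_by_group.items() if k != "control"}
        report_lines = ["# Assay report", "",
                        f"Wells per group: " + ", ".join(
                            f"{k}={len(v)}" for k, v in pairs_by_group.items()), ""]
        if "control" in pairs_by_group and treated_groups:
            comparison = compare_groups(pairs_by_group["control"], treated_groups,
                                        metric="survival_rate")
            comparison.to_csv(outdir / "group_comparison.csv")
            report_lines += ["## Survival rate (% of d0) vs control", "",
                             comparison.to_string(), ""]
        report_lines += ["## Per-well summary", "", summary.to_string(index=False)]
        (outdir / "assay_report.md").write_text("\n".join(report_lines) + "\n")

        (outdir / "resolved_config.yaml").write_text(
            yaml.safe_dump(cfg, sort_keys=False))
        logger.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outdir
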