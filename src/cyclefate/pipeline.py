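"""One-command end-to-end run: simulate -> phases -> fate -> lineage -> report.

Produces all stage CSVs, a summary JSON (phase-duration table, per-group fate
fractions, mother-daughter correlations, sibling statistics, binned
proliferation-vs-time table) and a reproducibility manifest.  The whole run
is deterministic given (config, seed).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import io as cfio
from .config import SimConfig
from .fate import FateParams, cdk2_activity, classify_fate, cohort_fate_fractions
from .lineage import (
    LineageParams,
    concordance_table,
    mother_daughter_correlation,
    mother_daughter_window_means,
    pooled_sibling_discrepancy,
    proliferation_vs_time,
    sibling_pairs_from_cohort,
)
from .phases import call_phases, phase_duration_summary
from .simulate import Cohort, simulate_cohort


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits) if np.isfinite(obj) else None
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def annotate_cohort(cohort: Cohort, smooth_window: int = 5):
    """Phase-call every track, passing recorded division times (lineage rows
    are authoritative for mothers; the simulator's own division record covers
    daughters whose second division is not in the lineage table)."""
    cfg = cohort.config
    div_by_cell = {}
    for t in cohort.tracks:
        d = t.truth.get("division_time", np.nan)
        if d is not None and np.isfinite(d):
            div_by_cell[t.cell_id] = float(d)
    for parent, grp in cohort.lineage.groupby("parent_id"):
        div_by_cell[parent] = float(grp["division_time_h"].iloc[0])
    return [
        call_phases(
            t,
            division_time=div_by_cell.get(t.cell_id),
            observation_end=cfg.horizon,
            smooth_window=smooth_window,
        )
        for t in cohort.tracks
    ]


def classify_cohort(cohort: Cohort, fate_params: FateParams | None = None):
    """Fate-call every daughter; returns (calls, mother-stage grouping)."""
    fate_params = fate_params or FateParams()
    calls, stage_of = [], {}
    for t in cohort.daughters:
        ratio = cdk2_activity(t.channels["cdk2_nuc"], t.channels["cdk2_cyt"])
        calls.append(
            classify_fate(ratio, t.times, t.channels["Cdt1"], fate_params,
                          cell_id=t.cell_id)
        )
        stage_of[t.cell_id] = str(t.truth.get("stage_at_treatment", "all"))
    return calls, stage_of


def analyze_cohort(cohort: Cohort, fate_params: FateParams | None = None,
                   lineage_params: LineageParams | None = None):
    """Run every analysis stage on an in-memory cohort.

    Returns ``(summary, artifacts)`` where artifacts holds the per-stage
    objects (annotations, calls, pair records, tables).
    """
    cfg = cohort.config
    fate_params = fate_params or FateParams()
    lineage_params = lineage_params or LineageParams()

    annotations = annotate_cohort(cohort)
    durations = phase_duration_summary(annotations)

    calls, stage_of = classify_cohort(cohort, fate_params)
    fate_by_cell = {c.cell_id: c.binary for c in calls}
    fractions_all = cohort_fate_fractions(calls)
    fractions_by_stage = (
        cohort_fate_fractions(calls, stage_of) if stage_of else fractions_all
    )

    # --- lineage statistics ---------------------------------------------
    wm = mother_daughter_window_means(cohort, lineage_params)
    correlations = {}
    for group, sub in wm.groupby("group"):
        try:
            correlations[str(group)] = mother_daughter_correlation(
                sub["pre_mean"], sub["post_mean"]
            )
        except ValueError as e:
            correlations[str(group)] = {"r": None, "p": None, "n": len(sub),
                                        "flag": str(e)}

    pairs = sibling_pairs_from_cohort(cohort, fate_by_cell, lineage_params)
    conc = concordance_table(pairs)
    sibling_stats = {}
    for group in sorted({p.group for p in pairs}):
        gp = [p for p in pairs if p.group == group and p.concordance == "concordant"]
        if len(gp) >= 2:
            d, r2 = pooled_sibling_discrepancy(gp)
            sibling_stats[group] = {"n_pairs": len(gp), "D": d, "R2": r2}

    div_of = dict(zip(cohort.lineage["cell_id"], cohort.lineage["division_time_h"]))
    ttm, prolif = [], []
    for c in calls:
        if c.binary == "indeterminate" or c.cell_id not in div_of:
            continue
        ttm.append(div_of[c.cell_id])
        prolif.append(c.binary == "proliferative")
    if len(ttm) >= 2:
        prolif_table, prolif_corr = proliferation_vs_time(
            ttm, prolif, lineage_params.bin_width
        )
    else:
        prolif_table, prolif_corr = None, {"r": None, "flag": "too few daughters"}

    summary = {
        "condition": cfg.condition,
        "n_mothers": cfg.n_mothers,
        "seed": cfg.rng_seed,
        "phase_durations": durations.to_dict(orient="records"),
        "fate_fractions": {
            "all": fractions_all.to_dict(orient="records"),
            "by_mother_stage": fractions_by_stage.to_dict(orient="records"),
        },
        "mother_daughter_p21_correlation": correlations,
        "sibling_concordance": conc.to_dict(orient="records"),
        "sibling_p21_resemblance": sibling_stats,
        "proliferation_vs_time_r": prolif_corr,
    }
    artifacts = {
        "annotations": annotations,
        "calls": calls,
        "pairs": pairs,
        "window_means": wm,
        "prolif_table": prolif_table,
    }
    return summary, artifacts


def run_pipeline(config: SimConfig, out_dir, render: bool = False):
    """Simulate a cohort and run every analysis stage, writing a bundle of
    CSVs, a summary JSON and a manifest into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        cohort = simulate_cohort(config)
    except Exception as e:  # invalid config surfaces before any stage output
        raise StageError("simulate", e) from e

    cfio.write_cohort(cohort, out)

    try:
        summary, artifacts = analyze_cohort(cohort)
    except Exception as e:
        raise StageError("analyze", e) from e

    cfio.write_annotations_csv(
        artifacts["annotations"], out / "phases.csv", out / "phase_boundaries.csv"
    )
    cfio.write_fates_csv(artifacts["calls"], out / "fates.csv")
    if artifacts["prolif_table"] is not None:
        artifacts["prolif_table"].to_csv(
            out / "proliferation_vs_time.csv", index=False, float_format="%.4f",
            lineterminator="\n",
        )

    if render:
        from .render import FieldRenderer, RenderParams

        renderer = FieldRenderer(cohort.tracks, RenderParams(rng_seed=config.rng_seed))
        times = np.arange(0.0, min(config.horizon, 4.0), config.sampling_interval)
        stacks, truth = renderer.render_movie(times)
        cfio.write_stack_tiff(stacks, out / "field.tiff", out / "field_channels.json")
        truth.to_csv(out / "field_truth.csv", index=False, float_format="%.4f",
                     lineterminator="\n")

    with open(out / "summary.json", "w") as fh:
        json.dump(_round_floats(summary), fh, indent=1, sort_keys=True)

    files = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    cfio.write_manifest(out / "manifest.json", config, config.rng_seed, files)
    return summary
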