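"""End-to-end orchestration: recordings -> per-cell metrics table.

Runs the full chain for every unit of every session — speed filtering,
rate maps, place-field metrics, within-session and between-session
stability — and flattens everything into the long-format metrics table
the statistics layer consumes. Exclusions (non-place cells, failed QC)
are logged, never silently dropped.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd

from .io_interface import SessionRecording, logger, new_metrics_table
from .placefield_metrics import cell_session_metrics
from .preprocessing import (behavior_summary, compute_speed, filter_inactive,
                            restrict_spikes)
from .ratemap import compute_occupancy, compute_ratemap, smooth_ratemap
from .stability import (between_session_stability_batch,
                        within_session_stability_batch)


def analyze_session(rec: SessionRecording, quarters: bool = False
                    ) -> list[dict]:
    """Metric rows for one session (per-unit metrics + behavior)."""
    speed = compute_speed(rec.trace)
    intervals = filter_inactive(rec.trace, speed)
    beh = behavior_summary(rec.trace, intervals, rec.arena, speed)
    base = dict(animal_id=rec.animal_id, genotype=rec.genotype,
                experiment_index=rec.experiment_index,
                session_index=rec.session_index,
                cue_condition=rec.cue_condition)
    rows = [
        dict(base, unit_id="__session__", metric_name="median_speed",
             value=beh.median_speed),
        dict(base, unit_id="__session__", metric_name="thigmotaxis",
             value=beh.thigmotaxis),
    ]
    occ = compute_occupancy(rec.trace, intervals, rec.arena)
    halves = within_session_stability_batch(rec, kind="halves")
    if quarters:
        quarter_scores = within_session_stability_batch(rec, kind="quarters")
    for unit in rec.units:
        active = restrict_spikes(unit, intervals)
        raw = compute_ratemap(active, rec.trace, occ)
        smooth = smooth_ratemap(raw)
        m = cell_session_metrics(occ, raw, smooth)
        per_unit = {
            "n_fields": float(m.n_fields),
            "field_area_bins": (float(np.mean(m.field_areas_bins))
                                if m.field_areas_bins else np.nan),
            "field_area_cm2": (float(np.mean(m.field_areas_cm2))
                               if m.field_areas_cm2 else np.nan),
            "active_bins_normalized": float(m.active_bins_normalized),
            "spatial_info": m.spatial_info,
            "specificity_ratio": m.specificity_ratio,
            "mean_rate": m.mean_rate,
            "max_rate": m.max_rate,
        }
        rows.extend(dict(base, unit_id=unit.unit_id, metric_name=k, value=v)
                    for k, v in per_unit.items())
        for score in halves[unit.unit_id]:
            rows.append(dict(base, unit_id=unit.unit_id,
                             metric_name="stability_halves", value=score.r))
        if quarters:
            finite = [s.r for s in quarter_scores[unit.unit_id]
                      if np.isfinite(s.r)]
            rows.append(dict(
                base, unit_id=unit.unit_id, metric_name="stability_quarters",
                value=float(np.mean(finite)) if finite else np.nan))
    return rows


def analyze_recordings(recordings: list[SessionRecording],
                       quarters: bool = False,
                       between_sessions: bool = True,
                       place_cells_only: bool = True) -> pd.DataFrame:
    """Full cohort analysis -> long-format metrics table.

    With ``place_cells_only``, units without a place field in any session
    of their animal are dropped (with a log line), mirroring the usual
    inclusion rule.
    """
    rows: list[dict] = []
    for rec in recordings:
        rows.extend(analyze_session(rec, quarters=quarters))
    table = new_metrics_table(rows)

    if between_sessions:
        between_rows = []
        by_day = defaultdict(list)
        for rec in recordings:
            by_day[(rec.animal_id, rec.experiment_index, rec.day)].append(rec)
        for (animal, exp, day), recs in sorted(by_day.items()):
            if len(recs) != 2:
                continue
            r1, r2 = sorted(recs, key=lambda r: r.session_index)
            scores = between_session_stability_batch(r1, r2)
            pair_kind = ("full-full" if r2.cue_condition == "full"
                         else "full-probe")
            for uid, score in sorted(scores.items()):
                between_rows.append(dict(
                    animal_id=animal, genotype=r1.genotype,
                    experiment_index=exp, session_index=r2.session_index,
                    cue_condition=pair_kind, unit_id=uid,
                    metric_name="stability_between", value=score.r))
        table = pd.concat([table, new_metrics_table(between_rows)],
                          ignore_index=True)

    if place_cells_only:
        table = filter_place_cells(table)
    return table


def filter_place_cells(table: pd.DataFrame) -> pd.DataFrame:
    """Keep session rows and units with >= 1 field in >= 1 session."""
    nf = table[table["metric_name"] == "n_fields"]
    keep_units = set(
        nf.loc[nf["value"] >= 1, ["animal_id", "unit_id"]]
        .itertuples(index=False, name=None))
    all_units = set(nf[["animal_id", "unit_id"]]
                    .itertuples(index=False, name=None))
    for animal, unit in sorted(all_units - keep_units):
        logger.info("excluding %s/%s: no place field in any session",
                    animal, unit)
    key = list(zip(table["animal_id"], table["unit_id"]))
    mask = [(u == "__session__") or ((a, u) in keep_units) for a, u in key]
    return table[np.asarray(mask)].reset_index(drop=True)
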