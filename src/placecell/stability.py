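"""Stability of spatial representations via masked pixel correlations.

Within-session stability compares the rate maps built from the halves (or
quarters) of a session; between-session stability compares two full
sessions of the same day, distinguishing Full-cue from Probe pairs. All
scores are Pearson correlations over the bins that are valid in both maps,
with per-segment occupancy masks re-derived from scratch — a bin visited
in one half may be undersampled in the other.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io_interface import PositionTrace, SessionRecording, SpikeTrain
from .preprocessing import compute_speed, filter_inactive, restrict_spikes
from .ratemap import BIN_SIZE_CM, SMOOTH_RADIUS_BINS, RateMap

MIN_SHARED_BINS = 20


@dataclass(frozen=True)
class StabilityScore:
    r: float                # Pearson correlation, NaN if undefined
    kind: str               # halves | quarters | between_session
    pair_label: str         # e.g. "S1H1-S1H2", "S3-S4"
    n_shared_bins: int

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.r)


def split_session(rec: SessionRecording, n_parts: int) -> list[SessionRecording]:
    """Contiguous, equal-duration temporal segments of one recording.

    Segments are half-open in time, the last closed at the session end, so
    spikes and samples are partitioned losslessly.
    """
    if n_parts not in (2, 4):
        raise ValueError("n_parts must be 2 or 4")
    if len(rec.trace) < 2:
        raise ValueError("cannot split an empty session")
    t0, t1 = float(rec.trace.t[0]), float(rec.trace.t[-1])
    if t1 <= t0:
        raise ValueError("session duration must be positive")
    edges = t0 + (t1 - t0) * np.arange(n_parts + 1) / n_parts
    # snap interior edges to trace sample times so every segment's spikes
    # fall inside its own position span
    for k in range(1, n_parts):
        i = int(np.argmin(np.abs(rec.trace.t - edges[k])))
        edges[k] = rec.trace.t[i]
    parts = []
    for k in range(n_parts):
        a, b = edges[k], edges[k + 1]
        last = k == n_parts - 1
        # traces share the boundary sample (it owns no time span in the
        # earlier segment, so occupancy is not double-counted)
        tmask = (rec.trace.t >= a) & (rec.trace.t <= b)
        trace = PositionTrace(rec.trace.t[tmask], rec.trace.x[tmask],
                              rec.trace.y[tmask])
        units = []
        for u in rec.units:
            smask = (u.t >= a) & ((u.t <= b) if last else (u.t < b))
            units.append(SpikeTrain(u.unit_id, u.t[smask]))
        parts.append(replace(rec, trace=trace, units=tuple(units)))
    return parts


def ratemap_correlation(a: RateMap, b: RateMap,
                        min_shared: int = MIN_SHARED_BINS,
                        kind: str = "pair", pair_label: str = "") -> StabilityScore:
    """Pearson r over bins valid in both maps.

    Missing (NaN) when fewer than ``min_shared`` bins are shared or either
    map is constant on the shared set (zero variance leaves r undefined).
    """
    if not a.same_geometry(b):
        raise ValueError("rate maps have different grid geometry")
    shared = a.valid & b.valid
    n = int(shared.sum())
    if n < min_shared:
        return StabilityScore(float("nan"), kind, pair_label, n)
    va, vb = a.rate[shared], b.rate[shared]
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        return StabilityScore(float("nan"), kind, pair_label, n)
    r = float(np.corrcoef(va, vb)[0, 1])
    return StabilityScore(r, kind, pair_label, n)


def session_unit_maps(rec: SessionRecording, unit_ids=None,
                      bin_size: float = BIN_SIZE_CM,
                      radius_bins: float = SMOOTH_RADIUS_BINS
                      ) -> dict[str, RateMap]:
    """Smoothed maps for several units, sharing one occupancy computation.

    Runs the full pipeline (speed filter onward) once for the segment and
    reuses intervals and occupancy across units.
    """
    from .ratemap import compute_occupancy, compute_ratemap, smooth_ratemap
    if unit_ids is None:
        unit_ids = [u.unit_id for u in rec.units]
    speed = compute_speed(rec.trace)
    intervals = filter_inactive(rec.trace, speed)
    occ = compute_occupancy(rec.trace, intervals, rec.arena, bin_size)
    out = {}
    for uid in unit_ids:
        spikes = restrict_spikes(rec.unit(uid), intervals)
        raw = compute_ratemap(spikes, rec.trace, occ)
        out[uid] = smooth_ratemap(raw, radius_bins)
    return out


def within_session_stability_batch(rec: SessionRecording, unit_ids=None,
                                   kind: str = "halves",
                                   all_quarter_pairs: bool = False,
                                   min_shared: int = MIN_SHARED_BINS,
                                   bin_size: float = BIN_SIZE_CM,
                                   radius_bins: float = SMOOTH_RADIUS_BINS
                                   ) -> dict[str, list[StabilityScore]]:
    """Within-session stability for many units with shared segment maps."""
    if kind not in ("halves", "quarters"):
        raise ValueError("kind must be 'halves' or 'quarters'")
    if unit_ids is None:
        unit_ids = [u.unit_id for u in rec.units]
    n_parts = 2 if kind == "halves" else 4
    parts = split_session(rec, n_parts)
    maps = [session_unit_maps(p, unit_ids, bin_size, radius_bins)
            for p in parts]
    s = rec.session_index
    if kind == "halves":
        pairs = [(0, 1)]
        tag = "H"
    else:
        pairs = ([(i, j) for i in range(4) for j in range(i + 1, 4)]
                 if all_quarter_pairs else [(0, 1), (1, 2), (2, 3)])
        tag = "Q"
    return {
        uid: [ratemap_correlation(maps[i][uid], maps[j][uid], min_shared,
                                  kind, f"S{s}{tag}{i + 1}-S{s}{tag}{j + 1}")
              for i, j in pairs]
        for uid in unit_ids
    }


def within_session_stability(rec: SessionRecording, unit_id: str,
                             kind: str = "halves",
                             all_quarter_pairs: bool = False,
                             min_shared: int = MIN_SHARED_BINS,
                             bin_size: float = BIN_SIZE_CM,
                             radius_bins: float = SMOOTH_RADIUS_BINS
                             ) -> list[StabilityScore]:
    """Split-half (or split-quarter) stability of one unit's rate map.

    Halves give one score (H1 vs H2); quarters give the adjacent pairs
    Q1-Q2, Q2-Q3, Q3-Q4 (all six pairs with ``all_quarter_pairs``).
    Each sub-map is built with the full pipeline, with the occupancy mask
    re-derived per segment.
    """
    return within_session_stability_batch(
        rec, [unit_id], kind, all_quarter_pairs, min_shared, bin_size,
        radius_bins)[unit_id]


def between_session_stability_batch(rec1: SessionRecording,
                                    rec2: SessionRecording, unit_ids=None,
                                    min_shared: int = MIN_SHARED_BINS,
                                    bin_size: float = BIN_SIZE_CM,
                                    radius_bins: float = SMOOTH_RADIUS_BINS
                                    ) -> dict[str, StabilityScore]:
    """Between-session stability for the units shared by two sessions."""
    if rec1.animal_id != rec2.animal_id or rec1.day != rec2.day:
        raise ValueError("between-session stability needs the same animal "
                         "and day")
    if unit_ids is None:
        unit_ids = sorted({u.unit_id for u in rec1.units}
                          & {u.unit_id for u in rec2.units})
    label = (f"S{rec1.session_index}-S{rec2.session_index}"
             f"({rec1.cue_condition}-{rec2.cue_condition})")
    maps1 = session_unit_maps(rec1, unit_ids, bin_size, radius_bins)
    maps2 = session_unit_maps(rec2, unit_ids, bin_size, radius_bins)
    return {
        uid: ratemap_correlation(maps1[uid], maps2[uid], min_shared,
                                 "between_session", label)
        for uid in unit_ids
    }


def between_session_stability(rec1: SessionRecording, rec2: SessionRecording,
                              unit_id: str,
                              min_shared: int = MIN_SHARED_BINS,
                              bin_size: float = BIN_SIZE_CM,
                              radius_bins: float = SMOOTH_RADIUS_BINS
                              ) -> StabilityScore:
    """Correlation of one unit's smoothed maps across two sessions of a day.

    The pair label records the cue conditions (full-full vs full-probe) so
    the statistics layer can contrast cue-intact and cue-removed days.
    Missing (NaN) when the unit is absent from either session.
    """
    if rec1.animal_id != rec2.animal_id or rec1.day != rec2.day:
        raise ValueError("between-session stability needs the same animal "
                         "and day")
    label = (f"S{rec1.session_index}-S{rec2.session_index}"
             f"({rec1.cue_condition}-{rec2.cue_condition})")
    try:
        rec1.unit(unit_id), rec2.unit(unit_id)
    except KeyError:
        return StabilityScore(float("nan"), "between_session", label, 0)
    return between_session_stability_batch(
        rec1, rec2, [unit_id], min_shared, bin_size, radius_bins)[unit_id]
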