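"""Speed filtering, cluster-drift QC, pyramidal classification, behavior.

The analysis excludes periods of inactivity (speed < 3 cm/s), drops units
whose spike-sorting cluster drifted along the first principal component by
more than three standard deviations over the day, and keeps only putative
pyramidal cells (low firing rate, bursty autocorrelogram). Behavioral
summaries — median running speed and thigmotaxis (mean distance from the
arena center) — are the paper-level controls that exploration itself does
not differ between groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .io_interface import (ArenaGeometry, PositionTrace, SpikeTrain,
                           UnitFeatureSeries, logger)

SPEED_THRESHOLD_CMS = 3.0
SPEED_SMOOTH_WINDOW_S = 0.4


@dataclass(frozen=True)
class SpeedSeries:
    """Instantaneous running speed (cm/s) aligned to a position trace."""

    t: np.ndarray
    speed: np.ndarray

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class ActiveIntervals:
    """Disjoint, sorted half-open [start, end) intervals of active movement."""

    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self):
        object.__setattr__(self, "intervals", tuple(
            (float(a), float(b)) for a, b in self.intervals))
        for (a, b) in self.intervals:
            if b < a:
                raise ValueError("interval end before start")
        starts = [a for a, _ in self.intervals]
        if starts != sorted(starts):
            raise ValueError("intervals must be sorted")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def total_duration(self) -> float:
        return float(sum(b - a for a, b in self.intervals))

    def contains(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask: which times fall in any [start, end) interval."""
        times = np.asarray(times, dtype=float)
        if not self.intervals:
            return np.zeros(len(times), dtype=bool)
        flat = np.array(self.intervals).ravel()
        # disjoint sorted intervals: inside iff an odd number of edges passed
        return np.searchsorted(flat, times, side="right") % 2 == 1

    def clip(self, start: float, end: float) -> "ActiveIntervals":
        """Intersect with [start, end)."""
        out = []
        for a, b in self.intervals:
            lo, hi = max(a, start), min(b, end)
            if hi > lo:
                out.append((lo, hi))
        return ActiveIntervals(tuple(out))


@dataclass(frozen=True)
class BehaviorSummary:
    median_speed: float    # cm/s over active samples
    thigmotaxis: float     # mean distance from arena center (cm), active samples
    active_duration: float  # s


def compute_speed(trace: PositionTrace,
                  smooth_window: float = SPEED_SMOOTH_WINDOW_S) -> SpeedSeries:
    """Speed by central finite differences, optionally boxcar-smoothed.

    Endpoints use one-sided differences. ``smooth_window`` (s) is converted
    to an odd number of samples; 0 disables smoothing. Smoothing suppresses
    tracker jitter that would otherwise toggle the 3 cm/s activity cut.
    """
    if len(trace) < 2:
        raise ValueError("speed needs at least 2 samples")
    t, x, y = trace.t, trace.x, trace.y
    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    speed = np.hypot(vx, vy)
    if smooth_window and smooth_window > 0:
        dt = trace.sample_period()
        n = max(1, int(round(smooth_window / dt)))
        if n % 2 == 0:
            n += 1
        if n > 1:
            kernel = np.ones(n) / n
            # edge-padded boxcar keeps the series length and endpoint scale
            padded = np.pad(speed, n // 2, mode="edge")
            speed = np.convolve(padded, kernel, mode="valid")
    return SpeedSeries(t=t, speed=speed)


def filter_inactive(trace: PositionTrace, speed: SpeedSeries,
                    threshold: float = SPEED_THRESHOLD_CMS) -> ActiveIntervals:
    """Intervals where speed >= threshold (strictly slower samples excluded).

    Each sample owns the half-open span up to the next sample, so total
    active + inactive time equals the session duration exactly (the final
    sample owns no span).
    """
    if len(speed) != len(trace):
        raise ValueError("speed series not aligned to trace")
    t = trace.t
    active = speed.speed >= threshold
    out: list[tuple[float, float]] = []
    start = None
    for i in range(len(t) - 1):
        if active[i] and start is None:
            start = t[i]
        elif not active[i] and start is not None:
            out.append((start, t[i]))
            start = None
    if start is not None:
        out.append((start, t[-1]))
    return ActiveIntervals(tuple(out))


def restrict_spikes(spikes: SpikeTrain, intervals: ActiveIntervals) -> SpikeTrain:
    """Keep spikes that fall inside any active interval (order preserved)."""
    if len(spikes) == 0 or len(intervals) == 0:
        return SpikeTrain(spikes.unit_id, np.empty(0))
    return SpikeTrain(spikes.unit_id, spikes.t[intervals.contains(spikes.t)])


def qc_cluster_drift(features: UnitFeatureSeries,
                     session_labels: Sequence | None = None,
                     sd_threshold: float = 3.0) -> Literal["retain", "exclude"]:
    """Cluster-stability QC on the first-PC amplitude of a unit's spikes.

    Drift is the difference between the mean feature amplitude in the last
    and first deciles of the day's spikes, in units of the pooled
    within-decile standard deviation; units drifting by more than
    ``sd_threshold`` are excluded. With fewer than two sessions' worth of
    data the check is skipped (retained with a warning): drift is defined
    across both sessions of a day.

    Invariant to affine rescaling of the feature axis.
    """
    if len(features) < 2:
        raise ValueError("drift QC needs at least 2 spikes")
    if session_labels is not None and len(set(session_labels)) < 2:
        logger.warning("qc_cluster_drift: single-session data, QC skipped")
        return "retain"
    f = features.feature
    n = len(f)
    k = max(1, n // 10)
    first, last = f[:k], f[-k:]
    if k >= 2:
        pooled_var = (np.var(first, ddof=1) + np.var(last, ddof=1)) / 2.0
        pooled_sd = float(np.sqrt(pooled_var))
    else:
        pooled_sd = 0.0
    diff = abs(float(np.mean(last)) - float(np.mean(first)))
    if pooled_sd == 0.0:
        drift = 0.0 if diff == 0.0 else np.inf
    else:
        drift = diff / pooled_sd
    return "exclude" if drift > sd_threshold else "retain"


def spike_autocorrelogram_mean_lag(spike_times: np.ndarray,
                                   window_ms: float = 50.0) -> float:
    """Mean positive lag (ms) of spike pairs within ``window_ms``.

    A bursty pyramidal cell piles mass at short lags relative to its firing
    rate; a Poisson train is flat over the window (mean lag ~ window/2).
    Returns NaN when no pair falls in the window.
    """
    t = np.asarray(spike_times, dtype=float)
    window = window_ms / 1000.0
    total = 0.0
    count = 0
    hi = np.searchsorted(t, t + window, side="right")
    for i in range(len(t)):
        lags = t[i + 1:hi[i]] - t[i]
        total += lags.sum()
        count += len(lags)
    if count == 0:
        return float("nan")
    return 1000.0 * total / count


def classify_pyramidal(spikes: SpikeTrain, session_duration: float,
                       rate_ceiling: float = 8.0,
                       acg_window_ms: float = 50.0,
                       acg_mean_min_ms: float = 8.0,
                       min_spikes: int = 50) -> Literal["pyramidal", "other"]:
    """Putative pyramidal vs other, by firing rate and autocorrelogram mean.

    Pyramidal iff mean rate <= ``rate_ceiling`` Hz and the mean lag of the
    autocorrelogram within ``acg_window_ms`` is at least ``acg_mean_min_ms``
    (slow-firing but not dominated by ultra-short intervals, i.e. not a
    fast-spiking interneuron). These are surrogate thresholds; all are
    configurable. Units with fewer than ``min_spikes`` spikes are "other".
    """
    if session_duration <= 0:
        raise ValueError("session duration must be positive")
    if len(spikes) < min_spikes:
        logger.info("classify_pyramidal: unit %s has %d < %d spikes",
                    spikes.unit_id, len(spikes), min_spikes)
        return "other"
    mean_rate = len(spikes) / session_duration
    if mean_rate > rate_ceiling:
        return "other"
    mean_lag = spike_autocorrelogram_mean_lag(spikes.t, acg_window_ms)
    if not np.isfinite(mean_lag) or mean_lag < acg_mean_min_ms:
        return "other"
    return "pyramidal"


def behavior_summary(trace: PositionTrace, intervals: ActiveIntervals,
                     arena: ArenaGeometry,
                     speed: SpeedSeries | None = None) -> BehaviorSummary:
    """Median active speed and thigmotaxis over active samples."""
    if speed is None:
        speed = compute_speed(trace)
    mask = intervals.contains(trace.t)
    if not mask.any():
        return BehaviorSummary(float("nan"), float("nan"), 0.0)
    r = arena.distance_from_center(trace.x[mask], trace.y[mask])
    return BehaviorSummary(
        median_speed=float(np.median(speed.speed[mask])),
        thigmotaxis=float(np.mean(r)),
        active_duration=intervals.total_duration,
    )
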