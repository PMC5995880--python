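"""Occupancy maps and occupancy-normalized, smoothed firing-rate maps.

The firing map of a unit is built in three steps: spikes are binned on the
arena occupancy grid (2 x 2 cm pixels), normalized by the time spent in
each bin, and smoothed with a flat disk kernel of radius 2 bins. Bins
sampled for less than 200 ms, and bins wholly outside the circular arena,
are masked invalid and carry NaN — never zero — so that they drop out of
every downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .io_interface import ArenaGeometry, PositionTrace, SpikeTrain
from .preprocessing import ActiveIntervals

BIN_SIZE_CM = 2.0
MIN_OCCUPANCY_S = 0.2
SMOOTH_RADIUS_BINS = 2


@dataclass(frozen=True)
class OccupancyMap:
    """Seconds of active occupancy per spatial bin, with validity mask."""

    occupancy: np.ndarray       # (ny, nx) seconds
    x_edges: np.ndarray         # (nx+1,) cm
    y_edges: np.ndarray         # (ny+1,) cm
    valid: np.ndarray           # (ny, nx) bool
    bin_size: float

    @property
    def total_time(self) -> float:
        return float(self.occupancy.sum())


@dataclass(frozen=True)
class RateMap:
    """Firing rate (Hz) per bin; NaN on invalid bins."""

    rate: np.ndarray            # (ny, nx) Hz, NaN where invalid
    valid: np.ndarray           # (ny, nx) bool
    x_edges: np.ndarray
    y_edges: np.ndarray
    smoothed: bool
    mean_rate: float            # spike count / active duration (Hz)

    @property
    def max_rate(self) -> float:
        vals = self.rate[self.valid]
        return float(np.nanmax(vals)) if vals.size else float("nan")

    def same_geometry(self, other: "RateMap") -> bool:
        return (self.rate.shape == other.rate.shape
                and np.allclose(self.x_edges, other.x_edges)
                and np.allclose(self.y_edges, other.y_edges))


def _grid_edges(arena: ArenaGeometry, bin_size: float):
    """Bin edges covering the arena; grid spans the bounding square."""
    n = int(np.ceil(2 * arena.radius / bin_size))
    x0 = arena.center_x - n * bin_size / 2.0
    y0 = arena.center_y - n * bin_size / 2.0
    x_edges = x0 + bin_size * np.arange(n + 1)
    y_edges = y0 + bin_size * np.arange(n + 1)
    return x_edges, y_edges


def _inside_arena_mask(arena: ArenaGeometry, x_edges, y_edges) -> np.ndarray:
    """Bins whose nearest point to the center is within the wall.

    A bin wholly outside the circle can never be visited; it is invalid
    regardless of (numerically zero) occupancy.
    """
    xl, xr = x_edges[:-1], x_edges[1:]
    yl, yr = y_edges[:-1], y_edges[1:]
    # distance from the center to the closest point of each bin rectangle
    dx = np.maximum(np.maximum(xl - arena.center_x, arena.center_x - xr), 0.0)
    dy = np.maximum(np.maximum(yl - arena.center_y, arena.center_y - yr), 0.0)
    return np.hypot(dx[None, :], dy[:, None]) <= arena.radius


def compute_occupancy(trace: PositionTrace, intervals: ActiveIntervals,
                      arena: ArenaGeometry,
                      bin_size: float = BIN_SIZE_CM,
                      min_occupancy: float = MIN_OCCUPANCY_S) -> OccupancyMap:
    """Bin active time on the 2-D grid.

    Each active sample contributes its own sample span (time to the next
    sample, clipped to its interval) to the bin containing it, so total
    occupancy equals total active duration up to one sample period.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be > 0, got {bin_size}")
    x_edges, y_edges = _grid_edges(arena, bin_size)
    occ = np.zeros((len(y_edges) - 1, len(x_edges) - 1))
    t = trace.t
    if len(t) >= 2:
        w = np.zeros(len(t))
        for a, b in intervals.intervals:
            i0, i1 = np.searchsorted(t, [a, b], side="left")
            i1 = min(i1, len(t) - 1)  # sample i owns [t_i, t_{i+1})
            if i1 <= i0:
                continue
            idx = np.arange(i0, i1)
            w[idx] += np.minimum(t[idx + 1], b) - t[idx]
        used = w > 0
        occ, _, _ = np.histogram2d(trace.y[used], trace.x[used],
                                   bins=(y_edges, x_edges), weights=w[used])
    inside = _inside_arena_mask(arena, x_edges, y_edges)
    valid = inside & (occ >= min_occupancy)
    return OccupancyMap(occ, x_edges, y_edges, valid, bin_size)


def _spike_positions(spikes: SpikeTrain, trace: PositionTrace):
    """Position at each spike time, linearly interpolated along the trace."""
    if len(spikes) == 0:
        return np.empty(0), np.empty(0)
    if len(trace) == 0 or spikes.t[0] < trace.t[0] or spikes.t[-1] > trace.t[-1]:
        raise ValueError("spike outside trace time span; filter spikes first")
    x = np.interp(spikes.t, trace.t, trace.x)
    y = np.interp(spikes.t, trace.t, trace.y)
    return x, y


def compute_ratemap(spikes: SpikeTrain, trace: PositionTrace,
                    occupancy: OccupancyMap) -> RateMap:
    """Occupancy-normalized firing rate map (unsmoothed)."""
    sx, sy = _spike_positions(spikes, trace)
    counts, _, _ = np.histogram2d(sy, sx,
                                  bins=(occupancy.y_edges, occupancy.x_edges))
    rate = np.full_like(occupancy.occupancy, np.nan)
    v = occupancy.valid
    with np.errstate(divide="ignore", invalid="ignore"):
        rate[v] = counts[v] / occupancy.occupancy[v]
    total = occupancy.total_time
    mean_rate = len(spikes) / total if total > 0 else float("nan")
    return RateMap(rate, v.copy(), occupancy.x_edges, occupancy.y_edges,
                   smoothed=False, mean_rate=mean_rate)


def disk_kernel(radius_bins: float) -> np.ndarray:
    """Flat kernel over bins at Euclidean offset <= radius (13 bins at r=2)."""
    r = int(np.floor(radius_bins))
    ii, jj = np.mgrid[-r:r + 1, -r:r + 1]
    return (np.hypot(ii, jj) <= radius_bins).astype(float)


def smooth_ratemap(rmap: RateMap, radius_bins: float = SMOOTH_RADIUS_BINS,
                   kernel: str = "disk") -> RateMap:
    """Mask-aware smoothing: each valid bin becomes the mean of valid bins
    within ``radius_bins`` (disk kernel); invalid bins stay invalid.

    Renormalizing by the local count of valid bins keeps edge bins unbiased
    rather than smearing them toward zero. A Gaussian option (sigma =
    radius/2 bins) is provided; the disk mean is the default.
    """
    if radius_bins < 0:
        raise ValueError("smoothing radius must be >= 0")
    if rmap.smoothed:
        raise ValueError("map is already smoothed")
    if radius_bins == 0:
        return replace(rmap, smoothed=True)
    v = rmap.valid.astype(float)
    filled = np.where(rmap.valid, rmap.rate, 0.0)
    if kernel == "disk":
        k = disk_kernel(radius_bins)
        num = ndimage.convolve(filled, k, mode="constant", cval=0.0)
        den = ndimage.convolve(v, k, mode="constant", cval=0.0)
    elif kernel == "gaussian":
        sigma = radius_bins / 2.0
        num = ndimage.gaussian_filter(filled, sigma, mode="constant", cval=0.0)
        den = ndimage.gaussian_filter(v, sigma, mode="constant", cval=0.0)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    rate = np.full_like(rmap.rate, np.nan)
    good = rmap.valid & (den > 0)
    rate[good] = num[good] / den[good]
    return RateMap(rate, rmap.valid.copy(), rmap.x_edges, rmap.y_edges,
                   smoothed=True, mean_rate=rmap.mean_rate)


def ratemap_pipeline(spikes: SpikeTrain, trace: PositionTrace,
                     intervals: ActiveIntervals, arena: ArenaGeometry,
                     bin_size: float = BIN_SIZE_CM,
                     radius_bins: float = SMOOTH_RADIUS_BINS):
    """Occupancy + unsmoothed + smoothed maps for one unit segment."""
    from .preprocessing import restrict_spikes
    occ = compute_occupancy(trace, intervals, arena, bin_size)
    active_spikes = restrict_spikes(spikes, intervals)
    raw = compute_ratemap(active_spikes, trace, occ)
    smooth = smooth_ratemap(raw, radius_bins)
    return occ, raw, smooth
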