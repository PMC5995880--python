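"""Place-field detection and per-cell spatial metrics.

A place field is a connected region of more than 10 adjacent pixels
(2 x 2 cm bins) in which the cell fires above 30% of its maximum rate.
Per cell and session we report the number and size of fields, Skaggs
spatial information per spike, and the spatial-specificity ratio
(in-field over out-field firing rate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .ratemap import OccupancyMap, RateMap

FIELD_THRESHOLD_FRAC = 0.3
FIELD_MIN_BINS = 11           # "larger than 10 adjacent pixels" -> >= 11

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]),
    8: np.ones((3, 3), dtype=int),
}


@dataclass(frozen=True)
class PlaceField:
    """One connected suprathreshold region of a smoothed rate map."""

    member_bins: frozenset          # {(row, col)}
    area_bins: int
    area_cm2: float
    peak_rate: float                # Hz
    peak_bin: tuple[int, int]
    centroid: tuple[float, float]   # cm, rate-weighted


@dataclass(frozen=True)
class CellSessionMetrics:
    """Everything the group statistics consume for one cell in one session."""

    n_fields: int
    field_areas_bins: tuple[int, ...]
    field_areas_cm2: tuple[float, ...]
    active_bins_normalized: int     # contiguity-free count on unsmoothed map
    spatial_info: float             # bits/spike (NaN if undefined)
    specificity_ratio: float        # dimensionless (NaN if undefined)
    mean_rate: float                # Hz
    max_rate: float                 # Hz, smoothed map


def detect_fields(rmap: RateMap, threshold_frac: float = FIELD_THRESHOLD_FRAC,
                  min_bins: int = FIELD_MIN_BINS,
                  adjacency: int = 4) -> list[PlaceField]:
    """Connected components of valid bins firing above the peak fraction.

    Components must be strictly larger than 10 bins (``min_bins`` = 11) to
    count as fields. Adjacency is 4-connected by default (the conservative
    reading of "adjacent"); 8-connected available. Fields are returned
    sorted by peak rate, descending. A silent map yields no fields.
    """
    if adjacency not in _STRUCTURES:
        raise ValueError("adjacency must be 4 or 8")
    maxr = rmap.max_rate
    if not np.isfinite(maxr) or maxr <= 0:
        return []
    supra = rmap.valid & (np.nan_to_num(rmap.rate, nan=-np.inf)
                          > threshold_frac * maxr)
    labels, n = ndimage.label(supra, structure=_STRUCTURES[adjacency])
    bin_area = ((rmap.x_edges[1] - rmap.x_edges[0])
                * (rmap.y_edges[1] - rmap.y_edges[0]))
    xc = 0.5 * (rmap.x_edges[:-1] + rmap.x_edges[1:])
    yc = 0.5 * (rmap.y_edges[:-1] + rmap.y_edges[1:])
    fields = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        if len(rows) < min_bins:
            continue
        rates = rmap.rate[rows, cols]
        k = int(np.argmax(rates))
        w = rates / rates.sum()
        fields.append(PlaceField(
            member_bins=frozenset(zip(rows.tolist(), cols.tolist())),
            area_bins=len(rows),
            area_cm2=len(rows) * float(bin_area),
            peak_rate=float(rates[k]),
            peak_bin=(int(rows[k]), int(cols[k])),
            centroid=(float(np.sum(w * xc[cols])), float(np.sum(w * yc[rows]))),
        ))
    fields.sort(key=lambda f: f.peak_rate, reverse=True)
    return fields


def spatial_information(rmap: RateMap, occ: OccupancyMap) -> float:
    """Skaggs spatial information per spike (bits/spike).

    I = sum_i p_i (lambda_i / lambda_bar) log2(lambda_i / lambda_bar),
    with p_i the occupancy probability of bin i and lambda_bar the
    occupancy-weighted mean rate. Zero-rate bins contribute nothing.
    Undefined (NaN) when the cell never fires or nothing is occupied.
    """
    v = rmap.valid & occ.valid
    occ_t = occ.occupancy[v]
    rates = rmap.rate[v]
    total = occ_t.sum()
    if total <= 0:
        return float("nan")
    p = occ_t / total
    lam_bar = float(np.sum(p * rates))
    if lam_bar <= 0:
        return float("nan")
    pos = rates > 0
    ratio = rates[pos] / lam_bar
    return float(np.sum(p[pos] * ratio * np.log2(ratio)))


def specificity_ratio(rmap: RateMap, fields: list[PlaceField],
                      occ: OccupancyMap) -> float:
    """In-field over out-field occupancy-weighted mean firing rate.

    Both means are time-weighted (occupancy-weighted) so the ratio compares
    the rates a downstream reader would estimate from the raw spike counts.
    NaN when there is no field, no valid out-field bin, or the cell is
    silent outside its fields.
    """
    if not fields:
        return float("nan")
    in_mask = np.zeros_like(rmap.valid)
    for f in fields:
        for (r, c) in f.member_bins:
            in_mask[r, c] = True
    v = rmap.valid & occ.valid
    out_mask = v & ~in_mask
    in_mask &= v
    if not out_mask.any() or not in_mask.any():
        return float("nan")

    def wmean(mask):
        w = occ.occupancy[mask]
        return float(np.sum(w * rmap.rate[mask]) / np.sum(w))

    out_rate = wmean(out_mask)
    if out_rate <= 0:
        return float("nan")
    return wmean(in_mask) / out_rate


def field_size_normalized(rmap_unsmoothed: RateMap,
                          threshold_frac: float = FIELD_THRESHOLD_FRAC) -> int:
    """Active-pixel count on the unsmoothed normalized map.

    Counts every valid bin above the peak fraction with no contiguity
    requirement — a scatter-tolerant companion to the smoothed-map field
    areas.
    """
    maxr = rmap_unsmoothed.max_rate
    if not np.isfinite(maxr) or maxr <= 0:
        return 0
    supra = rmap_unsmoothed.valid & (
        np.nan_to_num(rmap_unsmoothed.rate, nan=-np.inf) > threshold_frac * maxr)
    return int(supra.sum())


def classify_place_cell(metrics_per_session: list[CellSessionMetrics]) -> bool:
    """A cell is included iff it has a place field in at least one session."""
    if not metrics_per_session:
        raise ValueError("need at least one analyzed session")
    return any(m.n_fields >= 1 for m in metrics_per_session)


def cell_session_metrics(occ: OccupancyMap, raw: RateMap, smooth: RateMap,
                         threshold_frac: float = FIELD_THRESHOLD_FRAC,
                         min_bins: int = FIELD_MIN_BINS,
                         adjacency: int = 4) -> CellSessionMetrics:
    """All per-cell-session metrics from the three pipeline maps.

    Field detection runs on the smoothed map; spatial information on the
    unsmoothed normalized map (smoothing inflates apparent information).
    """
    fields = detect_fields(smooth, threshold_frac, min_bins, adjacency)
    return CellSessionMetrics(
        n_fields=len(fields),
        field_areas_bins=tuple(f.area_bins for f in fields),
        field_areas_cm2=tuple(f.area_cm2 for f in fields),
        active_bins_normalized=field_size_normalized(raw, threshold_frac),
        spatial_info=spatial_information(raw, occ),
        specificity_ratio=specificity_ratio(smooth, fields, occ),
        mean_rate=raw.mean_rate,
        max_rate=smooth.max_rate,
    )
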