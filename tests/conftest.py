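import numpy as np
import pytest

from placecell import ArenaGeometry, PositionTrace
from placecell.preprocessing import ActiveIntervals
from placecell.ratemap import OccupancyMap, RateMap


@pytest.fixture
def arena():
    return ArenaGeometry()


def make_trace(duration=10.0, rate=25.0, x=0.0, y=0.0):
    """Trace sitting at a fixed point (or following callables x(t), y(t))."""
    t = np.arange(int(round(duration * rate))) / rate
    xs = x(t) if callable(x) else np.full(len(t), float(x))
    ys = y(t) if callable(y) else np.full(len(t), float(y))
    return PositionTrace(t, xs, ys)


def full_interval(trace):
    return ActiveIntervals(((float(trace.t[0]), float(trace.t[-1])),))


def square_ratemap(rate, valid=None, bin_size=2.0, smoothed=True,
                   mean_rate=1.0):
    """RateMap over an n x n grid straight from an array (no arena mask)."""
    rate = np.asarray(rate, dtype=float)
    ny, nx = rate.shape
    if valid is None:
        valid = np.ones_like(rate, dtype=bool)
    r = np.where(valid, rate, np.nan)
    return RateMap(r, valid, bin_size * np.arange(nx + 1),
                   bin_size * np.arange(ny + 1), smoothed=smoothed,
                   mean_rate=mean_rate)


def square_occupancy(occ, valid=None, bin_size=2.0):
    occ = np.asarray(occ, dtype=float)
    ny, nx = occ.shape
    if valid is None:
        valid = occ >= 0.2
    return OccupancyMap(occ, bin_size * np.arange(nx + 1),
                        bin_size * np.arange(ny + 1), valid, bin_size)
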