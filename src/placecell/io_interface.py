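"""Core data containers and plain-text I/O for open-field recordings.

All session data live in three small CSV files:

* positions: columns ``t,x,y`` — timestamps (s, strictly increasing) and
  arena-centered coordinates (cm, y-up);
* spikes: columns ``unit_id,t`` — sorted spike times per putative single
  unit;
* metadata: columns ``key,value`` — animal id, genotype, experiment/day/
  session indices, cue condition and arena geometry.

Derived metrics are exchanged as a long-format table (one row per unit,
session and metric) so the statistics layer can consume every stage's
output through one schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("placecell")

#: fixed column order of the long-format metrics table
METRICS_COLUMNS = [
    "animal_id",
    "genotype",
    "experiment_index",
    "session_index",
    "cue_condition",
    "unit_id",
    "metric_name",
    "value",
]

#: how far outside the wall a tracked sample may sit before it is rejected
ARENA_TOLERANCE_CM = 1.0


class FormatError(ValueError):
    """Raised when an input file violates the documented format contract."""


@dataclass(frozen=True)
class ArenaGeometry:
    """Circular open-field arena in arena-centered cm coordinates."""

    center_x: float = 0.0
    center_y: float = 0.0
    radius: float = 32.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"arena radius must be > 0, got {self.radius}")

    def distance_from_center(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return np.hypot(np.asarray(x) - self.center_x, np.asarray(y) - self.center_y)


@dataclass(frozen=True)
class PositionTrace:
    """Timestamped 2-D trajectory; the substrate of all occupancy analysis."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (len(t) == len(x) == len(y)):
            raise ValueError("t, x, y must have equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) > 1 else 0.0

    def sample_period(self) -> float:
        """Median inter-sample interval (s)."""
        if len(self.t) < 2:
            return 0.0
        return float(np.median(np.diff(self.t)))


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (s) of one putative single unit in one session."""

    unit_id: str
    t: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if len(t) > 1 and np.any(np.diff(t) < 0):
            raise ValueError(f"unit {self.unit_id}: spike times must be sorted")
        object.__setattr__(self, "t", t)

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class UnitFeatureSeries:
    """Per-spike first-principal-component amplitude used for cluster QC."""

    t: np.ndarray
    feature: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        f = np.asarray(self.feature, dtype=float)
        if len(t) != len(f):
            raise ValueError("feature series must align with spike times")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "feature", f)

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class SessionRecording:
    """One 30-min exploration session of one animal with its sorted units."""

    animal_id: str
    genotype: str
    experiment_index: int
    day: int
    session_index: int
    cue_condition: str
    arena: ArenaGeometry
    trace: PositionTrace
    units: tuple[SpikeTrain, ...]
    features: dict[str, UnitFeatureSeries] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "units", tuple(self.units))
        if self.cue_condition not in ("full", "probe"):
            raise ValueError(f"unknown cue condition {self.cue_condition!r}")
        if len(self.trace) >= 2:
            t0, t1 = self.trace.t[0], self.trace.t[-1]
            for u in self.units:
                if len(u) and (u.t[0] < t0 or u.t[-1] > t1):
                    raise FormatError(
                        f"unit {u.unit_id}: spikes outside trace span "
                        f"[{t0:.3f}, {t1:.3f}] s"
                    )

    def unit(self, unit_id: str) -> SpikeTrain:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)


# ---------------------------------------------------------------------------
# session files
# ---------------------------------------------------------------------------

def write_session(rec: SessionRecording, position_path, spikes_path,
                  metadata_path) -> None:
    """Write one recording as the position/spikes/metadata CSV trio."""
    pd.DataFrame({"t": rec.trace.t, "x": rec.trace.x, "y": rec.trace.y}).to_csv(
        position_path, index=False, float_format="%.12g")
    rows = [(u.unit_id, t) for u in rec.units for t in u.t]
    pd.DataFrame(rows, columns=["unit_id", "t"]).to_csv(
        spikes_path, index=False, float_format="%.12g")
    meta = {
        "animal_id": rec.animal_id,
        "genotype": rec.genotype,
        "experiment_index": rec.experiment_index,
        "day": rec.day,
        "session_index": rec.session_index,
        "cue_condition": rec.cue_condition,
        "arena_center_x": rec.arena.center_x,
        "arena_center_y": rec.arena.center_y,
        "arena_radius": rec.arena.radius,
    }
    pd.DataFrame(list(meta.items()), columns=["key", "value"]).to_csv(
        metadata_path, index=False)


_REQUIRED_META = (
    "animal_id", "genotype", "experiment_index", "day", "session_index",
    "cue_condition", "arena_radius",
)


def read_session(position_path, spikes_path, metadata_path) -> SessionRecording:
    """Read and validate a position/spikes/metadata CSV trio.

    Samples further than 1 cm outside the arena wall are rejected (a
    tracking artifact); anything inside the tolerance band is clipped to
    the wall. Unsorted spikes and missing metadata keys raise
    :class:`FormatError`.
    """
    meta_df = pd.read_csv(metadata_path, dtype=str)
    if list(meta_df.columns) != ["key", "value"]:
        raise FormatError(f"{metadata_path}: expected columns key,value")
    meta = dict(zip(meta_df["key"], meta_df["value"]))
    for k in _REQUIRED_META:
        if k not in meta:
            raise FormatError(f"{metadata_path}: missing metadata key {k!r}")
    arena = ArenaGeometry(
        center_x=float(meta.get("arena_center_x", 0.0)),
        center_y=float(meta.get("arena_center_y", 0.0)),
        radius=float(meta["arena_radius"]),
    )

    pos = pd.read_csv(position_path)
    if not {"t", "x", "y"} <= set(pos.columns):
        raise FormatError(f"{position_path}: expected columns t,x,y")
    r = arena.distance_from_center(pos["x"].to_numpy(), pos["y"].to_numpy())
    bad = r > arena.radius + ARENA_TOLERANCE_CM
    if bad.any():
        raise FormatError(
            f"{position_path}: {int(bad.sum())} samples more than "
            f"{ARENA_TOLERANCE_CM} cm outside the arena wall")
    # clip the tolerance band back onto the wall
    over = r > arena.radius
    x = pos["x"].to_numpy(dtype=float)
    y = pos["y"].to_numpy(dtype=float)
    if over.any():
        scale = arena.radius / r[over]
        x[over] = arena.center_x + (x[over] - arena.center_x) * scale
        y[over] = arena.center_y + (y[over] - arena.center_y) * scale
        logger.info("read_session: clipped %d near-wall samples", int(over.sum()))
    trace = PositionTrace(pos["t"].to_numpy(dtype=float), x, y)

    spk = pd.read_csv(spikes_path)
    if not {"unit_id", "t"} <= set(spk.columns):
        raise FormatError(f"{spikes_path}: expected columns unit_id,t")
    units = []
    for unit_id, grp in spk.groupby("unit_id", sort=True):
        times = grp["t"].to_numpy(dtype=float)
        if np.any(np.diff(times) < 0):
            raise FormatError(f"{spikes_path}: unit {unit_id} spikes unsorted")
        if len(times) and len(trace) >= 2 and (
                times[0] < trace.t[0] or times[-1] > trace.t[-1]):
            raise FormatError(
                f"{spikes_path}: unit {unit_id} has spikes outside the "
                f"position time span")
        units.append(SpikeTrain(str(unit_id), times))

    return SessionRecording(
        animal_id=str(meta["animal_id"]),
        genotype=str(meta["genotype"]),
        experiment_index=int(meta["experiment_index"]),
        day=int(meta["day"]),
        session_index=int(meta["session_index"]),
        cue_condition=str(meta["cue_condition"]),
        arena=arena,
        trace=trace,
        units=tuple(units),
    )


# ---------------------------------------------------------------------------
# metrics table
# ---------------------------------------------------------------------------

def read_config(path) -> dict[str, str]:
    """Read a plain-text ``key = value`` config file.

    Blank lines and ``#`` comments are ignored; values stay strings for
    the caller to coerce.
    """
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value'")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def new_metrics_table(rows: Iterable[dict] | None = None) -> pd.DataFrame:
    """Create an (optionally pre-filled) long-format metrics table."""
    df = pd.DataFrame(list(rows or []), columns=METRICS_COLUMNS)
    return df[METRICS_COLUMNS]


def validate_metrics_table(table: pd.DataFrame) -> None:
    if list(table.columns) != METRICS_COLUMNS:
        raise FormatError(
            f"metrics table must have columns {METRICS_COLUMNS}, "
            f"got {list(table.columns)}")
    dup = table.duplicated(
        subset=["animal_id", "session_index", "unit_id", "metric_name"])
    if dup.any():
        raise FormatError(
            f"{int(dup.sum())} duplicate (unit, session, metric) rows")


def write_metrics(table: pd.DataFrame, path) -> Path:
    """Write a metrics table as CSV with deterministic row ordering."""
    validate_metrics_table(table)
    ordered = table.sort_values(
        ["animal_id", "session_index", "unit_id", "metric_name"],
        kind="mergesort").reset_index(drop=True)
    path = Path(path)
    ordered.to_csv(path, index=False, float_format="%.12g")
    return path


def read_metrics(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal_id": str, "unit_id": str,
                                  "genotype": str, "cue_condition": str,
                                  "metric_name": str})
    validate_metrics_table(df)
    return df
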