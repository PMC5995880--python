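"""Synthetic open-field sessions with controllable place-cell phenotypes.

No public dataset accompanies the recordings this pipeline targets, so
every downstream stage is exercised against simulated sessions built to
the same statistics: 30-min free exploration of a 64-cm circular arena at
a realistic median running speed (~5.9 cm/s) with mild wall preference
(mean distance from center ~25 cm), and pyramidal units with Gaussian
place fields firing as inhomogeneous Poisson processes.

Two genotype profiles provide the phenotypes of interest: a "WT-like"
profile (compact, strong, stable fields) and a "KO-like" profile (broader
fields, weaker peak-to-baseline contrast, and within-session drift of the
field centers). Drift is the mechanism behind degraded split-half
stability; field width behind field size; contrast behind the specificity
ratio.

The trajectory model is a mean-reverting (Ornstein-Uhlenbeck) 2-D
velocity process with specular reflection at the wall and an outward
radial acceleration (thigmotaxis bias). Spikes are drawn by exact
thinning against the instantaneous rate, so there is no time-
discretization bias beyond linear interpolation of the trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io_interface import (ArenaGeometry, PositionTrace, SessionRecording,
                           SpikeTrain, UnitFeatureSeries)

#: outward radial acceleration at wall_bias = 1 (cm/s^2); calibrated so the
#: default wall_bias reproduces a mean center distance of ~25 cm
WALL_BIAS_ACCEL = 2.4

#: default wall-hugging strength
DEFAULT_WALL_BIAS = 0.6

#: default target mean speed (cm/s); yields a realized median active speed
#: near 5.9 cm/s after the 3 cm/s activity filter
DEFAULT_MEAN_SPEED = 5.6

DRIFT_REFERENCE_S = 900.0      # drift_rate is expressed in cm per 15 min


@dataclass(frozen=True)
class TrajectoryParams:
    """Parameters of the Ornstein-Uhlenbeck exploration model.

    ``mean_speed`` sets the stationary Rayleigh mean of the speed process;
    ``speed_relaxation`` (1/s) is the velocity mean-reversion rate (higher
    = straighter, faster-decorrelating runs); ``speed_noise`` (cm/s per
    sqrt(s)) overrides the noise amplitude otherwise derived from the two;
    ``wall_bias`` in [0, 1] scales an outward radial acceleration that
    shifts the stationary radial density toward the wall (0 = uniform
    exploration).
    """

    duration: float = 1800.0
    sample_rate: float = 25.0
    mean_speed: float = DEFAULT_MEAN_SPEED
    speed_relaxation: float = 0.5
    speed_noise: float | None = None
    wall_bias: float = DEFAULT_WALL_BIAS
    seed: int = 0

    def __post_init__(self):
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.mean_speed < 0:
            raise ValueError("mean_speed must be >= 0")
        if not 0 <= self.wall_bias <= 1:
            raise ValueError("wall_bias must be in [0, 1]")

    @property
    def noise(self) -> float:
        """Velocity noise amplitude; Rayleigh mean of |v| = mean_speed."""
        if self.speed_noise is not None:
            return self.speed_noise
        component_sd = self.mean_speed / math.sqrt(math.pi / 2.0)
        return component_sd * math.sqrt(2.0 * self.speed_relaxation)


def simulate_trajectory(arena: ArenaGeometry,
                        params: TrajectoryParams) -> PositionTrace:
    """Simulate an exploration trajectory; every sample strictly inside.

    Euler-Maruyama integration of the velocity process at the sample rate,
    with specular reflection of position and radial velocity at the wall.
    Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.sample_rate))
    dt = 1.0 / params.sample_rate
    t = np.arange(n) * dt
    if n == 0:
        return PositionTrace(t, np.empty(0), np.empty(0))
    x = np.empty(n)
    y = np.empty(n)
    theta = params.speed_relaxation
    sig = params.noise * math.sqrt(dt)
    accel = params.wall_bias * WALL_BIAS_ACCEL
    center = np.array([arena.center_x, arena.center_y])
    # start at a random interior point, stationary velocity
    r0 = arena.radius * 0.5 * math.sqrt(rng.uniform())
    a0 = rng.uniform(0, 2 * math.pi)
    pos = center + r0 * np.array([math.cos(a0), math.sin(a0)])
    comp_sd = params.noise / math.sqrt(2 * theta) if theta > 0 else 0.0
    vel = rng.normal(0.0, comp_sd, size=2)
    noise = rng.normal(size=(n, 2))
    for i in range(n):
        x[i], y[i] = pos
        rel = pos - center
        r = math.hypot(rel[0], rel[1])
        rhat = rel / r if r > 1e-9 else np.zeros(2)
        vel = vel + (-theta * vel + accel * rhat) * dt + sig * noise[i]
        pos = pos + vel * dt
        # specular reflection keeps speed; repeat for rare large overshoots
        rel = pos - center
        r = math.hypot(rel[0], rel[1])
        while r >= arena.radius:
            rhat = rel / r
            pos = center + rhat * (2.0 * arena.radius - r)
            vn = float(vel @ rhat)
            vel = vel - 2.0 * vn * rhat
            rel = pos - center
            r = math.hypot(rel[0], rel[1])
            if r >= arena.radius:        # overshoot past the center and back
                continue
            if arena.radius - r < 1e-9:  # landed exactly on the wall
                pos = center + rel * (1.0 - 1e-9)
                break
    return PositionTrace(t, x, y)


@dataclass(frozen=True)
class PlaceTuning:
    """Gaussian place tuning of one unit.

    The instantaneous rate is ``baseline + sum_f peak_f * exp(-d_f^2 /
    (2 sigma_f^2))`` where ``d_f`` is the distance to field f's center,
    which translates linearly by ``drift_rate`` cm per 15 min in a random
    direction fixed by ``drift_direction_seed``.
    """

    field_centers: tuple[tuple[float, float], ...] = ()
    field_sigma: tuple[float, ...] = ()
    peak_rate: tuple[float, ...] = ()
    baseline_rate: float = 0.0
    drift_rate: float = 0.0
    drift_direction_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "field_centers",
                           tuple((float(a), float(b))
                                 for a, b in self.field_centers))
        object.__setattr__(self, "field_sigma",
                           tuple(float(s) for s in self.field_sigma))
        object.__setattr__(self, "peak_rate",
                           tuple(float(p) for p in self.peak_rate))
        k = len(self.field_centers)
        if not (len(self.field_sigma) == len(self.peak_rate) == k):
            raise ValueError("field parameter lists must have equal length")
        if any(s <= 0 for s in self.field_sigma):
            raise ValueError("field_sigma must be > 0")
        if self.baseline_rate < 0 or any(p < 0 for p in self.peak_rate):
            raise ValueError("rates must be >= 0")
        if self.drift_rate < 0:
            raise ValueError("drift_rate must be >= 0")

    @property
    def max_rate(self) -> float:
        return self.baseline_rate + sum(self.peak_rate)

    def drift_directions(self) -> np.ndarray:
        rng = np.random.default_rng(self.drift_direction_seed)
        ang = rng.uniform(0, 2 * math.pi, size=len(self.field_centers))
        return np.column_stack([np.cos(ang), np.sin(ang)])

    def rate_at(self, t: np.ndarray, x: np.ndarray, y: np.ndarray,
                t0: float = 0.0) -> np.ndarray:
        """Instantaneous rate at positions (x, y) occupied at times t."""
        t = np.asarray(t, dtype=float)
        lam = np.full(len(t), self.baseline_rate)
        dirs = self.drift_directions()
        for f, (cx, cy) in enumerate(self.field_centers):
            shift = self.drift_rate * (t - t0) / DRIFT_REFERENCE_S
            fx = cx + shift * dirs[f, 0]
            fy = cy + shift * dirs[f, 1]
            d2 = (x - fx) ** 2 + (y - fy) ** 2
            lam = lam + self.peak_rate[f] * np.exp(
                -d2 / (2.0 * self.field_sigma[f] ** 2))
        return lam


def simulate_place_cell(trace: PositionTrace, tuning: PlaceTuning,
                        seed: int) -> SpikeTrain:
    """Inhomogeneous-Poisson spikes by thinning against the tuning rate.

    Candidate spikes are drawn as a homogeneous Poisson process at the
    rate ceiling ``baseline + sum(peaks)`` and accepted with probability
    ``rate(t)/ceiling``, with the position at each candidate time linearly
    interpolated from the trace. Exact, sorted, and deterministic given
    the seed.
    """
    rng = np.random.default_rng(seed)
    lam_max = tuning.max_rate
    if len(trace) < 2 or lam_max == 0:
        return SpikeTrain("sim", np.empty(0))
    t0, t1 = float(trace.t[0]), float(trace.t[-1])
    n_cand = rng.poisson(lam_max * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, size=n_cand))
    x = np.interp(cand, trace.t, trace.x)
    y = np.interp(cand, trace.t, trace.y)
    lam = tuning.rate_at(cand, x, y, t0=t0)
    keep = rng.uniform(size=n_cand) < lam / lam_max
    return SpikeTrain("sim", cand[keep])


# ---------------------------------------------------------------------------
# genotype profiles and cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamDist:
    """Clipped-normal distribution for one tuning parameter."""

    mean: float
    sd: float
    lo: float
    hi: float

    def draw(self, rng: np.random.Generator, size=None):
        return np.clip(rng.normal(self.mean, self.sd, size=size),
                       self.lo, self.hi)


@dataclass(frozen=True)
class GenotypeProfile:
    """Distributions from which a cohort's per-cell tuning is drawn."""

    label: str                       # "WT-like" or "KO-like"
    field_sigma: ParamDist
    peak_rate: ParamDist
    baseline_rate: ParamDist
    drift_rate: ParamDist
    n_fields_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.8, 2: 0.2})

    @property
    def genotype(self) -> str:
        return self.label.split("-")[0]

    def draw_tuning(self, rng: np.random.Generator,
                    arena: ArenaGeometry) -> PlaceTuning:
        ks = sorted(self.n_fields_probs)
        probs = np.array([self.n_fields_probs[k] for k in ks], dtype=float)
        n_fields = int(rng.choice(ks, p=probs / probs.sum()))
        centers = tuple(map(tuple, draw_field_centers(rng, arena, n_fields)))
        return PlaceTuning(
            field_centers=centers,
            field_sigma=tuple(self.field_sigma.draw(rng, n_fields)),
            peak_rate=tuple(self.peak_rate.draw(rng, n_fields)),
            baseline_rate=float(self.baseline_rate.draw(rng)),
            drift_rate=float(self.drift_rate.draw(rng)),
            drift_direction_seed=int(rng.integers(2 ** 31 - 1)),
        )


def draw_field_centers(rng: np.random.Generator, arena: ArenaGeometry,
                       n: int, margin_frac: float = 0.8) -> np.ndarray:
    """Uniform field centers within ``margin_frac`` of the arena radius."""
    rmax = arena.radius * margin_frac
    r = rmax * np.sqrt(rng.uniform(size=n))
    ang = rng.uniform(0, 2 * math.pi, size=n)
    return np.column_stack([arena.center_x + r * np.cos(ang),
                            arena.center_y + r * np.sin(ang)])


def default_profiles() -> tuple[GenotypeProfile, GenotypeProfile]:
    """The two study phenotypes.

    The KO-like profile has broader fields, a weaker peak-to-baseline
    contrast, and much faster within-session field drift than the WT-like
    profile; everything else (trajectory statistics, field counts) is
    shared, so group differences downstream isolate the tuning phenotype.
    """
    wt = GenotypeProfile(
        label="WT-like",
        field_sigma=ParamDist(6.0, 1.0, 4.0, 9.0),
        peak_rate=ParamDist(12.0, 3.0, 6.0, 20.0),
        baseline_rate=ParamDist(0.4, 0.15, 0.05, 1.0),
        drift_rate=ParamDist(1.0, 0.5, 0.0, 2.5),
    )
    ko = GenotypeProfile(
        label="KO-like",
        field_sigma=ParamDist(9.0, 1.5, 6.0, 14.0),
        peak_rate=ParamDist(7.0, 2.0, 3.0, 12.0),
        baseline_rate=ParamDist(1.0, 0.3, 0.2, 2.0),
        drift_rate=ParamDist(6.0, 2.0, 2.0, 12.0),
    )
    return wt, ko


@dataclass(frozen=True)
class SessionPlan:
    """Two days x two sessions, cues removed in the final (probe) session."""

    n_days: int = 2
    sessions_per_day: int = 2
    remap_on_probe: float = 0.25

    def __post_init__(self):
        if not 0 <= self.remap_on_probe <= 1:
            raise ValueError("remap_on_probe must be in [0, 1]")

    @property
    def n_sessions(self) -> int:
        return self.n_days * self.sessions_per_day

    def cue_condition(self, session_index: int) -> str:
        return "probe" if session_index == self.n_sessions else "full"

    def day(self, session_index: int) -> int:
        return (session_index - 1) // self.sessions_per_day + 1


def simulate_cohort(profiles: Sequence[GenotypeProfile],
                    n_animals_per_profile: int,
                    n_cells_per_animal: int,
                    plan: SessionPlan | None = None,
                    arena: ArenaGeometry | None = None,
                    seed: int = 0,
                    trajectory: TrajectoryParams | None = None,
                    return_tunings: bool = False):
    """Simulate a full multi-animal, multi-session cohort.

    Per animal, tuning parameters are drawn once from its profile and the
    same cells are tracked across all sessions; in the probe session a
    ``remap_on_probe`` fraction of units gets freshly drawn field centers
    (cue removal destabilizing part of the map). Fully reproducible from
    ``seed``.

    With ``return_tunings`` also returns a dict keyed by
    ``(animal_id, session_index, unit_id)`` holding the
    :class:`PlaceTuning` actually used for each unit and session.
    """
    if not profiles:
        raise ValueError("need at least one genotype profile")
    if n_animals_per_profile < 1 or n_cells_per_animal < 1:
        raise ValueError("need at least one animal and one cell")
    plan = plan or SessionPlan()
    arena = arena or ArenaGeometry()
    trajectory = trajectory or TrajectoryParams()
    master = np.random.default_rng(seed)
    recordings: list[SessionRecording] = []
    tunings_used: dict[tuple, PlaceTuning] = {}
    for profile in profiles:
        for a in range(n_animals_per_profile):
            arng = np.random.default_rng(master.integers(2 ** 31 - 1))
            animal_id = f"{profile.label}-m{a + 1}"
            tunings = [profile.draw_tuning(arng, arena)
                       for _ in range(n_cells_per_animal)]
            remap = arng.uniform(size=n_cells_per_animal) < plan.remap_on_probe
            for s in range(1, plan.n_sessions + 1):
                cue = plan.cue_condition(s)
                traj_seed = int(arng.integers(2 ** 31 - 1))
                trace = simulate_trajectory(
                    arena, replace(trajectory, seed=traj_seed))
                units = []
                for c, tuning in enumerate(tunings):
                    if cue == "probe" and remap[c]:
                        centers = draw_field_centers(
                            np.random.default_rng(traj_seed + c + 1), arena,
                            len(tuning.field_centers))
                        tuning = replace(tuning, field_centers=tuple(
                            map(tuple, centers)))
                    # fresh drift direction each session
                    tuning = replace(tuning, drift_direction_seed=int(
                        arng.integers(2 ** 31 - 1)))
                    spikes = simulate_place_cell(
                        trace, tuning, seed=int(arng.integers(2 ** 31 - 1)))
                    uid = f"u{c + 1:02d}"
                    tunings_used[(animal_id, s, uid)] = tuning
                    units.append(SpikeTrain(uid, spikes.t))
                recordings.append(SessionRecording(
                    animal_id=animal_id,
                    genotype=profile.genotype,
                    experiment_index=1,
                    day=plan.day(s),
                    session_index=s,
                    cue_condition=cue,
                    arena=arena,
                    trace=trace,
                    units=tuple(units),
                ))
    if return_tunings:
        return recordings, tunings_used
    return recordings


def simulate_feature_drift(n_spikes: int, drift_magnitude: float,
                           noise_sd: float, seed: int = 0,
                           duration: float = 3600.0) -> UnitFeatureSeries:
    """First-PC amplitude series with a linear trend, for drift-QC tests.

    The trend's total amplitude is ``drift_magnitude * noise_sd`` (i.e.
    drift is expressed in noise-SD units) on top of white noise of SD
    ``noise_sd``; a drift_magnitude well above the QC threshold is
    excluded by construction, zero drift is retained.
    """
    if n_spikes < 2:
        raise ValueError("need at least 2 spikes")
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0.0, duration, size=n_spikes))
    trend = drift_magnitude * noise_sd * (t - t[0]) / max(t[-1] - t[0], 1e-12)
    feature = trend + rng.normal(0.0, noise_sd, size=n_spikes)
    return UnitFeatureSeries(t=t, feature=feature)
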