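"""Trajectory kinematics: spline resampling, curvature, overlap windows, ensembles.

Raw trajectories are timestamped 3D positions of one agent in one pair.
This module turns them into uniform-rate kinematic series (position,
velocity, acceleration, curvature), restricts a pair to the window where
both agents are present, and builds the concatenated, normalized ensemble
series that the coupling estimators consume.

Curvature of a 3D path is computed from velocity and acceleration as

    a_t = (a . v / ||v||^2) v        (tangential acceleration)
    a_n = a - a_t                    (normal acceleration)
    rho = ||a_n|| / ||v||^2          (curvature, 1/m)

which equals 1/R on a circle of radius R.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

BEHAVIOR_LABELS = ("NM", "MC", "MT")

#: Speeds below this floor (m/s) make curvature numerically meaningless;
#: such samples are flagged invalid and excluded downstream.
DEFAULT_SPEED_FLOOR = 1e-6


class UnusableTrajectoryError(ValueError):
    """Trajectory too short or otherwise unusable for spline fitting."""


class InputError(ValueError):
    """Malformed input data (non-monotone times, mismatched shapes, ...)."""


@dataclass
class RawTrajectory:
    """Timestamped 3D positions of one agent within one pair.

    agent_index 1 is the agent that entered the observation volume first
    (front position); 2 entered second (rear).
    """

    pair_id: str
    agent_index: int
    times: np.ndarray          # (n,) seconds, strictly increasing
    positions: np.ndarray      # (n, 3) meters
    native_rate: float         # Hz
    behavior_label: str = "NM"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise InputError("positions must have shape (n, 3)")
        if len(self.times) != len(self.positions):
            raise InputError("times and positions must have equal length")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.positions)):
            raise InputError("times and positions must be finite")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly increasing")
        if self.agent_index not in (1, 2):
            raise InputError("agent_index must be 1 or 2")
        if self.behavior_label not in BEHAVIOR_LABELS:
            raise InputError(f"behavior_label must be one of {BEHAVIOR_LABELS}")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


@dataclass
class KinematicSeries:
    """Uniform-rate kinematics of one agent: position, derivatives, curvature.

    ``valid`` marks samples whose speed exceeds the configured floor;
    curvature at invalid samples is NaN and is excluded downstream.
    """

    times: np.ndarray            # (n,) uniform grid
    position: np.ndarray         # (n, 3) m
    velocity: np.ndarray         # (n, 3) m/s
    acceleration: np.ndarray     # (n, 3) m/s^2
    tangential_acceleration: np.ndarray  # (n, 3) m/s^2
    normal_acceleration: np.ndarray      # (n, 3) m/s^2
    curvature: np.ndarray        # (n,) 1/m, NaN where invalid
    speed: np.ndarray            # (n,) m/s
    valid: np.ndarray            # (n,) bool
    rate: float                  # Hz

    def __len__(self) -> int:
        return len(self.times)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def slice(self, start: int, stop: int) -> "KinematicSeries":
        """Return the sub-series covering sample indices [start, stop)."""
        return KinematicSeries(
            times=self.times[start:stop],
            position=self.position[start:stop],
            velocity=self.velocity[start:stop],
            acceleration=self.acceleration[start:stop],
            tangential_acceleration=self.tangential_acceleration[start:stop],
            normal_acceleration=self.normal_acceleration[start:stop],
            curvature=self.curvature[start:stop],
            speed=self.speed[start:stop],
            valid=self.valid[start:stop],
            rate=self.rate,
        )


@dataclass
class PairRecord:
    """Kinematics of the two agents of one pair plus the co-presence window."""

    pair_id: str
    series_1: KinematicSeries
    series_2: KinematicSeries
    overlap: tuple[float, float]
    behavior_label: str = "NM"


@dataclass
class EnsembleSeries:
    """Concatenation of per-pair series with segment bookkeeping.

    ``segment_bounds`` holds the start index of each pair's contribution;
    transitions that cross a bound are not dynamical transitions and are
    masked out by the estimators.
    """

    values: np.ndarray           # (n,) or (n, d)
    segment_bounds: np.ndarray   # (n_segments,) start indices, first == 0
    variable_name: str
    normalized: bool = False
    pair_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.segment_bounds = np.asarray(self.segment_bounds, dtype=int)
        n = len(self.values)
        if len(self.segment_bounds) == 0 or self.segment_bounds[0] != 0:
            raise InputError("segment_bounds must start at 0")
        if np.any(np.diff(self.segment_bounds) <= 0) or self.segment_bounds[-1] >= n:
            raise InputError("segment_bounds must be increasing and < length")

    def __len__(self) -> int:
        return len(self.values)

    def boundary_mask(self) -> np.ndarray:
        """Indices t for which the (t, t+1) transition crosses a segment join.

        A transition starting at the last sample of a segment leads into an
        unrelated flight; those t values are invalid transition starts.
        """
        ends = np.append(self.segment_bounds[1:], len(self.values))
        return ends - 1


def fit_spline_and_resample(raw: RawTrajectory, resample_rate: float) -> KinematicSeries:
    """Fit an interpolating cubic spline per coordinate and resample.

    Velocity and acceleration are the analytic first and second derivatives
    of the spline evaluated on a uniform grid spanning the trajectory; the
    spline uses not-a-knot boundary conditions, so trajectories that are
    exactly cubic polynomials are reproduced exactly, derivatives included.

    Parameters
    ----------
    raw
        Input trajectory; needs at least 4 samples.
    resample_rate
        Target grid rate in Hz (e.g. 180).
    """
    if resample_rate <= 0:
        raise InputError("resample_rate must be positive")
    if len(raw.times) < 4:
        raise UnusableTrajectoryError(
            f"pair {raw.pair_id} agent {raw.agent_index}: "
            f"{len(raw.times)} samples < 4 required for a cubic spline"
        )
    t0, t1 = raw.span
    n_out = int(np.floor((t1 - t0) * resample_rate + 1e-9)) + 1
    grid = t0 + np.arange(n_out) / resample_rate
    spline = CubicSpline(raw.times, raw.positions, axis=0)
    pos = spline(grid)
    vel = spline(grid, 1)
    acc = spline(grid, 2)
    return _assemble_series(grid, pos, vel, acc, resample_rate)


def _assemble_series(
    grid: np.ndarray,
    pos: np.ndarray,
    vel: np.ndarray,
    acc: np.ndarray,
    rate: float,
    speed_floor: float = DEFAULT_SPEED_FLOOR,
) -> KinematicSeries:
    curv, a_t, a_n, valid = compute_curvature(vel, acc, speed_floor=speed_floor, full=True)
    speed = np.linalg.norm(vel, axis=1)
    if not valid.all():
        logger.info("curvature invalid at %d samples (speed below %g m/s)",
                    int((~valid).sum()), speed_floor)
    return KinematicSeries(
        times=grid, position=pos, velocity=vel, acceleration=acc,
        tangential_acceleration=a_t, normal_acceleration=a_n,
        curvature=curv, speed=speed, valid=valid, rate=rate,
    )


def compute_curvature(
    velocity: np.ndarray,
    acceleration: np.ndarray,
    speed_floor: float = DEFAULT_SPEED_FLOOR,
    full: bool = False,
):
    """Curvature rho = ||a_n|| / ||v||^2 from velocity and acceleration.

    Samples with speed below ``speed_floor`` get NaN curvature and are
    marked invalid.  With ``full=True`` also returns the tangential and
    normal acceleration decomposition and the validity mask.
    """
    v = np.asarray(velocity, dtype=float)
    a = np.asarray(acceleration, dtype=float)
    if v.shape != a.shape or v.ndim != 2:
        raise InputError("velocity and acceleration must both be (n, d)")
    speed2 = np.einsum("ij,ij->i", v, v)
    valid = np.sqrt(speed2) > speed_floor
    safe = np.where(valid, speed2, 1.0)
    a_t = (np.einsum("ij,ij->i", a, v) / safe)[:, None] * v
    a_n = a - a_t
    curv = np.linalg.norm(a_n, axis=1) / safe
    curv = np.where(valid, curv, np.nan)
    a_t = np.where(valid[:, None], a_t, np.nan)
    a_n = np.where(valid[:, None], a_n, np.nan)
    if full:
        return curv, a_t, a_n, valid
    return curv


class OverlapError(ValueError):
    """The two agents of a pair are never simultaneously present."""


def make_pair_record(
    raw_1: RawTrajectory,
    raw_2: RawTrajectory,
    resample_rate: float = 180.0,
) -> PairRecord:
    """Resample both agents of a pair onto one shared grid over their overlap.

    The grid is anchored at the start of the co-presence window so the two
    series are sample-aligned, as the coupling estimators require.
    """
    if raw_1.pair_id != raw_2.pair_id:
        raise InputError("trajectories belong to different pairs")
    if {raw_1.agent_index, raw_2.agent_index} != {1, 2}:
        raise InputError("need one agent-1 and one agent-2 trajectory")
    if raw_1.agent_index == 2:
        raw_1, raw_2 = raw_2, raw_1
    t_start = max(raw_1.span[0], raw_2.span[0])
    t_end = min(raw_1.span[1], raw_2.span[1])
    if t_end <= t_start:
        raise OverlapError(
            f"pair {raw_1.pair_id}: agents never co-present "
            f"(spans {raw_1.span} and {raw_2.span})"
        )
    n_out = int(np.floor((t_end - t_start) * resample_rate + 1e-9)) + 1
    grid = t_start + np.arange(n_out) / resample_rate

    def _on_grid(raw: RawTrajectory) -> KinematicSeries:
        if len(raw.times) < 4:
            raise UnusableTrajectoryError(
                f"pair {raw.pair_id} agent {raw.agent_index}: fewer than 4 samples"
            )
        spline = CubicSpline(raw.times, raw.positions, axis=0)
        return _assemble_series(grid, spline(grid), spline(grid, 1), spline(grid, 2),
                                resample_rate)

    return PairRecord(
        pair_id=raw_1.pair_id,
        series_1=_on_grid(raw_1),
        series_2=_on_grid(raw_2),
        overlap=(t_start, float(grid[-1])),
        behavior_label=raw_1.behavior_label,
    )


def extract_overlap(pair: PairRecord) -> PairRecord:
    """Trim both series of a pair to the intersection of their time spans.

    Requires both series on grids of the same rate with aligned phases
    (as produced by :func:`make_pair_record`); idempotent.
    """
    s1, s2 = pair.series_1, pair.series_2
    if abs(s1.rate - s2.rate) > 1e-9:
        raise InputError("the two series must share a resample rate")
    t_start = max(s1.span[0], s2.span[0])
    t_end = min(s1.span[1], s2.span[1])
    if t_end < t_start - 1e-12:
        raise OverlapError(f"pair {pair.pair_id}: disjoint time spans, excluded")

    def _trim(s: KinematicSeries) -> KinematicSeries:
        keep = (s.times >= t_start - 1e-9) & (s.times <= t_end + 1e-9)
        idx = np.flatnonzero(keep)
        return s.slice(int(idx[0]), int(idx[-1]) + 1)

    out1, out2 = _trim(s1), _trim(s2)
    if len(out1) != len(out2) or np.max(np.abs(out1.times - out2.times)) > 1e-9:
        raise InputError(
            f"pair {pair.pair_id}: grids are not phase-aligned; "
            "resample both agents onto a shared grid first"
        )
    return PairRecord(pair.pair_id, out1, out2, (t_start, t_end), pair.behavior_label)


def concatenate_ensemble(
    pairs: Sequence[PairRecord],
    variable: Literal["curvature", "velocity"] = "curvature",
) -> tuple[EnsembleSeries, EnsembleSeries]:
    """Concatenate one variable across pairs, independently per agent.

    Pairs are concatenated in ascending ``pair_id`` order.  For curvature,
    samples where either agent's curvature is invalid are dropped from both
    agents so the ensembles stay sample-aligned.  Returns the agent-1 and
    agent-2 ensembles with identical segment bounds.
    """
    if variable not in ("curvature", "velocity"):
        raise InputError(f"unknown variable {variable!r}")
    if not pairs:
        raise InputError("no pairs to concatenate")
    rates = {round(p.series_1.rate, 9) for p in pairs} | {round(p.series_2.rate, 9) for p in pairs}
    if len(rates) > 1:
        raise InputError(f"mixed resample rates in ensemble: {sorted(rates)}")
    ordered = sorted(pairs, key=lambda p: str(p.pair_id))
    chunks_1, chunks_2, bounds, pair_ids = [], [], [], []
    offset = 0
    for p in ordered:
        if len(p.series_1) != len(p.series_2):
            raise InputError(f"pair {p.pair_id}: agents have unequal lengths; "
                             "run extract_overlap first")
        if variable == "curvature":
            keep = p.series_1.valid & p.series_2.valid
            if not keep.all():
                logger.info("pair %s: dropping %d invalid-curvature samples",
                            p.pair_id, int((~keep).sum()))
            c1 = p.series_1.curvature[keep]
            c2 = p.series_2.curvature[keep]
        else:
            c1 = p.series_1.velocity
            c2 = p.series_2.velocity
        if len(c1) == 0:
            logger.warning("pair %s contributes no valid samples; skipped", p.pair_id)
            continue
        bounds.append(offset)
        pair_ids.append(str(p.pair_id))
        chunks_1.append(c1)
        chunks_2.append(c2)
        offset += len(c1)
    if not chunks_1:
        raise InputError("no valid samples in any pair")
    ens_1 = EnsembleSeries(np.concatenate(chunks_1), np.array(bounds), variable,
                           pair_ids=tuple(pair_ids))
    ens_2 = EnsembleSeries(np.concatenate(chunks_2), np.array(bounds), variable,
                           pair_ids=tuple(pair_ids))
    return ens_1, ens_2


class ZeroVarianceError(ValueError):
    """A normalization scope has zero variance."""


def normalize(
    ensemble: EnsembleSeries,
    scope: Literal["global", "per_segment"] = "global",
) -> EnsembleSeries:
    """Standardize to zero mean and unit (sample) variance.

    ``global`` standardizes the whole ensemble at once; ``per_segment``
    standardizes each pair's contribution separately.  Multivariate values
    are standardized per dimension.
    """
    values = ensemble.values.copy()
    if len(values) < 2:
        raise InputError("need at least 2 samples to normalize")

    def _std(chunk: np.ndarray, label: str) -> np.ndarray:
        mu = chunk.mean(axis=0)
        sd = chunk.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            raise ZeroVarianceError(f"zero variance in normalization scope {label!r}")
        return (chunk - mu) / sd

    if scope == "global":
        values = _std(values, "global")
    elif scope == "per_segment":
        bounds = list(ensemble.segment_bounds) + [len(values)]
        for i, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
            label = ensemble.pair_ids[i] if ensemble.pair_ids else str(i)
            values[lo:hi] = _std(values[lo:hi], label)
    else:
        raise InputError(f"unknown normalization scope {scope!r}")
    return replace(ensemble, values=values, normalized=True)


# ---------------------------------------------------------------------------
# Delimited-text I/O

CSV_COLUMNS = ["pair_id", "agent", "t", "x", "y", "z", "behavior"]


def read_trajectories(path) -> list[RawTrajectory]:
    """Read raw trajectories from the package CSV dialect.

    Columns: ``pair_id, agent, t, x, y, z, behavior`` — one row per sample,
    seconds and meters, header required.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for (pair_id, agent), g in df.groupby(["pair_id", "agent"], sort=True):
        g = g.sort_values("t")
        times = g["t"].to_numpy(dtype=float)
        rate = 1.0 / float(np.median(np.diff(times))) if len(times) > 1 else float("nan")
        out.append(RawTrajectory(
            pair_id=str(pair_id),
            agent_index=int(agent),
            times=times,
            positions=g[["x", "y", "z"]].to_numpy(dtype=float),
            native_rate=rate,
            behavior_label=str(g["behavior"].iloc[0]),
        ))
    return out


def write_trajectories(trajectories: Sequence[RawTrajectory], path) -> None:
    """Write raw trajectories in the package CSV dialect.

    Floats are printed with 17 significant digits, so write -> read ->
    write round-trips are byte identical.
    """
    if not trajectories:
        raise InputError("no trajectories to write")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(CSV_COLUMNS) + "\n")
        for traj in trajectories:
            for t, (x, y, z) in zip(traj.times, traj.positions):
                fh.write(f"{traj.pair_id},{traj.agent_index},"
                         f"{t:.17g},{x:.17g},{y:.17g},{z:.17g},"
                         f"{traj.behavior_label}\n")


def write_kinematics_csv(series: KinematicSeries, path) -> None:
    """Write one agent's kinematics as CSV."""
    df = pd.DataFrame({
        "t": series.times,
        "x": series.position[:, 0], "y": series.position[:, 1], "z": series.position[:, 2],
        "vx": series.velocity[:, 0], "vy": series.velocity[:, 1], "vz": series.velocity[:, 2],
        "ax": series.acceleration[:, 0], "ay": series.acceleration[:, 1],
        "az": series.acceleration[:, 2],
        "speed": series.speed,
        "curvature": series.curvature,
    })
    df.to_csv(path, index=False)


def write_ensemble_csv(ensemble: EnsembleSeries, path) -> None:
    """Write an ensemble with a ``segment`` column marking each pair."""
    seg = np.zeros(len(ensemble), dtype=int)
    for i, b in enumerate(ensemble.segment_bounds):
        seg[b:] = i
    if ensemble.values.ndim == 1:
        data = {ensemble.variable_name: ensemble.values}
    else:
        data = {f"{ensemble.variable_name}_{ax}": ensemble.values[:, i]
                for i, ax in enumerate("xyz"[: ensemble.values.shape[1]])}
    df = pd.DataFrame({"segment": seg, **data})
    df.to_csv(path, index=False)
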