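"""Coupled self-propelled-pair simulator with ground-truth coupling direction.

Each agent is a constant-speed self-propelled particle whose heading (unit
vector) turns under three influences:

* smooth angular noise — an Ornstein-Uhlenbeck turning-rate process, so
  synthetic flight paths are wiggly but differentiable like real ones;
* a shared corridor — relaxation of the heading toward the local tangent
  of a gently sinuous centerline that both agents fly through.  This is the
  "same physical space" channel: it makes the two trajectories similar
  without any information passing between the agents;
* directed heading coupling — relaxation toward the partner's heading at a
  configurable sensorimotor delay, applied only in the configured
  direction(s).  This is the ground-truth interaction that the estimators
  are supposed to recover.

Agent 1 enters the observation window first (front); agent 2 enters
``entry_delay`` seconds later (rear).  The co-presence window is therefore
shorter than either flight, as in field recordings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .kinematics import RawTrajectory, write_trajectories

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "SimPair", "simulate_pair", "simulate_group", "write_fixture"]

CouplingMode = Literal["none", "front_to_rear", "rear_to_front", "bidirectional"]


@dataclass
class SimConfig:
    """Generator settings; defaults emulate short paired flights.

    Durations of ~1.3 s at 180 Hz with a 0.55 s stagger give co-presence
    windows of ~135 samples, so a 10-pair group concatenates to ~1.3e3
    samples.  Speed 4 m/s covers ~5 m per flight.
    """

    n_pairs: int = 10
    duration: float = 1.3            # s, flight duration of each agent
    sample_rate: float = 180.0       # Hz
    speed: float = 4.0               # m/s, constant per agent
    heading_noise: float = 0.5       # rad/s, stationary RMS of the noise turning rate
    noise_model: str = "ou"          # {"ou": Markov turning rate, "smooth": jerk-limited}
    noise_corr_time: float = 0.2     # s, correlation time of the turning noise ("ou")
                                     #    or of the angular-jerk state ("smooth")
    turning_relax_time: float = 0.3  # s, damping time of the turning rate ("smooth")
    coupling_mode: CouplingMode = "none"
    coupling_gain: float = 35.0      # 1/s, heading relaxation toward partner (strong)
    coupling_delay: float = 0.01     # s, sensorimotor delay of the coupling
    corridor_gain: float = 2.5       # 1/s, relaxation toward the corridor tangent
    corridor_amplitude: float = 0.3  # m, lateral amplitude of the corridor bend
    corridor_wavelength: float = 4.0 # m, spatial period of the bend
    entry_delay: float = 0.55        # s, agent 2 enters this much later
    initial_separation: float = 0.5  # m, lateral offset between starting points
    duration_jitter: float = 0.2     # relative, per-pair duration variability
    behavior_label: str = "NM"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("heading_noise", "coupling_gain", "coupling_delay",
                     "corridor_gain", "speed"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.duration * self.sample_rate < 50:
            raise ValueError("duration/dt must give at least 50 samples")
        if self.coupling_delay >= self.duration:
            raise ValueError("coupling delay must be shorter than the flight")
        if self.coupling_mode not in ("none", "front_to_rear", "rear_to_front",
                                      "bidirectional"):
            raise ValueError(f"unknown coupling_mode {self.coupling_mode!r}")


@dataclass
class SimPair:
    """One simulated pair with its ground-truth coupling."""

    trajectory_1: RawTrajectory     # front agent (entered first)
    trajectory_2: RawTrajectory     # rear agent
    ground_truth: dict = field(default_factory=dict)
    seed: int = 0


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _tangential(vec: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Component of vec orthogonal to the unit heading h."""
    return vec - (vec @ h) * h


def _corridor_tangent(pos: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Desired heading at a position: follow the bend, re-center laterally.

    The corridor centerline is y = A sin(2 pi x / lambda), z = 0; the
    desired heading blends the centerline tangent with a pull back toward
    the centerline (weight 1 per meter of lateral error).
    """
    k = 2.0 * np.pi / cfg.corridor_wavelength
    slope = cfg.corridor_amplitude * k * np.cos(k * pos[0])
    tangent = np.array([1.0, slope, 0.0])
    err = np.array([0.0,
                    cfg.corridor_amplitude * np.sin(k * pos[0]) - pos[1],
                    -pos[2]])
    return _unit(_unit(tangent) + err)


def simulate_pair(config: SimConfig, pair_id: str = "P000") -> SimPair:
    """Simulate one pair of coupled constant-speed agents.

    Both agents advance on a shared clock at ``1/sample_rate``; headings are
    stepped with Euler-Maruyama and renormalized each step, positions
    integrate ``speed * heading``.  The coupled agent's heading relaxes
    toward its partner's heading ``coupling_delay`` seconds in the past,
    while the partner is airborne.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    dt = 1.0 / cfg.sample_rate
    n_steps = int(round(cfg.duration * cfg.sample_rate))
    delay_steps = int(round(cfg.coupling_delay * cfg.sample_rate))
    entry_steps = int(round(cfg.entry_delay * cfg.sample_rate))

    # who listens to whom: coupled_to[i] = index of the partner agent i tracks
    listens = {
        "none": (None, None),
        "rear_to_front": (1, None),      # front (agent 0) tracks rear (agent 1)
        "front_to_rear": (None, 0),
        "bidirectional": (1, 0),
    }[cfg.coupling_mode]

    starts = (0, entry_steps)
    total = entry_steps + n_steps
    # heading history per agent on the global clock (NaN while absent)
    head = np.full((2, total + 1, 3), np.nan)
    pos = np.full((2, total + 1, 3), np.nan)
    # colored turning noise.  "ou": first-order Markov turning rate, so a
    # lone agent's curvature carries no information beyond its current value
    # (clean null for the uncoupled direction).  "smooth": an OU angular-jerk
    # state drives a damped turning rate (jerk-limited steering).
    omega = np.zeros((2, 3))            # noise turning rate, rad/s
    alpha = np.zeros((2, 3))            # angular jerk state ("smooth"), rad/s^2
    tau_a = cfg.noise_corr_time
    tau_w = cfg.turning_relax_time
    if cfg.noise_model == "ou":
        # sigma_w gives stationary RMS omega = heading_noise
        sigma_w = cfg.heading_noise * np.sqrt(2.0 / tau_a)
        sigma_a = 0.0
    elif cfg.noise_model == "smooth":
        sigma_w = 0.0
        # sigma_a gives stationary RMS omega = heading_noise
        sigma_a = cfg.heading_noise * np.sqrt(2.0 * (tau_a + tau_w)) / (tau_a * tau_w)
    else:
        raise ValueError(f"unknown noise_model {cfg.noise_model!r}")

    # stationary joint law of (alpha, omega) per axis, so flights start in
    # statistical steady state rather than with a zero-turning transient
    p11 = sigma_a**2 * tau_a / 2.0
    p12 = (p11 * tau_a * tau_w / (tau_a + tau_w)) if p11 > 0 else 0.0
    p22 = cfg.heading_noise**2
    lateral = cfg.initial_separation / 2.0
    for a in range(2):
        s = starts[a]
        p0 = np.array([0.0, (lateral if a == 0 else -lateral)
                       + 0.05 * rng.standard_normal(),
                       0.05 * rng.standard_normal()])
        pos[a, s] = p0
        head[a, s] = _corridor_tangent(p0, cfg)
        z1, z2 = rng.standard_normal((2, 3))
        if p11 > 0:
            alpha[a] = np.sqrt(p11) * z1
            omega[a] = (p12 / np.sqrt(p11)) * z1 \
                + np.sqrt(max(p22 - p12**2 / p11, 0.0)) * z2
        else:
            omega[a] = np.sqrt(p22) * z2

    for step in range(total):
        for a in range(2):
            s = starts[a]
            if not (s <= step < s + n_steps):
                continue
            h = head[a, step]
            p = pos[a, step]
            if sigma_a > 0:
                alpha[a] += (-alpha[a] / tau_a) * dt \
                    + sigma_a * np.sqrt(dt) * rng.standard_normal(3)
                omega[a] += (-omega[a] / tau_w + alpha[a]) * dt
            else:
                omega[a] += (-omega[a] / tau_a) * dt \
                    + sigma_w * np.sqrt(dt) * rng.standard_normal(3)
            drive = _tangential(omega[a], h)
            drive += cfg.corridor_gain * _tangential(_corridor_tangent(p, cfg), h)
            partner = listens[a]
            if partner is not None and step - delay_steps >= 0:
                h_past = head[partner, step - delay_steps]
                if np.all(np.isfinite(h_past)):
                    drive += cfg.coupling_gain * _tangential(h_past, h)
            h_new = h + drive * dt
            norm = np.linalg.norm(h_new)
            if norm < 1e-12:
                raise RuntimeError("heading collapsed to zero; unstable step")
            head[a, step + 1] = h_new / norm
            pos[a, step + 1] = p + cfg.speed * h * dt

    def _traj(a: int, agent_index: int) -> RawTrajectory:
        s = starts[a]
        sl = slice(s, s + n_steps + 1)
        return RawTrajectory(
            pair_id=pair_id,
            agent_index=agent_index,
            times=np.arange(s, s + n_steps + 1) * dt,
            positions=pos[a, sl].copy(),
            native_rate=cfg.sample_rate,
            behavior_label=cfg.behavior_label,
        )

    return SimPair(
        trajectory_1=_traj(0, 1),
        trajectory_2=_traj(1, 2),
        ground_truth={
            "coupling_mode": cfg.coupling_mode,
            "coupling_gain": cfg.coupling_gain,
            "coupling_delay": cfg.coupling_delay,
            "corridor_gain": cfg.corridor_gain,
        },
        seed=cfg.seed,
    )


def simulate_group(config: SimConfig, n_pairs: int | None = None) -> list[SimPair]:
    """Simulate ``n_pairs`` independent pairs with per-pair derived seeds.

    Pair durations are jittered by up to ``duration_jitter`` (relative,
    uniform) to emulate unequal trajectory lengths.  Groups of fewer than 2
    pairs are allowed but a partner-scrambled control is then infeasible.
    """
    n = config.n_pairs if n_pairs is None else n_pairs
    if n < 2:
        logger.warning("group of %d pair(s): shuffled-partner control infeasible", n)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n)
    jitter_rng = np.random.default_rng(ss.generate_state(1)[0] % (2**31))
    pairs = []
    for i, child in enumerate(children):
        factor = 1.0 + config.duration_jitter * jitter_rng.uniform(-1.0, 1.0)
        cfg_i = replace(config,
                        duration=config.duration * factor,
                        seed=int(child.generate_state(1)[0] % (2**31)))
        pairs.append(simulate_pair(cfg_i, pair_id=f"P{i:03d}"))
    return pairs


def write_fixture(pairs: list[SimPair], path) -> None:
    """Write simulated pairs in the trajectory CSV dialect.

    Columns ``pair_id,agent,t,x,y,z,behavior``; floats are printed with 17
    significant digits so a write -> read -> write cycle is byte identical.
    """
    if not pairs:
        raise ValueError("no pairs to write")
    trajs = []
    for sp in pairs:
        trajs.extend([sp.trajectory_1, sp.trajectory_2])
    write_trajectories(trajs, path)
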