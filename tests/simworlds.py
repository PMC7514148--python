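"""Shared helpers for tests: synthetic worlds, ensembles, and coupling metrics."""

from __future__ import annotations

import numpy as np

import pairflight as pf
from pairflight import crossmap, kinematics
from pairflight.infotransfer import transfer_entropy_ksg
from pairflight.nullcontrol import scramble_partners


def make_group(mode: str, seed: int, n_pairs: int = 10, **kw) -> list:
    """Simulate a group and return overlap-trimmed pair records."""
    cfg = pf.SimConfig(n_pairs=n_pairs, coupling_mode=mode, seed=seed, **kw)
    pairs = pf.simulate_group(cfg)
    return [kinematics.extract_overlap(
        kinematics.make_pair_record(p.trajectory_1, p.trajectory_2))
        for p in pairs]


def curvature_ensembles(recs):
    e1, e2 = kinematics.concatenate_ensemble(recs, "curvature")
    return kinematics.normalize(e1), kinematics.normalize(e2)


def te_both(recs, K: int = 8):
    """(T_{2->1}, T_{1->2}) on the normalized curvature ensembles."""
    e1, e2 = curvature_ensembles(recs)
    mask = e1.boundary_mask()
    t21 = transfer_entropy_ksg(e2.values, e1.values, K=K, boundary_mask=mask).value
    t12 = transfer_entropy_ksg(e1.values, e2.values, K=K, boundary_mask=mask).value
    return t21, t12


def te_null(recs, rng, n_shuffles: int, K: int = 8) -> np.ndarray:
    """(n_shuffles, 2) array of (T_{2->1}, T_{1->2}) under partner scrambling."""
    return np.array([te_both(scramble_partners(recs, rng), K=K)
                     for _ in range(n_shuffles)])


def logistic_map(n: int, r: float = 3.8, x0: float = 0.4) -> np.ndarray:
    x = np.empty(n)
    x[0] = x0
    for t in range(n - 1):
        x[t + 1] = r * x[t] * (1.0 - x[t])
    return x


def coupled_logistic_pair(n: int, seed: int):
    """Unidirectionally coupled logistic maps: X autonomous, X drives Y."""
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = rng.uniform(0.2, 0.8, 2)
    for t in range(n - 1):
        x[t + 1] = x[t] * (3.8 - 3.8 * x[t])
        y[t + 1] = y[t] * (3.5 - 3.5 * y[t] - 0.2 * x[t])
    return x, y


def gaussian_ar_pair(n: int, seed: int, a: float = 0.5, c: float = 1.0,
                     sigma_eps: float = 1.0):
    """y(t+1) = a y(t) + c x(t) + eps with i.i.d. N(0,1) x and N(0,sigma) eps.

    Closed-form transfer entropy X->Y is 0.5 ln((c^2 + sigma^2)/sigma^2).
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    eps = rng.normal(scale=sigma_eps, size=n)
    y = np.zeros(n)
    for t in range(n - 1):
        y[t + 1] = a * y[t] + c * x[t] + eps[t]
    return x, y
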