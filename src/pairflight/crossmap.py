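"""Convergent cross mapping: delay embedding, simplex projection, library sweeps.

Cross mapping tests for directed coupling between two series by asking
whether the delay-embedded state space (shadow manifold) of one series can
reconstruct contemporaneous values of the other.  When X drives Y, X's
dynamics leave imprints on Y, so Y's shadow manifold recovers X well; the
reverse map stays poor.  Skill is the Pearson correlation between the true
and cross-mapped values, clipped at zero, and the evidence criterion is
convergence of skill as the library of embedded points grows.

Direction convention used throughout: ``C[A -> B]`` is the skill of
estimating series A from the shadow manifold of series B — the putative
cause A recovered from the putative effect B.  A high ``C[2 -> 1]``
therefore reads "agent 2 drives agent 1".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingConfig",
    "ShadowManifold",
    "CCMResult",
    "select_embedding_dim",
    "build_shadow_manifold",
    "cross_map_skill",
    "ccm_sweep",
    "assess_convergence",
]

CONVENTION = "C[A->B] = skill of estimating A from the shadow manifold of B"


class InsufficientDataError(ValueError):
    """Series too short for the requested embedding or library."""


@dataclass
class EmbeddingConfig:
    """Delay-embedding settings for simplex projection and cross mapping."""

    E: int = 2                       # embedding dimension
    tau: int = 1                     # delay between embedding coordinates
    E_grid: tuple = tuple(range(1, 11))
    tp: int = 1                      # simplex forecast horizon
    exclusion_radius: int = 0        # temporal neighbor exclusion (0 = self only)
    max_windows: int = 200           # library-window subsampling cap per L
    convergence_tol: float = 0.02

    def __post_init__(self) -> None:
        if self.E < 1 or self.tau < 1:
            raise ValueError("E and tau must be >= 1")


@dataclass
class ShadowManifold:
    """Delay vectors (x(t), x(t-tau), ..., x(t-(E-1)tau)) of one series.

    ``time_index[i]`` is the series index of the most recent coordinate of
    point i.  Points whose lag window would cross a concatenation boundary
    are omitted.
    """

    points: np.ndarray        # (m, E)
    time_index: np.ndarray    # (m,)
    E: int
    tau: int
    series_id: str = ""

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class CCMResult:
    """Cross-map skill over a library-size sweep for one direction."""

    direction: tuple[str, str]        # (cause_id, effect_id): estimate cause from effect's manifold
    convention: str
    E: int
    tau: int
    library_sizes: np.ndarray
    skills: np.ndarray                # mean clipped skill per library size
    skill_at_lmax: float
    n_windows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    convergence: str = ""


def _segment_of(segment_bounds, n: int) -> np.ndarray:
    """Segment id per sample index."""
    seg = np.zeros(n, dtype=int)
    if segment_bounds is not None:
        for i, b in enumerate(np.asarray(segment_bounds, dtype=int)):
            seg[b:] = i
    return seg


def build_shadow_manifold(
    series,
    E: int,
    tau: int = 1,
    segment_bounds=None,
    series_id: str = "",
) -> ShadowManifold:
    """Embed a series into E-dimensional delay vectors.

    With ``segment_bounds`` given (start index of each concatenated
    segment), points whose lag window spans two segments are dropped: a lag
    across unrelated flights is not a state of any dynamical system.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = len(x)
    if n <= (E - 1) * tau:
        raise InsufficientDataError(
            f"series length {n} too short for E={E}, tau={tau}")
    t = np.arange((E - 1) * tau, n)
    lags = np.arange(E) * tau
    pts = x[t[:, None] - lags[None, :]]     # column j = x(t - j*tau)
    if segment_bounds is not None:
        seg = _segment_of(segment_bounds, n)
        keep = seg[t] == seg[t - (E - 1) * tau]
        t, pts = t[keep], pts[keep]
    if len(t) == 0:
        raise InsufficientDataError("no valid embedded points")
    return ShadowManifold(points=pts, time_index=t, E=E, tau=tau, series_id=series_id)


def _simplex_weights(dist: np.ndarray) -> np.ndarray:
    """Exponential simplex weights u_i = exp(-d_i / d_1), normalized.

    If the nearest neighbor is at zero distance, weight collapses onto the
    zero-distance neighbors (the standard degenerate-tie rule).
    """
    d1 = dist[:, :1]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.exp(-dist / np.where(d1 > 0, d1, 1.0))
    zero_first = (d1 == 0).ravel()
    if zero_first.any():
        u[zero_first] = (dist[zero_first] == 0).astype(float)
    return u / u.sum(axis=1, keepdims=True)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _knn_excluding(
    tree: cKDTree,
    lib_times: np.ndarray,
    query_pts: np.ndarray,
    query_times: np.ndarray,
    k: int,
    exclusion_radius: int,
) -> tuple[np.ndarray, np.ndarray]:
    """k nearest library neighbors per query, excluding temporal self-matches."""
    # request extra neighbors to survive the exclusion, then filter
    extra = k + 1 + 2 * exclusion_radius
    extra = min(extra, len(lib_times))
    dist, idx = tree.query(query_pts, k=extra)
    if extra == 1:
        dist, idx = dist[:, None], idx[:, None]
    excluded = np.abs(lib_times[idx] - query_times[:, None]) <= exclusion_radius
    dist = np.where(excluded, np.inf, dist)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    rows = np.arange(len(query_pts))[:, None]
    out_d = dist[rows, order]
    out_i = idx[rows, order]
    if np.isinf(out_d).any():
        raise InsufficientDataError(
            f"fewer than {k} usable neighbors in library after exclusion")
    return out_d, out_i


def simplex_forecast_skill(
    series,
    E: int,
    config: EmbeddingConfig | None = None,
    segment_bounds=None,
) -> float:
    """One-step simplex-projection forecast skill of a series at dimension E.

    Each embedded point's value ``tp`` steps ahead is forecast as the
    weighted average of its E+1 nearest neighbors' futures (leave-self-out);
    skill is the Pearson correlation of forecasts against observations.
    """
    cfg = config or EmbeddingConfig()
    x = np.asarray(series, dtype=float).ravel()
    man = build_shadow_manifold(x, E, cfg.tau, segment_bounds)
    seg = _segment_of(segment_bounds, len(x))
    # forecast targets: t + tp must exist and stay within the segment
    ok = man.time_index + cfg.tp < len(x)
    ok &= seg[np.minimum(man.time_index + cfg.tp, len(x) - 1)] == seg[man.time_index]
    pts, times = man.points[ok], man.time_index[ok]
    if len(pts) < E + 3:
        raise InsufficientDataError(
            f"too few embedded points ({len(pts)}) for simplex at E={E}")
    tree = cKDTree(pts)
    dist, idx = _knn_excluding(tree, times, pts, times, E + 1, cfg.exclusion_radius)
    w = _simplex_weights(dist)
    forecast = (w * x[times[idx] + cfg.tp]).sum(axis=1)
    observed = x[times + cfg.tp]
    return _pearson(observed, forecast)


def select_embedding_dim(
    series,
    config: EmbeddingConfig | None = None,
    segment_bounds=None,
) -> int:
    """Pick the embedding dimension maximizing simplex forecast skill.

    Ties go to the smallest E.  If no E in the grid leaves at least 20
    embedded points, raises naming the largest feasible dimension.
    """
    cfg = config or EmbeddingConfig()
    x = np.asarray(series, dtype=float).ravel()
    feasible = [E for E in cfg.E_grid if len(x) - (E - 1) * cfg.tau - cfg.tp >= 20]
    if len(feasible) < len(cfg.E_grid):
        if not feasible:
            raise InsufficientDataError(
                f"series too short for any E in grid; max feasible E is "
                f"{max(1, (len(x) - 20 - cfg.tp) // cfg.tau + 1)}")
        logger.warning("E grid truncated to %s (series too short for larger E)", feasible)
    skills = np.array([simplex_forecast_skill(x, E, cfg, segment_bounds)
                       for E in feasible])
    best = int(feasible[int(np.argmax(skills))])
    if skills.max() < 0.1:
        logger.info("low forecast skill (max %.3f): series weakly forecastable", skills.max())
    return best


def cross_map_skill(
    manifold: ShadowManifold,
    target_series,
    library_index=None,
    query_index=None,
    exclusion_radius: int = 0,
    clip: bool = True,
) -> float:
    """Cross-map estimate of a target series from a shadow manifold.

    For each query point, the E+1 nearest library points (excluding itself)
    give exponential simplex weights; the estimate of the target at the
    query time is the weighted average of the target at the neighbors'
    times.  Skill is the Pearson correlation between target and estimate;
    negative correlations are clipped to zero (they carry no cross-map
    information), so the returned value lies in [0, 1].

    ``library_index`` / ``query_index`` select subsets of manifold points
    (positions into ``manifold.points``); both default to all points.
    """
    a = np.asarray(target_series, dtype=float).ravel()
    lib = np.arange(len(manifold)) if library_index is None else np.asarray(library_index)
    qry = np.arange(len(manifold)) if query_index is None else np.asarray(query_index)
    k = manifold.E + 1
    if len(lib) < k + 1:
        raise InsufficientDataError(
            f"library of {len(lib)} points cannot supply {k} neighbors")
    tree = cKDTree(manifold.points[lib])
    lib_times = manifold.time_index[lib]
    qry_times = manifold.time_index[qry]
    dist, idx = _knn_excluding(tree, lib_times, manifold.points[qry], qry_times,
                               k, exclusion_radius)
    w = _simplex_weights(dist)
    estimate = (w * a[lib_times[idx]]).sum(axis=1)
    r = _pearson(a[qry_times], estimate)
    return max(0.0, r) if clip else r


def default_library_grid(n_usable: int, E: int, n_sizes: int = 10) -> np.ndarray:
    """Log-spaced library sizes from max(20, 10 E) up to the usable length."""
    lo = max(20, 10 * E)
    if n_usable <= lo:
        return np.array([n_usable], dtype=int)
    grid = np.unique(np.round(np.geomspace(lo, n_usable, n_sizes)).astype(int))
    return grid


def ccm_sweep(
    series_a,
    series_b,
    L_grid=None,
    config: EmbeddingConfig | None = None,
    segment_bounds=None,
    seed: int = 0,
    id_a: str = "A",
    id_b: str = "B",
) -> tuple[CCMResult, CCMResult]:
    """Library-size convergence sweep for both cross-map directions.

    For each library size L, skill is averaged over sequential windows of L
    consecutive samples (within a segment); window count per segment is
    ``len - L + 1``, subsampled uniformly above ``config.max_windows``.  The
    headline value per direction is the mean skill at the largest L.
    Returns ``(C[A->B], C[B->A])`` in the cause-from-effect convention.
    """
    cfg = config or EmbeddingConfig()
    a = np.asarray(series_a, dtype=float).ravel()
    b = np.asarray(series_b, dtype=float).ravel()
    if len(a) != len(b):
        raise ValueError("series must be sample-aligned with equal lengths")
    results = []
    for cause, effect, cid, eid in ((a, b, id_a, id_b), (b, a, id_b, id_a)):
        E = select_embedding_dim(effect, cfg, segment_bounds)
        man = build_shadow_manifold(effect, E, cfg.tau, segment_bounds,
                                    series_id=eid)
        grid = (default_library_grid(len(man), E) if L_grid is None
                else np.asarray(sorted(set(int(v) for v in L_grid))))
        rng = np.random.default_rng(seed)
        skills, counts, kept_sizes = [], [], []
        min_L = (E - 1) * cfg.tau + E + 2   # window must hold E+2 embedded points
        for L in grid:
            if L < min_L:
                warnings.warn(f"library size {L} below embedding minimum {min_L}; skipped")
                continue
            windows = _window_starts(len(a), int(L))
            if len(windows) == 0:
                warnings.warn(f"no window of length {L} fits the series; skipped")
                continue
            if len(windows) > cfg.max_windows:
                windows = rng.choice(windows, size=cfg.max_windows, replace=False)
                windows.sort()
            vals = []
            for s in windows:
                in_win = (man.time_index >= s) & (man.time_index < s + L)
                pos = np.flatnonzero(in_win)
                if len(pos) < E + 2:
                    continue
                try:
                    vals.append(cross_map_skill(man, cause, library_index=pos,
                                                query_index=pos,
                                                exclusion_radius=cfg.exclusion_radius))
                except InsufficientDataError:
                    continue
            if not vals:
                warnings.warn(f"library size {L}: no usable windows; skipped")
                continue
            skills.append(float(np.mean(vals)))
            counts.append(len(vals))
            kept_sizes.append(int(L))
        if not skills:
            raise InsufficientDataError("no usable library size in the sweep")
        res = CCMResult(
            direction=(cid, eid),
            convention=CONVENTION,
            E=E,
            tau=cfg.tau,
            library_sizes=np.asarray(kept_sizes),
            skills=np.asarray(skills),
            skill_at_lmax=skills[-1],
            n_windows=np.asarray(counts),
        )
        res.convergence = assess_convergence(res, tol=cfg.convergence_tol)
        results.append(res)
    return results[0], results[1]


def _window_starts(n: int, L: int) -> np.ndarray:
    """Start indices of all length-L sequential windows: 0 .. n-L.

    Windows range over the whole (possibly concatenated) series; a window
    only selects which manifold points populate the library, and points
    whose lags cross a segment join were never embedded, so no invalid
    state can enter a library.
    """
    if L > n:
        return np.array([], dtype=int)
    return np.arange(0, n - L + 1)


def assess_convergence(result: CCMResult, tol: float = 0.02) -> str:
    """Classify a library sweep as converged, increasing, or flat.

    Converged: the last two mean skills differ by less than ``tol`` and the
    whole trend is nondecreasing within ``tol``.  Increasing: skill is still
    rising by at least ``tol`` at the largest library.  Flat: anything else
    (e.g. non-monotone or decreasing tails).
    """
    skills = np.asarray(result.skills, dtype=float)
    if len(skills) < 2:
        return "flat"
    diffs = np.diff(skills)
    tail = skills[-1] - skills[-2]
    nondecreasing = bool(np.all(diffs >= -tol))
    if abs(tail) < tol and nondecreasing:
        return "converged"
    if tail >= tol:
        return "increasing"
    return "flat"
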