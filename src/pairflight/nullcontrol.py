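"""Shuffled-partner control condition and significance verdicts.

Two agents flying through the same space show similar trajectories even
without any interaction.  To separate direct coupling from that shared-
environment similarity, the control condition scrambles partners: each
agent-1 series is paired with an agent-2 series from a *different* pair (a
derangement over pair ids), the longer member of each pseudo-pair is
tail-truncated to match the shorter, and the full ensemble pipeline
(concatenate, normalize, estimate) is re-run.  Repeating this for many
derangements yields a null distribution whose empirical 95% interval
calibrates the observed coupling value: only values above the interval's
upper edge count as significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .kinematics import KinematicSeries, PairRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ShuffleScheme",
    "SignificanceResult",
    "DerangementError",
    "scramble_partners",
    "truncate_to_match",
    "null_distribution",
    "significance",
]


class DerangementError(ValueError):
    """No derangement exists (group of fewer than 2 pairs)."""


@dataclass
class ShuffleScheme:
    """Settings of the shuffled-partner null."""

    n_shuffles: int = 100
    seed: int = 0
    max_retries: int = 10    # per-shuffle resampling budget on metric failure

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")


@dataclass
class SignificanceResult:
    """An observed coupling value against its shuffled-partner null."""

    metric: str
    direction: tuple[str, str]
    observed: float
    null_values: np.ndarray
    ci_low: float
    ci_high: float
    verdict: str                      # {"significant", "insignificant"}
    level: float = 0.95

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "direction": list(self.direction),
            "observed": self.observed,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "verdict": self.verdict,
            "n_null": int(len(self.null_values)),
            "level": self.level,
        }


def random_derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random derangement of range(n) by rejection sampling."""
    if n < 2:
        raise DerangementError("a derangement needs at least 2 elements")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def truncate_to_match(series_a, series_b):
    """Trim the longer of two series (tail) so both have equal length.

    Works on :class:`KinematicSeries` and on plain arrays; leading samples
    are kept.
    """
    n = min(len(series_a), len(series_b))
    if n < 1:
        raise ValueError("both series must be nonempty")

    def _cut(s):
        if isinstance(s, KinematicSeries):
            return s.slice(0, n)
        return np.asarray(s)[:n]

    return _cut(series_a), _cut(series_b)


def scramble_partners(
    group: Sequence[PairRecord],
    seed: int | np.random.Generator = 0,
) -> list[PairRecord]:
    """One shuffled-partner pseudo-group: agent 1 of pair i meets agent 2 of pair d(i).

    ``d`` is a uniformly sampled derangement, so no agent is paired with the
    partner it actually flew with.  Each pseudo-pair is tail-truncated to
    the shorter member's length.
    """
    if len(group) < 2:
        raise DerangementError(
            f"group of {len(group)} pair(s): partner scrambling needs >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = random_derangement(len(group), rng)
    out = []
    for i, j in enumerate(d):
        s1, s2 = truncate_to_match(group[i].series_1, group[j].series_2)
        out.append(PairRecord(
            pair_id=f"{group[i].pair_id}x{group[j].pair_id}",
            series_1=s1,
            series_2=s2,
            overlap=(float(s1.times[0]), float(s1.times[-1])),
            behavior_label=group[i].behavior_label,
        ))
    return out


def null_distribution(
    metric: Callable[[Sequence[PairRecord]], float],
    group: Sequence[PairRecord],
    scheme: ShuffleScheme | None = None,
) -> np.ndarray:
    """Metric values over ``n_shuffles`` independent partner scrambles.

    ``metric`` receives a scrambled pseudo-group and must re-run the same
    preprocessing (concatenate, normalize) and estimator as the observed
    value, so the null experiences identical processing.  A shuffle on
    which the metric fails is logged and resampled, up to
    ``scheme.max_retries`` attempts.
    """
    scheme = scheme or ShuffleScheme()
    rng = np.random.default_rng(scheme.seed)
    values = np.empty(scheme.n_shuffles)
    for s in range(scheme.n_shuffles):
        for attempt in range(scheme.max_retries + 1):
            pseudo = scramble_partners(group, rng)
            try:
                values[s] = float(metric(pseudo))
                break
            except Exception as exc:  # noqa: BLE001 - metric is caller-supplied
                logger.warning("shuffle %d attempt %d failed: %s", s, attempt, exc)
        else:
            raise RuntimeError(
                f"shuffle {s}: metric failed {scheme.max_retries + 1} times")
    return values


def significance(
    observed: float,
    null_values,
    level: float = 0.95,
    metric: str = "",
    direction: tuple[str, str] = ("", ""),
    method: str = "percentile",
) -> SignificanceResult:
    """Verdict of an observed value against its shuffle null.

    The default interval is the empirical percentile interval (2.5%/97.5%
    at level 0.95); ``method="normal"`` uses mean +/- z * sd instead.  The
    verdict is ``significant`` only if the observed value strictly exceeds
    the interval's upper edge; values inside or below the interval are
    ``insignificant`` (conservative).
    """
    null = np.asarray(null_values, dtype=float)
    if len(null) == 0:
        raise ValueError("null_values must be nonempty")
    alpha = 1.0 - level
    if method == "percentile":
        lo, hi = np.percentile(null, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    elif method == "normal":
        from scipy.stats import norm
        z = norm.ppf(1 - alpha / 2)
        lo, hi = null.mean() - z * null.std(ddof=1), null.mean() + z * null.std(ddof=1)
    else:
        raise ValueError(f"unknown interval method {method!r}")
    verdict = "significant" if observed > hi else "insignificant"
    return SignificanceResult(
        metric=metric, direction=direction, observed=float(observed),
        null_values=null, ci_low=float(lo), ci_high=float(hi),
        verdict=verdict, level=level,
    )
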