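"""Group-level orchestration: TE + CCM with controls, and leadership inference.

For a group of pairs (all pairs, or a behavioral subgroup) the pipeline

1. concatenates the co-presence curvature series of agent 1 and agent 2
   across pairs and normalizes the ensembles;
2. estimates transfer entropy in both directions (KSG, with an optional
   neighbor-count sweep) and cross-map skill at the maximum library size;
3. rebuilds everything on shuffled-partner pseudo-groups to get a null
   distribution per quantity, and verdicts each observed value against the
   empirical 95% interval of its null;
4. combines the verdicts into a leadership call: agent i leads only when
   transfer entropy is significant i->j and insignificant j->i, AND the
   cross-map skill recovering i from j's manifold is significant and
   dominates the reverse direction by a margin delta.  Bidirectional
   information flow always reads as "no leadership".
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import crossmap, infotransfer, kinematics, nullcontrol
from .kinematics import EnsembleSeries, PairRecord
from .nullcontrol import ShuffleScheme, SignificanceResult, scramble_partners

logger = logging.getLogger(__name__)

__all__ = [
    "GroupSpec",
    "PipelineConfig",
    "LeadershipVerdict",
    "run_group_analysis",
    "infer_leadership",
    "summarize",
]

GROUP_LABELS = ("all", "NM", "MC", "MT")


@dataclass
class GroupSpec:
    """A named group of pairs analyzed as one ensemble."""

    label: str                       # one of GROUP_LABELS
    pair_ids: tuple[str, ...]
    variable: str = "curvature"

    def __post_init__(self) -> None:
        if self.label not in GROUP_LABELS:
            raise ValueError(f"label must be one of {GROUP_LABELS}")
        if not self.pair_ids:
            raise ValueError("group must have at least one pair")


@dataclass
class PipelineConfig:
    """Tunable parameters of the full analysis."""

    resample_rate: float = 180.0
    K: int = 8                        # KSG neighbor count for the headline TE
    k_grid: tuple = ()                # optional sweep, e.g. tuple(range(2, 16))
    e_grid: tuple = tuple(range(1, 11))
    tau: int = 1
    l_grid: tuple | None = None       # None -> auto log-spaced grid
    n_shuffles: int = 100
    delta: float = 0.2                # cross-map dominance margin for "much larger"
    normalization_scope: str = "global"
    velocity_te: bool = False         # also run multivariate TE on 3D velocity
    ccm_max_windows: int = 200
    seed: int = 0


@dataclass
class LeadershipVerdict:
    """Combined decision for one group."""

    group: str
    te_sig_1to2: str
    te_sig_2to1: str
    ccm_1to2: float
    ccm_2to1: float
    ccm_sig_1to2: str
    ccm_sig_2to1: str
    delta: float
    leadership: str                   # {"none", "agent_1", "agent_2"}
    rationale: str = ""


def _seed_streams(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from a master seed."""
    return [int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


def _ensembles(group: Sequence[PairRecord], variable: str, scope: str):
    ens1, ens2 = kinematics.concatenate_ensemble(group, variable)
    return kinematics.normalize(ens1, scope), kinematics.normalize(ens2, scope)


def _te_both_directions(ens1: EnsembleSeries, ens2: EnsembleSeries,
                        K: int, noise_seed: int) -> dict[str, float]:
    mask = ens1.boundary_mask()
    t12 = infotransfer.transfer_entropy_ksg(
        ens1.values, ens2.values, K=K, boundary_mask=mask,
        noise_seed=noise_seed, source_id="1", dest_id="2")
    t21 = infotransfer.transfer_entropy_ksg(
        ens2.values, ens1.values, K=K, boundary_mask=mask,
        noise_seed=noise_seed, source_id="2", dest_id="1")
    return {"1to2": t12.value, "2to1": t21.value, "n_effective": t12.n_effective}


def _ccm_at_lmax(ens1: EnsembleSeries, ens2: EnsembleSeries,
                 config: PipelineConfig,
                 fixed_E: dict[str, int] | None = None) -> dict[str, float]:
    """Cross-map skill at the maximum library (single full-library window).

    ``fixed_E`` maps direction label to an embedding dimension selected
    elsewhere; the control condition reuses the dimensions selected on the
    observed ensembles so observed and null runs are compared like for like
    (E is an analysis hyperparameter, not a statistic of the data under test).
    """
    cfg = crossmap.EmbeddingConfig(E_grid=config.e_grid, tau=config.tau,
                                   max_windows=config.ccm_max_windows)
    out = {}
    for cause, effect, label in ((ens1, ens2, "1to2"), (ens2, ens1, "2to1")):
        if fixed_E is None:
            E = crossmap.select_embedding_dim(effect.values, cfg, effect.segment_bounds)
        else:
            E = fixed_E[label]
        man = crossmap.build_shadow_manifold(effect.values, E, cfg.tau,
                                             effect.segment_bounds)
        out[label] = crossmap.cross_map_skill(man, cause.values)
        out[f"E_{label}"] = E
    return out


def _null_table(group, fn, scheme: ShuffleScheme) -> dict[str, np.ndarray]:
    """Per-shuffle dict-valued metric -> dict of null arrays."""
    rng = np.random.default_rng(scheme.seed)
    rows = []
    for s in range(scheme.n_shuffles):
        for attempt in range(scheme.max_retries + 1):
            pseudo = scramble_partners(group, rng)
            try:
                rows.append(fn(pseudo))
                break
            except Exception as exc:  # noqa: BLE001
                logger.warning("shuffle %d attempt %d failed: %s", s, attempt, exc)
        else:
            raise RuntimeError(f"shuffle {s}: metric kept failing")
    return {k: np.array([r[k] for r in rows]) for k in rows[0]
            if not k.startswith("E_") and k != "n_effective"}


def run_group_analysis(
    group: Sequence[PairRecord],
    label: str = "all",
    config: PipelineConfig | None = None,
) -> dict:
    """Full directed-coupling analysis of one group; returns a result bundle.

    The bundle is a JSON-serializable dict with, per direction, the TE
    estimate(s), cross-map skill at maximum library size, the library-size
    convergence sweep, shuffled-partner confidence intervals, and the
    leadership verdict.  Deterministic given the config seed.
    """
    cfg = config or PipelineConfig()
    seeds = _seed_streams(cfg.seed, 6)
    group = [kinematics.extract_overlap(p) for p in group]
    ens1, ens2 = _ensembles(group, "curvature", cfg.normalization_scope)

    bundle: dict = {
        "group": label,
        "n_pairs": len(group),
        "ensemble_length": len(ens1),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
    }

    # --- transfer entropy on curvature -----------------------------------
    te_obs = _te_both_directions(ens1, ens2, cfg.K, noise_seed=seeds[0])
    te_scheme = ShuffleScheme(n_shuffles=cfg.n_shuffles, seed=seeds[1])
    te_null = _null_table(
        group,
        lambda g: _te_both_directions(*_ensembles(g, "curvature", cfg.normalization_scope),
                                      cfg.K, noise_seed=seeds[0]),
        te_scheme,
    )
    te_sig = {
        d: nullcontrol.significance(te_obs[d], te_null[d], metric="te_curvature",
                                    direction=tuple(d.split("to")))
        for d in ("1to2", "2to1")
    }
    bundle["te_curvature"] = {
        "K": cfg.K,
        "n_effective": te_obs["n_effective"],
        "1to2": te_sig["1to2"].to_dict(),
        "2to1": te_sig["2to1"].to_dict(),
    }

    # optional neighbor-count sweep with per-K control intervals
    if cfg.k_grid:
        sweep = {"K_values": list(cfg.k_grid), "1to2": [], "2to1": []}
        nulls_per_k = {
            K: _null_table(
                group,
                lambda g, K=K: _te_both_directions(
                    *_ensembles(g, "curvature", cfg.normalization_scope),
                    K, noise_seed=seeds[0]),
                ShuffleScheme(n_shuffles=cfg.n_shuffles, seed=seeds[2]),
            )
            for K in cfg.k_grid
        }
        for K in cfg.k_grid:
            obs = _te_both_directions(ens1, ens2, int(K), noise_seed=seeds[0])
            for d in ("1to2", "2to1"):
                sig = nullcontrol.significance(obs[d], nulls_per_k[K][d],
                                               metric="te_curvature",
                                               direction=tuple(d.split("to")))
                sweep[d].append(sig.to_dict())
        bundle["te_curvature_knn_sweep"] = sweep

    # --- cross mapping on curvature --------------------------------------
    ccm_cfg = crossmap.EmbeddingConfig(E_grid=cfg.e_grid, tau=cfg.tau,
                                       max_windows=cfg.ccm_max_windows)
    res_12, res_21 = crossmap.ccm_sweep(
        ens1.values, ens2.values, L_grid=cfg.l_grid, config=ccm_cfg,
        segment_bounds=ens1.segment_bounds, seed=seeds[3], id_a="1", id_b="2")
    ccm_obs = {"1to2": res_12.skill_at_lmax, "2to1": res_21.skill_at_lmax}
    ccm_scheme = ShuffleScheme(n_shuffles=cfg.n_shuffles, seed=seeds[4])
    fixed_E = {"1to2": res_12.E, "2to1": res_21.E}
    ccm_null = _null_table(
        group,
        lambda g: _ccm_at_lmax(*_ensembles(g, "curvature", cfg.normalization_scope),
                               cfg, fixed_E=fixed_E),
        ccm_scheme,
    )
    ccm_sig = {
        d: nullcontrol.significance(ccm_obs[d], ccm_null[d], metric="ccm_curvature",
                                    direction=tuple(d.split("to")))
        for d in ("1to2", "2to1")
    }
    bundle["ccm_curvature"] = {
        "convention": crossmap.CONVENTION,
        "1to2": {**ccm_sig["1to2"].to_dict(), "E": res_12.E,
                 "library_sizes": res_12.library_sizes.tolist(),
                 "skills": res_12.skills.tolist(),
                 "convergence": res_12.convergence},
        "2to1": {**ccm_sig["2to1"].to_dict(), "E": res_21.E,
                 "library_sizes": res_21.library_sizes.tolist(),
                 "skills": res_21.skills.tolist(),
                 "convergence": res_21.convergence},
    }

    # --- optional multivariate TE on 3D velocity --------------------------
    if cfg.velocity_te:
        v1, v2 = _ensembles(group, "velocity", cfg.normalization_scope)
        vte_obs = _te_both_directions(v1, v2, cfg.K, noise_seed=seeds[0])
        vte_null = _null_table(
            group,
            lambda g: _te_both_directions(*_ensembles(g, "velocity", cfg.normalization_scope),
                                          cfg.K, noise_seed=seeds[0]),
            ShuffleScheme(n_shuffles=cfg.n_shuffles, seed=seeds[5]),
        )
        bundle["te_velocity"] = {
            "K": cfg.K,
            "1to2": nullcontrol.significance(vte_obs["1to2"], vte_null["1to2"],
                                             metric="te_velocity",
                                             direction=("1", "2")).to_dict(),
            "2to1": nullcontrol.significance(vte_obs["2to1"], vte_null["2to1"],
                                             metric="te_velocity",
                                             direction=("2", "1")).to_dict(),
        }

    verdict = infer_leadership(
        te_sig_1to2=te_sig["1to2"], te_sig_2to1=te_sig["2to1"],
        ccm_1to2=ccm_obs["1to2"], ccm_2to1=ccm_obs["2to1"],
        ccm_sig_1to2=ccm_sig["1to2"], ccm_sig_2to1=ccm_sig["2to1"],
        delta=cfg.delta, group=label,
    )
    bundle["leadership"] = asdict(verdict)
    return bundle


def infer_leadership(
    te_sig_1to2: SignificanceResult | str,
    te_sig_2to1: SignificanceResult | str,
    ccm_1to2: float,
    ccm_2to1: float,
    ccm_sig_1to2: SignificanceResult | str | None,
    ccm_sig_2to1: SignificanceResult | str | None,
    delta: float = 0.2,
    group: str = "",
) -> LeadershipVerdict:
    """Combine TE and CCM verdicts into a leadership call.

    ``agent_i`` leads iff TE is significant i->j and insignificant j->i, and
    the cross-map skill C[i->j] is significant and exceeds C[j->i] by at
    least ``delta``.  Bidirectional TE significance, or a missing CCM
    control, yields ``none``.
    """

    def _v(x) -> str:
        if x is None:
            return "missing"
        return x if isinstance(x, str) else x.verdict

    t12, t21 = _v(te_sig_1to2), _v(te_sig_2to1)
    c12, c21 = _v(ccm_sig_1to2), _v(ccm_sig_2to1)
    leadership, why = "none", ""
    if "missing" in (c12, c21):
        why = "missing cross-map control; verdict downgraded to none"
    elif t12 == "significant" and t21 == "significant":
        why = "bidirectional information flow: no directed causal relationship"
    elif (t12 == "significant" and t21 == "insignificant"
          and c12 == "significant" and ccm_1to2 - ccm_2to1 >= delta):
        leadership = "agent_1"
        why = (f"unidirectional TE 1->2 and dominant cross-map skill "
               f"C[1->2]={ccm_1to2:.3f} >= C[2->1]={ccm_2to1:.3f} + {delta}")
    elif (t21 == "significant" and t12 == "insignificant"
          and c21 == "significant" and ccm_2to1 - ccm_1to2 >= delta):
        leadership = "agent_2"
        why = (f"unidirectional TE 2->1 and dominant cross-map skill "
               f"C[2->1]={ccm_2to1:.3f} >= C[1->2]={ccm_1to2:.3f} + {delta}")
    else:
        why = "no consistent unidirectional evidence from both methods"
    return LeadershipVerdict(
        group=group, te_sig_1to2=t12, te_sig_2to1=t21,
        ccm_1to2=float(ccm_1to2), ccm_2to1=float(ccm_2to1),
        ccm_sig_1to2=c12, ccm_sig_2to1=c21,
        delta=delta, leadership=leadership, rationale=why,
    )


def summarize(bundles: Sequence[dict]) -> pd.DataFrame:
    """One row per analyzed group, mirroring the headline results table."""
    if not bundles:
        raise ValueError("no results to summarize")
    rows = []
    for b in bundles:
        lead = b["leadership"]
        row = {
            "group": b["group"],
            "n_pairs": b["n_pairs"],
            "ensemble_length": b["ensemble_length"],
            "te_1to2": lead["te_sig_1to2"],
            "te_2to1": lead["te_sig_2to1"],
            "ccm_1to2": lead["ccm_1to2"],
            "ccm_2to1": lead["ccm_2to1"],
            "ccm_sig_1to2": lead["ccm_sig_1to2"],
            "ccm_sig_2to1": lead["ccm_sig_2to1"],
        }
        if "te_velocity" in b:
            row["te_velocity_1to2"] = b["te_velocity"]["1to2"]["verdict"]
            row["te_velocity_2to1"] = b["te_velocity"]["2to1"]["verdict"]
        else:
            row["te_velocity_1to2"] = "not run"
            row["te_velocity_2to1"] = "not run"
        row["leadership"] = lead["leadership"]
        rows.append(row)
    return pd.DataFrame(rows)


def bundle_to_json(bundle: dict) -> str:
    """Canonical JSON rendering (sorted keys) for reproducibility checks."""
    return json.dumps(bundle, sort_keys=True, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
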