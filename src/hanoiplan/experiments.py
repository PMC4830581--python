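"""Scripted reproductions of the four simulation studies.

Each experiment runs the full decision procedure under fixed seeds and
returns an :class:`ExperimentReport` holding the per-run records and the
aggregate statistics behind the reference figures:

1. *Community structure* — choosing between the two six-move routes from
   S11 to S13 (one crossing a single community boundary, one crossing two);
   reports the per-round vote share of each route family.
2. *Nested structure* — deterministic: the prior probability of traversing
   the level-1/2/3 bottleneck edges.
3. *Counterintuitive movements* — S27 to S20 under mixtures of look-ahead
   and perceptual particles; reports the probability of selecting the
   seven-move plan, the subgoal-count histogram, and per-step subgoal
   distribution snapshots for a representative particle.
4. *Lesion simulation* — 85/15 strategy mixtures ("control" vs "lesioned")
   on three problems of increasing difficulty, all with goal S20.

Success throughout is defined as the selected solution's realized path
length equalling the breadth-first shortest-path length.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .decision import DecisionConfig, DecisionResult, decide
from .planner import GraphArrays, plan
from .priors import PriorModel, clamp_goal, perceptual_prior_vector
from .state_space import ProblemGraph

__all__ = [
    "ExperimentReport",
    "W1_PATH",
    "W2_PATH",
    "classify_route",
    "exp_community",
    "exp_nested",
    "exp_counterintuitive",
    "exp_lesion",
    "LESION_PROBLEMS",
]

#: The two six-move solutions of the community-structure problem.
W1_PATH = ("S11", "S14", "S18", "S24", "S23", "S17", "S13")
W2_PATH = ("S11", "S9", "S8", "S7", "S6", "S10", "S13")

#: The three lesion-study problems (start states; common goal S20):
#: easy (3 moves), intermediate (7 moves, one bottleneck), hard (7 moves,
#: one bottleneck plus counterintuitive moves away from the goal).
LESION_PROBLEMS = {"P1": "S13", "P2": "S27", "P3": "S9"}


@dataclass
class ExperimentReport:
    """Per-run records plus aggregates; aggregates are recomputable."""

    experiment: str
    runs: pd.DataFrame
    aggregates: dict = field(default_factory=dict)
    series: dict[str, pd.DataFrame] = field(default_factory=dict)


def _edge_in(trace: Sequence[str], u: str, v: str) -> bool:
    return any(
        (a == u and b == v) or (a == v and b == u)
        for a, b in zip(trace, trace[1:])
    )


def classify_route(trace: Sequence[str]) -> str:
    """Classify a S11-to-S13 solution by the community boundaries it crosses.

    ``w1`` crosses only the deep bottleneck S23-S24; ``w2`` crosses the two
    bottlenecks S9-S11 and S6-S10 through the third cluster.  Anything
    else (or a mixture) is ``other``.
    """
    via_top = _edge_in(trace, "S9", "S11") and _edge_in(trace, "S6", "S10")
    via_low = _edge_in(trace, "S23", "S24")
    if via_low and not via_top:
        return "w1"
    if via_top and not via_low:
        return "w2"
    return "other"


def _route_shares(res: DecisionResult, round_index: int) -> dict[str, float]:
    idx = min(round_index, len(res.theta_trajectory) - 1)
    theta = res.theta_trajectory[idx]
    shares = {"w1": 0.0, "w2": 0.0, "other": 0.0}
    for sol, score in theta.items():
        shares[classify_route(sol)] += score
    return shares


def exp_community(
    g: ProblemGraph,
    model: PriorModel,
    cfg: DecisionConfig,
    seeds: Sequence[int],
    arrays: GraphArrays | None = None,
) -> ExperimentReport:
    """Community-structure study: decide between the two S11-to-S13 routes."""
    arrays = arrays or GraphArrays(g)
    records = []
    theta_rows = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        res = decide(g, model, "S11", "S13", cfg, rng, arrays)
        shares4 = _route_shares(res, 3)
        final = _route_shares(res, len(res.theta_trajectory) - 1)
        records.append(
            {
                "seed": seed,
                "winner_class": classify_route(res.winner) if res.winner else "none",
                "winner_steps": res.winner_steps,
                "rounds": res.rounds,
                "w1_share_round4": shares4["w1"],
                "w2_share_round4": shares4["w2"],
                "w1_share_final": final["w1"],
                "w2_share_final": final["w2"],
            }
        )
        for r in range(len(res.theta_trajectory)):
            sh = _route_shares(res, r)
            theta_rows.append({"seed": seed, "round": r + 1, **sh})
    runs = pd.DataFrame(records)
    wins = Counter(runs["winner_class"])
    report = ExperimentReport(
        experiment="community",
        runs=runs,
        aggregates={
            "w1_share_round4_mean": float(runs["w1_share_round4"].mean()),
            "w1_win_fraction": wins["w1"] / len(runs),
            "w2_win_fraction": wins["w2"] / len(runs),
            "w1_path_length": len(W1_PATH) - 1,
            "w2_path_length": len(W2_PATH) - 1,
        },
        series={"theta": pd.DataFrame(theta_rows)},
    )
    return report


#: The three nested bottleneck edges, shallowest first.
NESTED_EDGES = [("S2", "S3"), ("S7", "S8"), ("S23", "S24")]


def exp_nested(model: PriorModel) -> ExperimentReport:
    """Nested-structure study: traversal products of the bottleneck edges.

    Deterministic: reports ``P(to | from) * P(from)`` for the level-1,
    level-2 and level-3 bottleneck edges and whether crossing a deeper
    boundary is strictly less probable a priori.
    """
    rows = [
        {
            "level": level,
            "edge": f"{u}-{v}",
            "product": model.traversal_product(u, v),
        }
        for level, (u, v) in enumerate(NESTED_EDGES, start=1)
    ]
    runs = pd.DataFrame(rows)
    vals = list(runs["product"])
    return ExperimentReport(
        experiment="nested",
        runs=runs,
        aggregates={
            "ordering_level1_gt_level2": vals[0] > vals[1],
            "ordering_level2_gt_level3": vals[1] > vals[2],
            "products": vals,
        },
    )


def exp_counterintuitive(
    g: ProblemGraph,
    model: PriorModel,
    cfg: DecisionConfig,
    mixtures: Sequence[float],
    seeds: Sequence[int],
    arrays: GraphArrays | None = None,
    snapshot_seed: int | None = None,
) -> ExperimentReport:
    """Counterintuitive-movement study: S27 to S20 under strategy mixtures.

    For each mixture level (fraction of look-ahead particles) the decision
    procedure is repeated over the seeds; reported per level: probability
    that the selected solution is the seven-move plan, the distribution of
    selected solution lengths, and the subgoal-count histogram of the
    successful particles.  Intermediate mixtures run without resampling.
    """
    arrays = arrays or GraphArrays(g)
    shortest = g.shortest_path_length("S27", "S20")
    records = []
    subgoal_rows = []
    for mix in mixtures:
        for seed in seeds:
            rng = np.random.default_rng(seed)
            mcfg = DecisionConfig(
                n_particles=cfg.n_particles,
                max_resamplings=cfg.max_resamplings,
                decision_threshold=cfg.decision_threshold,
                g_res=cfg.g_res,
                mixture_lookahead=mix,
                plan=cfg.plan,
            )
            res = decide(g, model, "S27", "S20", mcfg, rng, arrays)
            n_subgoals = Counter()
            for b in res.batches:
                for r in b:
                    if r.reached_goal:
                        n_subgoals[len(r.seq)] += 1
            records.append(
                {
                    "mixture_lookahead": mix,
                    "seed": seed,
                    "winner_steps": res.winner_steps,
                    "found_shortest": res.winner_steps == shortest,
                    "rounds": res.rounds,
                }
            )
            for k, c in sorted(n_subgoals.items()):
                subgoal_rows.append(
                    {"mixture_lookahead": mix, "seed": seed,
                     "n_subgoals": k, "count": c}
                )
    runs = pd.DataFrame(records)
    per_mix = (
        runs.groupby("mixture_lookahead")
        .agg(
            success_probability=("found_shortest", "mean"),
            modal_steps=("winner_steps", lambda s: _modal_steps(s)),
        )
        .reset_index()
    )

    series = {
        "per_mixture": per_mix,
        "subgoal_histogram": pd.DataFrame(subgoal_rows),
    }
    if snapshot_seed is not None:
        series["sg_snapshots"] = _representative_snapshots(
            g, model, cfg, arrays, snapshot_seed
        )
    pure = {
        float(row["mixture_lookahead"]): row
        for _, row in per_mix.iterrows()
    }
    return ExperimentReport(
        experiment="counterintuitive",
        runs=runs,
        aggregates={
            "shortest_steps": shortest,
            "modal_steps_lookahead": int(pure[1.0]["modal_steps"]) if 1.0 in pure else None,
            "modal_steps_perceptual": int(pure[0.0]["modal_steps"]) if 0.0 in pure else None,
            "success_by_mixture": {
                float(r["mixture_lookahead"]): float(r["success_probability"])
                for _, r in per_mix.iterrows()
            },
        },
        series=series,
    )


def _modal_steps(steps: pd.Series) -> int:
    """Modal selected-solution length; ties break toward fewer moves."""
    counts = Counter(int(s) for s in steps.dropna())
    if not counts:
        return -1
    return min(counts, key=lambda k: (-counts[k], k))


def _representative_snapshots(g, model, cfg, arrays, seed) -> pd.DataFrame:
    """Per-step subgoal-distribution snapshots of one successful particle."""
    rng = np.random.default_rng(seed)
    clamped = clamp_goal(model.prior, model.index("S20"))
    for _ in range(200):
        res = plan(
            g, model, "S27", "S20", clamped, cfg.plan, rng, arrays,
            record_snapshots=True,
        )
        if res.reached_goal:
            rows = []
            for t, snap in enumerate(res.prior_snapshots, start=1):
                for s, p in zip(model.order, snap):
                    rows.append({"step": t, "state": s, "p_sg": float(p)})
            return pd.DataFrame(rows)
    return pd.DataFrame(columns=["step", "state", "p_sg"])


def exp_lesion(
    g: ProblemGraph,
    model: PriorModel,
    cfg: DecisionConfig,
    seeds: Sequence[int],
    arrays: GraphArrays | None = None,
) -> ExperimentReport:
    """Lesion study: 85/15 strategy mixtures on three graded problems.

    The simulated control group runs 85% look-ahead particles, the
    simulated lesioned group 85% perceptual.  Reports per group and
    problem the success-rate mean and variance, the number of distinct
    solutions receiving votes, and the vote mass of the most-voted
    solution.
    """
    arrays = arrays or GraphArrays(g)
    groups = {"control": 0.85, "lesioned": 0.15}
    records = []
    for pname, s0 in LESION_PROBLEMS.items():
        shortest = g.shortest_path_length(s0, "S20")
        for gname, mix in groups.items():
            for seed in seeds:
                rng = np.random.default_rng(seed)
                mcfg = DecisionConfig(
                    n_particles=cfg.n_particles,
                    max_resamplings=cfg.max_resamplings,
                    decision_threshold=cfg.decision_threshold,
                    g_res=cfg.g_res,
                    mixture_lookahead=mix,
                    plan=cfg.plan,
                )
                res = decide(g, model, s0, "S20", mcfg, rng, arrays)
                records.append(
                    {
                        "problem": pname,
                        "group": gname,
                        "seed": seed,
                        "shortest": shortest,
                        "winner_steps": res.winner_steps,
                        "success": res.winner_steps == shortest,
                        "n_solutions": len(res.votes.scores),
                        "top_vote": res.votes.max_score,
                    }
                )
    runs = pd.DataFrame(records)
    agg = (
        runs.groupby(["problem", "group"])
        .agg(
            success_mean=("success", "mean"),
            success_var=("success", "var"),
            n_solutions_mean=("n_solutions", "mean"),
            top_vote_mean=("top_vote", "mean"),
        )
        .reset_index()
    )
    return ExperimentReport(
        experiment="lesion",
        runs=runs,
        aggregates={
            (r["problem"], r["group"]): {
                "success_mean": float(r["success_mean"]),
                "success_var": float(r["success_var"]),
                "n_solutions_mean": float(r["n_solutions_mean"]),
                "top_vote_mean": float(r["top_vote_mean"]),
            }
            for _, r in agg.iterrows()
        },
        series={"by_group": agg},
    )
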