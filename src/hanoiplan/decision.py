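"""Plan selection by Bayesian vote accumulation over particle ensembles.

The inner inference (:func:`hanoiplan.planner.plan`) is stochastic, so
repeated runs propose different solutions.  The outer procedure resolves
this by an accumulation-to-bound process over at most ``R`` resampling
rounds: each round launches up to ``K`` particles (stopping early once a
fraction ``G_res`` of the ensemble reached the goal), pools the successful
particles by the solution they produced, multiplies each solution's
posterior score ``theta_h`` by the fraction of particles producing it
(Bayes rule with the batch as evidence), and renormalizes.  The procedure
stops when some score reaches the decision threshold ``Theta`` or after
``R`` rounds; the highest-scoring solution is selected for execution.

Votes are pooled over realized solution paths: a "solution" in the sense
of the competing hypotheses (the two six-move routes of the community
study, the solution matrices of the lesion study) is the state path the
particle executed, which many different subgoal sequences can realize.
The subgoal sequences behind each solution are retained alongside the
votes for reporting.

When resampling is enabled the subgoal prior is also sharpened between
rounds: each non-goal state's mass is multiplied by the fraction of
successful particles that used it as a subgoal (the goal is re-clamped
rather than usage-boosted — it appears in every successful sequence, so
its usage carries no information), concentrating later rounds on the
subgoal sequences that worked.  Mixed populations (a fraction of particles
on the look-ahead prior, the rest on the perceptual prior) run with
resampling disabled, so neither strategy's prior is contaminated by the
other's successes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .planner import GraphArrays, PlanConfig, PlanResult, plan
from .priors import PriorModel, clamp_goal, perceptual_prior_vector
from .state_space import ProblemGraph

__all__ = [
    "LOOKAHEAD",
    "PERCEPTUAL",
    "DecisionConfig",
    "VoteTable",
    "DecisionResult",
    "run_particle_batch",
    "update_votes",
    "update_prior",
    "decide",
]

LOOKAHEAD = "lookahead"
PERCEPTUAL = "perceptual"

Solution = tuple  # tuple[str, ...]: the realized state path


@dataclass(frozen=True)
class DecisionConfig:
    """Parameters of the outer decision loop (reference-table defaults).

    ``mixture_lookahead`` is the fraction of particles initialized with the
    look-ahead (algorithmic) prior; the rest use the perceptual prior.
    Resampling is forced off for genuine mixtures.
    """

    n_particles: int = 100  # K
    max_resamplings: int = 10  # R
    decision_threshold: float = 0.8  # Theta
    g_res: float = 0.30  # fraction-reached-goal early-stop threshold
    mixture_lookahead: float = 1.0
    resampling_enabled: bool = True
    plan: PlanConfig = field(default_factory=PlanConfig)

    def __post_init__(self):
        if not 0 < self.decision_threshold <= 1:
            raise ValueError("decision threshold must be in (0, 1]")
        if not 0 <= self.g_res <= 1:
            raise ValueError("G_res must be in [0, 1]")
        if self.n_particles < 1:
            raise ValueError("particle count must be >= 1")
        if not 0 <= self.mixture_lookahead <= 1:
            raise ValueError("mixture must be in [0, 1]")
        if 0 < self.mixture_lookahead < 1 and self.resampling_enabled:
            # mixed strategies run without prior resampling
            object.__setattr__(self, "resampling_enabled", False)


@dataclass
class VoteTable:
    """Posterior scores ``theta_h`` over discovered solutions."""

    scores: dict[Solution, float] = field(default_factory=dict)

    def normalized(self) -> "VoteTable":
        tot = sum(self.scores.values())
        if tot <= 0:
            return VoteTable(dict(self.scores))
        return VoteTable({k: v / tot for k, v in self.scores.items()})

    @property
    def winner(self) -> Solution | None:
        if not self.scores:
            return None
        return max(self.scores, key=self.scores.get)

    @property
    def max_score(self) -> float:
        return max(self.scores.values()) if self.scores else 0.0


@dataclass
class DecisionResult:
    """Outcome of the sequential decision procedure."""

    winner: list[str] | None  # the selected solution path
    votes: VoteTable
    theta_trajectory: list[dict[Solution, float]]
    batches: list[list[PlanResult]]
    rounds: int
    #: subgoal sequences observed for each solution, with counts
    seq_pool: dict[Solution, Counter]

    @property
    def decided(self) -> bool:
        return self.winner is not None

    @property
    def winner_steps(self) -> int | None:
        return len(self.winner) - 1 if self.winner else None

    def winner_seq(self) -> list[str] | None:
        """Modal subgoal sequence among particles realizing the winner."""
        if self.winner is None:
            return None
        pool = self.seq_pool.get(tuple(self.winner))
        if not pool:
            return None
        modal = min(pool.items(), key=lambda kv: (-kv[1], len(kv[0])))[0]
        return list(modal)


def run_particle_batch(
    g: ProblemGraph,
    model: PriorModel,
    s0: str,
    goal: str,
    priors: list[np.ndarray],
    strategy_of: np.ndarray,
    cfg: DecisionConfig,
    rng: np.random.Generator,
    arrays: GraphArrays,
) -> tuple[list[PlanResult], int]:
    """Launch particles sequentially until K are run or G_res is reached.

    ``priors`` holds one clamped prior vector per strategy and
    ``strategy_of[k]`` assigns particle ``k`` its strategy.  Returns the
    goal-reaching plans and the number of particles launched.  The
    early-stop fraction is measured against the full ensemble size ``K``.
    """
    successes: list[PlanResult] = []
    launched = 0
    for k in range(cfg.n_particles):
        if len(successes) / cfg.n_particles >= cfg.g_res:
            break
        launched += 1
        result = plan(
            g, model, s0, goal, priors[strategy_of[k]], cfg.plan, rng, arrays
        )
        if result.reached_goal:
            successes.append(result)
    return successes, launched


def update_votes(
    votes: VoteTable, batch: list[PlanResult], n_particles: int
) -> VoteTable:
    """Bayes update of solution scores with the batch as evidence.

    Each score is multiplied by the proportion (out of the ensemble size)
    of particles realizing that solution; solutions first seen this round
    enter with a flat share of the prior mass before the update.  An empty
    batch leaves the table unchanged.
    """
    if not batch:
        return votes
    counts = Counter(tuple(r.trace) for r in batch)
    keys = set(votes.scores) | set(counts)
    flat = 1.0 / len(keys)
    updated = {
        sol: votes.scores.get(sol, flat) * (counts.get(sol, 0) / n_particles)
        for sol in keys
    }
    return VoteTable(updated).normalized()


def update_prior(
    prior: np.ndarray,
    batch: list[PlanResult],
    order: list[str],
    goal: str,
) -> np.ndarray:
    """Multiply each state's prior mass by its usage rate among successes.

    States that no successful particle used as a subgoal drop to zero.  The
    goal appears in every successful sequence by construction, so its usage
    carries no information; instead of being boosted multiplicatively it is
    re-clamped on the updated distribution by the usual goal-clamping rule.
    With no successes the prior is returned unchanged.
    """
    if not batch:
        return prior
    usage = np.zeros(len(order))
    index = {s: i for i, s in enumerate(order)}
    for r in batch:
        for sg in set(r.seq):
            usage[index[sg]] += 1
    usage /= len(batch)
    out = prior * usage
    gi = index[goal]
    out[gi] = 0.0
    if out.sum() <= 0:
        return prior
    out = out / out.sum()
    return clamp_goal(out, gi)


def decide(
    g: ProblemGraph,
    model: PriorModel,
    s0: str,
    goal: str,
    cfg: DecisionConfig,
    rng: np.random.Generator,
    arrays: GraphArrays | None = None,
) -> DecisionResult:
    """Run the full sequential decision procedure.

    Returns the winning solution path (or a no-decision result when no
    particle ever reached the goal in ``R`` rounds), the vote table and its
    per-round trajectory, every batch, and the subgoal sequences observed
    per solution.
    """
    arrays = arrays or GraphArrays(g)
    look = clamp_goal(model.prior, model.index(goal))
    perc = clamp_goal(perceptual_prior_vector(g, goal), model.index(goal))
    priors = [look, perc]

    k = cfg.n_particles
    n_look = int(round(cfg.mixture_lookahead * k))
    strategy_of = np.array([0] * n_look + [1] * (k - n_look))
    rng.shuffle(strategy_of)

    votes = VoteTable()
    trajectory: list[dict[Solution, float]] = []
    batches: list[list[PlanResult]] = []
    seq_pool: dict[Solution, Counter] = {}

    rounds = 0
    for _ in range(cfg.max_resamplings):
        rounds += 1
        batch, _ = run_particle_batch(
            g, model, s0, goal, priors, strategy_of, cfg, rng, arrays
        )
        batches.append(batch)
        votes = update_votes(votes, batch, cfg.n_particles)
        trajectory.append(dict(votes.scores))
        for r in batch:
            seq_pool.setdefault(tuple(r.trace), Counter())[tuple(r.seq)] += 1
        if cfg.resampling_enabled and batch:
            used = 0 if cfg.mixture_lookahead >= 1.0 else 1
            priors[used] = update_prior(priors[used], batch, model.order, goal)
        if votes.max_score >= cfg.decision_threshold:
            break

    winner = votes.winner
    return DecisionResult(
        winner=list(winner) if winner is not None else None,
        votes=votes,
        theta_trajectory=trajectory,
        batches=batches,
        rounds=rounds,
        seq_pool=seq_pool,
    )
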