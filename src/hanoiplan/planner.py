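"""Forward subgoaling inference: one particle's plan (the inner procedure).

A particle starts at ``s0``, samples a subgoal from the (goal-clamped)
subgoal prior, and then iterates: select a policy by Monte-Carlo sampling
(the sampled policy whose rollout reaches the current subgoal with the
shortest program wins), execute one action, evaluate the ternary progress
monitor ``F`` (0 pursuing, 1 subgoal reached, 2 goal reached), draw a new
subgoal when ``F = 1``, and zero out the just-visited state in the working
prior (an on-line memory that prevents re-selecting visited states as
subgoals).  The loop stops at ``F = 2`` or after ``t_max`` steps; failing to
reach the goal is a valid outcome.

Policy sampling is implemented lazily: drawing a uniform random policy and
rolling it out is distributionally identical to a self-avoiding uniform
random walk, because a deterministic policy that revisits a state loops
forever and its program never halts.  Only the actions along the realized
walk are ever needed, so the walk *is* the policy rollout; walks are stepped
in vectorized batches.  Rollouts also treat states already visited by the
particle's trace as blocked, which together with the on-line subgoal memory
keeps every trace vertex-simple.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .priors import PriorModel
from .state_space import ProblemGraph

__all__ = [
    "PlanConfig",
    "PlanResult",
    "GraphArrays",
    "evaluate_F",
    "rollout",
    "sample_policy_program",
    "sample_subgoal_initial",
    "sample_subgoal_transition",
    "plan",
]


@dataclass(frozen=True)
class PlanConfig:
    """Sampling parameters of the inner inference loop.

    ``t_max`` is the forward-inference cap from the reference parameter
    table.  ``n_policy_samples`` policies are drawn per policy selection and
    ``n_candidates`` candidate subgoals are drawn (with replacement, from
    the particle's masked prior) per subgoal transition; both are package
    calibration choices, see the methods note.  ``rollout_horizon`` equals
    the state count: any halting simple rollout is shorter, so exceeding it
    means the program does not halt.
    """

    t_max: int = 12
    n_policy_samples: int = 16
    n_candidates: int = 9
    rollout_horizon: int = 27
    policy_retry_cap: int = 2
    #: follow the selected policy until its subgoal (Option-like commitment)
    #: instead of re-selecting a policy at every step
    commit_policy: bool = True


@dataclass
class PlanResult:
    """One particle's trajectory."""

    trace: list[str]
    seq: list[str]
    reached_goal: bool
    #: per-step snapshots of the particle's working subgoal distribution
    #: (only recorded when requested; None otherwise)
    prior_snapshots: list[np.ndarray] | None = None

    @property
    def steps(self) -> int:
        return len(self.trace) - 1


class GraphArrays:
    """Integer-indexed adjacency of a :class:`ProblemGraph` for fast rollout."""

    def __init__(self, g: ProblemGraph):
        self.order = g.states
        self.index = {s: i for i, s in enumerate(self.order)}
        n = len(self.order)
        self.n = n
        max_deg = max(g.degree(s) for s in self.order)
        self.neighbors = np.full((n, max_deg), -1, dtype=np.int64)
        self.degrees = np.zeros(n, dtype=np.int64)
        for s in self.order:
            i = self.index[s]
            nbrs = [self.index[t] for t in g.neighbors(s)]
            self.degrees[i] = len(nbrs)
            self.neighbors[i, : len(nbrs)] = nbrs


def evaluate_F(s: str, sg: str, goal: str) -> int:
    """Progress monitor: 2 at the goal, 1 at the current subgoal, else 0."""
    if s == goal:
        return 2
    if s == sg:
        return 1
    return 0


def rollout(
    arrays: GraphArrays,
    policy: dict[int, int],
    s: int,
    sg: int,
    horizon: int,
    blocked: np.ndarray | None = None,
) -> list[int] | None:
    """Follow a deterministic policy (state index -> successor index).

    Returns the state path if ``sg`` is reached within ``horizon`` steps and
    before any state repeats; ``None`` signals a non-halting program (its
    probability weight is zero).  ``blocked`` marks additional states that
    abort the walk.
    """
    path = [s]
    visited = {s}
    cur = s
    for _ in range(horizon):
        if cur == sg:
            return path
        nxt = policy[cur]
        if nxt in visited or (blocked is not None and blocked[nxt]):
            return None
        path.append(nxt)
        visited.add(nxt)
        cur = nxt
    return path if cur == sg else None


def sample_policy_program(
    arrays: GraphArrays,
    s: int,
    sg: int,
    blocked: np.ndarray,
    cfg: PlanConfig,
    rng: np.random.Generator,
) -> list[int] | None:
    """Monte-Carlo policy selection; returns the winning program's path.

    ``cfg.n_policy_samples`` uniform policies are sampled (lazily, as
    self-avoiding walks) and scored by ``2^-|program|`` with a uniform
    policy prior, so the argmax is the sampled policy with the shortest
    halting rollout; ties are broken uniformly at random.  The batch is
    redrawn up to ``cfg.policy_retry_cap`` times if no sampled policy halts;
    ``None`` signals final failure.
    """
    if s == sg:
        return [s]
    n = cfg.n_policy_samples
    nbrs, degs = arrays.neighbors, arrays.degrees
    for _ in range(cfg.policy_retry_cap):
        cur = np.full(n, s, dtype=np.int64)
        visited = np.zeros((n, arrays.n), dtype=bool)
        visited[:, blocked] = True
        visited[:, s] = True
        paths = np.full((n, cfg.rollout_horizon + 1), -1, dtype=np.int64)
        paths[:, 0] = s
        alive = np.ones(n, dtype=bool)
        halted_len = np.full(n, -1, dtype=np.int64)
        for t in range(1, cfg.rollout_horizon + 1):
            if not alive.any():
                break
            idx = np.flatnonzero(alive)
            c = cur[idx]
            choice = (rng.random(len(idx)) * degs[c]).astype(np.int64)
            nxt = nbrs[c, choice]
            dead = visited[idx, nxt]
            ok = idx[~dead]
            nxt_ok = nxt[~dead]
            alive[idx[dead]] = False
            cur[ok] = nxt_ok
            visited[ok, nxt_ok] = True
            paths[ok, t] = nxt_ok
            arrived = ok[nxt_ok == sg]
            halted_len[arrived] = t
            alive[arrived] = False
        halted = np.flatnonzero(halted_len > 0)
        if len(halted) == 0:
            continue
        best_len = halted_len[halted].min()
        winners = halted[halted_len[halted] == best_len]
        w = winners[rng.integers(len(winners))]
        return [int(x) for x in paths[w, : halted_len[w] + 1]]
    return None


def sample_subgoal_initial(
    prior: np.ndarray, rng: np.random.Generator
) -> int:
    """One categorical draw from the (clamped, normalized) subgoal prior."""
    return int(rng.choice(len(prior), p=prior))


def sample_subgoal_transition(
    model: PriorModel,
    masked_prior: np.ndarray,
    sg: int,
    goal: int,
    cfg: PlanConfig,
    rng: np.random.Generator,
) -> int | None:
    """Next subgoal after attainment: Monte-Carlo argmax of transition scores.

    Candidates are drawn with replacement from the particle's masked prior
    (so the strategy's prior shapes *which* states compete) and the drawn
    set is scored by the goal-clamped transition score; the argmax wins,
    with ties broken uniformly.  Returns ``None`` when the masked prior has
    no support left.
    """
    mass = masked_prior.sum()
    if mass <= 0:
        return None
    p = masked_prior / mass
    draws = rng.choice(len(p), size=cfg.n_candidates, p=p)
    cand = np.unique(draws)
    order = model.order
    scores = model.subgoal_scores(order[sg], order[goal], cand)
    best = scores.max()
    winners = cand[scores == best]
    return int(winners[rng.integers(len(winners))])


def plan(
    g: ProblemGraph,
    model: PriorModel,
    s0: str,
    goal: str,
    clamped_prior: np.ndarray,
    cfg: PlanConfig,
    rng: np.random.Generator,
    arrays: GraphArrays | None = None,
    record_snapshots: bool = False,
) -> PlanResult:
    """Run the forward subgoaling inference for a single particle.

    ``clamped_prior`` is the particle's strategy prior (algorithmic or
    perceptual, already goal-clamped, possibly reweighted by the outer
    decision loop).  The scoring machinery (joint weights and their
    normalizing priors) always comes from ``model``; the strategies differ
    only through the prior the subgoals are drawn from.
    """
    if s0 == goal:
        raise ValueError("start state equals goal state")
    arrays = arrays or GraphArrays(g)
    idx = arrays.index
    s = idx[s0]
    gl = idx[goal]

    masked = np.asarray(clamped_prior, dtype=float).copy()
    sg = sample_subgoal_initial(masked / masked.sum(), rng)
    seq = [arrays.order[sg]]
    trace = [s0]
    blocked = np.zeros(arrays.n, dtype=bool)
    blocked[s] = True
    masked[s] = 0.0
    snapshots: list[np.ndarray] | None = [] if record_snapshots else None

    f = evaluate_F(arrays.order[s], arrays.order[sg], goal)
    t = 0
    program: list[int] | None = None
    while f < 2 and t < cfg.t_max:
        t += 1
        if f == 1:  # subgoal just attained: draw the next one
            nsg = sample_subgoal_transition(model, masked, sg, gl, cfg, rng)
            if nsg is None:
                return PlanResult(
                    trace=trace, seq=seq, reached_goal=False,
                    prior_snapshots=snapshots,
                )
            sg = nsg
            seq.append(arrays.order[sg])
            program = None
        if not cfg.commit_policy:
            program = None
        if program is None or len(program) < 2:
            # select a policy for the current subgoal; under commitment it is
            # followed until the subgoal is reached — an Option-like sub-plan
            program = sample_policy_program(arrays, s, sg, blocked, cfg, rng)
            if program is None or len(program) < 2:
                return PlanResult(
                    trace=trace, seq=seq, reached_goal=False,
                    prior_snapshots=snapshots,
                )
        program = program[1:]
        s = program[0]  # execute the next action of the committed policy
        trace.append(arrays.order[s])
        f = evaluate_F(arrays.order[s], arrays.order[sg], goal)
        blocked[s] = True
        masked[s] = 0.0
        if masked.sum() > 0:
            masked = masked / masked.sum()
        if snapshots is not None:
            snapshots.append(masked.copy())

    reached = f == 2
    if reached and seq[-1] != goal:
        seq.append(goal)  # F = 2 clamps the final subgoal to the goal
    return PlanResult(
        trace=trace, seq=seq, reached_goal=reached, prior_snapshots=snapshots
    )
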