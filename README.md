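# hanoiplan

Planning-as-inference with subgoaling on the Tower of Hanoi.

`hanoiplan` implements a probabilistic model of human problem solving in
the 3-disk, 3-rod Tower of Hanoi (ToH). The puzzle is mapped onto its
27-state transition graph (39 legal moves; corners are the three full
towers), and solving a problem becomes path planning on that graph. The
model explains both human *successes* (sensitivity to the puzzle's nested
community structure) and human *failures* (difficulty with counterintuitive
moves, as seen in prefrontal-lesion patients) with a single inference
scheme whose only degree of freedom is the prior over subgoals.

## The model

**Subgoal priors.** Every state is a potential subgoal `SG`. Its
*algorithmic* prior comes from program-length weighting: a deterministic
policy `π` rolled out from state `s_i` until it first reaches `s_k` defines
a program of code length `|p|` (one action per move), weighted
`2^-|p|`. Summing over policies — equivalently over simple paths `c` with
policy multiplicities `μ(c)` — gives the joint

    p(s_k, s_i) = Σ_{c ∈ C(s_k, s_i)} μ(c) · 2^-|c|,

and `P(SG = s_k) ∝ Σ_i p(s_k, s_i)`. States that afford many short
programs score high; bottleneck states bridging the graph's communities
score low. The joint is evaluated exactly (integer arithmetic over all
simple paths), so the prior is exactly constant on each rod-permutation
orbit. The competing *perceptual* prior is a softmax of the negative L1
distance between disk-rod vectors, `p(s | goal) ∝ exp(−‖v(s) − v(goal)‖₁)`
— apparent similarity to the goal configuration.

**Inference.** Given a start and a goal (clamped to the top of the prior),
a *particle* samples a subgoal, selects a policy by Monte-Carlo sampling
(the sampled policy reaching the subgoal with the shortest program wins),
follows it to the subgoal, and repeats — a ternary monitor `F` reports
ongoing pursuit / subgoal reached / goal reached — until the goal is
reached or `T_max = 12` steps elapse. Goal-clamped transition scores make
successive subgoals march toward the goal ("moving target").

**Decision.** An ensemble of `K = 100` particles runs for up to `R = 10`
resampling rounds. Solutions accumulate posterior votes `θ_h` (Bayes
updates with the per-round share of particles producing each solution);
between rounds the subgoal prior is sharpened by subgoal usage among the
successful particles. The procedure stops at vote threshold `Θ = 0.8` and
executes the most-voted solution. The "look-ahead" and "perceptual"
strategies share all of this machinery and differ only in the prior the
subgoals are drawn from; mixed ensembles model patient populations.

## Worked example

Decide how to move the full tower from rod 3 to rod 2 (state S27 to state
S20 — the problem whose optimal solution requires all 7 moves and a
counterintuitive excursion):

```
$ hanoiplan decide --start S27 --goal S20 --seed 3
{
  "winner": ["S27", "S26", "S25", "S24", "S23", "S22", "S21", "S20"],
  "winner_steps": 7,
  "winner_subgoals": ["S23", "S20"],
  "rounds": 5,
  "top_votes": {
    "S27->S26->S25->S24->S23->S22->S21->S20": 0.9713293488451515
  }
}
```

The ensemble converged in 5 rounds on the unique 7-move plan, reaching it
via one intermediate subgoal (S23, the deep bottleneck state on the
cluster boundary) before the goal — the waypoint-style decomposition the
model predicts. `winner_steps` is the executed move count and `top_votes`
the posterior vote share of the winning solution.

The subgoal priors themselves:

```
$ hanoiplan priors algorithmic | head -4
state,prior
S1,0.024833730384348565
S2,0.04090293505660805
S3,0.04090293505660805
```

Corners (S1, S20, S27) carry the least prior mass, corner-adjacent states
the most, and the bottleneck states sit below the other interior states —
the structural map that steers particles away from community boundaries.

Other entry points: `hanoiplan plan` (a single particle, with per-step
subgoal-distribution snapshots), `hanoiplan graph export` (GraphML/DOT
with configurations and priors), and `hanoiplan experiment
{community,nested,counterintuitive,lesion}` for the four simulation
studies (CSV + JSON reports).

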