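# Methods

This note documents the modelling conventions, numerical choices and
calibrations behind `hanoiplan`, and the points where the package's exact
recomputation departs from the published values it set out to reproduce.

## State space

The 3-disk Tower of Hanoi is encoded as vectors `v(s) = (rod_1, rod_2,
rod_3)` with disk 1 the smallest; every one of the 3³ = 27 assignments is
legal because stacking order on a rod is forced by size. Legal moves
(transfer a top disk onto a larger top disk or an empty rod) induce the
27-node, 39-edge Hanoi graph: three 9-state communities (one per rod of
the largest disk), each split into three 3-state sub-communities, joined
by single bottleneck edges (S9–S11, S6–S10, S23–S24 at the deepest level;
S7–S8 and S2–S3 at the shallower levels of the top community).

The conventional labels S1..S27 are not fully tabulated in the reference
material, so the mapping was reconstructed from printed anchors: the
corner assignments S1=(1,1,1), S20=(2,2,2), S27=(3,3,3); the two six-move
solution paths w1 = S11-S14-S18-S24-S23-S17-S13 and
w2 = S11-S9-S8-S7-S6-S10-S13; the seven-move corner path S27..S20; the
bottleneck edges; the sub-community memberships {S1,S2,S3}, {S5,S8,S9},
{S4,S6,S7}; and the perceptual-prior examples that pin S16=(1,2,2). These
anchors over-determine the labeling (a row-by-row reading of the standard
drawing confirms every deduced label); it ships as
`src/hanoiplan/data/labeling.tsv` and every anchor is re-verified at graph
build time, failing loudly on any mismatch.

Disk 1 is the smallest disk by convention; the perceptual metric is
insensitive to this choice, and the labeling fixture records it. Movement
actions act1..act6 enumerate ordered rod pairs (1→2, 1→3, 2→1, 2→3, 3→1,
3→2); the rest action maps every state to itself. The deterministic-policy
count multiplies movement degrees only (3²⁴·2³ ≈ 2.26·10¹², matching the
printed ~2.3·10¹²; including the rest action per state would give ~6·10¹⁵).

## Algorithmic priors

The joint weight of a state pair sums `μ(c)·2^(−|c|)` over all
vertex-simple paths `c` between them; non-simple paths cannot be generated
by a deterministic policy (any revisit loops forever), which makes the
simple-path universe the exact policy-based one. The multiplicity
convention and the zero-length identity program are genuinely ambiguous in
the source description, so both are explicit parameters:

* `mu_variant`: `offpath` (product of movement degrees strictly off the
  path) or `arrival` (also multiplying the arrival state's degree — the
  exact policy count, since a first-hit rollout leaves the arrival action
  free);
* `identity`: the zero-length program carries weight 1 (generated by the
  rest policy alone), or the multiplicity over the 26 other states, or
  over all 27.

The frozen defaults are `arrival` + rest-policy identity: this is the one
combination that coincides, integer for integer, with an independent
oracle that enumerates every deterministic policy on small graphs and
scores its first-hit rollouts (`tests/test_priors.py`), and of the six
combinations it also lies closest to the published class values.

**Known discrepancy.** The published figure assigns the five
rod-permutation orbits the priors 0.026 / 0.0355 / 0.0358 / 0.0359 /
0.0465. The exact evaluation gives 0.0248 / 0.0376 / 0.0376 / 0.0381 /
0.0409 — the same qualitative map (corners far lowest, corner-adjacent
states far highest, deep bottlenecks at the bottom of the interior
states), but the middle-class values differ in the third decimal and the
corner-neighbour class by 0.006. An extensive search over evaluation
conventions (both `mu` variants, rest-inclusive degrees, every identity
convention, alternative decay bases, path-length caps, walk and trail
universes, per-start normalizations, every-visit discounted occupancies of
sampled policy rollouts) found no convention reproducing all five printed
values to ±0.001; the published numbers most plausibly derive from an
earlier sampling-based evaluation whose exact protocol is not recoverable.
The package reports its exactly-computed values and asserts the structural
properties (orbit constancy is exact in integer arithmetic; the
class ordering corners < interior < corner-neighbours).

The printed traversal products for the nested-structure study (0.0464 /
0.0358 / 0.0355) equal the printed priors of the first edge state to
within 1e-4, implying a conditional of essentially 1; the package computes
`P(to|from)·P(from)` by the chain rule on the joint
(`P(to|from) = joint(to,from)/Σ_x joint(x,from)`), which yields 0.0122 /
0.00859 / 0.00858 — smaller in value but preserving the strict
level-1 > level-2 > level-3 ordering that constitutes the study's claim.

## Perceptual priors

`p(s|goal) ∝ exp(−‖v(s)−v(goal)‖₁)` over all 27 states. For the goal
(2,2,2) every misplaced disk contributes exactly 1, giving the closed form
`p(goal|goal) = 1/(1+6e⁻¹+12e⁻²+8e⁻³) ≈ 0.1912` used as a test anchor.

## Inference conventions

* **Goal clamping.** The goal's prior is set to `max(prior) + Δ`, `Δ`
  being the largest gap between consecutive values of the
  descending-sorted prior, then the vector is renormalized. After each
  resampling update of the prior the goal is re-clamped by the same rule
  rather than multiplied by its usage (it occurs in every successful
  sequence, so its usage carries no information and would otherwise
  swallow the distribution).
* **Policy selection.** Policies are sampled lazily: a uniform random
  policy rolled out from the current state is distributionally a
  self-avoiding uniform walk (a revisit implies an endless loop, i.e. a
  non-halting program). Per selection, `n_policy_samples` walks are
  stepped in a vectorized batch; the shortest halting walk wins (uniform
  tie-break), with up to `policy_retry_cap` batch redraws when none halts.
  Walks also treat the particle's visited states as blocked, which keeps
  every executed trace vertex-simple (the on-line memory extended to
  execution).
* **Commitment.** The selected policy is followed until its subgoal is
  reached — the "Option built on the fly" reading — rather than re-derived
  every step. Per-step re-selection acts as a powerful stochastic
  hill-climb toward the subgoal; under it both strategies solve the
  hardest problems near-optimally and every documented strategy difference
  (subgoal-count histogram, perceptual penalty, community preference)
  disappears.
* **Subgoal transitions.** At subgoal attainment, `n_candidates` candidate
  states are drawn with replacement from the particle's masked strategy
  prior and scored by
  `p(goal|x)·p(x|sg) = [joint(goal,x)/P(x)]·joint(x,sg)` from the
  algorithmic model; the argmax wins. The strategy thus shapes *which*
  states compete while the scoring machinery is shared — the sense in
  which the two strategies differ only in their priors. The goal's
  self-likelihood uses the policy-counting identity weight (every policy
  trivially generates the zero-length program), so the goal outcompetes
  local waypoints only once the current subgoal is near it: successive
  subgoals form a moving target that approaches the goal (a tested
  majority property).
* **Vote pooling.** Posterior votes accumulate over realized solution
  paths. The competing hypotheses of the studies are solutions (the two
  six-move routes; the solution matrices of the lesion study), and many
  distinct subgoal sequences realize the same solution; pooling by
  sequence identity instead fragments the look-ahead strategy's votes
  across its waypoint variants while direct-to-goal particles pool into
  one hypothesis, which empirically inverts the control/lesioned contrast.
  Subgoal sequences are retained per solution for reporting.
* **Route classification.** In the community study a solution is
  classified by the community boundaries it crosses: w1-family crosses
  only S23–S24, w2-family crosses S9–S11 and S6–S10. This is the construct
  the underlying behavioral comparison measures (which of the two
  cluster-respecting routes was chosen); exact six-move-path equality
  would discard the longer realizations of the same route choice.

## Calibrated sampling parameters

The reference parameter table fixes K=100 particles, R=10 resamplings,
Θ=0.8, T_max=12 and G_res=30%, but not the Monte-Carlo budgets. These were
calibrated against the documented study behavior and frozen:

| parameter          | default | role                                      |
|--------------------|---------|-------------------------------------------|
| `n_policy_samples` | 16      | policy rollouts per selection              |
| `n_candidates`     | 9       | subgoal candidate draws per transition     |
| `policy_retry_cap` | 2       | batch redraws when no rollout halts        |
| `commit_policy`    | True    | follow the selected policy to its subgoal  |

At these values the package reproduces: one-bottleneck route vote share
≈ 0.72 at round 4 with that route winning in ~20/25 runs; modal 7-move
solutions with 2–3 subgoals for the pure look-ahead strategy; monotone
degradation of success as the perceptual fraction grows; and the
control > lesioned contrast with both groups at ceiling on the easy
problem. Larger budgets (e.g. the order of 10³ rollouts) make the policy
sampler an effectively exact shortest-path solver and erase all of these
contrasts.

**Known limitation.** The pure perceptual strategy's modal selected
solution is 8 moves here, not the documented 9: the best-of-n self-avoiding
walk to a target at distance 7 has a modal length of 8 on this graph at
every sampling budget, and the characteristic 6+3-move detour through the
perceptually attractive S13 never out-votes the direct solutions. The
look-ahead/perceptual contrast itself (7 < 8, plus a large success-rate
gap) is robust.

## Problem sizes and reproducibility

The studies use the reference repetition count (25 runs per condition; the
lesion comparison pools three 25-run batches per group, and the
acceptance script averages the community study over 50 seeded repetitions
to tighten the share estimate). A single root seed derives every
per-run generator; given the seed, results are bit-reproducible
(asserted), and run manifests record the seed, resolved configuration and
prior-model conventions.

## What the simulations do and do not show

All inputs are self-generated from the puzzle definition; there is no
empirical data in the package. Passing tests show that the implemented
inference reproduces the qualitative and most quantitative signatures
claimed for this model class on the 27-state graph — not that the model
fits human trial-level data, and not that the conclusions generalize to
larger Hanoi instances (the machinery is generic in disk count, but no
anchors exist to validate priors or behavior beyond three disks).
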