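"""Algorithmic and perceptual subgoal priors.

The core check is a dual-route equivalence: the path-based evaluation
(depth-first path enumeration with policy multiplicities) must agree
exactly, in integer arithmetic, with an independent oracle that enumerates
every deterministic policy on a small graph and scores its rollouts.
"""

import math
from fractions import Fraction
from itertools import product

import networkx as nx
import numpy as np
import pytest

from hanoiplan import clamp_goal, perceptual_prior_vector
from hanoiplan.priors import (
    ID_ALL,
    ID_OFFPATH,
    ID_REST,
    MU_ARRIVAL,
    MU_OFFPATH,
    PriorModel,
    algorithmic_joint_numerators,
    calibrate_mu_variant,
    enumerate_simple_paths,
    policy_multiplicity,
)

TOY_GRAPHS = {
    "path4": nx.path_graph(4),
    "cycle5": nx.cycle_graph(5),
    "star+edge": nx.Graph([(0, 1), (0, 2), (0, 3), (2, 3), (3, 4)]),
    "near-complete": nx.Graph(
        [(0, 1), (0, 2), (1, 2), (1, 3), (2, 3), (3, 4), (4, 5), (2, 5)]
    ),
}


def policy_enumeration_joint(g: nx.Graph):
    """Oracle: score every deterministic policy's rollouts from every start.

    A movement policy assigns each state one neighbor; its rollout from a
    start state contributes ``2^-t`` to the pair (first-hit state, start)
    for every state it reaches before looping.  The rest policy alone
    contributes the zero-length identity program at each start.  Weights
    are returned scaled by ``2^(n-1)`` as exact integers.
    """
    nodes = sorted(g.nodes)
    n = len(nodes)
    scale = n - 1
    idx = {v: i for i, v in enumerate(nodes)}
    J = [[0] * n for _ in range(n)]
    for i in range(n):
        J[i][i] += 1 << scale  # rest policy: identity program
    neighbor_choices = [sorted(g.neighbors(v)) for v in nodes]
    for actions in product(*neighbor_choices):
        policy = dict(zip(nodes, actions))
        for start in nodes:
            cur = start
            seen = {start}
            for t in range(1, n):
                cur = policy[cur]
                if cur in seen:
                    break
                seen.add(cur)
                J[idx[cur]][idx[start]] += 1 << (scale - t)
    return nodes, J


class TestSimplePaths:
    def test_trivial_path(self, graph):
        assert enumerate_simple_paths(graph, "S5", "S5") == [("S5",)]

    def test_bottleneck_single_edge_path_present(self, graph):
        paths = enumerate_simple_paths(graph, "S23", "S24")
        assert ("S23", "S24") in paths
        assert len(set(paths)) == len(paths)

    @pytest.mark.parametrize("name", list(TOY_GRAPHS))
    def test_count_matches_matrix_backtracking_oracle(self, name):
        g = TOY_GRAPHS[name]
        a = nx.to_numpy_array(g, nodelist=sorted(g.nodes))
        nodes = sorted(g.nodes)

        def backtrack(i, target, visited):
            if i == target:
                return 1
            total = 0
            for j in np.flatnonzero(a[i]):
                if j not in visited:
                    total += backtrack(int(j), target, visited | {int(j)})
            return total

        for s in range(len(nodes)):
            for t in range(len(nodes)):
                if s == t:
                    continue
                got = len(enumerate_simple_paths(g, nodes[s], nodes[t]))
                assert got == backtrack(s, t, {s})


class TestPolicyMultiplicity:
    def test_full_cover_path_has_multiplicity_one(self):
        g = nx.path_graph(4)
        assert policy_multiplicity([0, 1, 2, 3], g, MU_OFFPATH) == 1

    def test_arrival_variant_adds_arrival_degree(self):
        g = nx.path_graph(4)
        assert policy_multiplicity([0, 1, 2, 3], g, MU_ARRIVAL) == g.degree(3)

    def test_offpath_product(self, graph):
        # a single edge leaves 25 states free
        mu = policy_multiplicity(["S23", "S24"], graph, MU_OFFPATH)
        expected = 1
        for s in graph.states:
            if s not in ("S23", "S24"):
                expected *= graph.degree(s)
        assert mu == expected


class TestPolicyEnumerationOracle:
    """Path-based joint == exhaustive policy enumeration, exactly."""

    @pytest.mark.parametrize("name", list(TOY_GRAPHS))
    def test_joint_equals_policy_enumeration(self, name):
        g = TOY_GRAPHS[name]
        nodes, expected = policy_enumeration_joint(g)
        order, got = algorithmic_joint_numerators(
            g, nodes, mu_variant=MU_ARRIVAL, identity=ID_REST
        )
        assert order == nodes
        assert got == expected

    def test_priors_agree_on_toy_graph(self):
        g = TOY_GRAPHS["near-complete"]
        nodes, oracle = policy_enumeration_joint(g)
        _, ours = algorithmic_joint_numerators(g, nodes, MU_ARRIVAL, ID_REST)
        oracle_rows = [sum(r) for r in oracle]
        our_rows = [sum(r) for r in ours]
        tot_o, tot_m = sum(oracle_rows), sum(our_rows)
        for ro, rm in zip(oracle_rows, our_rows):
            assert Fraction(ro, tot_o) == Fraction(rm, tot_m)


class TestHandComputedJoint:
    def test_path_graph_weights(self):
        """On 0-1-2-3 every pair has one simple path; check by hand.

        Degrees are (1,2,2,1); scaled weight of a path is
        mu_offpath * deg(arrival) * 2^(3 - length).
        """
        g = nx.path_graph(4)
        _, J = algorithmic_joint_numerators(g, [0, 1, 2, 3], MU_ARRIVAL, ID_REST)
        assert J[1][0] == (2 * 1) * 2 * 2**2  # off {2,3}; arrival deg(1)=2; L=1
        assert J[2][0] == 1 * 2 * 2**1  # off {3}; arrival deg(2)=2; L=2
        assert J[3][0] == 1 * 1 * 2**0  # off {}; arrival deg(3)=1; L=3
        assert J[0][0] == 2**3  # identity via the rest policy

    def test_symmetry_under_offpath_variant(self, graph):
        _, J = algorithmic_joint_numerators(
            graph, graph.states, MU_OFFPATH, ID_OFFPATH
        )
        n = len(J)
        for i in range(n):
            for j in range(n):
                assert J[i][j] == J[j][i]

    def test_all_entries_positive(self, model):
        assert (model.joint > 0).all()


class TestAlgorithmicPriors:
    def test_normalized(self, model):
        assert abs(model.prior.sum() - 1.0) < 1e-12

    def test_orbit_constancy_is_exact(self, graph, model):
        rows = [sum(r) for r in model.numerators]
        for orbit in graph.orbits():
            vals = {rows[model.index(s)] for s in orbit}
            assert len(vals) == 1  # exact integer equality

    def test_corners_lowest_corner_neighbors_highest(self, model):
        corners = [model.prior_of(s) for s in ("S1", "S20", "S27")]
        neighbors = [model.prior_of(s) for s in ("S2", "S3", "S16", "S19", "S21", "S26")]
        others = [
            model.prior_of(s)
            for s in model.order
            if s not in {"S1", "S20", "S27", "S2", "S3", "S16", "S19", "S21", "S26"}
        ]
        assert max(corners) < min(others)
        assert min(neighbors) > max(others)

    def test_calibration_selects_frozen_defaults(self, graph):
        report = calibrate_mu_variant(graph)
        assert report["best"]["mu_variant"] == MU_ARRIVAL
        assert report["best"]["identity"] == ID_REST
        assert len(report["combinations"]) == 6

    def test_identity_all_weight_dominates_column(self, model):
        # the policy-counting identity weight exceeds every joint entry
        assert model.identity_all_weight > model.joint.max()


class TestClampGoal:
    def test_argmax_is_goal_and_normalized(self, model):
        out = clamp_goal(model.prior, model.index("S20"))
        assert out.argmax() == model.index("S20")
        assert abs(out.sum() - 1.0) < 1e-12

    def test_uniform_prior_gap_zero(self):
        out = clamp_goal(np.full(5, 0.2), 3)
        assert out[3] == pytest.approx(0.2)
        assert abs(out.sum() - 1.0) < 1e-12

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError):
            clamp_goal(np.array([1.0, 2.0]), 0)


class TestPerceptualPriors:
    def test_argmax_at_goal_and_normalized(self, graph):
        for goal in ("S20", "S1", "S14"):
            p = perceptual_prior_vector(graph, goal)
            assert abs(p.sum() - 1.0) < 1e-12
            assert graph.states[int(np.argmax(p))] == goal

    def test_goal_value_closed_form(self, graph):
        # from the goal, states sit at L1 distance k with count C(3,k)*2^k
        p = perceptual_prior_vector(graph, "S20")
        expected = 1.0 / (1 + 6 * math.e**-1 + 12 * math.e**-2 + 8 * math.e**-3)
        i = graph.states.index("S20")
        assert p[i] == pytest.approx(expected, abs=1e-12)
        assert p[i] == pytest.approx(0.1912, abs=5e-4)

    def test_distance_ratio_is_e(self, graph):
        p = perceptual_prior_vector(graph, "S20")
        i21 = graph.states.index("S21")  # distance 1 from the goal
        i22 = graph.states.index("S22")  # distance 2
        assert p[i21] / p[i22] == pytest.approx(math.e, rel=1e-12)


class TestConditional:
    def test_normalized(self, model):
        dist = model.conditional_subgoal_distribution("S2", "S13")
        assert abs(sum(dist.values()) - 1.0) < 1e-12

    def test_masking_removes_candidates(self, model):
        masked = np.zeros(27)
        masked[model.index("S5")] = 1.0
        dist = model.conditional_subgoal_distribution(
            "S2", "S13", masked_prior=masked
        )
        assert set(dist) == {"S5"}

    def test_fully_masked_raises(self, model):
        with pytest.raises(ValueError):
            model.conditional_subgoal_distribution(
                "S2", "S13", masked_prior=np.zeros(27)
            )


class TestTraversalProducts:
    def test_nested_ordering_strict(self, model):
        p1 = model.traversal_product("S2", "S3")
        p2 = model.traversal_product("S7", "S8")
        p3 = model.traversal_product("S23", "S24")
        assert p1 > p2 > p3

    def test_symmetric_pairs_in_same_orbit_agree(self, model):
        # the three deep bottleneck edges lie in one orbit of edges
        a = model.traversal_product("S23", "S24")
        b = model.traversal_product("S9", "S11")
        c = model.traversal_product("S6", "S10")
        assert a == pytest.approx(b, rel=1e-9)
        assert a == pytest.approx(c, rel=1e-9)


class TestClampGoalProperties:
    """Goal clamping on arbitrary normalized priors (property-based)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=40),
        st.integers(min_value=0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_clamped_goal_tops_any_prior(self, weights, goal):
        import numpy as np

        p = np.asarray(weights) / np.sum(weights)
        gi = goal % len(p)
        out = clamp_goal(p, gi)
        assert abs(out.sum() - 1.0) < 1e-9
        assert out[gi] == out.max()
        # non-goal entries keep their relative proportions
        rest = [i for i in range(len(p)) if i != gi]
        for i, j in zip(rest, rest[1:]):
            if p[j] > 0:
                assert out[i] / out[j] == pytest.approx(p[i] / p[j], rel=1e-9)
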