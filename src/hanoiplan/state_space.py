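"""The 3-disk Tower of Hanoi state space as a labeled transition graph.

The puzzle has three rods and ``D`` size-ordered disks; a legal move
transfers the top disk of one rod onto a rod whose top disk is larger (or
which is empty).  A configuration is fully described by the rod index of
each disk, ``v(s) = (rod_1, ..., rod_D)`` with disk 1 the smallest, because
stacking order on a rod is forced by disk size.  For ``D = 3`` this yields
3^3 = 27 states and 39 undirected transitions; drawn in the plane the graph
is the Sierpinski-triangle-shaped "Hanoi graph", whose three-level nested
community structure (clusters joined by bottleneck edges) drives everything
else in this package.

States carry the conventional labels ``S1 .. S27``.  The published figure
the labeling reproduces does not print the full label-to-configuration
table, so the mapping was reconstructed from its printed anchors (the three
corner states, two printed six-move solution paths, the seven-move
corner-to-corner path, the bottleneck edges and the five symmetry classes)
and is shipped as a plain-text fixture which :func:`build_graph` re-verifies
on every load.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from math import prod
from typing import Iterator

import networkx as nx

__all__ = [
    "N_DISKS",
    "N_RODS",
    "ACTIONS",
    "EPSILON",
    "DiskConfiguration",
    "ProblemGraph",
    "enumerate_configurations",
    "legal_moves",
    "apply_action",
    "build_graph",
]

N_DISKS = 3
N_RODS = 3

#: Movement actions in their conventional order: ``act1`` = rod 1 -> rod 2,
#: ``act2`` = rod 1 -> rod 3, ``act3`` = rod 2 -> rod 1, ``act4`` = rod 2 -> rod 3,
#: ``act5`` = rod 3 -> rod 1, ``act6`` = rod 3 -> rod 2.
ACTIONS: dict[str, tuple[int, int]] = {
    "act1": (1, 2),
    "act2": (1, 3),
    "act3": (2, 1),
    "act4": (2, 3),
    "act5": (3, 1),
    "act6": (3, 2),
}

#: The auxiliary rest action: maps every state to itself.
EPSILON = "eps"

DiskConfiguration = tuple  # tuple[int, ...], rod index per disk, disk 1 smallest


def enumerate_configurations(n_disks: int = N_DISKS) -> list[DiskConfiguration]:
    """All rod assignments of ``n_disks`` disks over three rods.

    Every assignment is a legal configuration: on a single rod the disks are
    necessarily stacked in size order.
    """
    return [tuple(c) for c in itertools.product(range(1, N_RODS + 1), repeat=n_disks)]


def _top_disk(config: DiskConfiguration, rod: int) -> int | None:
    on_rod = [d for d in range(len(config)) if config[d] == rod]
    return min(on_rod) if on_rod else None


def legal_moves(config: DiskConfiguration) -> list[tuple[str, DiskConfiguration]]:
    """Movement actions defined at ``config`` with their successor states.

    A movement action ``act_k = (src, tgt)`` is defined iff the source rod is
    non-empty and its top disk is smaller than the target rod's top disk.
    The rest action is excluded.  Every state admits 2 (the three "tower"
    corner states) or 3 legal moves.
    """
    out = []
    for name, (src, tgt) in ACTIONS.items():
        moving = _top_disk(config, src)
        if moving is None:
            continue
        blocking = _top_disk(config, tgt)
        if blocking is not None and blocking < moving:
            continue
        nxt = list(config)
        nxt[moving] = tgt
        out.append((name, tuple(nxt)))
    return out


def apply_action(config: DiskConfiguration, action: str) -> DiskConfiguration:
    """Successor of ``config`` under ``action``; raises if undefined there."""
    if action == EPSILON:
        return config
    for name, nxt in legal_moves(config):
        if name == action:
            return nxt
    raise ValueError(f"action {action!r} is not defined in configuration {config}")


# ---------------------------------------------------------------------------
# Printed anchors the shipped labeling must satisfy.

_CORNERS = {"S1": (1, 1, 1), "S20": (2, 2, 2), "S27": (3, 3, 3)}
_W1 = ["S11", "S14", "S18", "S24", "S23", "S17", "S13"]
_W2 = ["S11", "S9", "S8", "S7", "S6", "S10", "S13"]
_CORNER_PATH = ["S27", "S26", "S25", "S24", "S23", "S22", "S21", "S20"]
_ANCHOR_EDGES = [
    ("S9", "S11"),
    ("S6", "S10"),
    ("S23", "S24"),  # level-3 bottlenecks bridging the three main clusters
    ("S7", "S8"),  # level-2 bottleneck
    ("S2", "S3"),  # level-1 bottleneck
]


@dataclass(frozen=True)
class ProblemGraph:
    """The labeled 27-state transition system with an undirected edge view."""

    graph: nx.Graph
    labeling: dict[str, DiskConfiguration]  # label -> configuration
    transition: dict[tuple[str, str], str] = field(repr=False)  # (label, action) -> label

    @property
    def states(self) -> list[str]:
        return [f"S{i}" for i in range(1, len(self.labeling) + 1)]

    def state_vector(self, label: str) -> DiskConfiguration:
        """Disk-rod vector ``v(s)`` of a labeled state."""
        try:
            return self.labeling[label]
        except KeyError:
            raise KeyError(f"unknown state label {label!r}") from None

    def label_of(self, config: DiskConfiguration) -> str:
        return self._inverse[tuple(config)]

    @property
    def _inverse(self) -> dict[DiskConfiguration, str]:
        return {v: k for k, v in self.labeling.items()}

    def neighbors(self, label: str) -> list[str]:
        return sorted(self.graph.neighbors(label), key=_state_index)

    def degree(self, label: str) -> int:
        """Movement degree (rest action excluded)."""
        return self.graph.degree(label)

    def shortest_path_length(self, s: str, t: str) -> int:
        """Breadth-first shortest edge-path length; 0 iff ``s == t``."""
        return nx.shortest_path_length(self.graph, s, t)

    def count_policies(self) -> int:
        """Number of deterministic state-to-movement-action maps.

        The product of movement degrees, 3^24 * 2^3 ~= 2.3e12.  The rest
        action is excluded from each state's choice set; the all-rest policy
        is the single additional policy kept outside this count.
        """
        return prod(self.graph.degree(s) for s in self.graph)

    # -- rod-permutation symmetry ------------------------------------------

    def automorphisms(self) -> Iterator[dict[str, str]]:
        """Label maps induced by the six permutations of the three rods."""
        inv = self._inverse
        for perm in itertools.permutations(range(1, N_RODS + 1)):
            yield {
                lab: inv[tuple(perm[r - 1] for r in cfg)]
                for lab, cfg in self.labeling.items()
            }

    def orbits(self) -> list[frozenset[str]]:
        """Orbit partition of the states under rod permutations.

        Exactly five classes of sizes {3, 6, 6, 6, 6}: the corners, the
        corner-adjacent states, and three six-state middle classes.
        """
        seen: set[str] = set()
        out = []
        autos = list(self.automorphisms())
        for lab in self.states:
            if lab in seen:
                continue
            orb = frozenset(a[lab] for a in autos)
            seen |= orb
            out.append(orb)
        return out

    # -- export -------------------------------------------------------------

    def to_graphml(self, path, priors: dict[str, float] | None = None) -> None:
        g = self._export_graph(priors)
        nx.write_graphml(g, path)

    def to_dot(self, path, priors: dict[str, float] | None = None) -> None:
        g = self._export_graph(priors)
        lines = ["graph hanoi {"]
        for n, data in g.nodes(data=True):
            attrs = ",".join(f'{k}="{v}"' for k, v in data.items())
            lines.append(f'  "{n}" [{attrs}];')
        for u, v in g.edges():
            lines.append(f'  "{u}" -- "{v}";')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    def _export_graph(self, priors: dict[str, float] | None) -> nx.Graph:
        g = self.graph.copy()
        for lab, cfg in self.labeling.items():
            g.nodes[lab]["configuration"] = ",".join(map(str, cfg))
            if priors is not None:
                g.nodes[lab]["prior"] = float(priors[lab])
        return g


def _state_index(label: str) -> int:
    return int(label[1:])


def _load_labeling() -> dict[str, DiskConfiguration]:
    text = resources.files("hanoiplan.data").joinpath("labeling.tsv").read_text()
    labeling: dict[str, DiskConfiguration] = {}
    for line in text.strip().splitlines():
        label, cfg = line.split("\t")
        labeling[label] = tuple(int(x) for x in cfg.split(","))
    return labeling


def build_graph() -> ProblemGraph:
    """Construct the labeled 27-state graph and verify every printed anchor.

    Raises ``AssertionError`` if the shipped labeling fixture violates any
    anchor (corner states, the two printed six-move paths, the printed
    seven-move corner path, the bottleneck edges) or the graph-level
    invariants (27 states, 39 edges, degree multiset {2^3, 3^24}).
    """
    labeling = _load_labeling()
    configs = enumerate_configurations()
    assert sorted(labeling.values()) == sorted(configs), "labeling is not a bijection"

    inverse = {cfg: lab for lab, cfg in labeling.items()}
    graph = nx.Graph()
    graph.add_nodes_from(labeling)
    transition: dict[tuple[str, str], str] = {}
    for lab, cfg in labeling.items():
        for action, nxt_cfg in legal_moves(cfg):
            nxt = inverse[nxt_cfg]
            transition[(lab, action)] = nxt
            graph.add_edge(lab, nxt)

    assert graph.number_of_nodes() == 27, "expected 27 states"
    assert graph.number_of_edges() == 39, "expected 39 transitions"
    degs = sorted(d for _, d in graph.degree())
    assert degs == [2] * 3 + [3] * 24, "degree multiset must be {2^3, 3^24}"

    for lab, cfg in _CORNERS.items():
        assert labeling[lab] == cfg, f"corner anchor {lab} -> {cfg} violated"
    for path in (_W1, _W2, _CORNER_PATH):
        for u, v in zip(path, path[1:]):
            assert graph.has_edge(u, v), f"printed path edge {u}-{v} missing"
    for u, v in _ANCHOR_EDGES:
        assert graph.has_edge(u, v), f"printed edge {u}-{v} missing"

    return ProblemGraph(graph=graph, labeling=labeling, transition=transition)
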