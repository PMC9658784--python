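"""Shared fixtures: toy nodes, reference graphs and numeric helpers."""

from __future__ import annotations

import numpy as np
import pytest

from fhenet.graph import ComputationGraph, Node
from fhenet.layers import GenericNode, RotationNode


class Doubler(Node):
    """Toy computation node: doubles its signal."""

    def forward(self, s):
        return s * 2

    def backward(self, g):
        return g * 2


class AddOne(Node):
    def forward(self, s):
        return s + 1

    def backward(self, g):
        return g


class Recorder(Node):
    """Counts activations and remembers the signals it saw."""

    def __init__(self):
        self.calls = []

    def forward(self, s):
        self.calls.append(s)
        return s

    def backward(self, g):
        self.calls.append(("backward", g))
        return g


class ConcernNode(GenericNode):
    """Marker node type used as the parameterisation boundary in fixtures."""


@pytest.fixture
def chain_graph():
    """A -> B -> C with B doubling and C adding one."""
    g = ComputationGraph()
    g.add_node("A", Recorder())
    g.add_node("B", Doubler())
    g.add_node("C", Recorder())
    g.add_edge("A", "B")
    g.add_edge("B", "C")
    return g


@pytest.fixture
def diamond_graph():
    """A -> (B, C) -> D; D must activate exactly once per firing."""
    g = ComputationGraph()
    g.add_node("A", Recorder())
    g.add_node("B", Doubler())
    g.add_node("C", AddOne())
    g.add_node("D", Recorder())
    g.add_edge("A", "B")
    g.add_edge("A", "C")
    g.add_edge("B", "D")
    g.add_edge("C", "D")
    return g


@pytest.fixture
def fig4_graph():
    """Two cyphertext ingresses meeting before a rotation boundary.

    x1 experiences computations c0 and c1 while x0 experiences only c1;
    both must therefore share parameters sized for the deeper path (cost 2),
    and the rotation r0 restarts a fresh source.
    """
    g = ComputationGraph()
    g.add_node("x0", GenericNode(cost=0))
    g.add_node("x1", GenericNode(cost=0))
    g.add_node("c0", GenericNode(cost=1))
    g.add_node("c1", GenericNode(cost=1))
    g.add_node("r0", RotationNode("refresh"))
    g.add_edge("x1", "c0")
    g.add_edge("c0", "c1")
    g.add_edge("x0", "c1")
    g.add_edge("c1", "r0")
    return g


def random_mdg(rng: np.random.Generator, max_nodes: int = 12,
               max_parallel: int = 3, max_cost: int = 3):
    """Random acyclic multi-directed graph for oracle-equivalence tests.

    Nodes are topologically ordered by construction (edges only point from
    lower to higher index); a random subset become concern (boundary) nodes
    and every zero-in-degree node is an ingress source.
    """
    n = int(rng.integers(2, max_nodes + 1))
    g = ComputationGraph()
    kinds = []
    for i in range(n):
        concern = i > 0 and rng.random() < 0.2
        cost = int(rng.integers(0, max_cost + 1))
        g.add_node(f"n{i}", ConcernNode(cost) if concern
                   else GenericNode(cost))
        kinds.append(concern)
    has_pred = [False] * n
    for j in range(1, n):
        for i in range(j):
            if rng.random() < 0.35:
                for _ in range(int(rng.integers(1, max_parallel + 1))):
                    g.add_edge(f"n{i}", f"n{j}")
                has_pred[j] = True
    sources = [f"n{i}" for i in range(n) if not has_pred[i] and not kinds[i]]
    if not sources:
        sources = ["n0"]
    return g, sources


def central_difference(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of an array."""
    x = np.asarray(x, dtype=np.float64)
    grad = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        grad[idx] = (f(xp) - f(xm)) / (2 * eps)
    return grad
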