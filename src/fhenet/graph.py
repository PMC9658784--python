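"""Multi-directed computation graph and the neuronal-firing traversal.

Networks are node-centric multi-directed graphs: every node is a computation
object (a neuron, an encryption stage, a loss circuit element, ...) exposing
named *receptors* — callables such as ``forward`` and ``backward`` — and every
edge moves data (a *signal*) between two nodes.  Parallel edges are distinct
entities with independent signal slots.  A node activates only once all of its
inbound edges for the receptor being fired carry a signal; its output is then
placed on its outbound edges (broadcast for plain values, split per-edge for
generators) and propagation recurses into the successors, depth first.

Edge weights equal the multiplicative-depth cost of the directed-to node; they
are not used for routing but for the longest-path analysis that drives
automatic encryption parameterisation (:mod:`fhenet.autofhe`).
"""

from __future__ import annotations

import types
from typing import Any, Callable, Iterable, Sequence

import networkx as nx

from .errors import ArityError, CycleError, ReceptorError, UnknownNodeError

__all__ = [
    "Node",
    "ComputationGraph",
    "NodeRecord",
    "EdgeRecord",
    "neuronal_firing",
    "signal_carrier",
    "get_inbound_signal",
    "apply_signal",
    "set_outbound_signals",
    "register_receptor",
    "RECEPTOR_REGISTRY",
]

#: receptor name -> flow direction (+1 follows edge direction, -1 reverses it)
RECEPTOR_REGISTRY: dict[str, int] = {"forward": +1, "backward": -1}


def register_receptor(name: str, direction: int = +1) -> None:
    """Register an additional receptor name and its traversal direction."""
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 (with edges) or -1 (against)")
    RECEPTOR_REGISTRY[name] = direction


class Node:
    """Base computational object held by a graph node.

    Subclasses implement receptor methods named after the receptors they
    support (``forward``, ``backward``, ...).  ``cost`` reports the integer
    multiplicative depth a cyphertext spends traversing this node, which
    becomes the weight of every inbound edge.
    """

    def cost(self) -> int:
        return 0

    def receptor(self, name: str, signal: Any) -> Any:
        if name not in RECEPTOR_REGISTRY:
            raise ReceptorError(f"unknown receptor {name!r}")
        fn: Callable[[Any], Any] | None = getattr(self, name, None)
        if fn is None or not callable(fn):
            raise ReceptorError(
                f"{type(self).__name__} does not support receptor {name!r}"
            )
        return fn(signal)

    def supports(self, name: str) -> bool:
        return callable(getattr(self, name, None))

    # -- learning hooks (no-ops for stateless nodes) --
    def apply_gradients(self, lr: float) -> None:
        pass

    def zero_gradients(self) -> None:
        pass

    # -- serialisation hooks --
    def get_config(self) -> tuple[dict, dict]:
        """Return (json-safe config, named parameter arrays)."""
        return {}, {}

    @classmethod
    def from_config(cls, config: dict, arrays: dict) -> "Node":
        return cls(**config)


class NodeRecord:
    """View onto one graph node: the computation object and its metadata.

    ``meta`` holds mutable bookkeeping such as the ``"sources"`` cost labels
    written by parameterisation discovery and the last activation output.
    """

    __slots__ = ("name", "node", "meta")

    def __init__(self, name: str, node: Node, meta: dict):
        self.name = name
        self.node = node
        self.meta = meta

    def __repr__(self) -> str:  # pragma: no cover
        return f"NodeRecord({self.name!r}, {type(self.node).__name__})"


class EdgeRecord:
    """View onto one directed edge: per-receptor signal slots and its weight.

    ``signals`` maps receptor name -> signal; a missing key means the slot is
    empty.  ``receptors`` restricts which receptors this edge serves, which is
    how output-only branches (prediction circuits) opt out of gradient flow.
    """

    __slots__ = ("src", "dst", "key", "signals", "receptors", "_graph")

    def __init__(self, graph: "ComputationGraph", src: str, dst: str, key,
                 signals: dict, receptors: tuple):
        self._graph = graph
        self.src = src
        self.dst = dst
        self.key = key
        self.signals = signals
        self.receptors = receptors

    @property
    def weight(self) -> int:
        """Cost of the directed-to node."""
        return self._graph.node(self.dst).node.cost()

    def __repr__(self) -> str:  # pragma: no cover
        return f"EdgeRecord({self.src!r}->{self.dst!r}#{self.key})"


class ComputationGraph:
    """Named nodes joined by parallel-capable directed edges."""

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()
        self.meta: dict = {}

    # -- construction ----------------------------------------------------
    def add_node(self, name: str, node: Node) -> None:
        if name in self._g:
            raise ValueError(f"node name {name!r} already present")
        if not isinstance(node, Node):
            raise TypeError("node must be a fhenet.graph.Node")
        self._g.add_node(name, node=node, meta={})

    def add_edge(self, src: str, dst: str, key=None,
                 receptors: Iterable[str] = ("forward", "backward")):
        """Add a directed edge; returns its key (unique per (src, dst))."""
        for n in (src, dst):
            if n not in self._g:
                raise UnknownNodeError(n)
        k = self._g.add_edge(src, dst, key=key, signals={},
                             receptors=tuple(receptors))
        return k

    # -- access ----------------------------------------------------------
    def __contains__(self, name: str) -> bool:
        return name in self._g

    def node(self, name: str) -> NodeRecord:
        try:
            d = self._g.nodes[name]
        except KeyError:
            raise UnknownNodeError(name) from None
        return NodeRecord(name, d["node"], d["meta"])

    def node_names(self) -> list[str]:
        return list(self._g.nodes)

    def records(self) -> Iterable[NodeRecord]:
        for name in self._g.nodes:
            yield self.node(name)

    def successors(self, name: str) -> list[str]:
        return list(self._g.successors(name))

    def predecessors(self, name: str) -> list[str]:
        return list(self._g.predecessors(name))

    def _edge_record(self, u: str, v: str, k) -> EdgeRecord:
        d = self._g.edges[u, v, k]
        return EdgeRecord(self, u, v, k, d["signals"], d["receptors"])

    def in_edges(self, name: str) -> list[EdgeRecord]:
        return [self._edge_record(u, v, k)
                for u, v, k in self._g.in_edges(name, keys=True)]

    def out_edges(self, name: str) -> list[EdgeRecord]:
        return [self._edge_record(u, v, k)
                for u, v, k in self._g.out_edges(name, keys=True)]

    def edges(self) -> list[EdgeRecord]:
        return [self._edge_record(u, v, k)
                for u, v, k in self._g.edges(keys=True)]

    def number_of_nodes(self) -> int:
        return self._g.number_of_nodes()

    # -- state -----------------------------------------------------------
    def clear_signals(self) -> None:
        for _, _, d in self._g.edges(data=True):
            d["signals"].clear()

    def clear_sources(self) -> None:
        for _, d in self._g.nodes(data=True):
            d["meta"].pop("sources", None)


# ---------------------------------------------------------------------------
# Neuronal firing
# ---------------------------------------------------------------------------

def _direction(r: str) -> int:
    try:
        return RECEPTOR_REGISTRY[r]
    except KeyError:
        raise ReceptorError(f"unknown receptor {r!r}") from None


def _flow_in_edges(g: ComputationGraph, n: str, r: str) -> list[EdgeRecord]:
    edges = g.in_edges(n) if _direction(r) > 0 else g.out_edges(n)
    return [e for e in edges if r in e.receptors]


def _flow_out_edges(g: ComputationGraph, n: str, r: str) -> list[EdgeRecord]:
    edges = g.out_edges(n) if _direction(r) > 0 else g.in_edges(n)
    return [e for e in edges if r in e.receptors]


def _flow_successors(g: ComputationGraph, n: str, r: str) -> list[str]:
    seen: list[str] = []
    for e in _flow_out_edges(g, n, r):
        nxt = e.dst if _direction(r) > 0 else e.src
        if nxt not in seen:
            seen.append(nxt)
    return seen


def neuronal_firing(g: ComputationGraph, n: Sequence[str], s: Sequence[Any],
                    r: Sequence[str]) -> ComputationGraph:
    """Exhaustively stimulate the graph, depth first and blocking.

    Each (node, signal, receptor) triple is seeded in order via
    :func:`signal_carrier`; activations cascade into successors as soon as all
    of a node's inbound edges carry data.
    """
    if not (len(n) == len(s) == len(r)):
        raise ValueError("n, s and r must have equal lengths")
    for name, rec_name in zip(n, r):
        record = g.node(name)  # raises UnknownNodeError
        _direction(rec_name)
        if not record.node.supports(rec_name):
            raise ReceptorError(
                f"node {name!r} ({type(record.node).__name__}) has no "
                f"receptor {rec_name!r}")
    for name, sig, rec_name in zip(n, s, r):
        signal_carrier(g, name, rec_name, sig)
    return g


def signal_carrier(g: ComputationGraph, n: str, r: str,
                   bootstrap: Any = None, _path: frozenset = frozenset()) -> None:
    """Propagate a single signal from node ``n`` as far as it will travel.

    Incomplete inbound data is a silent no-op.  Consumed inbound signals are
    cleared on successful activation so a subsequent pass starts clean.
    """
    g.node(n)  # existence check
    s = get_inbound_signal(g, n, r, bootstrap)
    if s is None:
        return
    out = apply_signal(g, n, r, s)
    if bootstrap is None:
        for e in _flow_in_edges(g, n, r):
            e.signals.pop(r, None)
    if out is None:
        return
    if not isinstance(out, types.GeneratorType):
        g.node(n).meta["output"] = out
    set_outbound_signals(g, n, r, out)
    path = _path | {n}
    for succ in _flow_successors(g, n, r):
        if succ == n:
            # self-loops rely on the node's own termination logic
            continue
        if succ in path:
            raise CycleError(
                f"cycle detected through nodes {sorted(path | {succ})}")
        signal_carrier(g, succ, r, None, path)


def get_inbound_signal(g: ComputationGraph, n: str, r: str,
                       bootstrap: Any = None) -> Any:
    """Accumulate the inbound signal for one receptor.

    Returns the bootstrap when given, the unwrapped signal when exactly one
    inbound edge exists, the ordered sequence of signals otherwise, and None
    whenever any inbound edge still lacks data.
    """
    if bootstrap is not None:
        return bootstrap
    edges = _flow_in_edges(g, n, r)
    if not edges:
        return None
    s = []
    for e in edges:
        if r not in e.signals:
            return None
        s.append(e.signals[r])
    if len(s) == 1:
        return s[0]
    return s


def apply_signal(g: ComputationGraph, n: str, r: str, s: Any) -> Any:
    """Activate node ``n``'s receptor ``r`` on the accumulated signal."""
    if s is None:
        return None
    node = g.node(n).node
    try:
        return node.receptor(r, s)
    except ReceptorError:
        raise
    except Exception as exc:
        exc.add_note(f"while activating node {n!r} receptor {r!r}")
        raise


def set_outbound_signals(g: ComputationGraph, n: str, r: str, s: Any) -> None:
    """Distribute an activation result onto the outbound edges.

    Generators are split one item per edge in edge order; any other value is
    broadcast to every outbound edge.
    """
    if s is None:
        return
    edges = _flow_out_edges(g, n, r)
    if isinstance(s, types.GeneratorType):
        for e in edges:
            try:
                e.signals[r] = next(s)
            except StopIteration:
                raise ArityError(
                    f"generator from node {n!r} exhausted before all "
                    f"{len(edges)} outbound edges were served") from None
    else:
        for e in edges:
            e.signals[r] = s
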