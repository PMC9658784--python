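"""Automatic levelled-CKKS parameterisation from computation-graph costs.

The cyphertexts flowing through a network must be provisioned for the worst
multiplicative depth they will experience between the point where data becomes
a cyphertext (a source) and the next key rotation or decryption (a concern
node).  Cyphertexts that interact at any node must additionally share
encryption parameters and originate from the same private key — they form a
*parameter group*.

Discovery walks the graph from every source, accumulating the cost of each
directed-to node along every path and recording, on each node reached, the
maximal accumulated cost per source (``meta["sources"]``).  Concern nodes
truncate the walk and restart as fresh sources, since a rotation re-encrypts
under new parameters.  Grouping then merges sources whose cost labels co-occur
on any node; each group's cost is the maximum labelled cost over its members,
i.e. the longest path any member's cyphertext must survive.

A rough heuristic finally turns a group cost into RNS-CKKS parameters: a
coefficient-modulus chain of ``cost`` scale-sized primes flanked by two
scale-stabilised special primes, and the smallest power-of-two polynomial
modulus degree whose bit budget (27 bits per 1024 degree) covers the chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Sequence

import networkx as nx

from .errors import ConsistencyError, CycleError, UnknownNodeError
from .graph import ComputationGraph

__all__ = [
    "FHEParams",
    "ParamGroups",
    "parameterise_ckks",
    "autohe",
    "autohe_discover",
    "assign_parameters",
    "brute_force_group_cost",
    "default_concern",
]

#: MS-SEAL-style scheme identifier for CKKS
CKKS_SCHEME_ID = 2


@dataclass(frozen=True)
class FHEParams:
    """Levelled RNS-CKKS parameter set.

    ``coeff_mod_bit_sizes`` has ``cost + 2`` entries: the first and last are
    special primes of ``int(scale_power * special_mult)`` bits, the middle
    entries are the rescaling primes of ``scale_power`` bits each — one
    consumed per multiplication.
    """

    scheme: int
    scale_power: int
    poly_modulus_degree: int
    coeff_mod_bit_sizes: tuple[int, ...]

    @property
    def scale(self) -> int:
        return 2 ** self.scale_power

    @property
    def slot_capacity(self) -> int:
        """CKKS packs half as many slots as the polynomial degree."""
        return self.poly_modulus_degree // 2

    @property
    def depth(self) -> int:
        """Multiplicative rescales available before exhaustion."""
        return len(self.coeff_mod_bit_sizes) - 2

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "scale_power": self.scale_power,
            "poly_modulus_degree": self.poly_modulus_degree,
            "coeff_mod_bit_sizes": list(self.coeff_mod_bit_sizes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FHEParams":
        return cls(scheme=d["scheme"], scale_power=d["scale_power"],
                   poly_modulus_degree=d["poly_modulus_degree"],
                   coeff_mod_bit_sizes=tuple(d["coeff_mod_bit_sizes"]))


def parameterise_ckks(c: int, s: int = 40, p: float = 1.5) -> FHEParams:
    """Heuristically parameterise RNS-CKKS for ``c`` multiplications.

    Parameters
    ----------
    c : maximal multiplicative cost of the cyphertext group.
    s : scale power (bits of fixed-point precision).  Going below 30 is
        inadvisable: noise accumulation and prime availability both suffer.
    p : special prime multiplier for the chain's first and last entries.
    """
    if c < 0:
        raise ValueError(f"cost must be non-negative, got {c}")
    if p < 1:
        raise ValueError(f"special prime multiplier must be >= 1, got {p}")
    if s < 30:
        warnings.warn(
            f"scale power {s} is below the advised minimum of 30; expect "
            "noise accumulation and a shortage of usable primes",
            UserWarning, stacklevel=2)
    m = [s for _ in range(c + 2)]
    m[0] = int(m[0] * p)
    m[-1] = int(m[-1] * p)
    b = 27
    while b < sum(m):
        b *= 2
    return FHEParams(
        scheme=CKKS_SCHEME_ID,
        scale_power=s,
        poly_modulus_degree=int(1024 * (b / 27)),
        coeff_mod_bit_sizes=tuple(m),
    )


@dataclass
class ParamGroups:
    """Map source-name -> group index plus per-group maximal cost.

    Equality is semantic: two results are equal when they induce the same
    partition of sources with the same per-group costs, regardless of how the
    groups happen to be numbered.
    """

    membership: dict[str, int]
    group_cost: list[int]

    def members(self, index: int) -> list[str]:
        return [s for s, g in self.membership.items() if g == index]

    def canonical(self) -> frozenset:
        return frozenset(
            (frozenset(self.members(i)), cost)
            for i, cost in enumerate(self.group_cost)
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParamGroups):
            return NotImplemented
        return self.canonical() == other.canonical()

    def __hash__(self):  # pragma: no cover
        return hash(self.canonical())


def default_concern() -> tuple[type, ...]:
    """Node types at which cyphertext keys change: rotations and decrypts."""
    from .layers import DecryptNode, RotationNode
    return (RotationNode, DecryptNode)


def autohe_discover(g: ComputationGraph, n: str, s: str,
                    concern: tuple[type, ...], c: int,
                    _path: frozenset = frozenset(),
                    _restarted: dict | None = None) -> None:
    """Recursively label reachable nodes with per-source maximal costs.

    Starting from node ``n`` attributed to source ``s`` with accumulated cost
    ``c``, every node reached records ``max`` accumulated cost under ``s`` in
    its ``meta["sources"]``.  Concern nodes truncate the walk and restart as
    fresh sources at cost zero.
    """
    if c < 0:
        raise ValueError("accumulated cost must be non-negative")
    rec = g.node(n)  # raises UnknownNodeError
    if _restarted is None:
        _restarted = {}  # insertion-ordered set of restarted concern nodes
    sources = rec.meta.setdefault("sources", {})
    if s != n:
        prev = sources.get(s)
        if prev is None or prev < c:
            sources[s] = c
    if isinstance(rec.node, concern) and s != n:
        if n not in _restarted:
            _restarted[n] = True
            autohe_discover(g, n, n, concern, 0, frozenset(), _restarted)
        return
    path = _path | {n}
    for succ in g.successors(n):
        if succ == n:
            continue  # self-loop: node-internal configuration, not a path
        if succ in path:
            raise CycleError(
                f"cycle through {succ!r} during parameterisation discovery")
        nxt = c + g.node(succ).node.cost()
        autohe_discover(g, succ, s, concern, nxt, path, _restarted)


def _all_labelled_sources(g: ComputationGraph, caller_order: Sequence[str],
                          restarted: Sequence[str]) -> list[str]:
    order = list(caller_order)
    for name in restarted:
        if name not in order:
            order.append(name)
    for rec in g.records():
        for k in rec.meta.get("sources", {}):
            if k not in order:
                order.append(k)
    return order


def autohe(g: ComputationGraph, n: Sequence[str],
           concern: tuple[type, ...] | None = None) -> ParamGroups:
    """Parameterisation by source and cost discovery over the graph.

    ``n`` lists the ingress nodes where data becomes a cyphertext.  Returns
    the parameter groups: interacting sources (including rotation stages
    discovered along the way) share a group, and each group's cost is the
    highest computational depth experienced by any member's cyphertext.
    """
    if concern is None:
        concern = default_concern()
    for name in n:
        if name not in g:
            raise UnknownNodeError(name)
    g.clear_sources()
    restarted: dict = {}
    for name in n:
        autohe_discover(g, name, name, concern, 0, frozenset(), restarted)

    order = _all_labelled_sources(g, n, list(restarted))
    # deterministic union-find: the root is the earliest source in `order`
    rank = {s: i for i, s in enumerate(order)}
    parent = {s: s for s in order}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra == rb:
            return
        if rank[ra] > rank[rb]:
            ra, rb = rb, ra
        parent[rb] = ra

    label_max: dict[str, int] = {s: 0 for s in order}
    for rec in g.records():
        srcs = rec.meta.get("sources", {})
        keys = [k for k in order if k in srcs]
        for a, b in zip(keys, keys[1:]):
            union(a, b)
        for k, cost in srcs.items():
            if cost > label_max[k]:
                label_max[k] = cost

    membership: dict[str, int] = {}
    group_cost: list[int] = []
    root_index: dict[str, int] = {}
    for s in order:
        root = find(s)
        if root not in root_index:
            root_index[root] = len(group_cost)
            group_cost.append(0)
        gi = root_index[root]
        membership[s] = gi
        if label_max[s] > group_cost[gi]:
            group_cost[gi] = label_max[s]
    return ParamGroups(membership, group_cost)


def brute_force_group_cost(g: ComputationGraph, sources: Sequence[str],
                           concern: tuple[type, ...] | None = None
                           ) -> ParamGroups:
    """Exhaustive test oracle for :func:`autohe` on small graphs.

    Enumerates every simple path from each source, truncated at the first
    concern node (which then restarts as a new source), taking the cost of a
    path as the sum of directed-to node costs.  Groups are the connected
    components of the "cost labels co-occur on a node" relation.
    """
    if concern is None:
        concern = default_concern()
    labels: dict[str, dict[str, int]] = {}
    pending = list(sources)
    seen = set(pending)
    order: list[str] = []

    def walk(node: str, src: str, cost: int, on_path: frozenset) -> None:
        for succ in g.successors(node):
            if succ == node:
                continue
            if succ in on_path:
                raise CycleError(f"cycle through {succ!r}")
            c2 = cost + g.node(succ).node.cost()
            lab = labels.setdefault(succ, {})
            if lab.get(src, -1) < c2:
                lab[src] = c2
            if isinstance(g.node(succ).node, concern):
                if succ not in seen:
                    seen.add(succ)
                    pending.append(succ)
            else:
                walk(succ, src, c2, on_path | {node})

    while pending:
        src = pending.pop(0)
        if src not in g:
            raise UnknownNodeError(src)
        order.append(src)
        walk(src, src, 0, frozenset())

    h = nx.Graph()
    h.add_nodes_from(order)
    for lab in labels.values():
        for a, b in combinations(lab, 2):
            h.add_edge(a, b)
    membership: dict[str, int] = {}
    group_cost: list[int] = []
    for s in order:
        if s in membership:
            continue
        gi = len(group_cost)
        comp = nx.node_connected_component(h, s)
        cost = max(
            (lab[k] for lab in labels.values() for k in lab if k in comp),
            default=0)
        group_cost.append(cost)
        for m in sorted(comp, key=order.index):
            membership[m] = gi
    return ParamGroups(membership, group_cost)


def assign_parameters(g: ComputationGraph, groups: ParamGroups,
                      parameteriser: Callable[[int], FHEParams] = parameterise_ckks,
                      ) -> dict[str, FHEParams]:
    """Build one FHEParams per group and configure the graph's FHE nodes.

    All sources in a group receive the identical parameter object and share a
    key id; encrypt and rotation nodes named as sources are configured in
    place via their ``configure_fhe`` hook.
    """
    params_by_group = {gi: parameteriser(cost)
                       for gi, cost in enumerate(groups.group_cost)}
    assignment: dict[str, FHEParams] = {}
    for source, gi in groups.membership.items():
        params = params_by_group[gi]
        assignment[source] = params
        if source not in g:
            raise ConsistencyError(
                f"group source {source!r} is not a node of the graph")
        node = g.node(source).node
        hook = getattr(node, "configure_fhe", None)
        if callable(hook):
            hook(params, f"key-group-{gi}")
    return assignment
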