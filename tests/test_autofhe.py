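"""Parameter discovery, group merging and the CKKS heuristic parameteriser."""

import numpy as np
import pytest

from fhenet.autofhe import (FHEParams, ParamGroups, assign_parameters, autohe,
                            autohe_discover, brute_force_group_cost,
                            parameterise_ckks)
from fhenet.errors import ConsistencyError, CycleError, UnknownNodeError
from fhenet.graph import ComputationGraph
from fhenet.layers import GenericNode, RotationNode

from conftest import ConcernNode, random_mdg


def _hand_trace(c: int, s: int, p: float):
    """Independent hand-derivation of the heuristic's chain and degree."""
    chain = [int(s * p)] + [s] * c + [int(s * p)]
    bits = 27
    while bits < sum(chain):
        bits *= 2
    return tuple(chain), 1024 * bits // 27


# ---------------------------------------------------------------------------
# parameterise_ckks
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("c,s,chain,degree", [
    (0, 40, (60, 60), 8192),
    (1, 40, (60, 40, 60), 8192),
    (2, 40, (60, 40, 40, 60), 8192),
    (3, 40, (60, 40, 40, 40, 60), 16384),
    (6, 40, (60, 40, 40, 40, 40, 40, 40, 60), 16384),
    (0, 30, (45, 45), 4096),
    (1, 30, (45, 30, 45), 8192),
    (4, 30, (45, 30, 30, 30, 30, 45), 8192),
    (5, 30, (45,) + (30,) * 5 + (45,), 16384),
])
def test_ckks_heuristic_matches_hand_trace(c, s, chain, degree):
    if s < 30:
        pytest.skip("warning case covered separately")
    params = parameterise_ckks(c, s, 1.5)
    assert params.coeff_mod_bit_sizes == chain
    assert params.poly_modulus_degree == degree
    assert params.scheme == 2 and params.scale == 2 ** s
    assert (chain, degree) == _hand_trace(c, s, 1.5)


def test_ckks_invariants_hold_across_costs():
    for c in range(0, 8):
        fp = parameterise_ckks(c)
        assert len(fp.coeff_mod_bit_sizes) == c + 2
        assert fp.coeff_mod_bit_sizes[0] == fp.coeff_mod_bit_sizes[-1] == 60
        assert all(m == 40 for m in fp.coeff_mod_bit_sizes[1:-1])
        assert fp.slot_capacity == fp.poly_modulus_degree // 2
        assert fp.depth == c
        # power-of-two degree
        assert fp.poly_modulus_degree & (fp.poly_modulus_degree - 1) == 0


def test_ckks_degree_monotone_in_cost_and_scale():
    degrees = [parameterise_ckks(c).poly_modulus_degree for c in range(10)]
    assert degrees == sorted(degrees)
    for c in (0, 2, 5):
        d30 = parameterise_ckks(c, 30).poly_modulus_degree
        d40 = parameterise_ckks(c, 40).poly_modulus_degree
        d50 = parameterise_ckks(c, 50).poly_modulus_degree
        assert d30 <= d40 <= d50


def test_ckks_low_scale_warns_and_bad_inputs_raise():
    with pytest.warns(UserWarning, match="below the advised minimum"):
        parameterise_ckks(1, 20)
    with pytest.raises(ValueError):
        parameterise_ckks(-1)
    with pytest.raises(ValueError):
        parameterise_ckks(1, 40, 0.5)


def test_params_roundtrip_dict():
    fp = parameterise_ckks(2)
    assert FHEParams.from_dict(fp.to_dict()) == fp


# ---------------------------------------------------------------------------
# discovery (source/cost labelling)
# ---------------------------------------------------------------------------

def _linear_concern_graph():
    g = ComputationGraph()
    g.add_node("x1", GenericNode(0))
    g.add_node("c0", GenericNode(1))
    g.add_node("c1", GenericNode(1))
    g.add_node("r0", RotationNode("refresh"))
    g.add_edge("x1", "c0")
    g.add_edge("c0", "c1")
    g.add_edge("c1", "r0")
    return g


def test_discover_accumulates_costs_and_restarts_at_concern():
    g = _linear_concern_graph()
    autohe_discover(g, "x1", "x1", (RotationNode,), 0)
    assert g.node("c0").meta["sources"] == {"x1": 1}
    assert g.node("c1").meta["sources"] == {"x1": 2}
    assert g.node("r0").meta["sources"] == {"x1": 2}


def test_discover_max_wins_over_parallel_paths():
    g = ComputationGraph()
    g.add_node("x", GenericNode(0))
    g.add_node("A", GenericNode(1))
    g.add_node("C", GenericNode(1))
    g.add_edge("x", "A")
    g.add_edge("A", "C")
    g.add_edge("x", "C")
    autohe_discover(g, "x", "x", (RotationNode,), 0)
    assert g.node("C").meta["sources"] == {"x": 2}


def test_discover_is_idempotent():
    g = _linear_concern_graph()
    autohe_discover(g, "x1", "x1", (RotationNode,), 0)
    first = {rec.name: dict(rec.meta.get("sources", {}))
             for rec in g.records()}
    autohe_discover(g, "x1", "x1", (RotationNode,), 0)
    second = {rec.name: dict(rec.meta.get("sources", {}))
              for rec in g.records()}
    assert first == second


def test_discover_cycle_error():
    g = ComputationGraph()
    g.add_node("x", GenericNode(0))
    g.add_node("A", GenericNode(1))
    g.add_node("B", GenericNode(1))
    g.add_edge("x", "A")
    g.add_edge("A", "B")
    g.add_edge("B", "A")
    with pytest.raises(CycleError):
        autohe_discover(g, "x", "x", (RotationNode,), 0)


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def test_fig4_topology_one_group_cost_two(fig4_graph):
    groups = autohe(fig4_graph, ["x0", "x1"], (RotationNode,))
    gx0, gx1 = groups.membership["x0"], groups.membership["x1"]
    assert gx0 == gx1
    assert groups.group_cost[gx0] == 2
    assert groups == brute_force_group_cost(fig4_graph, ["x0", "x1"],
                                            (RotationNode,))


def test_disconnected_chains_get_separate_groups():
    g = ComputationGraph()
    g.add_node("x0", GenericNode(0))
    g.add_node("A", GenericNode(1))
    g.add_node("sinkA", GenericNode(0))
    g.add_node("x1", GenericNode(0))
    g.add_node("B", GenericNode(3))
    g.add_node("sinkB", GenericNode(0))
    g.add_edge("x0", "A")
    g.add_edge("A", "sinkA")
    g.add_edge("x1", "B")
    g.add_edge("B", "sinkB")
    groups = autohe(g, ["x0", "x1"], (RotationNode,))
    assert groups.membership["x0"] != groups.membership["x1"]
    assert groups.group_cost[groups.membership["x0"]] == 1
    assert groups.group_cost[groups.membership["x1"]] == 3


def test_lone_source_is_its_own_zero_cost_group():
    g = ComputationGraph()
    g.add_node("x", GenericNode(0))
    groups = autohe(g, ["x"], (RotationNode,))
    assert groups.membership == {"x": 0}
    assert groups.group_cost == [0]


def test_unknown_source_raises(fig4_graph):
    with pytest.raises(UnknownNodeError):
        autohe(fig4_graph, ["nope"], (RotationNode,))


def test_autohe_equals_brute_force_on_random_graphs():
    """Oracle equivalence over 200 seeded random acyclic multi-digraphs."""
    mismatches = 0
    for seed in range(200):
        rng = np.random.default_rng(seed)
        g, sources = random_mdg(rng)
        got = autohe(g, sources, (ConcernNode,))
        want = brute_force_group_cost(g, sources, (ConcernNode,))
        if got != want:
            mismatches += 1
    assert mismatches == 0


def test_param_groups_equality_is_canonical():
    a = ParamGroups({"x": 0, "y": 1}, [2, 3])
    b = ParamGroups({"y": 0, "x": 1}, [3, 2])
    c = ParamGroups({"x": 0, "y": 0}, [3])
    assert a == b
    assert a != c


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def test_assignment_shares_params_within_group(fig4_graph):
    groups = autohe(fig4_graph, ["x0", "x1"], (RotationNode,))
    assignment = assign_parameters(fig4_graph, groups)
    assert assignment["x0"] is assignment["x1"]
    assert assignment["x0"].depth == 2
    # the rotation restarts a fresh source -> its own parameter set
    assert assignment["r0"] is not assignment["x0"]
    rot = fig4_graph.node("r0").node
    assert rot.params == assignment["r0"]
    assert rot.key_id is not None


def test_assignment_reflects_graph_edits(fig4_graph):
    before = autohe(fig4_graph, ["x0", "x1"], (RotationNode,))
    fig4_graph.add_node("c2", GenericNode(2))
    fig4_graph.add_edge("c1", "c2")
    after = autohe(fig4_graph, ["x0", "x1"], (RotationNode,))
    assert before != after
    assert after.group_cost[after.membership["x0"]] == 4  # c1(1)+c2(2)+c0 path
    assert after == brute_force_group_cost(fig4_graph, ["x0", "x1"],
                                           (RotationNode,))


def test_assignment_missing_source_is_inconsistent(fig4_graph):
    groups = ParamGroups({"ghost": 0}, [1])
    with pytest.raises(ConsistencyError):
        assign_parameters(fig4_graph, groups)
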