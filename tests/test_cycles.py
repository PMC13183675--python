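import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from loopscout.cycles import (
    Cycle,
    canonical_rotation,
    filter_regulatory,
    find_cycles,
    interpret_cycle,
    is_negative_feedback,
    motif_of,
    nested_cycles,
)
from loopscout.errors import CycleBudgetExceededError
from loopscout.model import GraphIntegrityError, NodeType

from _oracles import brute_force_cycles, random_graph
from conftest import make_graph


def cycle_key_set(cycles):
    return {(c.vertex_seq, c.edge_seq) for c in cycles}


def test_triangle_has_exactly_one_cycle(triangle):
    cycles = find_cycles(triangle)
    assert len(cycles) == 1
    assert cycles[0].length_nodes == 3
    assert cycles[0].vertex_seq == ("A", "B", "C")


def test_complete_digraph_on_three_vertices_has_five_cycles():
    """All six arcs among three vertices: three 2-cycles and two oriented
    3-cycles (value frozen from the brute-force oracle)."""
    g = make_graph(
        [
            (u, v, "mim-stimulation")
            for u in "ABC"
            for v in "ABC"
            if u != v
        ]
    )
    cycles = find_cycles(g)
    assert [c.length_nodes for c in cycles] == [2, 2, 2, 3, 3]
    assert cycle_key_set(cycles) == brute_force_cycles(g)


def test_dag_has_no_cycles():
    g = make_graph(
        [("A", "B", "arrow"), ("A", "C", "arrow"), ("B", "C", "arrow")]
    )
    assert find_cycles(g) == []


def test_self_edges_are_loops_not_cycles():
    g = make_graph([("A", "A", "mim-stimulation"), ("A", "B", "arrow")])
    assert find_cycles(g) == []


def test_parallel_edges_yield_one_cycle_per_combination():
    """Two parallel A->B edges and one B->A edge give two distinct
    cycles, distinguished by which parallel edge is traversed."""
    g = make_graph(
        [
            ("A", "B", "mim-stimulation"),
            ("A", "B", "mim-inhibition"),
            ("B", "A", "mim-stimulation"),
        ]
    )
    cycles = find_cycles(g)
    assert len(cycles) == 2
    flags = sorted(
        interpret_cycle(g, c).contains_inhibition for c in cycles
    )
    assert flags == [False, True]


def test_budget_overrun_raises_named_error():
    g = make_graph(
        [(u, v, "arrow") for u in "ABCD" for v in "ABCD" if u != v],
        pathway_id="dense",
    )
    with pytest.raises(CycleBudgetExceededError) as err:
        find_cycles(g, max_cycles=3)
    assert err.value.pathway_id == "dense"


@pytest.mark.parametrize("seed", range(5))
def test_enumeration_matches_brute_force_on_random_multigraphs(seed):
    """150 random directed multigraphs (n <= 6, m <= 12, parallel and
    self edges allowed) per seed batch: Johnson-with-expansion equals the
    exhaustive subset/ordering oracle."""
    rng = random.Random(1000 + seed)
    for _ in range(30):
        g = random_graph(rng)
        assert cycle_key_set(find_cycles(g)) == brute_force_cycles(g)


def test_returned_cycles_satisfy_structural_invariants():
    rng = random.Random(42)
    for _ in range(25):
        g = random_graph(rng)
        for c in find_cycles(g):
            assert len(set(c.vertex_seq)) == c.length_nodes >= 2
            n = c.length_nodes
            for i, eid in enumerate(c.edge_seq):
                e = g.edge(eid)
                assert (e.source, e.target) == (
                    c.vertex_seq[i],
                    c.vertex_seq[(i + 1) % n],
                )


@pytest.mark.parametrize(
    "types, inhibition, parity",
    [
        (("mim-stimulation", "mim-stimulation", "mim-inhibition"), True, "negative"),
        (("mim-inhibition", "mim-inhibition"), True, "positive"),
        (("mim-stimulation", "none"), False, "unsigned"),
        (("mim-stimulation", "mim-stimulation"), False, "positive"),
        (("mim-inhibition", "mim-conversion", "mim-inhibition"), True, "unsigned"),
    ],
)
def test_cycle_interpretation_truth_table(types, inhibition, parity):
    """contains_inhibition and sign-product parity on hand-enumerated
    edge-type sequences (the double-inhibition case exposes the
    difference between the two conventions)."""
    n = len(types)
    verts = [f"V{i}" for i in range(n)]
    g = make_graph(
        [(verts[i], verts[(i + 1) % n], types[i]) for i in range(n)]
    )
    (cycle,) = find_cycles(g)
    interp = interpret_cycle(g, cycle)
    assert interp.contains_inhibition is inhibition
    assert interp.parity_sign == parity
    assert is_negative_feedback(interp, "contains_inhibition") is inhibition
    assert is_negative_feedback(interp, "parity") is (parity == "negative")


def test_interpret_rejects_cycle_not_in_graph(triangle):
    rogue = Cycle(("A", "B"), ("e1", "bogus"))
    with pytest.raises(GraphIntegrityError):
        interpret_cycle(triangle, rogue)


def test_nested_cycles_proper_subset_rule():
    inner = Cycle(("A", "B"), ("x1", "x2"))
    outer = Cycle(("A", "B", "C"), ("y1", "y2", "y3"))
    pairs, summary = nested_cycles([inner, outer])
    assert pairs == [(0, 1)]
    assert summary == {"n_cycles": 2, "n_nested": 1, "pct_nested": 50.0}


def test_identical_vertex_sets_are_not_nested():
    a = Cycle(("A", "B"), ("x1", "x2"))
    b = Cycle(("A", "B"), ("z1", "z2"))
    pairs, summary = nested_cycles([a, b])
    assert pairs == [] and summary["n_nested"] == 0


def test_nesting_relation_is_irreflexive_and_transitive():
    rng = random.Random(7)
    for _ in range(40):
        g = random_graph(rng, max_nodes=6, max_edges=12)
        try:
            cycles = find_cycles(g, max_cycles=5000)
        except CycleBudgetExceededError:
            continue
        pairs, _ = nested_cycles(cycles)
        pair_set = set(pairs)
        assert all(i != j for i, j in pair_set)
        for i, j in pair_set:
            for k, l in pair_set:
                if j == k:
                    assert (i, l) in pair_set


def test_no_cycles_gives_zero_percent_nested():
    _, summary = nested_cycles([])
    assert summary == {"n_cycles": 0, "n_nested": 0, "pct_nested": 0.0}


# ---------------------------------------------------------------------------
# motifs


def test_mdm2_tp53_motif_rendering():
    g = make_graph(
        [("TP53", "MDM2", "mim-stimulation"), ("MDM2", "TP53", "mim-inhibition")]
    )
    (cycle,) = find_cycles(g)
    assert str(motif_of(g, cycle)) == "MDM2-TP53"


@given(st.lists(st.text(alphabet="ABCDE", min_size=1, max_size=3),
                min_size=2, max_size=6))
@settings(max_examples=200, derandomize=True)
def test_motif_canonicalization_is_rotation_invariant_and_idempotent(labels):
    base, _ = canonical_rotation(tuple(labels))
    for shift in range(len(labels)):
        rotated = tuple(labels[shift:] + labels[:shift])
        assert canonical_rotation(rotated)[0] == base
    assert canonical_rotation(base)[0] == base


def test_motif_orientation_is_preserved():
    cw = make_graph(
        [("A", "B", "arrow"), ("B", "C", "arrow"), ("C", "A", "arrow")]
    )
    ccw = make_graph(
        [("A", "C", "arrow"), ("C", "B", "arrow"), ("B", "A", "arrow")]
    )
    (c1,) = find_cycles(cw)
    (c2,) = find_cycles(ccw)
    assert str(motif_of(cw, c1)) == "A-B-C"
    assert str(motif_of(ccw, c2)) == "A-C-B"


# ---------------------------------------------------------------------------
# regulatory filter


def test_filter_keeps_only_signed_edges_between_molecular_nodes():
    g = make_graph(
        [
            ("X", "Y", "mim-inhibition"),
            ("Y", "Z", "mim-stimulation"),
            ("Z", "anc", "anchor-segment"),
            ("anc", "X", "mim-conversion"),
            ("lab", "X", "mim-stimulation"),
        ],
        node_types={"anc": NodeType.ANCHOR, "lab": NodeType.LABEL},
    )
    f = filter_regulatory(g)
    assert {(e.source, e.target) for e in f.edges} == {("X", "Y"), ("Y", "Z")}
    assert not f.has_node("anc") and not f.has_node("lab")


def test_filter_on_conversion_only_graph_is_edgeless():
    g = make_graph([("A", "B", "mim-conversion"), ("B", "C", "mim-conversion")])
    assert filter_regulatory(g).n_edges == 0


def test_filter_is_idempotent_on_random_graphs():
    rng = random.Random(11)
    for _ in range(30):
        g = random_graph(rng)
        once = filter_regulatory(g)
        twice = filter_regulatory(once)
        assert once == twice
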