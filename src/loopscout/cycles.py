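"""Elementary-cycle enumeration and feedback classification.

A *cycle* here is an elementary directed circuit through at least two
distinct vertices; a self-edge is a *loop* and is tracked separately by
the metrics panel, never enumerated as a cycle.  Enumeration runs on the
unfiltered multigraph by default, so schema-level anchor segments and
conversion chains can and do appear inside cycles; the regulatory filter
(:func:`filter_regulatory`) is an explicit opt-in pre-pass that strips
the graph down to molecular vertices and signed regulatory edges.

Feedback sign is classified under two conventions:

``contains_inhibition`` (default)
    a cycle is negative feedback iff it traverses at least one
    ``mim-inhibition`` edge — the convention used for corpus counting;
``parity``
    the control-theory convention: negative iff the product of edge
    signs is -1; a cycle traversing any unsigned edge is ``unsigned``.

The two disagree, e.g., on a double-inhibition 2-cycle (negative under
the first, positive under the second); both are exposed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import prod

import networkx as nx

from .errors import CycleBudgetExceededError
from .model import (
    MOLECULAR_NODE_TYPES,
    GraphIntegrityError,
    PathwayGraph,
)

__all__ = [
    "Cycle",
    "CycleInterpretation",
    "Motif",
    "find_cycles",
    "interpret_cycle",
    "is_negative_feedback",
    "nested_cycles",
    "motif_of",
    "filter_regulatory",
    "canonical_rotation",
]

DEFAULT_MAX_CYCLES = 100_000


@dataclass(frozen=True)
class Cycle:
    """An elementary directed circuit.

    ``vertex_seq`` lists each vertex once (the start is not repeated at
    the end); ``edge_seq[i]`` connects ``vertex_seq[i]`` to
    ``vertex_seq[(i+1) % n]``.  Stored in canonical rotation: the
    rotation whose vertex-id sequence is lexicographically smallest.
    """

    vertex_seq: tuple[str, ...]
    edge_seq: tuple[str, ...]

    @property
    def length_nodes(self) -> int:
        return len(self.vertex_seq)

    def __post_init__(self) -> None:
        if len(self.vertex_seq) < 2:
            raise ValueError("a cycle traverses at least 2 distinct vertices")
        if len(set(self.vertex_seq)) != len(self.vertex_seq):
            raise ValueError("elementary circuits visit each vertex once")
        if len(self.edge_seq) != len(self.vertex_seq):
            raise ValueError("edge_seq length must equal vertex_seq length")


@dataclass(frozen=True)
class CycleInterpretation:
    """Per-cycle detail read off in traversal order."""

    gene_labels: tuple[str, ...]
    edge_ids: tuple[str, ...]
    edge_types: tuple[str, ...]
    contains_inhibition: bool
    #: 'negative' | 'positive' | 'unsigned' — sign-product parity;
    #: 'unsigned' whenever any traversed edge has sign 0
    parity_sign: str


@dataclass(frozen=True)
class Motif:
    """Rotation-canonical, orientation-preserving gene-label sequence."""

    canonical_labels: tuple[str, ...]

    def __str__(self) -> str:
        return "-".join(self.canonical_labels)


def canonical_rotation(seq: tuple):
    """Rotate ``seq`` to its lexicographically smallest rotation.

    Ties from duplicate items are broken by continuing the comparison
    around the rotation (i.e. plain tuple comparison over the full
    rotation).  Returns ``(rotated_seq, offset)``.
    """
    n = len(seq)
    best = min(range(n), key=lambda i: tuple(seq[i:]) + tuple(seq[:i]))
    return tuple(seq[best:]) + tuple(seq[:best]), best


def find_cycles(
    graph: PathwayGraph, max_cycles: int = DEFAULT_MAX_CYCLES
) -> list[Cycle]:
    """Enumerate all elementary directed circuits of node-length >= 2.

    Vertex cycles come from Johnson's algorithm on the simple projection;
    each vertex cycle is then expanded into one :class:`Cycle` per
    distinct combination of parallel edges along it, because sign
    classification depends on which parallel edge is traversed.  Output
    is sorted by ``(length_nodes, canonical vertex sequence, edge
    sequence)`` for determinism.  Exceeding ``max_cycles`` raises
    :class:`CycleBudgetExceededError` naming the pathway.
    """
    if max_cycles < 1:
        raise ValueError("max_cycles must be >= 1")
    multi = graph.to_networkx()
    # parallel edge ids per ordered pair, excluding self-edges
    bundles: dict[tuple[str, str], list[str]] = {}
    for edge in graph.edges:
        if edge.source != edge.target:
            bundles.setdefault((edge.source, edge.target), []).append(edge.edge_id)
    simple = nx.DiGraph()
    simple.add_nodes_from(multi.nodes)
    simple.add_edges_from(bundles)

    cycles: list[Cycle] = []
    for vertex_cycle in nx.simple_cycles(simple):
        verts, _ = canonical_rotation(tuple(vertex_cycle))
        n = len(verts)
        hop_choices = [
            sorted(bundles[(verts[i], verts[(i + 1) % n])]) for i in range(n)
        ]
        for combo in itertools.product(*hop_choices):
            cycles.append(Cycle(verts, tuple(combo)))
            if len(cycles) > max_cycles:
                raise CycleBudgetExceededError(graph.pathway_id, max_cycles)
    cycles.sort(key=lambda c: (c.length_nodes, c.vertex_seq, c.edge_seq))
    return cycles


def interpret_cycle(graph: PathwayGraph, cycle: Cycle) -> CycleInterpretation:
    """Read labels, edge ids, and edge types off a cycle in order.

    Raises :class:`GraphIntegrityError` when the cycle does not fit the
    graph (missing edge id, or an edge not connecting consecutive
    vertices).
    """
    n = cycle.length_nodes
    types = []
    signs = []
    for i, eid in enumerate(cycle.edge_seq):
        edge = graph.edge(eid)
        expected = (cycle.vertex_seq[i], cycle.vertex_seq[(i + 1) % n])
        if (edge.source, edge.target) != expected:
            raise GraphIntegrityError(
                f"edge {eid!r} connects {edge.source}->{edge.target}, "
                f"cycle expects {expected[0]}->{expected[1]}"
            )
        types.append(edge.mim_type)
        signs.append(edge.sign)
    if 0 in signs:
        parity = "unsigned"
    else:
        parity = "negative" if prod(signs) == -1 else "positive"
    return CycleInterpretation(
        gene_labels=tuple(graph.label_of(v) for v in cycle.vertex_seq),
        edge_ids=tuple(cycle.edge_seq),
        edge_types=tuple(types),
        contains_inhibition="mim-inhibition" in types,
        parity_sign=parity,
    )


def is_negative_feedback(
    interp: CycleInterpretation, convention: str = "contains_inhibition"
) -> bool:
    """Classify a cycle as negative feedback under the chosen convention."""
    if convention == "contains_inhibition":
        return interp.contains_inhibition
    if convention == "parity":
        return interp.parity_sign == "negative"
    raise ValueError(f"unknown convention {convention!r}")


def nested_cycles(
    cycles: list[Cycle],
) -> tuple[list[tuple[int, int]], dict[str, float]]:
    """Detect nesting: cycle *i* is nested in *j* iff vertex-set(i) is a
    proper subset of vertex-set(j).

    Returns the sorted pair list and a summary with ``n_cycles``,
    ``n_nested`` (cycles that are inner in at least one pair) and
    ``pct_nested`` (0 when there are no cycles).
    """
    sets = [frozenset(c.vertex_seq) for c in cycles]
    pairs = [
        (i, j)
        for i in range(len(cycles))
        for j in range(len(cycles))
        if i != j and sets[i] < sets[j]
    ]
    inner = {i for i, _ in pairs}
    n = len(cycles)
    summary = {
        "n_cycles": n,
        "n_nested": len(inner),
        "pct_nested": 100.0 * len(inner) / n if n else 0.0,
    }
    return sorted(pairs), summary


def motif_of(graph: PathwayGraph, cycle: Cycle) -> Motif:
    """Canonical motif of a cycle: its vertex-label sequence rotated to
    the lexicographically smallest rotation, orientation preserved (no
    reversal), labels verbatim and case-sensitive."""
    labels = tuple(graph.label_of(v) for v in cycle.vertex_seq)
    canonical, _ = canonical_rotation(labels)
    return Motif(canonical)


def filter_regulatory(graph: PathwayGraph) -> PathwayGraph:
    """Strip a pathway graph down to its regulatory core.

    Retains only molecular vertices (gene products, proteins, RNAs,
    metabolites, complexes, groups) and only signed regulatory edges
    (stimulation, necessary stimulation, inhibition) whose endpoints both
    survive.  Anchors, labels, conversions, catalysis, binding and other
    schema-level or unsigned links are removed.  Idempotent; may return
    an edgeless graph.
    """
    kept_nodes = [n for n in graph.nodes if n.node_type in MOLECULAR_NODE_TYPES]
    kept_ids = {n.node_id for n in kept_nodes}
    kept_edges = [
        e
        for e in graph.edges
        if e.sign != 0 and e.source in kept_ids and e.target in kept_ids
    ]
    return PathwayGraph(
        graph.pathway_id,
        kept_nodes,
        kept_edges,
        title=graph.title,
        organism=graph.organism,
        source_format=graph.source_format,
    )
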