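from __future__ import annotations

import pytest

from loopscout.model import NodeType, PathwayEdge, PathwayGraph, PathwayNode


def make_graph(edges, pathway_id="g", node_types=None, extra_nodes=()):
    """Build a PathwayGraph from (source, target, mim_type) triples.

    Vertices are inferred from edge endpoints (label == id, type
    GeneProduct unless overridden via ``node_types``).
    """
    node_types = node_types or {}
    ids: list[str] = []
    for s, t, _ in edges:
        for v in (s, t):
            if v not in ids:
                ids.append(v)
    for v in extra_nodes:
        if v not in ids:
            ids.append(v)
    nodes = [
        PathwayNode(v, v, node_types.get(v, NodeType.GENE_PRODUCT)) for v in ids
    ]
    pe = [
        PathwayEdge(f"e{k}", s, t, mim)
        for k, (s, t, mim) in enumerate(edges, start=1)
    ]
    return PathwayGraph(pathway_id, nodes, pe)


@pytest.fixture
def triangle():
    return make_graph(
        [
            ("A", "B", "mim-stimulation"),
            ("B", "C", "mim-stimulation"),
            ("C", "A", "mim-stimulation"),
        ],
        pathway_id="triangle",
    )
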