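"""Core graph data model shared by the GPML/KGML parsers and all analyses.

A pathway is modeled as a directed multigraph: typed vertices
(:class:`PathwayNode`) and ordered, signed edges (:class:`PathwayEdge`)
whose interaction types are normalized to the Molecular Interaction Map
(MIM) arrowhead vocabulary.  Signs encode regulatory polarity:
``mim-inhibition`` is -1, ``mim-stimulation`` and
``mim-necessary-stimulation`` are +1, and every other type (conversions,
catalysis, binding, schema-level links ...) is unsigned (0).

Two schema-level edge types are model-internal rather than MIM proper:

``contained``
    group-membership edge (member -> group vertex);
``anchor-segment``
    the untyped leading portions of an interaction that has been split at
    anchor points so that other edges may terminate on it.

Both carry sign 0, so regulatory analyses can discard them uniformly.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import networkx as nx

__all__ = [
    "MIM_VOCABULARY",
    "NodeType",
    "SourceFormat",
    "PathwayNode",
    "PathwayEdge",
    "PathwayGraph",
    "VocabularyError",
    "GraphIntegrityError",
    "sign_of",
    "write_graphml",
    "write_edge_csv",
]


class VocabularyError(ValueError):
    """Raised when an edge-type label is not in the closed MIM vocabulary."""


class GraphIntegrityError(ValueError):
    """Raised when a :class:`PathwayGraph` violates a structural invariant."""


#: The closed edge-type vocabulary.  Parsers must normalize every source
#: annotation into this set; free-form annotations fall back to ``none``.
MIM_VOCABULARY = frozenset(
    {
        "mim-stimulation",
        "mim-necessary-stimulation",
        "mim-inhibition",
        "mim-conversion",
        "mim-catalysis",
        "mim-binding",
        "mim-modification",
        "mim-cleavage",
        "mim-transcription-translation",
        "mim-covalent-bond",
        "mim-gap",
        "arrow",
        "contained",
        "anchor-segment",
        "none",
    }
)

_NEGATIVE_TYPES = frozenset({"mim-inhibition"})
_POSITIVE_TYPES = frozenset({"mim-stimulation", "mim-necessary-stimulation"})


def sign_of(mim_type: str) -> int:
    """Return the regulatory sign (-1, 0, +1) of a MIM edge type.

    Total and deterministic over the 15-member vocabulary; any label
    outside it raises :class:`VocabularyError` (parsers are expected to
    normalize raw annotations first).
    """
    if mim_type not in MIM_VOCABULARY:
        raise VocabularyError(f"unknown edge type {mim_type!r}")
    if mim_type in _NEGATIVE_TYPES:
        return -1
    if mim_type in _POSITIVE_TYPES:
        return 1
    return 0


class NodeType(str, Enum):
    """Vertex categories.  Unknown source annotations map to ``Undefined``."""

    GENE_PRODUCT = "GeneProduct"
    PROTEIN = "Protein"
    RNA = "Rna"
    METABOLITE = "Metabolite"
    PATHWAY = "Pathway"
    COMPLEX = "Complex"
    GROUP = "Group"
    LABEL = "Label"
    ANCHOR = "Anchor"
    UNDEFINED = "Undefined"

    @classmethod
    def from_source(cls, raw: str | None) -> "NodeType":
        """Map a raw node-type annotation onto the enum; fallback Undefined."""
        if raw is None:
            return cls.UNDEFINED
        try:
            return cls(raw)
        except ValueError:
            return cls.UNDEFINED


class SourceFormat(str, Enum):
    GPML = "GPML"
    KGML = "KGML"
    SYNTHETIC = "SYNTHETIC"


# Molecular vertex types retained by the regulatory filter.
MOLECULAR_NODE_TYPES = frozenset(
    {
        NodeType.GENE_PRODUCT,
        NodeType.PROTEIN,
        NodeType.RNA,
        NodeType.METABOLITE,
        NodeType.COMPLEX,
        NodeType.GROUP,
    }
)


@dataclass(frozen=True)
class PathwayNode:
    node_id: str
    label: str
    node_type: NodeType = NodeType.UNDEFINED


@dataclass(frozen=True)
class PathwayEdge:
    edge_id: str
    source: str
    target: str
    mim_type: str = "none"
    sign: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sign", sign_of(self.mim_type))


class PathwayGraph:
    """A directed, edge-typed pathway multigraph.

    Parallel edges and self-edges are permitted.  Construction validates
    the structural invariants: unique vertex and edge identifiers, and
    every edge endpoint resolving to a vertex.
    """

    def __init__(
        self,
        pathway_id: str,
        nodes: Iterable[PathwayNode],
        edges: Iterable[PathwayEdge],
        *,
        title: str = "",
        organism: str = "",
        source_format: SourceFormat = SourceFormat.SYNTHETIC,
    ) -> None:
        self.pathway_id = pathway_id
        self.title = title
        self.organism = organism
        self.source_format = SourceFormat(source_format)
        self._nodes: dict[str, PathwayNode] = {}
        self._edges: dict[str, PathwayEdge] = {}
        self._edge_order: list[str] = []
        for node in nodes:
            if node.node_id in self._nodes:
                raise GraphIntegrityError(
                    f"duplicate vertex id {node.node_id!r} in {pathway_id}"
                )
            self._nodes[node.node_id] = node
        for edge in edges:
            if edge.edge_id in self._edges:
                raise GraphIntegrityError(
                    f"duplicate edge id {edge.edge_id!r} in {pathway_id}"
                )
            for endpoint in (edge.source, edge.target):
                if endpoint not in self._nodes:
                    raise GraphIntegrityError(
                        f"edge {edge.edge_id!r} references missing vertex "
                        f"{endpoint!r} in {pathway_id}"
                    )
            self._edges[edge.edge_id] = edge
            self._edge_order.append(edge.edge_id)

    # -- accessors ---------------------------------------------------------

    @property
    def nodes(self) -> list[PathwayNode]:
        return list(self._nodes.values())

    @property
    def edges(self) -> list[PathwayEdge]:
        return [self._edges[eid] for eid in self._edge_order]

    @property
    def n_vertices(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def node(self, node_id: str) -> PathwayNode:
        return self._nodes[node_id]

    def edge(self, edge_id: str) -> PathwayEdge:
        try:
            return self._edges[edge_id]
        except KeyError:
            raise GraphIntegrityError(
                f"edge id {edge_id!r} absent from {self.pathway_id}"
            ) from None

    def has_node(self, node_id: str) -> bool:
        return node_id in self._nodes

    def label_of(self, node_id: str) -> str:
        return self._nodes[node_id].label

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayGraph):
            return NotImplemented
        return (
            self.pathway_id == other.pathway_id
            and self._nodes == other._nodes
            and self._edges == other._edges
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"PathwayGraph({self.pathway_id!r}, {self.n_vertices} vertices, "
            f"{self.n_edges} edges)"
        )

    # -- conversions -------------------------------------------------------

    def to_networkx(self) -> nx.MultiDiGraph:
        """Render as a :class:`networkx.MultiDiGraph` (edge key = edge_id)."""
        g = nx.MultiDiGraph(
            pathway_id=self.pathway_id,
            title=self.title,
            organism=self.organism,
        )
        for node in self.nodes:
            g.add_node(node.node_id, label=node.label, node_type=node.node_type.value)
        for edge in self.edges:
            g.add_edge(
                edge.source,
                edge.target,
                key=edge.edge_id,
                edge_id=edge.edge_id,
                mim_type=edge.mim_type,
                sign=edge.sign,
            )
        return g


def write_graphml(graph: PathwayGraph, stream) -> None:
    """Write GraphML with label/node_type vertex attributes and
    mim_type/sign/edge_id edge attributes, in document order (byte-stable
    for a fixed input)."""
    nxg = graph.to_networkx()
    buffer = io.BytesIO()
    nx.write_graphml(nxg, buffer, named_key_ids=True, edge_id_from_attribute="edge_id")
    data = buffer.getvalue()
    if hasattr(stream, "write"):
        stream.write(data)
    else:
        with open(stream, "wb") as fh:
            fh.write(data)


def write_edge_csv(graph: PathwayGraph, stream) -> None:
    """Write the edge list as CSV: source_label, target_label, mim_type,
    sign, edge_id."""

    def _write(fh) -> None:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["source_label", "target_label", "mim_type", "sign", "edge_id"])
        for edge in graph.edges:
            writer.writerow(
                [
                    graph.label_of(edge.source),
                    graph.label_of(edge.target),
                    edge.mim_type,
                    edge.sign,
                    edge.edge_id,
                ]
            )

    if hasattr(stream, "write"):
        _write(stream)
    else:
        with open(stream, "w", newline="") as fh:
            _write(fh)
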