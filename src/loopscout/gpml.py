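"""WikiPathways GPML reader.

Parses GPML 2013a-style documents into :class:`~loopscout.model.PathwayGraph`:

* ``DataNode`` elements become typed vertices;
* ``Group`` elements become one vertex each, labelled ``Group1``,
  ``Group2``, ... in order of appearance, with ``contained`` edges from
  each member;
* ``Label`` elements become vertices only when an interaction point
  references them (free-floating captions are dropped);
* ``Anchor`` points declared on interactions become vertices, and the
  owning interaction is split into a chain of segments so that edges
  terminating on the anchor stay attached to the topology;
* interaction arrowheads are normalized into the MIM vocabulary via
  :func:`map_arrowhead`.

Only the first and last points of a multi-point interaction define its
endpoints; intermediate bend points and all layout geometry are ignored.
Interactions are never re-oriented: direction is always point order, and
an arrowhead sitting on the first point is logged but not honoured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO

from lxml import etree

from .errors import ParseError
from .model import (
    MIM_VOCABULARY,
    NodeType,
    PathwayEdge,
    PathwayGraph,
    PathwayNode,
    SourceFormat,
    sign_of,
)

logger = logging.getLogger(__name__)

__all__ = ["parse_gpml", "map_arrowhead", "RawInteraction"]

#: Arrowhead aliases outside the MIM vocabulary.
_ARROWHEAD_ALIASES = {
    "tbar": "mim-inhibition",
    "arrow": "arrow",
}


def map_arrowhead(arrowhead: str | None) -> tuple[str, int]:
    """Normalize a GPML ``ArrowHead`` annotation to ``(mim_type, sign)``.

    Case-insensitive and total: MIM labels pass through, ``TBar`` maps to
    ``mim-inhibition``, ``Arrow`` to the generic ``arrow`` type, an empty
    or absent annotation to ``none``, and any free-form label falls back
    to ``none`` with a warning recording the original text.
    """
    if not arrowhead:
        return "none", 0
    lowered = arrowhead.strip().lower()
    if lowered in MIM_VOCABULARY:
        return lowered, sign_of(lowered)
    if lowered in _ARROWHEAD_ALIASES:
        mim = _ARROWHEAD_ALIASES[lowered]
        return mim, sign_of(mim)
    logger.warning("unrecognized arrowhead %r mapped to 'none'", arrowhead)
    return "none", 0


@dataclass
class RawInteraction:
    """Intermediate record for one GPML ``Interaction`` element."""

    graph_id: str
    #: ordered (graph_ref, arrowhead) pairs; empty strings when absent
    points: list[tuple[str, str]] = field(default_factory=list)
    #: graph ids of Anchor elements declared on this interaction, in order
    anchors: list[str] = field(default_factory=list)


def _local(el) -> str:
    return etree.QName(el).localname


def _gpml_children(parent, name: str):
    for child in parent:
        if isinstance(child.tag, str) and etree.QName(child).localname == name:
            yield child


def _iter_descendants(root, name: str):
    for el in root.iter():
        if isinstance(el.tag, str) and etree.QName(el).localname == name:
            yield el


def parse_gpml(
    source: str | Path | bytes | BinaryIO,
    pathway_id: str | None = None,
) -> PathwayGraph:
    """Parse a GPML document into a :class:`PathwayGraph`.

    ``pathway_id`` defaults to the file stem when parsing from a path,
    otherwise to the pathway ``Name`` attribute.  Interactions whose
    endpoints cannot be resolved are skipped with a warning; malformed
    XML raises :class:`ParseError` with line information.
    """
    root, default_id = _read_xml(source)
    if _local(root) != "Pathway":
        raise ParseError(f"root element is {_local(root)!r}, expected 'Pathway'")
    ns = etree.QName(root).namespace or ""
    if ns and "gpml" not in ns.lower():
        raise ParseError(f"root namespace {ns!r} does not look like GPML")

    title = root.get("Name", "")
    organism = root.get("Organism", "")
    if pathway_id is None:
        pathway_id = default_id or title or "pathway"

    nodes: list[PathwayNode] = []
    contained: list[tuple[str, str]] = []  # (member vertex id, group vertex id)
    #: any referencable id (GraphId, GroupId) -> vertex id
    ref_map: dict[str, str] = {}
    synth_node = 0

    def _node_id(el) -> str:
        nonlocal synth_node
        gid = el.get("GraphId")
        if gid:
            return gid
        synth_node += 1
        return f"n{synth_node}"

    # Groups first so GroupRef/GraphId references resolve either way.
    group_of: dict[str, str] = {}  # GroupId -> vertex id
    for ordinal, el in enumerate(_iter_descendants(root, "Group"), start=1):
        vid = el.get("GraphId") or el.get("GroupId") or f"group{ordinal}"
        label = f"Group{ordinal}"
        nodes.append(PathwayNode(vid, label, NodeType.GROUP))
        ref_map[vid] = vid
        if el.get("GroupId"):
            group_of[el.get("GroupId")] = vid
            ref_map[el.get("GroupId")] = vid

    for el in _iter_descendants(root, "DataNode"):
        vid = _node_id(el)
        label = el.get("TextLabel", vid)
        node_type = NodeType.from_source(el.get("Type"))
        nodes.append(PathwayNode(vid, label, node_type))
        ref_map[vid] = vid
        group_ref = el.get("GroupRef")
        if group_ref and group_ref in group_of:
            contained.append((vid, group_of[group_ref]))
        elif group_ref:
            logger.warning(
                "DataNode %s references undeclared group %r", vid, group_ref
            )

    # Labels are only materialized when referenced by an interaction point.
    label_elements: dict[str, str] = {}
    for el in _iter_descendants(root, "Label"):
        gid = el.get("GraphId")
        if gid:
            label_elements[gid] = el.get("TextLabel", gid)

    # Interactions: first pass collects raw records and declares anchors.
    raw: list[RawInteraction] = []
    synth_edge = 0
    for el in _iter_descendants(root, "Interaction"):
        gid = el.get("GraphId")
        if not gid:
            synth_edge += 1
            gid = f"e{synth_edge}"
        record = RawInteraction(graph_id=gid)
        for graphics in _gpml_children(el, "Graphics"):
            for pt in _gpml_children(graphics, "Point"):
                record.points.append(
                    (pt.get("GraphRef", "") or "", pt.get("ArrowHead", "") or "")
                )
            for anchor in _gpml_children(graphics, "Anchor"):
                aid = anchor.get("GraphId")
                if not aid:
                    synth_node += 1
                    aid = f"n{synth_node}"
                record.anchors.append(aid)
                nodes.append(PathwayNode(aid, aid, NodeType.ANCHOR))
                ref_map[aid] = aid
        raw.append(record)

    # Materialize referenced labels.
    referenced = {ref for r in raw for ref, _ in r.points if ref}
    for gid, text in label_elements.items():
        if gid in referenced:
            nodes.append(PathwayNode(gid, text, NodeType.LABEL))
            ref_map[gid] = gid

    edges: list[PathwayEdge] = []
    for member, group in contained:
        edges.append(PathwayEdge(f"c.{member}", member, group, "contained"))

    for record in raw:
        edges.extend(_interaction_edges(record, ref_map))

    return PathwayGraph(
        pathway_id,
        nodes,
        edges,
        title=title,
        organism=organism,
        source_format=SourceFormat.GPML,
    )


def _interaction_edges(
    record: RawInteraction, ref_map: dict[str, str]
) -> list[PathwayEdge]:
    """Resolve one interaction into edges, splitting at its anchors.

    An interaction owning anchors ``a1..ak`` contributes the chain
    ``source -> a1 -> ... -> ak -> target``; only the terminal segment
    carries the interaction's mapped MIM type, earlier segments are
    schema-level ``anchor-segment`` edges.
    """
    if len(record.points) < 2:
        logger.warning("interaction %s has fewer than 2 points; skipped", record.graph_id)
        return []
    (src_ref, first_arrow) = record.points[0]
    (tgt_ref, last_arrow) = record.points[-1]
    if first_arrow:
        logger.warning(
            "interaction %s carries arrowhead %r on its first point; "
            "direction kept as point order",
            record.graph_id,
            first_arrow,
        )
    source = ref_map.get(src_ref)
    target = ref_map.get(tgt_ref)
    if source is None or target is None:
        missing = src_ref if source is None else tgt_ref
        logger.warning(
            "interaction %s references unknown endpoint %r; edge skipped",
            record.graph_id,
            missing or "<no GraphRef>",
        )
        return []
    mim_type, _ = map_arrowhead(last_arrow)
    if not record.anchors:
        return [PathwayEdge(record.graph_id, source, target, mim_type)]
    chain = [source, *record.anchors, target]
    edges = []
    for i in range(len(chain) - 1):
        segment_type = mim_type if i == len(chain) - 2 else "anchor-segment"
        edges.append(
            PathwayEdge(f"{record.graph_id}.{i + 1}", chain[i], chain[i + 1], segment_type)
        )
    return edges


def _read_xml(source) -> tuple[etree._Element, str | None]:
    default_id = None
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source)
        elif isinstance(source, (str, Path)):
            default_id = Path(source).stem
            root = etree.parse(str(source)).getroot()
        else:
            root = etree.parse(source).getroot()
    except etree.XMLSyntaxError as exc:
        line = exc.lineno if exc.lineno else None
        raise ParseError(str(exc), line=line) from exc
    except OSError as exc:
        raise ParseError(str(exc)) from exc
    return root, default_id
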