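"""KEGG KGML reader.

Maps ``entry`` / ``relation`` / ``reaction`` elements onto the same
directed multigraph model the GPML reader produces, normalizing KEGG's
own relation-subtype vocabulary into MIM edge types so that downstream
cycle and sign analyses are format-agnostic.

Entry types map as: gene -> GeneProduct, compound -> Metabolite,
group -> Group (with ``contained`` member edges from its ``component``
children), map -> Pathway, anything else -> Undefined.  Each relation
contributes one edge per subtype (a subtype-less relation contributes a
single untyped edge); each reaction contributes ``mim-conversion`` edges
substrate -> product, duplicated in reverse when reversible.  The
ECrel/PPrel/GErel/PCrel/maplink distinction is logged only; edge
semantics come solely from the subtype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import BinaryIO

from .errors import ParseError
from .gpml import _iter_descendants, _read_xml  # shared XML plumbing
from .model import (
    NodeType,
    PathwayEdge,
    PathwayGraph,
    PathwayNode,
    SourceFormat,
)

logger = logging.getLogger(__name__)

__all__ = ["parse_kgml", "map_kegg_subtype", "KgmlEntry"]

_ENTRY_TYPE_MAP = {
    "gene": NodeType.GENE_PRODUCT,
    "compound": NodeType.METABOLITE,
    "group": NodeType.GROUP,
    "map": NodeType.PATHWAY,
}

_SUBTYPE_MAP = {
    "activation": "mim-stimulation",
    "expression": "mim-stimulation",
    "inhibition": "mim-inhibition",
    "repression": "mim-inhibition",
    "binding/association": "mim-binding",
    "phosphorylation": "mim-modification",
    "dephosphorylation": "mim-modification",
    "glycosylation": "mim-modification",
    "ubiquitination": "mim-modification",
    "methylation": "mim-modification",
    "dissociation": "mim-cleavage",
    "compound": "mim-conversion",
    "hidden compound": "mim-conversion",
    "indirect effect": "none",
    "state change": "none",
    "missing interaction": "none",
    "unknown": "none",
}


def map_kegg_subtype(subtype_name: str) -> str:
    """Normalize a KGML relation subtype name to a MIM edge type.

    Total: names outside the known table fall back to ``none`` with a
    warning.  Inhibition and repression are the only sources of negative
    sign from KGML.
    """
    key = (subtype_name or "").strip().lower()
    if key in _SUBTYPE_MAP:
        return _SUBTYPE_MAP[key]
    logger.warning("unrecognized KGML subtype %r mapped to 'none'", subtype_name)
    return "none"


@dataclass(frozen=True)
class KgmlEntry:
    """Intermediate record for one KGML ``entry`` element."""

    entry_id: str
    entry_type: str
    display_name: str


def _display_name(el) -> str:
    """First comma-separated token of the graphics name, sans trailing dots."""
    for g in el:
        if isinstance(g.tag, str) and g.tag.rsplit("}", 1)[-1] == "graphics":
            name = g.get("name")
            if name:
                token = name.split(",")[0].strip()
                return token.rstrip(".")
    return el.get("name", el.get("id", ""))


def parse_kgml(
    source: str | Path | bytes | BinaryIO,
    pathway_id: str | None = None,
) -> PathwayGraph:
    """Parse a KGML document into a :class:`PathwayGraph`.

    ``pathway_id`` defaults to the pathway ``name`` attribute with any
    ``path:`` prefix removed, falling back to the file stem.  Relations
    and reactions referencing unknown entry ids are skipped with a
    warning; malformed XML raises :class:`ParseError`.
    """
    root, default_id = _read_xml(source)
    local = root.tag.rsplit("}", 1)[-1]
    if local != "pathway":
        raise ParseError(f"root element is {local!r}, expected 'pathway'")

    name = (root.get("name") or "").removeprefix("path:")
    if pathway_id is None:
        pathway_id = name or default_id or "pathway"
    title = root.get("title", "")
    organism = root.get("org", "")

    nodes: list[PathwayNode] = []
    edges: list[PathwayEdge] = []
    known: set[str] = set()
    group_ordinal = 0

    # entries -> vertices
    components: list[tuple[str, str]] = []  # (member id, group id)
    for el in _iter_descendants(root, "entry"):
        eid = el.get("id")
        if eid is None or eid in known:
            logger.warning("entry with missing or duplicate id %r skipped", eid)
            continue
        etype = el.get("type", "other")
        if etype == "group":
            group_ordinal += 1
            label = f"Group{group_ordinal}"
            for comp in _iter_descendants(el, "component"):
                ref = comp.get("id")
                if ref:
                    components.append((ref, eid))
        else:
            label = _display_name(el)
        nodes.append(
            PathwayNode(eid, label, _ENTRY_TYPE_MAP.get(etype, NodeType.UNDEFINED))
        )
        known.add(eid)

    for member, group in components:
        if member in known:
            edges.append(PathwayEdge(f"c.{member}.{group}", member, group, "contained"))
        else:
            logger.warning(
                "group %s component %r not among entries; membership skipped",
                group,
                member,
            )

    # relations -> one edge per subtype
    for index, el in enumerate(_iter_descendants(root, "relation"), start=1):
        e1, e2 = el.get("entry1"), el.get("entry2")
        if e1 not in known or e2 not in known:
            logger.warning(
                "relation %s->%s references unknown entry; edge skipped", e1, e2
            )
            continue
        logger.debug("relation %s->%s of kind %s", e1, e2, el.get("type"))
        subtypes = [
            st.get("name", "") for st in _iter_descendants(el, "subtype")
        ]
        if not subtypes:
            edges.append(PathwayEdge(f"rel{index}", e1, e2, "none"))
            continue
        for j, st_name in enumerate(subtypes, start=1):
            edge_id = f"rel{index}" if len(subtypes) == 1 else f"rel{index}.{j}"
            edges.append(PathwayEdge(edge_id, e1, e2, map_kegg_subtype(st_name)))

    # reactions -> conversion edges substrate -> product
    for index, el in enumerate(_iter_descendants(root, "reaction"), start=1):
        substrates = [s.get("id") for s in _iter_descendants(el, "substrate")]
        products = [p.get("id") for p in _iter_descendants(el, "product")]
        reversible = el.get("type") == "reversible"
        j = 0
        for s in substrates:
            for p in products:
                if s not in known or p not in known:
                    logger.warning(
                        "reaction %s: endpoint %r unknown; edge skipped",
                        el.get("name", index),
                        s if s not in known else p,
                    )
                    continue
                j += 1
                edges.append(PathwayEdge(f"rx{index}.{j}", s, p, "mim-conversion"))
                if reversible:
                    edges.append(PathwayEdge(f"rx{index}.{j}r", p, s, "mim-conversion"))

    return PathwayGraph(
        pathway_id,
        nodes,
        edges,
        title=title,
        organism=organism,
        source_format=SourceFormat.KGML,
    )
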