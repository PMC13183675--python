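"""Minimal deterministic GPML 2013a / KGML document builders.

Used by the synthetic fixture generator and the bundled literature-style
example pathways.  Only the structural features the readers consume are
emitted (DataNodes, Labels, Groups, Interactions with Points/Anchors;
entries, relations, reactions); layout attributes are filled with fixed
placeholder geometry so the documents validate visually but carry no
information.
"""

from __future__ import annotations

from lxml import etree

GPML_NS = "http://pathvisio.org/GPML/2013a"


class GpmlBuilder:
    def __init__(self, name: str, organism: str = "Homo sapiens"):
        self.root = etree.Element(
            f"{{{GPML_NS}}}Pathway",
            nsmap={None: GPML_NS},
            Name=name,
            Organism=organism,
            Version="1",
        )

    def data_node(
        self, graph_id: str, label: str, node_type: str = "GeneProduct",
        group_ref: str | None = None,
    ) -> None:
        attrs = {"TextLabel": label, "GraphId": graph_id, "Type": node_type}
        if group_ref:
            attrs["GroupRef"] = group_ref
        el = etree.SubElement(self.root, f"{{{GPML_NS}}}DataNode", **attrs)
        etree.SubElement(
            el, f"{{{GPML_NS}}}Graphics", CenterX="0.0", CenterY="0.0",
            Width="80.0", Height="20.0",
        )

    def label(self, graph_id: str, text: str) -> None:
        el = etree.SubElement(
            self.root, f"{{{GPML_NS}}}Label", TextLabel=text, GraphId=graph_id
        )
        etree.SubElement(
            el, f"{{{GPML_NS}}}Graphics", CenterX="0.0", CenterY="0.0",
            Width="80.0", Height="20.0",
        )

    def interaction(
        self,
        graph_id: str,
        source_ref: str,
        target_ref: str,
        arrowhead: str | None = None,
        anchors: tuple[str, ...] = (),
    ) -> None:
        el = etree.SubElement(
            self.root, f"{{{GPML_NS}}}Interaction", GraphId=graph_id
        )
        graphics = etree.SubElement(el, f"{{{GPML_NS}}}Graphics")
        etree.SubElement(
            graphics, f"{{{GPML_NS}}}Point", X="0.0", Y="0.0", GraphRef=source_ref
        )
        end_attrs = {"X": "1.0", "Y": "1.0", "GraphRef": target_ref}
        if arrowhead:
            end_attrs["ArrowHead"] = arrowhead
        etree.SubElement(graphics, f"{{{GPML_NS}}}Point", **end_attrs)
        for aid in anchors:
            etree.SubElement(
                graphics, f"{{{GPML_NS}}}Anchor", Position="0.5", GraphId=aid
            )

    def group(self, group_id: str) -> None:
        etree.SubElement(self.root, f"{{{GPML_NS}}}Group", GroupId=group_id)

    def tobytes(self) -> bytes:
        return etree.tostring(
            self.root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
        )


class KgmlBuilder:
    def __init__(self, name: str, org: str = "hsa", title: str = ""):
        self.root = etree.Element(
            "pathway", name=f"path:{name}", org=org, number="0", title=title
        )
        self._relations: list[etree._Element] = []

    def entry(
        self, entry_id: str, name: str, entry_type: str = "gene",
        components: tuple[str, ...] = (),
    ) -> None:
        el = etree.SubElement(
            self.root, "entry", id=entry_id, name=name, type=entry_type
        )
        etree.SubElement(
            el, "graphics", name=name, type="rectangle", x="0", y="0",
            width="46", height="17",
        )
        for comp in components:
            etree.SubElement(el, "component", id=comp)

    def relation(
        self, entry1: str, entry2: str, subtypes: tuple[str, ...],
        rel_type: str = "PPrel",
    ) -> None:
        el = etree.SubElement(
            self.root, "relation", entry1=entry1, entry2=entry2, type=rel_type
        )
        for name in subtypes:
            etree.SubElement(el, "subtype", name=name, value="--")

    def reaction(
        self, substrates: tuple[str, ...], products: tuple[str, ...],
        reaction_type: str = "irreversible", name: str = "rn:R00000",
    ) -> None:
        el = etree.SubElement(
            self.root, "reaction", id=str(100 + len(self.root)), name=name,
            type=reaction_type,
        )
        for s in substrates:
            etree.SubElement(el, "substrate", id=s, name=f"cpd:{s}")
        for p in products:
            etree.SubElement(el, "product", id=p, name=f"cpd:{p}")

    def tobytes(self) -> bytes:
        return etree.tostring(
            self.root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
        )
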