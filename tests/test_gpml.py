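import pytest

from loopscout.errors import ParseError
from loopscout.gpml import map_arrowhead, parse_gpml
from loopscout.model import NodeType

NS = "http://pathvisio.org/GPML/2013a"


def gpml_doc(body: str) -> bytes:
    return f'<Pathway xmlns="{NS}" Name="test" Organism="Homo sapiens">{body}</Pathway>'.encode()


def data_node(gid, label=None, ntype="GeneProduct", group_ref=""):
    group = f' GroupRef="{group_ref}"' if group_ref else ""
    return (
        f'<DataNode TextLabel="{label or gid}" GraphId="{gid}" Type="{ntype}"{group}>'
        "<Graphics/></DataNode>"
    )


def interaction(gid, src, tgt, arrowhead=None, anchors=(), first_arrow=None):
    head = f' ArrowHead="{arrowhead}"' if arrowhead else ""
    first = f' ArrowHead="{first_arrow}"' if first_arrow else ""
    anchor_xml = "".join(f'<Anchor Position="0.5" GraphId="{a}"/>' for a in anchors)
    return (
        f'<Interaction GraphId="{gid}"><Graphics>'
        f'<Point X="0" Y="0" GraphRef="{src}"{first}/>'
        f'<Point X="1" Y="1" GraphRef="{tgt}"{head}/>'
        f"{anchor_xml}</Graphics></Interaction>"
    )


def test_three_node_chain_with_mixed_arrowheads():
    """A stimulation, an inhibition, and an untyped interaction map to
    signs +1, -1, 0 on a three-vertex graph (hand-built expectation)."""
    doc = gpml_doc(
        data_node("A") + data_node("B") + data_node("C")
        + interaction("i1", "A", "B", "mim-stimulation")
        + interaction("i2", "B", "C", "mim-inhibition")
        + interaction("i3", "C", "A")
    )
    g = parse_gpml(doc)
    assert g.n_vertices == 3 and g.n_edges == 3
    by_id = {e.edge_id: e for e in g.edges}
    assert (by_id["i1"].mim_type, by_id["i1"].sign) == ("mim-stimulation", 1)
    assert (by_id["i2"].mim_type, by_id["i2"].sign) == ("mim-inhibition", -1)
    assert (by_id["i3"].mim_type, by_id["i3"].sign) == ("none", 0)


def test_empty_document_yields_empty_graph():
    g = parse_gpml(gpml_doc(""))
    assert g.n_vertices == 0 and g.n_edges == 0
    assert g.title == "test" and g.organism == "Homo sapiens"


@pytest.mark.parametrize(
    "arrowhead, expected",
    [
        ("mim-inhibition", ("mim-inhibition", -1)),
        ("mim-stimulation", ("mim-stimulation", 1)),
        ("MIM-Necessary-Stimulation", ("mim-necessary-stimulation", 1)),
        ("TBar", ("mim-inhibition", -1)),
        ("tbar", ("mim-inhibition", -1)),
        ("Arrow", ("arrow", 0)),
        ("", ("none", 0)),
        (None, ("none", 0)),
        ("SomeFreeFormText", ("none", 0)),
    ],
)
def test_arrowhead_normalization_is_total_and_case_insensitive(arrowhead, expected):
    assert map_arrowhead(arrowhead) == expected


def test_anchor_splits_interaction_into_typed_terminal_segment():
    """S->T with one anchor plus a catalysis edge onto the anchor yields
    S->a (anchor-segment), a->T (original type), E->a (catalysis)."""
    doc = gpml_doc(
        data_node("S") + data_node("T") + data_node("E")
        + interaction("main", "S", "T", "mim-conversion", anchors=("a",))
        + interaction("side", "E", "a", "mim-catalysis")
    )
    g = parse_gpml(doc)
    assert g.node("a").node_type is NodeType.ANCHOR
    edges = {(e.source, e.target): e.mim_type for e in g.edges}
    assert edges == {
        ("S", "a"): "anchor-segment",
        ("a", "T"): "mim-conversion",
        ("E", "a"): "mim-catalysis",
    }


def test_two_anchors_make_three_segments_with_only_last_typed():
    doc = gpml_doc(
        data_node("S") + data_node("T")
        + interaction("m", "S", "T", "mim-inhibition", anchors=("a1", "a2"))
    )
    g = parse_gpml(doc)
    types = [e.mim_type for e in g.edges]
    assert types == ["anchor-segment", "anchor-segment", "mim-inhibition"]
    assert [(e.source, e.target) for e in g.edges] == [
        ("S", "a1"), ("a1", "a2"), ("a2", "T"),
    ]


def test_group_membership_and_group_endpoint_resolution():
    """Members connect to the group vertex via contained edges, and an
    interaction targeting the GroupId lands on the group vertex, which
    carries a synthesized ordinal label."""
    doc = gpml_doc(
        '<Group GroupId="gg"/>'
        + data_node("M1", group_ref="gg") + data_node("M2", group_ref="gg")
        + data_node("X")
        + interaction("i1", "X", "gg", "mim-stimulation")
    )
    g = parse_gpml(doc)
    group = g.node("gg")
    assert group.node_type is NodeType.GROUP and group.label == "Group1"
    contained = {(e.source, e.target) for e in g.edges if e.mim_type == "contained"}
    assert contained == {("M1", "gg"), ("M2", "gg")}
    assert any(e.target == "gg" and e.sign == 1 for e in g.edges)


def test_labels_become_vertices_only_when_referenced():
    doc = gpml_doc(
        data_node("A")
        + '<Label TextLabel="Imported" GraphId="lab1"><Graphics/></Label>'
        + '<Label TextLabel="Caption" GraphId="lab2"><Graphics/></Label>'
        + interaction("i1", "A", "lab1", "mim-stimulation")
    )
    g = parse_gpml(doc)
    assert g.has_node("lab1") and g.node("lab1").node_type is NodeType.LABEL
    assert g.node("lab1").label == "Imported"
    assert not g.has_node("lab2")


def test_dangling_endpoint_skips_edge_but_keeps_graph():
    doc = gpml_doc(
        data_node("A") + data_node("B")
        + interaction("ok", "A", "B", "mim-stimulation")
        + interaction("bad", "A", "ghost", "mim-inhibition")
    )
    g = parse_gpml(doc)
    assert [e.edge_id for e in g.edges] == ["ok"]


def test_malformed_xml_raises_parse_error_with_line():
    with pytest.raises(ParseError):
        parse_gpml(b"<Pathway xmlns='http://pathvisio.org/GPML/2013a'><DataNode>")


def test_non_gpml_namespace_is_rejected():
    with pytest.raises(ParseError):
        parse_gpml(b"<Pathway xmlns='http://example.org/other'/>")


def test_parsing_is_deterministic():
    doc = gpml_doc(
        data_node("A") + data_node("B")
        + interaction("i1", "A", "B", "TBar")
    )
    assert parse_gpml(doc) == parse_gpml(doc)


def test_arrowhead_on_first_point_does_not_reorient(caplog):
    doc = gpml_doc(
        data_node("A") + data_node("B")
        + interaction("i1", "A", "B", first_arrow="mim-inhibition")
    )
    g = parse_gpml(doc)
    (edge,) = g.edges
    assert (edge.source, edge.target) == ("A", "B")
    assert edge.mim_type == "none"  # last point carries no arrowhead
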