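"""Synthetic pathway fixtures with known ground truth.

Generates deterministic GPML or KGML documents in which the complete
topology — every vertex, every edge, and every elementary cycle — is
known by construction and recorded in a :class:`FixtureManifest`.  The
round trip *generate -> parse -> compare against manifest* is the
backbone of the test suite: it exercises the readers, the cycle engine,
and the sign classifier without any database downloads.

Planted cycles are vertex-disjoint, realized with ``mim-stimulation``
(+1), ``mim-inhibition`` (-1) or ``mim-conversion`` (0) edges according
to their sign pattern.  Additional random edges are drawn only among
vertices not on any planted cycle and only in ascending vertex order, so
they form a DAG and can never create an unplanned cycle.  Optional group
and anchor constructs exercise the schema-level features of each format
(KGML has no anchor concept, so there the anchor flag plants the closest
schema-level construct: a reaction with an associated enzyme relation).
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from math import prod

from ._xmlbuild import GpmlBuilder, KgmlBuilder
from .model import PathwayGraph

__all__ = ["FixtureSpec", "FixtureManifest", "generate_fixture"]

_SIGN_TO_GPML = {1: "mim-stimulation", -1: "mim-inhibition", 0: "mim-conversion"}
_SIGN_TO_KGML_SUBTYPE = {1: "activation", -1: "inhibition", 0: "compound"}
_SIGN_TO_MIM = {1: "mim-stimulation", -1: "mim-inhibition", 0: "mim-conversion"}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic pathway document."""

    n_genes: int = 6
    #: list of (length, sign_pattern); pattern length must equal length
    planted_cycles: tuple[tuple[int, tuple[int, ...]], ...] = ()
    n_random_dag_edges: int = 0
    with_group: bool = False
    with_anchor: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.n_random_dag_edges < 0:
            raise ValueError("counts must be non-negative")
        used = 0
        for length, pattern in self.planted_cycles:
            if length < 2:
                raise ValueError("planted cycles need length >= 2")
            if len(pattern) != length:
                raise ValueError("sign pattern length must equal cycle length")
            if any(s not in (-1, 0, 1) for s in pattern):
                raise ValueError("signs must be in {-1, 0, +1}")
            used += length
        if used > self.n_genes:
            raise ValueError(
                f"planted cycles need {used} vertices but only "
                f"{self.n_genes} genes requested"
            )
        free = self.n_genes - used
        if self.n_random_dag_edges > free * (free - 1) // 2:
            raise ValueError(
                "not enough non-cycle vertices to host the requested DAG edges"
            )


@dataclass(frozen=True)
class ExpectedCycle:
    labels: tuple[str, ...]  # canonical rotation
    contains_inhibition: bool
    parity_sign: str


@dataclass
class FixtureManifest:
    """Ground truth paired with a generated document."""

    pathway_id: str
    nodes: list[tuple[str, str, str]] = field(default_factory=list)
    edges: list[tuple[str, str, str, str, int]] = field(default_factory=list)
    cycles: list[ExpectedCycle] = field(default_factory=list)

    def node_set(self) -> set[tuple[str, str, str]]:
        return set(self.nodes)

    def edge_multiset(self) -> Counter:
        return Counter(self.edges)

    def assert_matches(self, graph: PathwayGraph) -> None:
        """Raise AssertionError unless ``graph`` equals the manifest."""
        got_nodes = {
            (n.node_id, n.label, n.node_type.value) for n in graph.nodes
        }
        if got_nodes != self.node_set():
            raise AssertionError(
                f"vertex mismatch: only-parsed={got_nodes - self.node_set()}, "
                f"only-expected={self.node_set() - got_nodes}"
            )
        got_edges = Counter(
            (e.edge_id, e.source, e.target, e.mim_type, e.sign)
            for e in graph.edges
        )
        if got_edges != self.edge_multiset():
            only_parsed = got_edges - self.edge_multiset()
            only_expected = self.edge_multiset() - got_edges
            raise AssertionError(
                f"edge mismatch: only-parsed={dict(only_parsed)}, "
                f"only-expected={dict(only_expected)}"
            )


def _canonical(labels: tuple[str, ...]) -> tuple[str, ...]:
    n = len(labels)
    best = min(range(n), key=lambda i: labels[i:] + labels[:i])
    return labels[best:] + labels[:best]


def _expected_cycle(labels: tuple[str, ...], pattern: tuple[int, ...]) -> ExpectedCycle:
    if 0 in pattern:
        parity = "unsigned"
    else:
        parity = "negative" if prod(pattern) == -1 else "positive"
    return ExpectedCycle(
        labels=_canonical(labels),
        contains_inhibition=-1 in pattern,
        parity_sign=parity,
    )


def generate_fixture(
    spec: FixtureSpec, format: str = "gpml"
) -> tuple[bytes, FixtureManifest]:
    """Generate a pathway document plus its ground-truth manifest.

    Deterministic: the same (spec, format) yields byte-identical output.
    """
    fmt = format.lower()
    if fmt == "gpml":
        return _generate_gpml(spec)
    if fmt == "kgml":
        return _generate_kgml(spec)
    raise ValueError(f"unknown format {format!r}")


def _plan(spec: FixtureSpec):
    """Shared layout: gene labels, cycle edge plan, DAG edge plan."""
    genes = [f"G{i + 1}" for i in range(spec.n_genes)]
    cycle_edges: list[tuple[int, int, int, int]] = []  # (cycle_no, src, tgt, sign)
    cursor = 0
    cycle_truth: list[ExpectedCycle] = []
    for c_no, (length, pattern) in enumerate(spec.planted_cycles, start=1):
        members = list(range(cursor, cursor + length))
        cursor += length
        for j in range(length):
            cycle_edges.append(
                (c_no, members[j], members[(j + 1) % length], pattern[j])
            )
        cycle_truth.append(
            _expected_cycle(tuple(genes[i] for i in members), tuple(pattern))
        )
    free = list(range(cursor, spec.n_genes))
    all_pairs = [(i, j) for i in free for j in free if i < j]
    rng = random.Random(spec.seed)
    dag_edges = sorted(rng.sample(all_pairs, spec.n_random_dag_edges))
    return genes, cycle_edges, dag_edges, cycle_truth


def _generate_gpml(spec: FixtureSpec) -> tuple[bytes, FixtureManifest]:
    pathway_id = f"synfix{spec.seed}"
    genes, cycle_edges, dag_edges, cycle_truth = _plan(spec)
    builder = GpmlBuilder(pathway_id)
    manifest = FixtureManifest(pathway_id=pathway_id, cycles=cycle_truth)

    for label in genes:
        builder.data_node(label, label, "GeneProduct")
        manifest.nodes.append((label, label, "GeneProduct"))

    if spec.with_group:
        builder.group("grp1")
        manifest.nodes.append(("grp1", "Group1", "Group"))
        for member in ("GM1", "GM2"):
            builder.data_node(member, member, "GeneProduct", group_ref="grp1")
            manifest.nodes.append((member, member, "GeneProduct"))
            manifest.edges.append((f"c.{member}", member, "grp1", "contained", 0))

    for k, (c_no, src, tgt, sign) in enumerate(cycle_edges, start=1):
        eid = f"cyc{c_no}e{k}"
        builder.interaction(eid, genes[src], genes[tgt], _SIGN_TO_GPML[sign])
        manifest.edges.append((eid, genes[src], genes[tgt], _SIGN_TO_MIM[sign], sign))

    for k, (src, tgt) in enumerate(dag_edges, start=1):
        eid = f"dag{k}"
        builder.interaction(eid, genes[src], genes[tgt], "Arrow")
        manifest.edges.append((eid, genes[src], genes[tgt], "arrow", 0))

    if spec.with_anchor:
        for vid in ("AX", "AY", "AZ"):
            builder.data_node(vid, vid, "GeneProduct")
            manifest.nodes.append((vid, vid, "GeneProduct"))
        builder.interaction("anch1", "AX", "AY", "mim-conversion", anchors=("anc1",))
        builder.interaction("anch2", "AZ", "anc1", "mim-catalysis")
        manifest.nodes.append(("anc1", "anc1", "Anchor"))
        manifest.edges.append(("anch1.1", "AX", "anc1", "anchor-segment", 0))
        manifest.edges.append(("anch1.2", "anc1", "AY", "mim-conversion", 0))
        manifest.edges.append(("anch2", "AZ", "anc1", "mim-catalysis", 0))

    return builder.tobytes(), manifest


def _generate_kgml(spec: FixtureSpec) -> tuple[bytes, FixtureManifest]:
    pathway_id = f"synfix{spec.seed}"
    genes, cycle_edges, dag_edges, cycle_truth = _plan(spec)
    builder = KgmlBuilder(pathway_id)
    manifest = FixtureManifest(pathway_id=pathway_id, cycles=cycle_truth)

    entry_id: dict[str, str] = {}
    next_id = 1

    def _add_entry(label: str, entry_type: str = "gene", **kwargs) -> str:
        nonlocal next_id
        eid = str(next_id)
        next_id += 1
        entry_id[label] = eid
        builder.entry(eid, label, entry_type, **kwargs)
        return eid

    for label in genes:
        eid = _add_entry(label)
        manifest.nodes.append((eid, label, "GeneProduct"))

    if spec.with_group:
        member_ids = []
        for member in ("GM1", "GM2"):
            eid = _add_entry(member)
            manifest.nodes.append((eid, member, "GeneProduct"))
            member_ids.append(eid)
        gid = str(next_id)
        next_id += 1
        builder.entry(gid, "group", "group", components=tuple(member_ids))
        manifest.nodes.append((gid, "Group1", "Group"))
        for mid in member_ids:
            manifest.edges.append((f"c.{mid}.{gid}", mid, gid, "contained", 0))

    anchor_ids: dict[str, str] = {}
    if spec.with_anchor:
        for label, etype, ntype in (
            ("X1", "compound", "Metabolite"),
            ("X2", "compound", "Metabolite"),
            ("EZ", "gene", "GeneProduct"),
        ):
            eid = _add_entry(label, etype)
            anchor_ids[label] = eid
            manifest.nodes.append((eid, label, ntype))

    rel_index = 0
    for c_no, src, tgt, sign in cycle_edges:
        rel_index += 1
        s, t = entry_id[genes[src]], entry_id[genes[tgt]]
        builder.relation(s, t, (_SIGN_TO_KGML_SUBTYPE[sign],))
        manifest.edges.append((f"rel{rel_index}", s, t, _SIGN_TO_MIM[sign], sign))

    for src, tgt in dag_edges:
        rel_index += 1
        s, t = entry_id[genes[src]], entry_id[genes[tgt]]
        builder.relation(s, t, ("binding/association",))
        manifest.edges.append((f"rel{rel_index}", s, t, "mim-binding", 0))

    if spec.with_anchor:
        rel_index += 1
        builder.relation(anchor_ids["EZ"], anchor_ids["X1"], ("compound",), "ECrel")
        manifest.edges.append(
            (f"rel{rel_index}", anchor_ids["EZ"], anchor_ids["X1"], "mim-conversion", 0)
        )
        builder.reaction((anchor_ids["X1"],), (anchor_ids["X2"],))
        manifest.edges.append(
            ("rx1.1", anchor_ids["X1"], anchor_ids["X2"], "mim-conversion", 0)
        )

    return builder.tobytes(), manifest
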