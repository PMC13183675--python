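"""Global graph-topology metrics for one pathway.

The panel mixes directed and undirected conventions, chosen to match the
common defaults of the metric definitions it reproduces:

* density and reciprocity are computed on the directed simple projection
  (self-edges excluded);
* radius, diameter, girth, and clique counts use the undirected simple
  projection, with radius/diameter taken over *finite* distances only so
  disconnected graphs yield finite values;
* global efficiency and average path length use directed distances —
  efficiency averages 1/d over all ordered pairs (unreachable pairs
  contribute 0), average path length averages d over reachable ordered
  pairs only;
* a pair of vertices joined by two or more edges (in any direction mix)
  gives girth 2; an acyclic projection gives girth +inf;
* Euler flags use the standard directed degree-balance + connectivity
  conditions, restricted to vertices with nonzero degree.

Cycle-derived fields (has_cycle, n_cycles, n_negative_cycles) are filled
only when a cycle report is supplied; otherwise they are None.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from math import inf

import networkx as nx

from .cycles import Cycle, interpret_cycle, is_negative_feedback
from .model import PathwayGraph

__all__ = ["MetricsRow", "compute_metrics", "METRICS_COLUMNS"]


@dataclass
class MetricsRow:
    pathway_id: str
    n_vertices: int
    n_edges: int
    n_negative: int
    has_loops: bool
    has_multi_edges: bool
    has_euler_path: bool
    has_euler_cycle: bool
    n_clusters: int
    density: float
    radius: float
    diameter: float
    girth: float
    efficiency: float
    avg_path_length: float
    n_cliques: int
    reciprocity: float
    has_cycle: bool | None = None
    n_cycles: int | None = None
    n_negative_cycles: int | None = None

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


METRICS_COLUMNS = [f.name for f in fields(MetricsRow)]


def compute_metrics(
    graph: PathwayGraph,
    cycles: list[Cycle] | None = None,
    *,
    cliques_mode: str = "maximal",
    convention: str = "contains_inhibition",
) -> MetricsRow:
    """Compute the metric panel for one pathway graph.

    ``cliques_mode`` selects the clique statistic: ``maximal`` counts
    maximal cliques of size >= 2, ``all`` counts every complete subgraph
    of size >= 2, ``max-size`` reports the order of the largest clique
    (0 when the graph has no edges).
    """
    n = graph.n_vertices
    m = graph.n_edges
    directed = graph.to_networkx()

    non_self = [(e.source, e.target) for e in graph.edges if e.source != e.target]
    simple_pairs = set(non_self)
    undirected_pairs = {frozenset(p) for p in simple_pairs}

    # --- booleans and counts ------------------------------------------------
    has_loops = any(e.source == e.target for e in graph.edges)
    pair_counts: dict[tuple[str, str], int] = {}
    for p in non_self:
        pair_counts[p] = pair_counts.get(p, 0) + 1
    self_counts: dict[str, int] = {}
    for e in graph.edges:
        if e.source == e.target:
            self_counts[e.source] = self_counts.get(e.source, 0) + 1
    has_multi = any(c > 1 for c in pair_counts.values()) or any(
        c > 1 for c in self_counts.values()
    )
    n_negative = sum(1 for e in graph.edges if e.sign == -1)
    n_clusters = nx.number_weakly_connected_components(directed) if n else 0
    density = len(simple_pairs) / (n * (n - 1)) if n > 1 else 0.0

    # --- undirected distances ----------------------------------------------
    undirected = nx.Graph()
    undirected.add_nodes_from(directed.nodes)
    undirected.add_edges_from(tuple(p) for p in undirected_pairs)
    eccentricities = []
    for component in nx.connected_components(undirected):
        sub = undirected.subgraph(component)
        ecc = nx.eccentricity(sub)
        eccentricities.extend(ecc.values())
    radius = float(min(eccentricities)) if eccentricities else 0.0
    diameter = float(max(eccentricities)) if eccentricities else 0.0

    # --- girth ----------------------------------------------------------------
    multi_between = {}
    for p in non_self:
        key = frozenset(p)
        multi_between[key] = multi_between.get(key, 0) + 1
    if any(c >= 2 for c in multi_between.values()):
        girth = 2.0
    else:
        girth = float(nx.girth(undirected)) if undirected.number_of_edges() else inf

    # --- directed distances ---------------------------------------------------
    dist = dict(nx.all_pairs_shortest_path_length(directed))
    inv_sum = 0.0
    reach_sum = 0
    reach_pairs = 0
    for u in directed.nodes:
        for v, d in dist.get(u, {}).items():
            if u == v:
                continue
            inv_sum += 1.0 / d
            reach_sum += d
            reach_pairs += 1
    efficiency = inv_sum / (n * (n - 1)) if n > 1 else 0.0
    avg_path_length = reach_sum / reach_pairs if reach_pairs else 0.0

    # --- cliques --------------------------------------------------------------
    if cliques_mode == "maximal":
        n_cliques = sum(1 for c in nx.find_cliques(undirected) if len(c) >= 2)
    elif cliques_mode == "all":
        n_cliques = sum(
            1 for c in nx.enumerate_all_cliques(undirected) if len(c) >= 2
        )
    elif cliques_mode == "max-size":
        sizes = [len(c) for c in nx.find_cliques(undirected)]
        largest = max(sizes, default=0)
        n_cliques = largest if largest >= 2 else 0
    else:
        raise ValueError(f"unknown cliques_mode {cliques_mode!r}")

    # --- reciprocity ------------------------------------------------------------
    reciprocal = sum(1 for (u, v) in non_self if (v, u) in simple_pairs)
    reciprocity = reciprocal / len(non_self) if non_self else 0.0

    # --- Euler flags ------------------------------------------------------------
    has_euler_path, has_euler_cycle = _euler_flags(directed)

    row = MetricsRow(
        pathway_id=graph.pathway_id,
        n_vertices=n,
        n_edges=m,
        n_negative=n_negative,
        has_loops=has_loops,
        has_multi_edges=has_multi,
        has_euler_path=has_euler_path,
        has_euler_cycle=has_euler_cycle,
        n_clusters=n_clusters,
        density=density,
        radius=radius,
        diameter=diameter,
        girth=girth,
        efficiency=efficiency,
        avg_path_length=avg_path_length,
        n_cliques=n_cliques,
        reciprocity=reciprocity,
    )
    if cycles is not None:
        interps = [interpret_cycle(graph, c) for c in cycles]
        row.n_cycles = len(cycles)
        row.has_cycle = bool(cycles)
        row.n_negative_cycles = sum(
            1 for i in interps if is_negative_feedback(i, convention)
        )
    return row


def _euler_flags(directed: nx.MultiDiGraph) -> tuple[bool, bool]:
    """Directed Euler path/cycle existence on the nonzero-degree subgraph.

    Cycle: every vertex balanced (in == out) and the nonzero-degree
    subgraph strongly connected.  Path: at most one vertex with
    out-in == 1, at most one with in-out == 1, all others balanced, and
    the nonzero-degree subgraph weakly connected.
    """
    if directed.number_of_edges() == 0:
        return False, False
    active = [
        v
        for v in directed.nodes
        if directed.in_degree(v) + directed.out_degree(v) > 0
    ]
    sub = directed.subgraph(active)
    balance = {v: sub.out_degree(v) - sub.in_degree(v) for v in sub.nodes}
    if not nx.is_weakly_connected(sub):
        return False, False
    if all(b == 0 for b in balance.values()):
        eulerian = nx.is_strongly_connected(sub)
        return eulerian, eulerian
    plus = [b for b in balance.values() if b > 0]
    minus = [b for b in balance.values() if b < 0]
    has_path = plus == [1] and minus == [-1]
    return has_path, False
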