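"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — exhaustive enumeration over
vertex subsets and orderings, Floyd-Warshall over explicit dictionaries —
and shares no code path with the package's own algorithms.
"""

from __future__ import annotations

import itertools
import random
from math import inf

from loopscout.model import PathwayEdge, PathwayGraph, PathwayNode, NodeType


def brute_force_cycles(graph: PathwayGraph) -> set[tuple[tuple, tuple]]:
    """All elementary directed circuits (length >= 2), by testing every
    cyclic ordering of every vertex subset; one entry per parallel-edge
    combination.  Cycles are keyed by the rotation starting at the
    smallest vertex id, which is the lexicographically minimal rotation
    when vertex ids are distinct."""
    nodes = sorted(n.node_id for n in graph.nodes)
    bundles: dict[tuple[str, str], list[str]] = {}
    for e in graph.edges:
        if e.source != e.target:
            bundles.setdefault((e.source, e.target), []).append(e.edge_id)
    found: set[tuple[tuple, tuple]] = set()
    for r in range(2, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            first = subset[0]
            for rest in itertools.permutations(subset[1:]):
                order = (first, *rest)
                hops = [(order[i], order[(i + 1) % r]) for i in range(r)]
                if not all(h in bundles for h in hops):
                    continue
                for combo in itertools.product(
                    *[sorted(bundles[h]) for h in hops]
                ):
                    found.add((order, combo))
    return found


def floyd_warshall(nodes: list[str], pairs: set[tuple[str, str]]):
    d = {(u, v): (0.0 if u == v else inf) for u in nodes for v in nodes}
    for u, v in pairs:
        if u != v:
            d[(u, v)] = 1.0
    for k in nodes:
        for i in nodes:
            ik = d[(i, k)]
            if ik == inf:
                continue
            for j in nodes:
                if ik + d[(k, j)] < d[(i, j)]:
                    d[(i, j)] = ik + d[(k, j)]
    return d


def brute_force_metrics(graph: PathwayGraph) -> dict:
    """Distance/clique/count metrics recomputed from first principles."""
    nodes = sorted(n.node_id for n in graph.nodes)
    n = len(nodes)
    non_self = [(e.source, e.target) for e in graph.edges if e.source != e.target]
    directed_pairs = set(non_self)
    und_pairs = {frozenset(p) for p in directed_pairs}

    out = {}
    out["n_vertices"] = n
    out["n_edges"] = len(graph.edges)
    out["n_negative"] = sum(1 for e in graph.edges if e.sign == -1)
    out["density"] = len(directed_pairs) / (n * (n - 1)) if n > 1 else 0.0

    # clusters by union-find over the undirected projection
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for p in und_pairs:
        a, b = tuple(p)
        parent[find(a)] = find(b)
    out["n_clusters"] = len({find(v) for v in nodes})

    # undirected distances -> eccentricity over finite values
    sym = {(u, v) for u, v in directed_pairs} | {(v, u) for u, v in directed_pairs}
    du = floyd_warshall(nodes, sym)
    eccs = []
    for u in nodes:
        finite = [du[(u, v)] for v in nodes if du[(u, v)] < inf]
        eccs.append(max(finite) if finite else 0.0)
    out["radius"] = min(eccs) if eccs else 0.0
    out["diameter"] = max(eccs) if eccs else 0.0

    # girth: parallel pair -> 2; else smallest undirected simple cycle
    pair_mult: dict[frozenset, int] = {}
    for p in non_self:
        key = frozenset(p)
        pair_mult[key] = pair_mult.get(key, 0) + 1
    if any(c >= 2 for c in pair_mult.values()):
        out["girth"] = 2.0
    else:
        adj = {frozenset(p) for p in und_pairs}
        best = inf
        for r in range(3, n + 1):
            for subset in itertools.combinations(nodes, r):
                first = subset[0]
                for rest in itertools.permutations(subset[1:]):
                    order = (first, *rest)
                    if all(
                        frozenset((order[i], order[(i + 1) % r])) in adj
                        for i in range(r)
                    ):
                        best = min(best, r)
                        break
                else:
                    continue
                break
            if best < inf:
                break
        out["girth"] = float(best)

    # directed distances
    dd = floyd_warshall(nodes, directed_pairs)
    inv = [1.0 / dd[(u, v)] for u in nodes for v in nodes if u != v and dd[(u, v)] < inf]
    reach = [dd[(u, v)] for u in nodes for v in nodes if u != v and dd[(u, v)] < inf]
    out["efficiency"] = sum(inv) / (n * (n - 1)) if n > 1 else 0.0
    out["avg_path_length"] = sum(reach) / len(reach) if reach else 0.0

    # cliques: exhaustive subset check
    adjacent = {tuple(sorted(p)) for p in (tuple(q) for q in und_pairs)}

    def is_clique(subset):
        return all(
            tuple(sorted((a, b))) in adjacent
            for a, b in itertools.combinations(subset, 2)
        )

    cliques = [
        set(s)
        for r in range(2, n + 1)
        for s in itertools.combinations(nodes, r)
        if is_clique(s)
    ]
    out["n_cliques_all"] = len(cliques)
    out["n_cliques_maximal"] = sum(
        1 for c in cliques if not any(c < other for other in cliques)
    )
    out["reciprocity"] = (
        sum(1 for (u, v) in non_self if (v, u) in directed_pairs) / len(non_self)
        if non_self
        else 0.0
    )
    return out


MIM_CHOICES = [
    "mim-stimulation",
    "mim-inhibition",
    "mim-conversion",
    "mim-catalysis",
    "none",
    "arrow",
]


def random_graph(
    rng: random.Random,
    max_nodes: int = 6,
    max_edges: int = 12,
    allow_self: bool = True,
) -> PathwayGraph:
    """Random directed multigraph with typed, signed edges."""
    n = rng.randint(1, max_nodes)
    node_ids = [f"v{i}" for i in range(n)]
    nodes = [PathwayNode(v, v, NodeType.GENE_PRODUCT) for v in node_ids]
    m = rng.randint(0, max_edges)
    edges = []
    for k in range(m):
        u = rng.choice(node_ids)
        v = rng.choice(node_ids)
        if not allow_self:
            while v == u and n > 1:
                v = rng.choice(node_ids)
            if v == u:
                continue
        edges.append(PathwayEdge(f"e{k}", u, v, rng.choice(MIM_CHOICES)))
    return PathwayGraph(f"rand{rng.random():.8f}", nodes, edges)
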