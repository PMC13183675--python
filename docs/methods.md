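# Methods

## Graph model and edge-sign semantics

A pathway is represented as a directed multigraph with typed vertices
and MIM-typed, signed edges. The edge-type vocabulary is closed (15
members): the eleven `mim-*` interaction types, the generic `arrow`, the
model-internal `contained` (group membership) and `anchor-segment`
(untyped leading portions of an interaction split at anchor points), and
`none` for everything the source annotates freely or not at all. Closing
the vocabulary is what makes corpus-scale sign analysis meaningful:
every free-form annotation is forced to declare itself unsigned rather
than silently dropping out of the statistics, and `none` is consequently
one of the most common edge types in real corpora.

Signs are derived, never stored independently: inhibition is −1,
stimulation and necessary stimulation are +1, all else 0. Catalysis is
deliberately unsigned — it marks an enzyme–reaction association, not a
regulatory direction; treating it as stimulatory would manufacture
spurious feedback through metabolic chains.

Graphs validate at construction (unique vertex/edge ids, resolvable
endpoints); parallel edges and self-edges are legal because curated
diagrams genuinely contain both.

## GPML reading

Vertices come from `DataNode` elements (typed by their `Type`
attribute, unknown types → `Undefined`), `Group` elements (one vertex
each, labelled `Group1`, `Group2`, ... by order of appearance, members
attached by `contained` edges), `Anchor` points (one vertex each), and
`Label` elements — but labels only when an interaction point actually
references them, since free-floating captions carry no topology.

Interactions use only their first and last points as endpoints; bend
points and all geometry are ignored. Direction is always point order. An
arrowhead observed on the *first* point (a reversed drawing) is logged
but not re-oriented, because the GPML schema does not say which reading
is intended; keeping point order is the deterministic choice. Arrowhead
normalization is case-insensitive and total: `mim-*` labels in the
vocabulary pass through, `TBar` → `mim-inhibition`, `Arrow` → `arrow`,
empty → `none`, anything else → `none` with a warning.

An interaction owning anchors `a1..ak` is split into the chain
`source → a1 → ... → ak → target`; only the terminal segment keeps the
interaction's type, earlier segments are `anchor-segment`. This keeps
edges that terminate on an anchor (typically catalysis) attached to the
topology — which is exactly how representation-driven "long cycles"
arise in conversion cascades, and why the regulatory filter exists.

Namespace handling accepts any URI containing "GPML", since files in
the wild mix dialect versions that are identical for the features read
here. Endpoint references that resolve nowhere skip the edge with a
warning rather than failing the document.

## KGML reading

Entries map to vertices (`gene` → GeneProduct, `compound` → Metabolite,
`group` → Group with `contained` edges from its `component` children,
`map` → Pathway, else Undefined); labels take the first comma-separated
token of the graphics name, stripped of trailing dots, because KEGG
lists aliases and motifs need a single stable label. Each relation emits
one edge per subtype (none → a single `none` edge); the
ECrel/PPrel/GErel distinction is logged only, since sign structure is
the analysis target, not relation provenance. The subtype → MIM table is
this package's own normalization: activation/expression → stimulation,
inhibition/repression → inhibition (the *only* negative sources),
binding/association → binding, the covalent-modification subtypes →
modification, dissociation → cleavage, compound links → conversion, and
the "indirect/state change/missing/unknown" family → none. Reactions
emit `mim-conversion` edges substrate → product, duplicated in reverse
when reversible.

## Cycle enumeration

Vertex cycles come from Johnson's elementary-circuit algorithm (as
implemented in networkx) on the simple projection of the multigraph
with self-edges removed; each vertex cycle is then expanded into one
cycle per combination of parallel edges along it, because feedback sign
depends on which parallel edge is traversed. Cycles are stored in their
lexicographically smallest rotation and sorted by (length, vertex
sequence, edge sequence), so output order is deterministic and
comparable across runs. Self-edges are excluded by definition: the
minimum cycle length is two vertices.

Enumeration is capped (default 100 000 cycles) because elementary
circuit counts grow exponentially; overrunning the cap raises a
distinct error naming the pathway, which the corpus survey records as a
failure while keeping the pathway's structural metrics (its cycle
fields stay unknown rather than being guessed).

Enumeration runs on the *unfiltered* graph by default, so
representation-driven cycles through anchors and conversion chains are
reported faithfully. The regulatory filter — keep molecular vertices
(gene product, protein, RNA, metabolite, complex, group) and only
signed edges whose endpoints survive — is an explicit opt-in pre-pass
that reduces such cycles to their regulatory core. It is idempotent.

Two negative-feedback conventions are implemented because the field
uses both: `contains_inhibition` (any inhibitory edge in the cycle;
the default, and the convention used in corpus counting) and `parity`
(odd number of inhibitions, no unsigned edges — the control-theory
definition). They disagree on, e.g., double-inhibition two-cycles;
both are always computed and reported per cycle.

## Motifs, nesting, gene frequency

A motif is the cycle's vertex-label sequence rotated to its
lexicographically smallest rotation, orientation preserved (no
reversal: `A-B-C` and `A-C-B` are different regulatory objects).
Ties from duplicate labels resolve by continuing comparison around the
rotation. The census maps each motif occurring in a negative cycle to
the sorted set of pathways containing it. Gene frequency counts, per
gene, the number of distinct negative cycles containing it (and,
separately, the number of pathways), excluding group/anchor/label
vertices, which are schema artifacts rather than genes. Cycle `i` is
nested in `j` iff its vertex set is a proper subset of `j`'s; the
percentage nested is over all cycles of the pathway (or corpus).

## Metric panel conventions

The sources that define these metrics leave directedness and
disconnectedness unstated, so the conventions here are explicit:

* density = distinct ordered non-self pairs with an edge / `n(n−1)`;
* components are weak; radius/diameter are min/max vertex eccentricity
  over *finite undirected* distances (0 for edgeless graphs);
* girth is the shortest cycle of the undirected simple projection, with
  any doubly-connected vertex pair (parallel edges or a mutual pair)
  giving girth 2, and +∞ when the projection is a forest;
* global efficiency averages `1/d` over all *directed* ordered pairs
  (unreachable → 0); average path length averages `d` over *reachable*
  ordered pairs only;
* clique count defaults to maximal cliques of size ≥ 2 on the
  undirected simple projection (configurable: all cliques, or largest
  clique order);
* reciprocity is the fraction of non-self edge instances whose reverse
  pair exists;
* Euler flags use the standard directed degree-balance plus
  connectivity conditions restricted to vertices of nonzero degree.

All distance/count metrics are validated against brute-force
recomputation (Floyd–Warshall over explicit dictionaries, exhaustive
clique enumeration) on random multigraphs with up to 8 vertices, and
cycle enumeration against exhaustive subset/ordering search on graphs
with up to 6 vertices and 12 edges.

## Synthetic data

Two generators make the package fully testable offline.

**Fixture generator** (`loopscout.fixtures`): plants vertex-disjoint
cycles with prescribed sign patterns (+1 → stimulation, −1 → inhibition,
0 → conversion), adds random extra edges only among non-cycle vertices
and only in ascending order (hence a DAG — augmentation can never add a
cycle), and optionally emits group and anchor constructs. Each document
is paired with a manifest recording every vertex, edge and cycle, and
generation is byte-deterministic for a fixed (spec, seed). Because
planted cycles are disjoint, the generator cannot produce *nested*
cycles; nesting is exercised on hand-built and literature-style graphs
instead. KGML has no anchor concept, so there the anchor flag plants the
closest schema-level construct (a reaction plus an enzyme relation).

**Literature-style stand-ins** (`loopscout.literature_examples`):
synthetic GPML documents whose topology realizes the documented
regulatory structure of known pathways — an IGF1-Akt signaling graph
wired to contain exactly five elementary cycles including a SMAD2+SMAD3
group vertex; a cholesterol-biosynthesis cascade whose conversion/anchor
chain closes through 25-hydroxycholesterol ⊣ SREBF2 → enzymes into a
50-node representation-driven cycle that the regulatory filter reduces
to the sterol-sensing core; and four TP53-pathway contexts each
embedding the MDM2–TP53 negative feedback two-cycle. These are reduced
regulatory backbones, not database snapshots: node sets are small,
layout is placeholder, and identifiers carry a `SYN-` prefix. Passing
tests on them demonstrates that the pipeline recovers planted and
documented topology; it does not certify behaviour on full database
exports, whose annotation noise (missing arrowheads, nonstandard types,
unreferenced endpoints) is only partially emulated by the fallback
rules.

## Problem sizes and determinism

The acceptance script runs 500 random graphs against the cycle oracle,
60 against the metric oracle, 20 fixture round trips per format, and a
40-pathway synthetic corpus — sizes chosen so the whole recomputation
finishes in seconds while still exercising every code path. All
randomness flows from the single `--seed` argument through explicit
`random.Random` instances; no global seeding is used anywhere.

## Known limitations

* GPML `State` elements and Biopax/SBGN inputs are not parsed.
* The KEGG subtype → MIM table is this package's normalization; other
  tools may map the "indirect effect" family differently.
* Reversed-drawn GPML interactions (arrowhead on the first point) are
  kept in point order; if a corpus contains many, inhibition counts
  could be affected (occurrences are logged).
* Corpus-scale counts depend on database release; the survey reports
  whatever corpus it is given and makes no claim of matching any
  particular snapshot.
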