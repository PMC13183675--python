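# loopscout

A pathway-topology toolkit for investigating feedback in biological
pathways. `loopscout` converts pathway diagrams — WikiPathways GPML and
KEGG KGML XML files — into directed, edge-typed multigraphs, enumerates
the elementary cycles of each graph, classifies negative feedback, and
surveys whole corpora of pathways for loop, motif and gene statistics.

It is written for systems biologists and bioinformaticians who want to
treat curated pathway diagrams as mathematical objects: cell signaling
and metabolic diagrams encode regulatory structure (stimulation,
inhibition, conversion, catalysis) that becomes computable once the
drawing is a graph.

## The model

A pathway is a directed multigraph `G = (V, E)`. Vertices are typed
(gene product, protein, RNA, metabolite, complex, group, label, anchor);
edges carry a Molecular Interaction Map (MIM) interaction type and a
derived regulatory sign:

```
sign(e) = -1  if type(e) = mim-inhibition
        = +1  if type(e) ∈ {mim-stimulation, mim-necessary-stimulation}
        =  0  otherwise (conversion, catalysis, binding, schema-level links, ...)
```

Both readers normalize their source vocabularies (free-form GPML
arrowheads, KEGG relation subtypes) into a closed 15-member MIM-based
vocabulary, so downstream analyses are format-agnostic.

A *cycle* is an elementary directed circuit through `n ≥ 2` distinct
vertices (a self-edge is a *loop* and is tracked separately). Cycles are
enumerated with Johnson's elementary-circuit algorithm, generalized to
multigraphs by expanding one cycle per distinct combination of parallel
edges. A cycle is a **negative feedback loop** under either of two
conventions:

* `contains_inhibition` (default): the cycle traverses at least one
  inhibitory edge;
* `parity`: the product of edge signs is −1 (a cycle traversing any
  unsigned edge is "unsigned").

Each pathway also gets a panel of global graph metrics (density, radius,
diameter, girth, global efficiency, average path length, clique count,
reciprocity, Euler path/cycle existence, component count, negative-edge
count), and corpora are summarized by motif census (rotation-canonical
gene-label sequences of negative cycles), per-gene loop frequency, and
nesting structure (cycle `i` nests in `j` when its vertex set is a
proper subset).

## Worked example

The package bundles synthetic, literature-style stand-in pathways
(generated GPML documents; see `loopscout.literature_examples`). The
IGF1-Akt signaling stand-in contains the PI3K → PDK1 → AKT1 ⊣ FoxO
kinase cascade with mTORC1/S6K/IRS1 feedback and a SMAD2+SMAD3 group:

```python
from loopscout import parse_gpml, find_cycles, interpret_cycle
from loopscout.literature_examples import igf1_akt_signaling_gpml

graph = parse_gpml(igf1_akt_signaling_gpml())
cycles = find_cycles(graph)
print(len(cycles))
for cycle in cycles:
    interp = interpret_cycle(graph, cycle)
    print(cycle.length_nodes, interp.gene_labels, interp.parity_sign)
```

prints

```
5
2 ('FoxO', 'MAFbx') positive
4 ('AKT1', 'FoxO', 'mTORC1', 'Group1') negative
5 ('AKT1', 'FoxO', 'MAFbx', 'mTORC1', 'Group1') negative
7 ('AKT1', 'FoxO', 'mTORC1', 'S6K', 'IRS1', 'PI3K', 'PDK1') negative
8 ('AKT1', 'FoxO', 'MAFbx', 'mTORC1', 'S6K', 'IRS1', 'PI3K', 'PDK1') negative
```

— five elementary cycles: a positive FoxO/MAFbx two-cycle and four
negative feedback loops through AKT1, with the SMAD2/SMAD3 pair
appearing as the single vertex `Group1`.

The same machinery is available from the shell:

```bash
loopscout parse pathway.gpml --graphml out.graphml --edges edges.csv
loopscout cycles pathway.gpml --convention contains --json report.json
loopscout metrics pathway.gpml --csv row.csv
loopscout survey pathways/ --format gpml --csv table.csv --motifs motifs.csv
loopscout simulate --spec spec.json --format kgml --out fixture.xml --manifest truth.json
```

## Scope

`loopscout` deliberately does not fit regression models on the survey
table, perform GO enrichment, export to Cytoscape, or render diagrams;
the survey CSV is designed to be consumed directly by standard
statistical tooling.
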