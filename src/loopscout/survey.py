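"""Batch survey of a pathway corpus.

Parses every file in a corpus, enumerates cycles, computes the metric
panel, and aggregates corpus-level summaries: how many pathways contain
any cycle, at least one inhibitory edge, and at least one negative
feedback loop; plus the motif census over negative cycles, per-gene
frequency in negative cycles, and nesting totals.

Failures (unparseable files, cycle-budget overruns) are recorded and
never abort the batch; a pathway whose cycle enumeration overran the
budget keeps its structural metrics but has unknown (None) cycle fields.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cycles import (
    Cycle,
    CycleInterpretation,
    DEFAULT_MAX_CYCLES,
    filter_regulatory,
    find_cycles,
    interpret_cycle,
    is_negative_feedback,
    motif_of,
    nested_cycles,
)
from .errors import CycleBudgetExceededError, ParseError
from .gpml import parse_gpml
from .kgml import parse_kgml
from .metrics import METRICS_COLUMNS, MetricsRow, compute_metrics
from .model import NodeType, PathwayGraph

logger = logging.getLogger(__name__)

__all__ = [
    "CycleReport",
    "SurveyTable",
    "survey",
    "survey_graphs",
    "analyze_graph",
    "motif_census",
    "gene_frequency",
]

#: vertex types excluded from gene-frequency counting
_NON_GENE_TYPES = {NodeType.GROUP, NodeType.ANCHOR, NodeType.LABEL}


@dataclass
class CycleReport:
    """Cycles of one pathway plus their interpretations and motifs."""

    pathway_id: str
    cycles: list[Cycle]
    interpretations: list[CycleInterpretation]
    #: motif string per *negative* cycle index (under the active convention)
    negative_motifs: dict[int, str]
    nesting_pairs: list[tuple[int, int]]
    nesting_summary: dict[str, float]
    #: vertex labels per cycle, Group/Anchor/Label vertices excluded
    gene_labels: list[tuple[str, ...]]


@dataclass
class SurveyTable:
    rows: list[MetricsRow] = field(default_factory=list)
    failures: list[tuple[str, str]] = field(default_factory=list)
    reports: dict[str, CycleReport] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        frame = pd.DataFrame([r.to_dict() for r in self.rows], columns=METRICS_COLUMNS)
        return frame

    def summary(self) -> dict[str, int]:
        """Corpus counts: total, with cycles, with >= 1 negative edge,
        with >= 1 negative feedback loop."""
        with_cycles = sum(1 for r in self.rows if r.has_cycle)
        with_negative = sum(1 for r in self.rows if r.n_negative > 0)
        with_negative_loops = sum(
            1 for r in self.rows if (r.n_negative_cycles or 0) > 0
        )
        return {
            "pathways_total": len(self.rows),
            "pathways_with_cycles": with_cycles,
            "pathways_with_negative_edges": with_negative,
            "pathways_with_negative_loops": with_negative_loops,
        }


def analyze_graph(
    graph: PathwayGraph,
    *,
    convention: str = "contains_inhibition",
    max_cycles: int = DEFAULT_MAX_CYCLES,
    apply_regulatory_filter: bool = False,
) -> tuple[MetricsRow, CycleReport]:
    """Cycle analysis + metric panel for one already-parsed graph."""
    target = filter_regulatory(graph) if apply_regulatory_filter else graph
    cycles = find_cycles(target, max_cycles=max_cycles)
    interps = [interpret_cycle(target, c) for c in cycles]
    negative_motifs = {
        i: str(motif_of(target, c))
        for i, (c, interp) in enumerate(zip(cycles, interps))
        if is_negative_feedback(interp, convention)
    }
    pairs, summary = nested_cycles(cycles)
    gene_labels = [
        tuple(
            target.label_of(v)
            for v in c.vertex_seq
            if target.node(v).node_type not in _NON_GENE_TYPES
        )
        for c in cycles
    ]
    report = CycleReport(
        pathway_id=graph.pathway_id,
        cycles=cycles,
        interpretations=interps,
        negative_motifs=negative_motifs,
        nesting_pairs=pairs,
        nesting_summary=summary,
        gene_labels=gene_labels,
    )
    row = compute_metrics(target, cycles, convention=convention)
    return row, report


def survey_graphs(
    graphs: list[PathwayGraph],
    *,
    convention: str = "contains_inhibition",
    max_cycles: int = DEFAULT_MAX_CYCLES,
    apply_regulatory_filter: bool = False,
) -> SurveyTable:
    """Survey already-parsed graphs (see :func:`survey` for files)."""
    table = SurveyTable()
    for graph in graphs:
        try:
            row, report = analyze_graph(
                graph,
                convention=convention,
                max_cycles=max_cycles,
                apply_regulatory_filter=apply_regulatory_filter,
            )
            table.rows.append(row)
            table.reports[graph.pathway_id] = report
        except CycleBudgetExceededError as exc:
            logger.warning("%s", exc)
            table.failures.append((graph.pathway_id, str(exc)))
            table.rows.append(compute_metrics(graph))  # cycle fields unknown
    table.rows.sort(key=lambda r: r.pathway_id)
    return table


def survey(
    paths: list[str | Path],
    format: str = "gpml",
    *,
    convention: str = "contains_inhibition",
    max_cycles: int = DEFAULT_MAX_CYCLES,
    apply_regulatory_filter: bool = False,
) -> SurveyTable:
    """Parse and analyze a corpus of pathway files.

    Rows are sorted by pathway id, so the table is independent of the
    input file order.  Unparseable files land in ``failures``.
    """
    parser = parse_gpml if format.lower() == "gpml" else parse_kgml
    graphs: list[PathwayGraph] = []
    failures: list[tuple[str, str]] = []
    for path in paths:
        try:
            graphs.append(parser(path))
        except (ParseError, OSError) as exc:
            logger.warning("failed to parse %s: %s", path, exc)
            failures.append((str(path), str(exc)))
    table = survey_graphs(
        graphs,
        convention=convention,
        max_cycles=max_cycles,
        apply_regulatory_filter=apply_regulatory_filter,
    )
    table.failures = failures + table.failures
    return table


def motif_census(table: SurveyTable) -> list[tuple[str, list[str]]]:
    """Map each negative-feedback motif to the sorted pathways containing
    it, ordered by (pathway count desc, motif asc)."""
    occurrences: dict[str, set[str]] = defaultdict(set)
    for report in table.reports.values():
        for motif in report.negative_motifs.values():
            occurrences[motif].add(report.pathway_id)
    return sorted(
        ((motif, sorted(ids)) for motif, ids in occurrences.items()),
        key=lambda item: (-len(item[1]), item[0]),
    )


def gene_frequency(table: SurveyTable) -> pd.DataFrame:
    """Per-gene participation in negative feedback loops.

    ``n_cycles`` counts distinct negative cycles (across all pathways)
    containing the gene; ``n_pathways`` counts pathways with at least one
    such cycle.  Group, anchor and label vertices are excluded.
    """
    cycle_counts: Counter = Counter()
    pathway_sets: dict[str, set[str]] = defaultdict(set)
    for report in table.reports.values():
        for i in report.negative_motifs:
            for gene in set(report.gene_labels[i]):
                cycle_counts[gene] += 1
                pathway_sets[gene].add(report.pathway_id)
    frame = pd.DataFrame(
        [
            {"gene": g, "n_cycles": c, "n_pathways": len(pathway_sets[g])}
            for g, c in cycle_counts.items()
        ],
        columns=["gene", "n_cycles", "n_pathways"],
    )
    return frame.sort_values(
        ["n_cycles", "gene"], ascending=[False, True], ignore_index=True
    )
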