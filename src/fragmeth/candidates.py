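"""Candidate-gene selection from differentially methylated fragments.

Mirrors the screening flowchart of the analysis: every DMF is annotated to
the genes whose promoter or gene body it overlaps (and flagged for CpG-island
overlap), then genes with at least one promoter-associated DMF become
candidates. A candidate's direction is the unanimous sign of its
promoter-overlapping DMFs (hyper / hypo), or "ambiguous" when the signs mix
— mixed genes are kept visible rather than silently dropped so the
hyper/hypo partition always audits back to the DMF table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set

import pandas as pd

from .diffmeth import DMRecord
from .regions import AnalysisUnit

__all__ = [
    "AnnotatedDMF",
    "CandidateGene",
    "annotate_dmfs",
    "select_candidates",
    "candidate_table",
]


@dataclass
class AnnotatedDMF:
    """A significant DMF with its gene links and region-kind overlaps."""

    record: DMRecord
    unit: AnalysisUnit
    promoter_genes: List[str] = field(default_factory=list)
    body_genes: List[str] = field(default_factory=list)
    cgi_overlap: bool = False

    @property
    def genes(self) -> Set[str]:
        return set(self.promoter_genes) | set(self.body_genes)

    @property
    def intergenic(self) -> bool:
        return not self.genes


@dataclass
class CandidateGene:
    """A gene supported by >= 1 promoter-associated DMF."""

    gene_id: str
    direction: str  # hyper | hypo | ambiguous
    supporting_units: List[str]
    kinds_hit: Set[str]
    best_diff: float
    best_q: float


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def annotate_dmfs(
    dmf_records: Sequence[DMRecord],
    units: Dict[str, AnalysisUnit],
    promoters: Sequence[AnalysisUnit],
    gene_bodies: Sequence[AnalysisUnit],
    cgis: Sequence[AnalysisUnit] = (),
    significant_only: bool = True,
) -> List[AnnotatedDMF]:
    """Link each DMF to genes via >= 1 bp overlap with promoters/gene bodies.

    ``units`` maps unit_id to its interval (as carried by the methylation
    matrix). With ``significant_only`` (default) only records with status
    hyper or hypo are annotated, matching the screening flowchart; DMFs
    overlapping no gene region remain in the output flagged intergenic.
    """
    annotated = []
    for rec in dmf_records:
        if significant_only and rec.status == "ns":
            continue
        unit = units[rec.unit_id]
        ann = AnnotatedDMF(record=rec, unit=unit)
        for prom in promoters:
            if prom.contig == unit.contig and _overlaps(
                unit.start, unit.end, prom.start, prom.end
            ):
                ann.promoter_genes.append(prom.gene_id)
        for body in gene_bodies:
            if body.contig == unit.contig and _overlaps(
                unit.start, unit.end, body.start, body.end
            ):
                ann.body_genes.append(body.gene_id)
        ann.cgi_overlap = any(
            c.contig == unit.contig
            and _overlaps(unit.start, unit.end, c.start, c.end)
            for c in cgis
        )
        annotated.append(ann)
    return annotated


def select_candidates(annotated_dmfs: Sequence[AnnotatedDMF]) -> List[CandidateGene]:
    """Select genes with >= 1 promoter-associated DMF and assign direction.

    Direction is "hyper" or "hypo" when every promoter-overlapping DMF of the
    gene shares that sign, "ambiguous" otherwise. Output is sorted by the
    largest absolute methylation difference, descending.
    """
    by_gene: Dict[str, List[AnnotatedDMF]] = {}
    for ann in annotated_dmfs:
        for g in ann.promoter_genes:
            by_gene.setdefault(g, []).append(ann)

    out = []
    for gene_id, anns in by_gene.items():
        statuses = {a.record.status for a in anns}
        direction = statuses.pop() if len(statuses) == 1 else "ambiguous"
        kinds = {a.unit.kind for a in anns}
        best = max(anns, key=lambda a: abs(a.record.diff))
        out.append(
            CandidateGene(
                gene_id=gene_id,
                direction=direction,
                supporting_units=[a.record.unit_id for a in anns],
                kinds_hit=kinds,
                best_diff=best.record.diff,
                best_q=min(a.record.q_value for a in anns),
            )
        )
    out.sort(key=lambda c: abs(c.best_diff), reverse=True)
    return out


def candidate_table(candidates: Sequence[CandidateGene]) -> pd.DataFrame:
    """Tabulate candidates (one row per gene)."""
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "direction": c.direction,
                "n_supporting": len(c.supporting_units),
                "kinds_hit": ",".join(sorted(c.kinds_hit)),
                "best_diff": c.best_diff,
                "best_q": c.best_q,
            }
            for c in candidates
        ]
    )
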