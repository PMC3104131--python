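"""Interval-overlap engine, gene annotation, segment sizes and inheritance calls.

One reciprocal-overlap code path serves both the common-CNV filter and the
parent-comparison inheritance labels, so "matches a control interval" and
"matches a parent call" mean exactly the same thing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

from intervaltree import IntervalTree

from .config import RunConfig
from .core import CnvSegment, GenomicInterval

INHERITED_MATERNAL = "inherited_maternal"
INHERITED_PATERNAL = "inherited_paternal"
NOT_IN_TESTED_PARENT = "not_in_tested_parent"
UNKNOWN = "unknown"

#: Report-column vocabulary for inheritance verdicts.
INHERITANCE_LABELS = {
    INHERITED_MATERNAL: "Inh (M)",
    INHERITED_PATERNAL: "Inh (P)",
    NOT_IN_TESTED_PARENT: "Not inh",
    UNKNOWN: "Unk",
}


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(|A ∩ B| / |A|, |A ∩ B| / |B|); 0 for different chromosomes."""
    if a.chromosome != b.chromosome:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / a.length, inter / b.length)


def max_reciprocal_overlap(query: GenomicInterval, candidates: Iterable[GenomicInterval]) -> float:
    return max((reciprocal_overlap(query, c) for c in candidates), default=0.0)


class GenomeIndex:
    """Interval-tree index over genomic intervals, keyed by chromosome."""

    def __init__(self, intervals: Iterable[GenomicInterval]) -> None:
        self._trees: Dict[str, IntervalTree] = {}
        for iv in intervals:
            self._trees.setdefault(iv.chromosome, IntervalTree()).addi(iv.start, iv.end, iv)

    def overlapping(self, chromosome: str, start: int, end: int) -> List[GenomicInterval]:
        tree = self._trees.get(chromosome)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(start, end)]


@dataclass
class GeneOverlapReport:
    """Genes fully contained in vs partially overlapped by one CNV segment."""

    segment: CnvSegment
    genes_fully_contained: List[str]
    genes_partially_overlapped: List[str]

    @property
    def gene_containing(self) -> bool:
        return bool(self.genes_fully_contained or self.genes_partially_overlapped)


def annotate_genes(
    segment: CnvSegment, genes: Sequence[GenomicInterval], index: Optional[GenomeIndex] = None
) -> GeneOverlapReport:
    """Classify each overlapping gene as entirely or partially within the CNV.

    A gene is fully contained iff its interval is a subset of the segment
    interval; any other non-empty intersection is partial. The segment's
    ``genes`` field is set to the union, each list sorted lexicographically.
    Pass a prebuilt :class:`GenomeIndex` to amortize lookups over many calls.
    """
    if index is None:
        index = GenomeIndex(genes)
    full, partial = set(), set()
    for gene in index.overlapping(segment.chromosome, segment.start, segment.end):
        if gene.start >= segment.start and gene.end <= segment.end:
            full.add(gene.payload)
        else:
            partial.add(gene.payload)
    report = GeneOverlapReport(segment, sorted(full), sorted(partial - full))
    segment.genes = sorted(full | partial)
    return report


def segment_size_mb(segment: CnvSegment) -> float:
    """Segment size in Mb: (end - start) / 1e6, from outermost probe positions."""
    return segment.size_mb


@dataclass
class InheritanceCall:
    segment: CnvSegment
    verdict: str

    @property
    def label(self) -> str:
        return INHERITANCE_LABELS[self.verdict]


def classify_inheritance(
    child_calls: Sequence[CnvSegment],
    parent_calls: Optional[Sequence[CnvSegment]],
    parent_role: str,
    config: RunConfig,
) -> List[InheritanceCall]:
    """Label each child call against one parent's call set.

    A call is inherited from the tested parent iff a same-type parent call
    reaches the same reciprocal-overlap threshold used by the common filter;
    otherwise it is absent from that parent. With no parent track supplied
    every verdict is unknown.
    """
    if parent_role not in ("maternal", "paternal"):
        raise ValueError(f"parent_role must be maternal or paternal, got {parent_role!r}")
    if parent_calls is None:
        return [InheritanceCall(c, UNKNOWN) for c in child_calls]
    inherited = INHERITED_MATERNAL if parent_role == "maternal" else INHERITED_PATERNAL
    out = []
    for call in child_calls:
        same_type = [p.interval() for p in parent_calls if p.state == call.state]
        frac = max_reciprocal_overlap(call.interval(), same_type)
        out.append(
            InheritanceCall(call, inherited if frac >= config.common_overlap_fraction else NOT_IN_TESTED_PARENT)
        )
    return out
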