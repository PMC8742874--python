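"""Assign motif hits to genes and classify them by gene feature.

A hit is assigned to every gene whose span it overlaps on the same
sequence; the transcribed-strand filter then retains only hits on the
gene's strand (the matches present in the pre-mRNA). Region labels are
the union over the gene's transcripts — a motif can sit in an intron of
one isoform and an exon of another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple

from intervaltree import IntervalTree

from .core import (
    REGION_3UTR,
    REGION_5UTR,
    REGION_CDS,
    REGION_EXON,
    REGION_INTRON,
    GeneAnnotation,
    GenomicInterval,
    MotifHit,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotatedHit:
    """A motif hit attached to one overlapping gene, with region labels."""

    hit: MotifHit
    gene_id: str
    gene_strand: str
    regions: frozenset[str] = frozenset()


class AssignmentResult(NamedTuple):
    hits: list[AnnotatedHit]
    n_dropped: int


def _gene_trees(ann: GeneAnnotation) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gene in ann.genes.values():
        trees.setdefault(gene.span.seq_id, IntervalTree()).addi(
            gene.span.start, gene.span.end, gene.id
        )
    return trees


def assign_genes(hits: Iterable[MotifHit], ann: GeneAnnotation) -> AssignmentResult:
    """Attach each hit to every gene whose span overlaps it.

    Hits overlapping no gene are dropped; the drop count is returned and
    logged. Output order is deterministic regardless of input order.
    """
    trees = _gene_trees(ann)
    out: list[AnnotatedHit] = []
    n_dropped = 0
    for hit in hits:
        tree = trees.get(hit.seq_id)
        overlapping = tree.overlap(hit.interval.start, hit.interval.end) if tree else ()
        if not overlapping:
            n_dropped += 1
            continue
        for iv in overlapping:
            out.append(AnnotatedHit(hit, iv.data, ann.genes[iv.data].strand))
    if n_dropped:
        logger.info("dropped %d hits overlapping no gene", n_dropped)
    out.sort(key=lambda a: (a.hit.seq_id, a.hit.interval.start, a.hit.strand, a.gene_id))
    return AssignmentResult(out, n_dropped)


def filter_transcribed_strand(ahits: Iterable[AnnotatedHit],
                              keep_unstranded: bool = True) -> list[AnnotatedHit]:
    """Retain hits on the transcribed strand of their gene.

    Unstranded hits or genes (strand '.') are retained by default and
    counted in the log.
    """
    kept: list[AnnotatedHit] = []
    n_unstranded = 0
    for a in ahits:
        if a.hit.strand == "." or a.gene_strand == ".":
            n_unstranded += 1
            if keep_unstranded:
                kept.append(a)
        elif a.hit.strand == a.gene_strand:
            kept.append(a)
    if n_unstranded:
        logger.info("%s %d unstranded hit/gene pairs",
                    "kept" if keep_unstranded else "removed", n_unstranded)
    return kept


def classify_regions(ahit: AnnotatedHit, ann: GeneAnnotation) -> frozenset[str]:
    """Region labels for a hit: union over the gene's transcripts of every
    feature class the hit overlaps by >= 1 base. UTR and CDS labels imply
    the exon label."""
    txs = ann.gene_transcripts(ahit.gene_id)
    if not txs:
        raise ValueError(f"gene {ahit.gene_id} has no transcripts")
    iv = ahit.hit.interval
    regions: set[str] = set()
    for tx in txs:
        for kind in (REGION_EXON, REGION_CDS, REGION_5UTR, REGION_3UTR, REGION_INTRON):
            if kind in regions:
                continue
            if any(iv.overlaps(f) for f in tx.regions(kind)):
                regions.add(kind)
    if regions & {REGION_CDS, REGION_5UTR, REGION_3UTR}:
        regions.add(REGION_EXON)
    return frozenset(regions)


def annotate_hits(hits: Iterable[MotifHit], ann: GeneAnnotation,
                  strand_filter: bool = True) -> list[AnnotatedHit]:
    """Full annotation pipeline: gene assignment, transcribed-strand
    filter, region classification."""
    assigned, _ = assign_genes(hits, ann)
    if strand_filter:
        assigned = filter_transcribed_strand(assigned)
    return [
        AnnotatedHit(a.hit, a.gene_id, a.gene_strand, classify_regions(a, ann))
        for a in assigned
    ]


def hits_to_intervals(ahits: Iterable[AnnotatedHit]) -> list[GenomicInterval]:
    return [a.hit.interval for a in ahits]
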