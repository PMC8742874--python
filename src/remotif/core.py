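"""Core domain types shared across the pipeline.

All coordinates are 0-based half-open on the forward genomic strand.
Conversion from 1-based closed conventions (GFF3, STAR SJ.out.tab)
happens only at format boundaries in :mod:`remotif.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

REGION_INTRON = "intron"
REGION_EXON = "exon"
REGION_CDS = "CDS"
REGION_5UTR = "5UTR"
REGION_3UTR = "3UTR"
REGIONS = (REGION_INTRON, REGION_EXON, REGION_CDS, REGION_5UTR, REGION_3UTR)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A, C, G, T, N}.

    RNA input (U) is stored as T; lowercase is upper-cased on load.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


def gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Bases strictly between two intervals; 0 for overlap or book-ending.

    Symmetric. Intervals on different sequences have no defined gap.
    """
    if a.seq_id != b.seq_id:
        raise ValueError("gap undefined across sequences")
    return max(0, b.start - a.end, a.start - b.end)


@dataclass(frozen=True)
class JunctionRecord:
    """One splice junction with supporting read counts.

    ``donor_pos``/``acceptor_pos`` delimit the intron: first intronic base
    (0-based) and last intronic base + 1 (exclusive), regardless of strand.
    """

    seq_id: str
    donor_pos: int
    acceptor_pos: int
    strand: str
    unique_reads: int
    multi_reads: int = 0

    def __post_init__(self) -> None:
        if self.donor_pos >= self.acceptor_pos:
            raise ValueError("donor_pos must be < acceptor_pos")
        if self.unique_reads < 0 or self.multi_reads < 0:
            raise ValueError("read counts must be non-negative")


@dataclass(frozen=True)
class MotifHit:
    """A located, stranded, scored motif occurrence."""

    motif_name: str
    interval: GenomicInterval
    score: float

    @property
    def seq_id(self) -> str:
        return self.interval.seq_id

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class Transcript:
    """One transcript: ordered exons plus CDS/UTR sub-intervals and
    introns derived as the gaps between sorted exons."""

    id: str
    gene_id: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)
    introns: list[GenomicInterval] = field(default_factory=list)

    def regions(self, kind: str) -> list[GenomicInterval]:
        return {
            REGION_EXON: self.exons,
            REGION_CDS: self.cds,
            REGION_5UTR: self.utr5,
            REGION_3UTR: self.utr3,
            REGION_INTRON: self.introns,
        }[kind]

    def derive_introns(self) -> None:
        exons = sorted(self.exons, key=lambda e: e.start)
        self.introns = [
            GenomicInterval(a.seq_id, a.end, b.start, self.strand)
            for a, b in zip(exons, exons[1:])
            if b.start > a.end
        ]


@dataclass
class Gene:
    id: str
    span: GenomicInterval
    transcript_ids: list[str] = field(default_factory=list)

    @property
    def strand(self) -> str:
        return self.span.strand


@dataclass
class GeneAnnotation:
    """Gene -> transcript -> feature intervals, one coordinate convention."""

    genes: dict[str, Gene] = field(default_factory=dict)
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def gene_transcripts(self, gene_id: str) -> list[Transcript]:
        return [self.transcripts[t] for t in self.genes[gene_id].transcript_ids]

    def add_gene(self, gene: Gene) -> None:
        self.genes[gene.id] = gene

    def add_transcript(self, tx: Transcript) -> None:
        self.transcripts[tx.id] = tx
        self.genes[tx.gene_id].transcript_ids.append(tx.id)

    def all_exons(self, unique: bool = True) -> list[GenomicInterval]:
        """Every exon interval in the annotation (deduplicated by default)."""
        seen: set[tuple] = set()
        out = []
        for tx in self.transcripts.values():
            for e in tx.exons:
                key = (e.seq_id, e.start, e.end)
                if unique:
                    if key in seen:
                        continue
                    seen.add(key)
                out.append(e)
        return out

    def __len__(self) -> int:
        return len(self.genes)


def as_intervals(hits: Iterable[MotifHit]) -> list[GenomicInterval]:
    return [h.interval for h in hits]
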