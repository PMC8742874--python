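"""Readers and writers for the external formats the pipeline touches.

FASTA (via Biopython), GFF3 (via gffutils), STAR ``SJ.out.tab`` junction
tables and BED6 motif-hit files. Every reader normalizes to the internal
0-based half-open convention; every writer converts back at the boundary.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .core import (
    Gene,
    GeneAnnotation,
    GenomicInterval,
    JunctionRecord,
    MotifHit,
    SequenceRecord,
    Transcript,
)

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a multi-record FASTA file.

    U is normalized to T and lowercase to uppercase. Record ids must be
    unique; empty sequences and files whose first entry is not a header
    are rejected with the offending line number.
    """
    header_lines: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(";"):
                continue
            if stripped.startswith(">"):
                header_lines.append(lineno)
            elif not header_lines:
                raise FormatError(
                    f"{path}: line {lineno}: expected FASTA header, got sequence data"
                )

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        line = header_lines[i] if i < len(header_lines) else "?"
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"{path}: line {line}: record {rec.id!r} has empty sequence")
        if rec.id in seen:
            raise FormatError(f"{path}: line {line}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_TX_TYPES = ("mRNA", "transcript")
_SUBFEATURE_MAP = {
    "exon": "exons",
    "CDS": "cds",
    "five_prime_UTR": "utr5",
    "three_prime_UTR": "utr3",
}


def _to_internal(feature: gffutils.Feature) -> GenomicInterval:
    # GFF3 is 1-based closed; internal is 0-based half-open.
    strand = feature.strand if feature.strand in ("+", "-") else "."
    return GenomicInterval(feature.seqid, feature.start - 1, feature.end, strand)


def read_gff3(path: str | os.PathLike) -> GeneAnnotation:
    """Read gene/mRNA/exon/CDS/UTR features into a :class:`GeneAnnotation`.

    Parent/child links are resolved through ID/Parent attributes; introns
    are derived per transcript as the gaps between its sorted exons.
    Sub-features with multiple parents are attached to every parent;
    sub-features with no resolvable parent are skipped with a warning.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) >= 5:
                try:
                    start, end = int(cols[3]), int(cols[4])
                except ValueError:
                    raise FormatError(f"{path}: line {lineno}: non-integer coordinates")
                if end < start:
                    raise FormatError(
                        f"{path}: line {lineno}: end {end} < start {start}"
                    )

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    ann = GeneAnnotation()
    for g in db.features_of_type("gene"):
        ann.add_gene(Gene(g.id, _to_internal(g)))
    for ttype in _TX_TYPES:
        for t in db.features_of_type(ttype):
            parents = t.attributes.get("Parent", [])
            gene_id = parents[0] if parents else t.id
            if gene_id not in ann.genes:
                logger.warning("transcript %s has no resolvable gene parent; skipped", t.id)
                continue
            ann.add_transcript(Transcript(t.id, gene_id, _to_internal(t).strand))

    n_orphans = 0
    for ftype, attr in _SUBFEATURE_MAP.items():
        for f in db.features_of_type(ftype):
            parents = [p for p in f.attributes.get("Parent", []) if p in ann.transcripts]
            if not parents:
                n_orphans += 1
                logger.warning("%s at %s:%d-%d has no resolvable transcript parent; skipped",
                               ftype, f.seqid, f.start, f.end)
                continue
            for pid in parents:
                getattr(ann.transcripts[pid], attr).append(_to_internal(f))

    for tx in ann.transcripts.values():
        tx.exons.sort(key=lambda e: e.start)
        tx.derive_introns()
    if n_orphans:
        logger.warning("skipped %d orphan sub-features", n_orphans)
    return ann


def write_gff3(ann: GeneAnnotation, path: str | os.PathLike,
               source: str = "remotif") -> None:
    """Serialize an annotation back to GFF3 (1-based closed coordinates)."""

    def line(ftype: str, iv: GenomicInterval, attrs: str) -> str:
        return (f"{iv.seq_id}\t{source}\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n")

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in sorted(ann.genes.values(), key=lambda g: (g.span.seq_id, g.span.start)):
            fh.write(line("gene", gene.span, f"ID={gene.id}"))
            for tx in ann.gene_transcripts(gene.id):
                span = GenomicInterval(
                    gene.span.seq_id, min(e.start for e in tx.exons),
                    max(e.end for e in tx.exons), tx.strand,
                )
                fh.write(line("mRNA", span, f"ID={tx.id};Parent={gene.id}"))
                for ftype, attr in _SUBFEATURE_MAP.items():
                    for iv in getattr(tx, attr):
                        fh.write(line(ftype, iv, f"Parent={tx.id}"))


# ---------------------------------------------------------------------------
# STAR SJ.out.tab

_SJ_STRAND = {0: ".", 1: "+", 2: "-"}
_SJ_COLUMNS = ["seq_id", "intron_start", "intron_end", "strand_code",
               "motif_code", "annotated", "unique_reads", "multi_reads",
               "max_overhang"]


def read_sj_tab(path: str | os.PathLike) -> list[JunctionRecord]:
    """Read a 9-column STAR ``SJ.out.tab`` junction table.

    STAR reports the intron 1-based closed (first and last intronic base);
    internally the intron becomes [start-1, end).
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=_SJ_COLUMNS,
                         dtype={"seq_id": str})
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: not a valid SJ.out.tab: {exc}") from exc
    if df.shape[1] != 9:
        raise FormatError(f"{path}: expected 9 columns, found {df.shape[1]}")
    int_cols = _SJ_COLUMNS[1:]
    try:
        df[int_cols] = df[int_cols].astype(int)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-integer field: {exc}") from exc
    if df[int_cols].isna().any().any():
        raise FormatError(f"{path}: missing fields (fewer than 9 columns?)")

    records = []
    for row in df.itertuples(index=False):
        records.append(JunctionRecord(
            seq_id=row.seq_id,
            donor_pos=row.intron_start - 1,
            acceptor_pos=row.intron_end,
            strand=_SJ_STRAND.get(row.strand_code, "."),
            unique_reads=row.unique_reads,
            multi_reads=row.multi_reads,
        ))
    return records


def write_sj_tab(records: Sequence[JunctionRecord], path: str | os.PathLike) -> None:
    strand_code = {".": 0, "+": 1, "-": 2}
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda r: (r.seq_id, r.donor_pos)):
            fh.write(f"{r.seq_id}\t{r.donor_pos + 1}\t{r.acceptor_pos}\t"
                     f"{strand_code[r.strand]}\t0\t1\t{r.unique_reads}\t"
                     f"{r.multi_reads}\t20\n")


# ---------------------------------------------------------------------------
# BED6

def write_bed(hits: Iterable[MotifHit], path: str | os.PathLike) -> None:
    """Write motif hits as BED6 sorted by (seq_id, start)."""
    rows = sorted(hits, key=lambda h: (h.seq_id, h.interval.start, h.interval.end))
    with open(path, "w") as fh:
        for h in rows:
            fh.write(f"{h.seq_id}\t{h.interval.start}\t{h.interval.end}\t"
                     f"{h.motif_name}\t{h.score:g}\t{h.strand}\n")


def read_bed(path: str | os.PathLike) -> list[MotifHit]:
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 6:
                raise FormatError(f"{path}: line {lineno}: expected 6 BED columns")
            seq_id, start, end, name, score, strand = cols[:6]
            hits.append(MotifHit(
                name,
                GenomicInterval(seq_id, int(start), int(end), strand),
                float(score),
            ))
    return hits
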