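"""Synthetic fixtures with ground truth for every pipeline stage.

Generates annotated mini-genomes (genes with introns, exons, CDS and both
UTRs on random strands), sequences with motif consensi planted at
controlled per-region rates — optionally antisense, optionally with a
second motif coupled within a distance window — splice-junction tables
drawn from known multinomial usage, and gel-band tables with known fold
changes. Each generator returns the truth needed to score the stage that
consumes it, and a single seed makes the whole fixture reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    REGION_3UTR,
    REGION_5UTR,
    REGION_CDS,
    REGION_INTRON,
    Gene,
    GeneAnnotation,
    GenomicInterval,
    JunctionRecord,
    SequenceRecord,
    Transcript,
    reverse_complement,
)

logger = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype="S1")

PLANT_REGIONS = (REGION_5UTR, REGION_CDS, REGION_3UTR, REGION_INTRON)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# Mini-genome

@dataclass
class GenomeSpec:
    """Layout of a synthetic annotated genome.

    Genes are placed left to right, never overlapping, separated by
    intergenic gaps; each gene has one transcript of 2-6 exons with a
    5'-UTR at the transcript start, a 3'-UTR at its end and CDS between.
    """

    n_seqs: int = 2
    seq_length: int = 100_000
    n_genes: int = 40
    n_exons: tuple[int, int] = (2, 6)
    exon_len: tuple[int, int] = (150, 400)
    intron_len: tuple[int, int] = (60, 200)
    utr5_len: tuple[int, int] = (30, 100)
    utr3_len: tuple[int, int] = (50, 150)
    intergenic: tuple[int, int] = (100, 400)
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)


def _uniform(rng: np.random.Generator, lo_hi: tuple[int, int]) -> int:
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


def make_genome(spec: GenomeSpec, seed=None
                ) -> tuple[list[SequenceRecord], GeneAnnotation, pd.DataFrame]:
    """Generate (sequences, annotation, truth table of feature intervals).

    Raises before writing anything if the requested genes cannot fit on
    the requested sequences.
    """
    rng = _rng(seed)
    seq_ids = [f"chr{i + 1}" for i in range(spec.n_seqs)]
    cursors = dict.fromkeys(seq_ids, 0)
    ann = GeneAnnotation()
    truth_rows = []

    for gi in range(spec.n_genes):
        # draw the structure first so feasibility is known before placement
        n_ex = _uniform(rng, spec.n_exons)
        exon_lens = [_uniform(rng, spec.exon_len) for _ in range(n_ex)]
        intron_lens = [_uniform(rng, spec.intron_len) for _ in range(n_ex - 1)]
        utr5 = min(_uniform(rng, spec.utr5_len), exon_lens[0] - 10)
        utr3 = min(_uniform(rng, spec.utr3_len), exon_lens[-1] - 10)
        if utr5 < 1 or utr3 < 1:
            raise ValueError("exon length range too small for UTR range")
        strand = "+" if rng.random() < 0.5 else "-"
        gap = _uniform(rng, spec.intergenic)
        gene_len = sum(exon_lens) + sum(intron_lens)

        seq_id = seq_ids[gi % spec.n_seqs]
        if cursors[seq_id] + gap + gene_len > spec.seq_length:
            placed = False
            for alt in seq_ids:
                if cursors[alt] + gap + gene_len <= spec.seq_length:
                    seq_id, placed = alt, True
                    break
            if not placed:
                raise ValueError(
                    f"gene {gi + 1}/{spec.n_genes} does not fit: "
                    f"increase seq_length or reduce n_genes")
        start = cursors[seq_id] + gap
        cursors[seq_id] = start + gene_len

        gene_id = f"g{gi + 1:04d}"
        tx_id = f"{gene_id}.t1"
        exons = []
        pos = start
        for k, elen in enumerate(exon_lens):
            exons.append(GenomicInterval(seq_id, pos, pos + elen, strand))
            pos += elen
            if k < n_ex - 1:
                pos += intron_lens[k]
        span = GenomicInterval(seq_id, start, pos, strand)

        # UTRs sit at the transcript ends; genomic side depends on strand
        if strand == "+":
            utr5_iv = GenomicInterval(seq_id, exons[0].start, exons[0].start + utr5, strand)
            utr3_iv = GenomicInterval(seq_id, exons[-1].end - utr3, exons[-1].end, strand)
        else:
            utr5_iv = GenomicInterval(seq_id, exons[-1].end - utr5, exons[-1].end, strand)
            utr3_iv = GenomicInterval(seq_id, exons[0].start, exons[0].start + utr3, strand)

        cds = []
        for e in exons:
            lo, hi = e.start, e.end
            for u in (utr5_iv, utr3_iv):
                if u.start <= lo < u.end:
                    lo = u.end
                if u.start < hi <= u.end:
                    hi = u.start
            if lo < hi:
                cds.append(GenomicInterval(seq_id, lo, hi, strand))

        ann.add_gene(Gene(gene_id, span))
        tx = Transcript(tx_id, gene_id, strand, exons=exons, cds=cds,
                        utr5=[utr5_iv], utr3=[utr3_iv])
        tx.derive_introns()
        ann.add_transcript(tx)

        for kind, ivs in ((REGION_5UTR, [utr5_iv]), (REGION_3UTR, [utr3_iv]),
                          (REGION_CDS, cds), ("exon", exons),
                          (REGION_INTRON, tx.introns)):
            for iv in ivs:
                truth_rows.append({"gene_id": gene_id, "transcript_id": tx_id,
                                   "region": kind, "seq_id": seq_id,
                                   "start": iv.start, "end": iv.end,
                                   "strand": strand})

    records = []
    for seq_id in seq_ids:
        codes = rng.choice(4, size=spec.seq_length, p=np.asarray(spec.base_probs))
        records.append(SequenceRecord(seq_id, BASES[codes].tobytes().decode()))
    return records, ann, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Motif planting

@dataclass
class MotifPlan:
    """Planting plan for one motif consensus."""

    name: str
    consensus: str  # DNA alphabet; RNA (U) accepted
    region_prob: dict[str, float] = field(default_factory=dict)
    antisense_prob: float = 0.0

    def __post_init__(self) -> None:
        self.consensus = self.consensus.upper().replace("U", "T")


@dataclass
class Coupling:
    """Plant a partner motif near each planted instance of another."""

    a_name: str
    b_name: str
    d_max: int = 50
    q: float = 1.0


@dataclass
class PlantSpec:
    motifs: list[MotifPlan] = field(default_factory=list)
    coupling: Coupling | None = None
    screen_spurious: bool = True


class _Editor:
    """Mutable per-sequence base arrays with an occupancy mask."""

    def __init__(self, records: list[SequenceRecord]):
        self.arrays = {r.id: np.frombuffer(r.seq.encode(), dtype="S1").copy()
                       for r in records}
        self.occupied = {r.id: np.zeros(len(r.seq), dtype=bool) for r in records}

    def free(self, seq_id: str, start: int, end: int) -> bool:
        return not self.occupied[seq_id][start:end].any()

    def write(self, seq_id: str, start: int, text: str) -> None:
        arr = np.frombuffer(text.encode(), dtype="S1")
        self.arrays[seq_id][start:start + len(text)] = arr
        self.occupied[seq_id][start:start + len(text)] = True

    def records(self) -> list[SequenceRecord]:
        return [SequenceRecord(sid, arr.tobytes().decode())
                for sid, arr in self.arrays.items()]


def _plant_site(editor: _Editor, rng, seq_id: str, iv: GenomicInterval,
                motif: str, sense_strand: str, antisense: bool) -> tuple[int, str] | None:
    """Choose a free start inside ``iv`` and write the motif; returns
    (start, planted strand) or None if the interval has no room."""
    L = len(motif)
    if iv.width < L:
        return None
    candidates = np.arange(iv.start, iv.end - L + 1)
    rng.shuffle(candidates)
    for start in candidates:
        if editor.free(seq_id, start, start + L):
            strand = sense_strand
            if antisense:
                strand = "-" if sense_strand == "+" else "+"
            text = motif if strand == "+" else reverse_complement(motif)
            editor.write(seq_id, int(start), text)
            return int(start), strand
    return None


def plant_motifs(records: list[SequenceRecord], ann: GeneAnnotation,
                 spec: PlantSpec, seed=None
                 ) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Plant motif consensi into gene regions on the transcribed strand.

    Per gene, per motif, per region class with probability p one instance
    is written wholly inside a random interval of that class; antisense
    plantings (for strand-filter tests) go on the opposite strand with
    their own probability. With a coupling, each planted A in exon space
    gets a B within ``d_max`` bases with probability q. Afterwards the
    background is screened so no spurious exact-consensus matches remain
    on either strand outside the truth (offending bases re-rolled).

    Returns the modified sequences and a truth table with one row per
    planted instance (motif, seq_id, start, end, strand, gene_id, region,
    antisense flag).
    """
    rng = _rng(seed)
    editor = _Editor(records)
    plans = {m.name: m for m in spec.motifs}
    truth_rows: list[dict] = []

    def record(plan, seq_id, start, strand, gene_id, region, antisense):
        truth_rows.append({
            "motif": plan.name, "seq_id": seq_id, "start": start,
            "end": start + len(plan.consensus), "strand": strand,
            "gene_id": gene_id, "region": region, "antisense": antisense,
        })

    for gene_id in sorted(ann.genes):
        gene = ann.genes[gene_id]
        tx = ann.gene_transcripts(gene_id)[0]
        for plan in spec.motifs:
            for region, prob in plan.region_prob.items():
                if rng.random() >= prob:
                    continue
                ivs = [iv for iv in tx.regions(region)
                       if iv.width >= len(plan.consensus)]
                if not ivs:
                    logger.info("gene %s: no %s interval long enough for %s",
                                gene_id, region, plan.name)
                    continue
                iv = ivs[int(rng.integers(len(ivs)))]
                placed = _plant_site(editor, rng, gene.span.seq_id, iv,
                                     plan.consensus, gene.strand, antisense=False)
                if placed:
                    record(plan, gene.span.seq_id, placed[0], placed[1],
                           gene_id, region, False)
            if plan.antisense_prob > 0 and rng.random() < plan.antisense_prob:
                ivs = [iv for iv in tx.exons if iv.width >= len(plan.consensus)]
                if ivs:
                    iv = ivs[int(rng.integers(len(ivs)))]
                    placed = _plant_site(editor, rng, gene.span.seq_id, iv,
                                         plan.consensus, gene.strand, antisense=True)
                    if placed:
                        record(plan, gene.span.seq_id, placed[0], placed[1],
                               gene_id, "exon", True)

    if spec.coupling is not None:
        c = spec.coupling
        b_plan = plans[c.b_name]
        L = len(b_plan.consensus)
        a_rows = [r for r in list(truth_rows)
                  if r["motif"] == c.a_name and not r["antisense"]]
        for r in a_rows:
            if rng.random() >= c.q:
                continue
            gene = ann.genes[r["gene_id"]]
            # candidate starts with gap(a, b) <= d_max inside the gene span
            lo = max(gene.span.start, r["start"] - c.d_max - L)
            hi = min(gene.span.end - L, r["end"] + c.d_max)
            candidates = np.arange(lo, hi + 1)
            rng.shuffle(candidates)
            for start in candidates:
                if editor.free(r["seq_id"], start, start + L):
                    text = (b_plan.consensus if gene.strand == "+"
                            else reverse_complement(b_plan.consensus))
                    editor.write(r["seq_id"], int(start), text)
                    record(b_plan, r["seq_id"], int(start), gene.strand,
                           r["gene_id"], "coupled", False)
                    break
            else:
                logger.warning("no room to couple %s near %s at %s:%d",
                               c.b_name, c.a_name, r["seq_id"], r["start"])

    truth = pd.DataFrame(truth_rows, columns=[
        "motif", "seq_id", "start", "end", "strand", "gene_id", "region",
        "antisense"])
    if spec.screen_spurious:
        _screen(editor, spec, truth, rng)
    out = editor.records()
    # keep the caller's sequence order
    order = {r.id: i for i, r in enumerate(records)}
    out.sort(key=lambda r: order[r.id])
    return out, truth.sort_values(["seq_id", "start"]).reset_index(drop=True)


def _find_all(hay: str, needle: str) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def _screen(editor: _Editor, spec: PlantSpec, truth: pd.DataFrame,
            rng: np.random.Generator, max_rounds: int = 50) -> None:
    """Re-roll background bases until no exact-consensus match (either
    strand) exists outside the planted truth."""
    # strand is omitted from the key: an opposite-strand exact match at a
    # planted start would require a palindromic consensus
    planted = {(r.motif, r.seq_id, r.start) for r in truth.itertuples(index=False)}
    patterns = []  # (motif name, text on forward strand, strand it implies)
    for m in spec.motifs:
        patterns.append((m.name, m.consensus, "+"))
        rc = reverse_complement(m.consensus)
        if rc != m.consensus:
            patterns.append((m.name, rc, "-"))

    for _ in range(max_rounds):
        dirty = False
        for seq_id, arr in editor.arrays.items():
            s = arr.tobytes().decode()
            occupied = editor.occupied[seq_id]
            for name, text, strand in patterns:
                for start in _find_all(s, text):
                    if (name, seq_id, start) in planted:
                        continue
                    free = [p for p in range(start, start + len(text))
                            if not occupied[p]]
                    if not free:
                        continue  # wedged between plants; vanishingly rare
                    p = int(rng.choice(free))
                    old = arr[p]
                    choices = BASES[BASES != old]
                    arr[p] = rng.choice(choices)
                    dirty = True
        if not dirty:
            return
    raise RuntimeError("spurious-match screening did not converge")


# ---------------------------------------------------------------------------
# Splice-junction tables

@dataclass
class SJEventSpec:
    """One shared-anchor event with true usage proportions."""

    event_id: str
    seq_id: str
    anchor: str  # 'donor' or 'acceptor'
    anchor_pos: int  # internal coordinate of the shared intron edge
    partners: list[tuple[str, int]]  # (label, partner coordinate)
    proportions: list[float]
    depth: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.proportions), 1.0):
            raise ValueError(f"event {self.event_id}: proportions must sum to 1")
        if len(self.partners) != len(self.proportions):
            raise ValueError(f"event {self.event_id}: partners/proportions mismatch")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")


def make_sj(events: list[SJEventSpec], seed=None
            ) -> tuple[list[JunctionRecord], pd.DataFrame]:
    """Draw junction reads multinomially per event at the stated depth.

    Returns junction records (zero-read junctions omitted) and a truth
    table with true and sampled usage per alternative.
    """
    rng = _rng(seed)
    records: list[JunctionRecord] = []
    rows = []
    for ev in events:
        reads = (rng.multinomial(ev.depth, ev.proportions) if ev.depth > 0
                 else np.zeros(len(ev.partners), dtype=int))
        total = reads.sum()
        for (label, coord), p, n in zip(ev.partners, ev.proportions, reads):
            if ev.anchor == "donor":
                donor, acceptor = ev.anchor_pos, coord
            else:
                donor, acceptor = coord, ev.anchor_pos
            if n > 0:
                records.append(JunctionRecord(ev.seq_id, donor, acceptor,
                                              ev.strand, int(n)))
            rows.append({"event_id": ev.event_id, "label": label,
                         "true_percent": 100.0 * p,
                         "reads": int(n),
                         "sampled_percent": 100.0 * n / total if total else np.nan})
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gel-band tables

def make_bands(fold_changes: dict[str, float], n_replicates: int = 3,
               target: str = "target", control_gene: str = "RpL32",
               reference_condition: str = "control",
               base_target: float = 1000.0, base_control: float = 800.0,
               noise_sd: float = 0.0, seed=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Band-intensity table with known normalized fold changes.

    Each replicate gets its own loading scale, which the normalization
    must cancel; multiplicative log-normal noise is optional. Returns
    (band table, truth table of fold changes).
    """
    rng = _rng(seed)
    rows = []
    conditions = [reference_condition, *fold_changes]
    for rep in range(1, n_replicates + 1):
        for cond in conditions:
            scale = rng.uniform(0.5, 2.0)
            fc = 1.0 if cond == reference_condition else fold_changes[cond]
            noise = (np.exp(rng.normal(0, noise_sd, size=2))
                     if noise_sd > 0 else np.ones(2))
            rows.append({"condition": cond, "replicate": rep, "target": target,
                         "intensity": base_target * fc * scale * noise[0]})
            rows.append({"condition": cond, "replicate": rep,
                         "target": control_gene,
                         "intensity": base_control * scale * noise[1]})
    truth = pd.DataFrame([{"condition": c, "true_fold_change": f}
                          for c, f in fold_changes.items()])
    return pd.DataFrame(rows), truth
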