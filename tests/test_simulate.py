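import numpy as np
import pytest

from remotif import io as rio
from remotif import simulate as sim
from remotif.core import reverse_complement
from remotif.pwm import ScanSettings, scan_all


class TestMakeGenome:
    def test_deterministic_under_seed(self):
        spec = sim.GenomeSpec(n_genes=10, seq_length=40_000)
        r1, _, t1 = sim.make_genome(spec, seed=3)
        r2, _, t2 = sim.make_genome(spec, seed=3)
        assert [(a.id, a.seq) for a in r1] == [(b.id, b.seq) for b in r2]
        assert t1.equals(t2)

    def test_genes_do_not_overlap(self, small_genome):
        _, ann, _ = small_genome
        spans = sorted((g.span for g in ann.genes.values()),
                       key=lambda s: (s.seq_id, s.start))
        for a, b in zip(spans, spans[1:]):
            assert a.seq_id != b.seq_id or a.end <= b.start

    def test_features_nest_correctly(self, small_genome):
        _, ann, _ = small_genome
        for gene in ann.genes.values():
            for tx in ann.gene_transcripts(gene.id):
                assert tx.strand == gene.strand
                for e in tx.exons:
                    assert gene.span.start <= e.start < e.end <= gene.span.end
                for kind in ("cds", "utr5", "utr3"):
                    for f in getattr(tx, kind):
                        assert any(e.start <= f.start and f.end <= e.end
                                   for e in tx.exons)
                # every transcript carries both UTRs and some CDS
                assert tx.utr5 and tx.utr3 and tx.cds

    def test_round_trips_through_io(self, tmp_path, small_genome):
        records, ann, _ = small_genome
        fa, gff = tmp_path / "g.fa", tmp_path / "g.gff3"
        rio.write_fasta(records, fa)
        rio.write_gff3(ann, gff)
        back_recs = rio.read_fasta(fa)
        back_ann = rio.read_gff3(gff)
        assert [(r.id, r.seq) for r in back_recs] == [(r.id, r.seq) for r in records]
        assert set(back_ann.genes) == set(ann.genes)
        for tx_id, tx in ann.transcripts.items():
            back = back_ann.transcripts[tx_id]
            assert back.exons == tx.exons and back.introns == tx.introns
            assert back.cds == tx.cds

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            sim.make_genome(sim.GenomeSpec(n_genes=100, seq_length=5_000), seed=0)


class TestPlantMotifs:
    def test_truth_sites_carry_the_consensus(self, planted_fixture):
        records, _, truth = planted_fixture
        seqs = {r.id: r.seq for r in records}
        consensi = {"Rbfox1": "TGCATG", "Bru1": "TGTGTG"}
        for r in truth.itertuples():
            text = seqs[r.seq_id][r.start:r.end]
            expected = consensi[r.motif]
            assert text == (expected if r.strand == "+" else reverse_complement(expected))

    def test_planted_sites_inside_declared_region(self, planted_fixture):
        _, ann, truth = planted_fixture
        for r in truth[~truth.antisense].itertuples():
            tx = ann.gene_transcripts(r.gene_id)[0]
            assert any(iv.start <= r.start and r.end <= iv.end
                       for iv in tx.regions(r.region))

    def test_no_spurious_consensus_matches(self, planted_fixture):
        """Screening leaves exactly the planted instances discoverable."""
        records, _, truth = planted_fixture
        for motif, consensus in (("Rbfox1", "TGCATG"), ("Bru1", "TGTGTG")):
            hits = scan_all(records, None,
                            ScanSettings(mode="consensus", iupac=consensus,
                                         both_strands=True, motif_name=motif))
            got = {(h.seq_id, h.interval.start) for h in hits}
            expected = {(r.seq_id, r.start)
                        for r in truth[truth.motif == motif].itertuples()}
            assert got == expected

    def test_zero_probability_plants_nothing(self, small_genome):
        records, ann, _ = small_genome
        spec = sim.PlantSpec(motifs=[sim.MotifPlan("A", "TGCATG", {})])
        out, truth = sim.plant_motifs(records, ann, spec, seed=1)
        assert truth.empty
        hits = scan_all(out, None, ScanSettings(mode="consensus", iupac="TGCATG",
                                                both_strands=True))
        assert hits == []

    def test_coupling_distance_bound(self, small_genome):
        records, ann, _ = small_genome
        spec = sim.PlantSpec(
            motifs=[sim.MotifPlan("A", "TGCATG", {"CDS": 0.8}),
                    sim.MotifPlan("B", "TGTGTG", {})],
            coupling=sim.Coupling("A", "B", d_max=50, q=1.0))
        _, truth = sim.plant_motifs(records, ann, spec, seed=9)
        from remotif.core import GenomicInterval, gap
        a_rows = truth[truth.motif == "A"]
        b_rows = truth[truth.motif == "B"]
        assert len(b_rows) == len(a_rows)
        for r in a_rows.itertuples():
            a_iv = GenomicInterval(r.seq_id, r.start, r.end)
            dmin = min(gap(a_iv, GenomicInterval(b.seq_id, b.start, b.end))
                       for b in b_rows.itertuples() if b.seq_id == r.seq_id)
            assert dmin <= 50

    def test_deterministic_under_seed(self, small_genome):
        records, ann, _ = small_genome
        spec = sim.PlantSpec(motifs=[sim.MotifPlan("A", "TGCATG", {"intron": 0.5})])
        o1, t1 = sim.plant_motifs(records, ann, spec, seed=4)
        o2, t2 = sim.plant_motifs(records, ann, spec, seed=4)
        assert [(r.id, r.seq) for r in o1] == [(r.id, r.seq) for r in o2]
        assert t1.equals(t2)


class TestMakeSJ:
    def test_high_depth_recovers_proportions(self):
        spec = sim.SJEventSpec("ev", "chr1", "donor", 1000,
                               [("A1", 2000), ("A2", 3000)], [0.6, 0.4],
                               depth=1_000_000)
        _, truth = sim.make_sj([spec], seed=2)
        for r in truth.itertuples():
            assert r.sampled_percent == pytest.approx(r.true_percent, abs=0.2)

    def test_depth_zero_emits_no_records(self):
        spec = sim.SJEventSpec("ev", "chr1", "donor", 1000,
                               [("A1", 2000)], [1.0], depth=0)
        records, truth = sim.make_sj([spec], seed=0)
        assert records == []
        assert np.isnan(truth["sampled_percent"]).all()

    def test_single_alternative_100_percent(self):
        spec = sim.SJEventSpec("ev", "chr1", "donor", 1000,
                               [("A1", 2000)], [1.0], depth=50)
        records, truth = sim.make_sj([spec], seed=0)
        assert truth["sampled_percent"].iloc[0] == 100.0
        assert records[0].unique_reads == 50

    def test_round_trips_through_io(self, tmp_path):
        spec = sim.SJEventSpec("ev", "chr1", "donor", 1000,
                               [("A1", 2000), ("A2", 3000)], [0.5, 0.5], depth=100)
        records, _ = sim.make_sj([spec], seed=3)
        p = tmp_path / "s.SJ.out.tab"
        rio.write_sj_tab(records, p)
        assert sorted(rio.read_sj_tab(p), key=lambda r: r.acceptor_pos) == \
            sorted(records, key=lambda r: r.acceptor_pos)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sim.SJEventSpec("ev", "chr1", "donor", 1000,
                            [("A1", 2000)], [0.5], depth=10)
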