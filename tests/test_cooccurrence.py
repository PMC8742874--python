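import numpy as np
import pandas as pd
import pytest

from remotif.annotate import annotate_hits
from remotif.cooccurrence import (
    CLASSES,
    category_percent,
    classify,
    cooccurrence_fraction,
    expected_percent,
    summarize_genes,
)
from remotif.pwm import ScanSettings, scan_all


def summaries_from_flags(flag_rows, motif="m"):
    rows = []
    for gene_id, (u5, u3, cds, intr) in flag_rows.items():
        rows.append({"gene_id": gene_id, "motif": motif, "has_5UTR": u5,
                     "has_3UTR": u3, "has_CDS": cds, "has_intron": intr,
                     "cls": classify(u5, u3, cds, intr), "intron_flag": intr})
    return pd.DataFrame(rows)


class TestClassify:
    @pytest.mark.parametrize("flags, expected", [
        ((False, True, False, False), "UTR_only"),
        ((False, False, True, True), "CDS_only"),
        ((True, False, True, False), "UTR_and_CDS"),
        ((False, False, False, True), "intron_only"),
        ((False, False, False, False), "none"),
    ])
    def test_class_rules(self, flags, expected):
        assert classify(*flags) == expected


class TestSummarizeGenes:
    def test_pipeline_matches_planted_truth(self, planted_fixture):
        records, ann, truth = planted_fixture
        hits = scan_all(records, None,
                        ScanSettings(mode="consensus", iupac="TGCATG",
                                     both_strands=True, motif_name="Rbfox1"))
        summ = summarize_genes(annotate_hits(hits, ann), ann, ["Rbfox1"])
        sense = truth[(truth.motif == "Rbfox1") & ~truth.antisense]
        for row in summ.itertuples():
            regions = set(sense[sense.gene_id == row.gene_id].region)
            assert row.cls == classify("5UTR" in regions, "3UTR" in regions,
                                       "CDS" in regions, "intron" in regions)
            assert row.intron_flag == ("intron" in regions)

    def test_exactly_one_class_per_gene_motif(self, planted_fixture):
        records, ann, _ = planted_fixture
        hits = scan_all(records, None,
                        ScanSettings(mode="consensus", iupac="TGCATG",
                                     both_strands=True, motif_name="Rbfox1"))
        summ = summarize_genes(annotate_hits(hits, ann), ann, ["Rbfox1"])
        assert len(summ) == len(ann.genes)
        assert summ["cls"].isin(CLASSES).all()

    def test_absent_motif_all_none(self, small_genome):
        _, ann, _ = small_genome
        summ = summarize_genes([], ann, ["ghost"])
        assert (summ["cls"] == "none").all()


class TestCategoryPercent:
    def test_planted_fraction(self):
        flags = {f"g{i}": (i < 7, False, False, False) for i in range(20)}
        stat = category_percent(summaries_from_flags(flags), flags.keys(), "m")
        assert stat.percent_with_motif == pytest.approx(35.0)
        assert stat.n_genes == 20

    def test_breakdown_sums_to_total(self):
        flags = {"g1": (True, False, True, False), "g2": (False, True, False, True),
                 "g3": (False, False, False, True), "g4": (False,) * 4,
                 "g5": (False, False, True, False)}
        stat = category_percent(summaries_from_flags(flags), flags.keys(), "m")
        assert sum(stat.breakdown.values()) == pytest.approx(stat.percent_with_motif)

    def test_all_none_is_zero(self):
        flags = {f"g{i}": (False,) * 4 for i in range(10)}
        stat = category_percent(summaries_from_flags(flags), flags.keys(), "m")
        assert stat.percent_with_motif == 0.0

    def test_empty_set_rejected(self):
        flags = {"g1": (True, False, False, False)}
        with pytest.raises(ValueError):
            category_percent(summaries_from_flags(flags), ["gX"], "m")

    def test_monotone_in_motif_bearing_genes(self):
        flags = {f"g{i}": (i % 3 == 0, False, False, False) for i in range(12)}
        summ = summaries_from_flags(flags)
        subset = [f"g{i}" for i in range(6)]
        before = category_percent(summ, subset, "m").percent_with_motif
        after = category_percent(summ, subset + ["g9"], "m").percent_with_motif
        assert after >= before


class TestExpectedPercent:
    @pytest.mark.parametrize("f", [0.1, 0.25, 0.4])
    def test_mean_within_three_se_of_population_fraction(self, f):
        n_pop, size, n_sims = 5000, 200, 150
        flags = {f"g{i}": (i < f * n_pop, False, False, False) for i in range(n_pop)}
        exp = expected_percent(summaries_from_flags(flags), "m", [size],
                               n_sims=n_sims, seed=42)
        # hypergeometric SE of the mean over n_sims draws
        se_one = 100 * np.sqrt(f * (1 - f) / size * (n_pop - size) / (n_pop - 1))
        assert exp.mean_percent[size] == pytest.approx(
            100 * f, abs=3 * se_one / np.sqrt(n_sims))

    def test_sd_decreases_with_size(self):
        n_pop = 5000
        flags = {f"g{i}": (i < 1250, False, False, False) for i in range(n_pop)}
        exp = expected_percent(summaries_from_flags(flags), "m",
                               [100, 500, 1000, 3000], n_sims=150, seed=1)
        sds = [exp.sd_percent[s] for s in (100, 500, 1000, 3000)]
        assert sds == sorted(sds, reverse=True)

    def test_full_population_single_sim_is_exact(self):
        flags = {f"g{i}": (i < 4, False, False, False) for i in range(10)}
        exp = expected_percent(summaries_from_flags(flags), "m", [10], n_sims=1, seed=0)
        assert exp.mean_percent[10] == pytest.approx(40.0)
        assert exp.sd_percent[10] == 0.0

    def test_oversized_set_rejected(self):
        flags = {"g1": (True, False, False, False)}
        with pytest.raises(ValueError):
            expected_percent(summaries_from_flags(flags), "m", [5], seed=0)

    def test_seed_reproducibility(self):
        flags = {f"g{i}": (i % 4 == 0, False, False, False) for i in range(1000)}
        summ = summaries_from_flags(flags)
        a = expected_percent(summ, "m", [100], n_sims=20, seed=9)
        b = expected_percent(summ, "m", [100], n_sims=20, seed=9)
        assert a.mean_percent == b.mean_percent and a.sd_percent == b.sd_percent


class TestCooccurrence:
    def test_arithmetic(self):
        a = {f"g{i}": (i < 12, False, False, False) for i in range(20)}
        b = {f"g{i}": (i < 9 or i >= 18, False, False, False) for i in range(20)}
        # both: g0..g8 (9); either: g0..g11 + g18,g19 (14)
        pct = cooccurrence_fraction(summaries_from_flags(a, "A"),
                                    summaries_from_flags(b, "B"), "A", "B")
        assert pct == pytest.approx(100 * 9 / 14)
        pct_all = cooccurrence_fraction(summaries_from_flags(a, "A"),
                                        summaries_from_flags(b, "B"), "A", "B",
                                        denominator="all")
        assert pct_all == pytest.approx(45.0)

    def test_disjoint_sets_zero(self):
        a = {f"g{i}": (i < 5, False, False, False) for i in range(10)}
        b = {f"g{i}": (i >= 5, False, False, False) for i in range(10)}
        assert cooccurrence_fraction(summaries_from_flags(a, "A"),
                                     summaries_from_flags(b, "B"), "A", "B") == 0.0

    def test_empty_denominator_rejected(self):
        a = {f"g{i}": (False,) * 4 for i in range(5)}
        with pytest.raises(ValueError):
            cooccurrence_fraction(summaries_from_flags(a, "A"),
                                  summaries_from_flags(a, "B"), "A", "B")

    def test_binomial_recovery(self):
        """Independent planting at P(both)=0.3 is recovered within 3 SE."""
        rng = np.random.default_rng(3)
        n = 1000
        both = rng.random(n) < 0.30
        a = {f"g{i}": (bool(both[i]) or rng.random() < 0.2, False, False, False)
             for i in range(n)}
        b = {f"g{i}": (bool(both[i]) or rng.random() < 0.2, False, False, False)
             for i in range(n)}
        pct = cooccurrence_fraction(summaries_from_flags(a, "A"),
                                    summaries_from_flags(b, "B"), "A", "B",
                                    denominator="all")
        se = 100 * np.sqrt(0.3 * 0.7 / n)
        assert pct == pytest.approx(30.0, abs=3 * se)
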