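import numpy as np
import pytest

from remotif import simulate as sim
from remotif.core import GenomicInterval


@pytest.fixture(scope="session")
def small_genome():
    """A 20-gene mini-genome shared by annotation-level tests."""
    return sim.make_genome(sim.GenomeSpec(n_genes=20, n_seqs=2,
                                          seq_length=60_000), seed=11)


@pytest.fixture(scope="session")
def planted_fixture(small_genome):
    """Genome with Rbfox1/Bru1 consensi planted at known sites."""
    records, ann, _ = small_genome
    spec = sim.PlantSpec(motifs=[
        sim.MotifPlan("Rbfox1", "TGCATG",
                      {"5UTR": 0.5, "3UTR": 0.6, "CDS": 0.5, "intron": 0.6},
                      antisense_prob=0.4),
        sim.MotifPlan("Bru1", "TGTGTG", {"3UTR": 0.5, "intron": 0.5}),
    ])
    planted_records, truth = sim.plant_motifs(records, ann, spec, seed=12)
    return planted_records, ann, truth


def brute_force_scan(seq: str, log_odds_matrix, threshold: float,
                     both_strands: bool = False):
    """Independent reference scorer: score every window by explicit loops.

    Returns a dict mapping (start, strand) to score. Windows containing a
    non-ACGT character are skipped.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = len(log_odds_matrix)
    out = {}
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        s = seq if strand == "+" else "".join(comp[c] for c in reversed(seq))
        for start in range(len(s) - L + 1):
            window = s[start:start + L]
            if any(c not in idx for c in window):
                continue
            score = sum(log_odds_matrix[i][idx[c]] for i, c in enumerate(window))
            if score >= threshold:
                fwd = start if strand == "+" else len(s) - start - L
                out[(fwd, strand)] = float(score)
    return out


def brute_force_nearest(a_intervals, b_intervals):
    """All-pairs reference for nearest_distance: list of min gaps, plus
    the count of A intervals with no same-sequence B."""
    dists, dropped = [], 0
    for a in sorted(a_intervals, key=lambda x: (x.seq_id, x.start, x.end)):
        gaps = [max(0, b.start - a.end, a.start - b.end)
                for b in b_intervals if b.seq_id == a.seq_id]
        if gaps:
            dists.append(min(gaps))
        else:
            dropped += 1
    return dists, dropped


def random_pwm(rng, length):
    probs = rng.dirichlet(np.ones(4) * 0.5, size=length)
    return probs


def random_intervals(rng, n, seq_ids=("chr1", "chr2"), span=10_000, width=(1, 50)):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        w = int(rng.integers(width[0], width[1] + 1))
        out.append(GenomicInterval(str(rng.choice(seq_ids)), start, start + w))
    return out
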