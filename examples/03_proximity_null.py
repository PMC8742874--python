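"""Are two motifs closer together than chance?

Plants an A motif (Rbfox1, UGCAUG) and couples a B motif (Bru1, UGUGUG)
within 50 nt of each A instance, then compares the observed
A-to-nearest-B distances with a null in which the same number of B
motifs is placed uniformly at random over annotated exon space
(50 simulations).
"""

from remotif import simulate as sim
from remotif.core import GenomicInterval
from remotif.proximity import compare_to_null, nearest_distance, simulate_null

records, ann, _ = sim.make_genome(sim.GenomeSpec(n_genes=30, n_seqs=2,
                                                 seq_length=60_000), seed=15)
spec = sim.PlantSpec(
    motifs=[sim.MotifPlan("Rbfox1", "TGCATG", {"CDS": 0.9, "intron": 0.9}),
            sim.MotifPlan("Bru1", "TGTGTG", {})],
    coupling=sim.Coupling("Rbfox1", "Bru1", d_max=50, q=1.0))
_, truth = sim.plant_motifs(records, ann, spec, seed=16)

a = [GenomicInterval(r.seq_id, r.start, r.end)
     for r in truth[truth.motif == "Rbfox1"].itertuples()]
b = [GenomicInterval(r.seq_id, r.start, r.end)
     for r in truth[truth.motif == "Bru1"].itertuples()]

observed = nearest_distance(a, b)
null = simulate_null(ann, a, n_b=len(b), motif_len_b=6, n_sims=50, seed=17)
report = compare_to_null(observed, null)

print(f"A motifs: {len(a)}, B motifs: {len(b)}")
print(f"observed median distance: {report.observed_median:.0f} nt")
print(f"null median (uniform in exons): {report.null_median_mean:.0f} "
      f"+/- {report.null_median_sd:.0f} nt over {report.n_sims} simulations")
print(f"empirical p (closer than random): {report.p_label}")
print("\nThe observed median sits far below every simulated null median: "
      "the coupling planted into the fixture is detected as non-random "
      "proximity, the same inference drawn for co-regulating RNA-binding "
      "proteins.")
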