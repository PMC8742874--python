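"""Percent usage of splice junctions sharing a donor.

Simulates a STAR SJ.out.tab junction table for one alternative-acceptor
event with true usage 60/30/10 at depth 1,000, then recovers the usage
percentages: reads(D->Ax) / sum_i reads(D->Ai) x 100.
"""

from remotif import simulate as sim
from remotif.junctions import JunctionEvent, usage

partners = [("exon_A", 2000), ("exon_B", 3000), ("exon_C", 4000)]
spec = sim.SJEventSpec("alt_acceptor", "chr1", "donor", anchor_pos=1000,
                       partners=partners, proportions=[0.6, 0.3, 0.1],
                       depth=1000)
records, truth = sim.make_sj([spec], seed=20)

event = JunctionEvent("alt_acceptor", "donor", "chr1", 1000, tuple(partners))
res = usage(event, records)

print(f"total junction reads: {res.total_reads}")
for label, true_pct in zip(("exon_A", "exon_B", "exon_C"), (60, 30, 10)):
    print(f"  {label}: {res.reads[label]:4d} reads -> "
          f"{res.percents[label]:5.1f}% (truth {true_pct}%)")
print("\nEach percentage is the share of junction-spanning reads from the "
      "shared donor that splice to that acceptor; sampling noise at this "
      "depth keeps estimates within a few percent of the truth.")
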