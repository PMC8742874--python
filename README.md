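# remotif

Analysis of RNA-binding-protein (RBP) motifs in annotated genomes, built
for questions like those raised by muscle-type-specific splicing in
*Drosophila*: where do Rbfox1-type elements (5′-UGCAUG-3′) sit within
genes, are they enriched in curated gene categories, do they co-occur
with and cluster near a second RBP's motifs (e.g. the CELF-family
protein Bruno1), and how is alternative splice-donor/acceptor choice
distributed in junction-read data?

The package provides, as a plain Python library:

- **Motif scanning** — position weight matrix (PWM) log-odds scoring and
  exact IUPAC-consensus matching over FASTA sequences, forward or both
  strands, with BED6 output. A window `x₁…x_L` scores
  `S = Σᵢ log₂[(pᵢ(xᵢ) + c·b(xᵢ)) / ((1+c)·b(xᵢ))]` bits against
  background `b` with pseudocount `c`; hits are windows with
  `S ≥ θ`, where `θ` is absolute or a fraction of the maximum
  attainable score.
- **Feature annotation** — assignment of hits to overlapping genes
  (GFF3), a transcribed-strand filter keeping only matches present in
  the pre-mRNA, and classification by intron / exon / CDS / 5′-UTR /
  3′-UTR across all isoforms.
- **Gene-category statistics** — per-gene motif classes (UTR-only,
  CDS-only, UTR-and-CDS, intron-only) and the percent of a gene set
  carrying a motif, compared against a Monte-Carlo expectation from 150
  random gene sets drawn without replacement at each set size.
- **Proximity analysis** — the distance from each A-motif instance to
  its nearest B-motif instance (0 for overlapping or book-ended
  intervals), against a null in which the observed number of B motifs is
  re-placed uniformly over annotated exon space, 50 simulations by
  default.
- **Splice-junction usage** — for junctions sharing a donor D (or, with
  roles swapped, an acceptor), `usage(Aₓ) = 100 · reads(D→Aₓ) / Σᵢ
  reads(D→Aᵢ)` from STAR `SJ.out.tab` tables.
- **Gel densitometry** — percent-of-signal per primer pair,
  `100 · Iⱼ / Σ I`, and fold change normalized to a control gene
  (RpL32 by default) within the same PCR replicate.
- **Synthetic data** — ground-truthed mini-genomes, motif plantings with
  controlled per-region rates, antisense fractions and A–B coupling,
  junction tables with known multinomial usage, and band tables with
  known fold changes, so every stage is testable without any download.

All coordinates are 0-based half-open internally; GFF3 and `SJ.out.tab`
(1-based closed) are converted at the format boundary.

## Worked example

`examples/03_proximity_null.py` plants Rbfox1 elements in a synthetic
30-gene genome and couples a Bru1 element within 50 nt of each, then
asks whether the two motifs are closer than chance:

```
A motifs: 52, B motifs: 52
observed median distance: 17 nt
null median (uniform in exons): 384 +/- 69 nt over 50 simulations
empirical p (closer than random): < 0.02
```

The observed median (17 nt) lies below every one of the 50 null medians
(384 ± 69 nt), so the empirical p-value bottoms out at the 1/50
resolution of the null — the planted coupling is detected as non-random
proximity. The other scripts in `examples/` walk through scanning,
gene-class summaries with the random-set expectation, junction usage and
densitometry the same way, each printing the numbers it computes.

A thin CLI mirrors the library for shell use (`remotif scan`,
`annotate`, `cooccur`, `distnull`, `junctions`, `gels`, `simulate`);
run `remotif --help`.

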