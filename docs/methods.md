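# Methods

## Coordinate conventions

Everything internal is 0-based half-open on the forward genomic strand.
GFF3 and STAR `SJ.out.tab` are 1-based closed and converted only inside
`remotif.io`; BED is already 0-based half-open. A junction's intron is
stored as `[donor_pos, acceptor_pos)` = (first intronic base, last
intronic base + 1) regardless of strand. Introns are not read from
annotation but derived per transcript as the gaps between its sorted
exons, which guarantees they partition the transcript span with the
exons.

## Motif model and scanning

A motif is an L×4 position probability matrix `p` with background `b`
(uniform 0.25 by default) and pseudocount `c` (default 0.01, scaled by
the background so that zero cells in database matrices stay finite
without distorting informative positions). The log-odds score of window
`x` is `Σᵢ log₂[(pᵢ(xᵢ)+c·b(xᵢ))/((1+c)·b(xᵢ))]` bits; with `c = 0` a
zero cell scores −∞, which simply excludes windows containing that base.
The scan threshold is either absolute bits or a fraction of the maximum
attainable score (sum of per-position row maxima); the default fraction
is 0.8, chosen as a reproducible, tunable cutoff in the absence of a
canonical one, with consensus mode available as the parameter-free
alternative for single-element motifs such as UGCAUG. Windows containing
N are skipped. Reverse-strand hits are matches of the reverse complement
reported in forward coordinates with strand `−`. All hits above
threshold are reported, including mutual overlaps — downstream distance
statistics need every instance. Genome-level scans are run on both
strands and the transcribed-strand filter is applied afterwards;
transcript-level scans should be forward-only.

Consensus mode assigns each hit the maximum score of the PWM implied by
the consensus (allowed bases uniform per position), so consensus and PWM
hits are comparable on one scale.

## Gene assignment and region classification

A hit is attached to **every** gene whose span overlaps it by at least
one base; minimum-overlap fractions are deliberately avoided because a
6-mer motif at a feature boundary would otherwise vanish silently. The
transcribed-strand filter then keeps hits whose strand equals the gene's
strand; unstranded hits or genes are kept by default (configurable) and
counted in the log. Strand filtering is per (hit, gene) pair, so a hit
antisense to one gene but sense to an overlapping gene survives for the
sense gene. Region labels are the union over the gene's transcripts of
every feature class overlapped (intron, exon, CDS, 5UTR, 3UTR); CDS and
UTR labels imply the exon label. A motif can therefore legitimately be
both intronic (one isoform) and exonic (another).

## Gene classes and the random-set expectation

Per (gene, motif) the class is: UTR_and_CDS if both a UTR hit and a CDS
hit exist; else UTR_only / CDS_only; intron_only when only intronic hits
exist; none otherwise — exactly one class per gene, with an intron flag
overlaid on the exonic classes. The expectation for "what fraction of a
random set of k genes carries the motif" draws 150 sets of size k
without replacement from all annotated genes and reports mean and SD of
the per-set percentages. Sampling without replacement matches the
set semantics of gene lists; the estimator is unbiased for the
population fraction (hypergeometric mean), and its SD decreases with k
on a fixed population. "Carries the motif" uses the same region scope
for observed and expected statistics (default: any class ≠ none), so the
two are directly comparable; a UTR/CDS-only scope is available. The
default set sizes are {100, 500, 1000, 3000}. Two-motif co-occurrence is
reported as the percent of genes carrying both motifs, with the
denominator defaulting to genes carrying at least one motif of either
factor (an explicitly conditioned comparison), and the whole-set
denominator available.

## Proximity null

The observed statistic is the gap from each A instance to its nearest B
instance on the same sequence: 0 for overlap or book-ending, otherwise
the number of bases strictly between. Interval toolkits differ by ±1 on
adjacency; this convention is fixed and used identically for observed
and null, so any constant offset cancels in the comparison. The null
re-places the observed number of B motifs, at their motif length,
uniformly over exon space: an exon is chosen with probability
proportional to its number of valid start positions (`len − L + 1`), the
start uniform within it, duplicated exon intervals deduplicated first.
Placements may overlap each other or A — no exclusion rule is imposed.
Per simulation the full distance multiset is kept; inference uses the
per-simulation medians (empirical p = fraction of null medians ≤
observed median, reported as `< 1/n_sims` when zero), while density
curves pool all simulated distances. A Kolmogorov–Smirnov two-sample
statistic between observed and pooled null distances is reported as a
descriptive supplement. A per-gene-count-preserving placement is not
implemented; the transcriptome-wide placement is the modeled hypothesis.

## Junction usage

Events are user-declared shared-anchor coordinate sets (hand-selected,
as in practice); a helper lists all junctions at an anchor to assist
event definition. Matching is exact on (seq_id, donor, acceptor) with
strand compatibility ('.' matches either). Counts default to uniquely
mapped reads (STAR column 7), with multi-mappers available by flag.
Events with zero total reads are flagged undefined rather than reported
as 0%, since a silent 0/0 → 0 would fabricate a percentage. Per-sample
and pooled outputs are both emitted when multiple samples are given.

## Densitometry

`percent_of_signal` and `fold_change` implement the two standard gel
formulas; replicate pairing for fold change is mandatory metadata, and
cross-replicate ratios refuse to compute. The control gene defaults to
RpL32 but is a parameter.

## Synthetic data

The generator emulates the *structure* the pipeline consumes, not the
fly genome's sequence statistics. Defaults: 2 sequences of 100 kb, 40
non-overlapping genes (random strand), 2–6 exons of 150–400 bp, introns
60–200 bp, 5′-UTRs 30–100 bp and 3′-UTRs 50–150 bp carved from the
terminal exons, one transcript per gene, uniform base composition.
Uniform composition makes spurious-match screening cheap and the
analytic checks clean; a GC-biased option exists for robustness tests.
Motif planting writes the consensus (reverse-complemented for
minus-strand genes) wholly inside a randomly chosen interval of the
declared region class, tracks occupancy so plantings never overlap, and
can plant antisense instances and couple a B motif within a distance
window of each A. After planting, the background is screened: any exact
match of a planted consensus (either strand) outside the truth table has
one free base re-rolled, iterating to a fixed point — so consensus-mode
scans recover exactly the truth. This screening is meaningful only for
consensus-mode tests; PWM hits in random background are legitimate
matches, not artifacts, so PWM-mode tests compare against
threshold-relative truth instead. Junction tables are drawn
multinomially at stated depths; band tables give each replicate its own
loading scale that within-replicate normalization must cancel.

What the generator does **not** emulate: realistic repeat content, codon
structure, splice-site sequence signals, expression-dependent read
depth, or multi-isoform genes (the classifier handles multiple isoforms;
the generator emits one transcript per gene). Passing tests therefore
demonstrate correctness of the computations and calibration of the
Monte-Carlo machinery, not performance on real genomes.

## Numerical and design notes

- Determinism: every stochastic routine takes a seed or
  `numpy.random.Generator`; one seed reproduces fixtures and results
  bit-for-bit.
- Degenerate inputs: sequences shorter than the motif scan to empty (not
  an error); empty A sets give empty distance sets; empty gene sets,
  zero-read events and all-zero band groups raise or flag explicitly.
- Problem sizes in tests and the acceptance script (200-gene recovery
  genome, 30-gene calibration genome, 200 calibration repetitions,
  depths 10²–10⁴) were chosen so that every Monte-Carlo check has
  comfortable statistical resolution while the whole suite runs in
  seconds on one CPU.
- Expectation set sizes are a parameter; the default {100, 500, 1000,
  3000} spans the range of typical curated gene categories.

## Known limitations

No p-value calibration of PWM scores against a background model; no
dinucleotide backgrounds; no junction discovery from alignments; no
per-isoform quantitative weighting; gene categories are inputs, not
curated by the package.
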