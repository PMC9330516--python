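# Methods

## Statistics

For an intron with 0-based half-open interval [s, e), the *boundary
bases* are the first intronic base at each end: position s and position
e−1 (donor and acceptor are assigned by transcript strand).  Two raw
quantities are counted per intron and sample:

- **transreads** `T`: alignments carrying an N (skipped-region) CIGAR
  operation whose gap equals the intron interval exactly at both ends.  A
  read with k N operations contributes to k junctions; secondary,
  supplementary, duplicate and unmapped records are excluded; paired
  fragments count once per junction (mate dedup by read name).  Junctions
  not matching any annotated intron are reported as novel, never merged.
- **boundary coverage** `C_d, C_a`: reads placing an M/=/X (or D) base on
  the boundary position.  A read whose N-gap spans the position does not
  cover it.  In error-free data these bases are covered only by
  retention reads, so T and C separate the spliced and unspliced
  transcript populations exactly.

From these:

- site efficiency `T / C_site`; intron efficiency pools the two sites,
  `2T / (C_d + C_a)`; gene efficiency pools across the gene's introns
  (sum of numerators over sum of denominators).  Pooled ratios are used
  instead of means of ratios because coverage weighting is
  variance-stabilising and absorbs a single empty site.  Efficiency is a
  spliced:unspliced odds, unbounded above, with infinite-depth limit
  `(1−ψ)/ψ` (up to a factor `(L−1)/L` for read length L, because a
  junction read needs one aligned base on each side of the gap, leaving
  L−1 eligible start positions versus L for a boundary base).
- retention PSI `ψ_IR = mean(C_d, C_a) / (mean(C_d, C_a) + T)`, bounded in
  [0, 1] with limit `ψ·L / (ψ·L + (1−ψ)(L−1)) ≈ ψ`.

A zero denominator makes a statistic *undefined* (NaN), never 0; a
`pseudocount` option adds a constant to numerator and denominator when a
defined value is preferred.  Introns with `T + mean(C) < min_evidence`
(default 10) are flagged low-confidence and excluded from differential
testing and gene pooling: ratio estimates below ~10 informative reads are
too unstable to compare.

### Minimum anchor

`min_anchor` (aligned bases required on each side of a gap; default 1)
filters junction evidence.  Anchors larger than 1 are useful against
spurious spliced alignments in real data (Regtools-style tools use 8),
but they are *not* neutral: an anchor of a censors junction evidence to
L−2a+1 start positions while boundary coverage keeps L, deflating
efficiency by (L−2a+1)/(L−1) and inflating ψ_IR (≈ +0.056 at ψ = 0.5 for
L = 75, a = 8).  The default therefore stays at the weakest value that a
junction alignment implies anyway, and the estimators remain consistent;
users raising the anchor for noisy data should expect that bias or keep
read lengths large relative to the anchor.

## Differential testing

The global shift between conditions is a two-sided Wilcoxon signed-rank
test (normal approximation with continuity correction) on per-intron
efficiencies paired by intron, replicate means per condition, undefined
entries dropped pairwise.  Pairing removes intron-level nuisance (length,
coverage, GC); the sign test structure is robust to the heavy right tail
of efficiency ratios.  Fewer than 20 pairs is refused as underpowered;
all-zero differences return p = 1 by convention.

Expression change is a deliberately simple stand-in for a dedicated
count-based DE engine: library-size normalisation to the grand mean
library, log2 fold change of normalised means with pseudocount 0.5,
Welch's t-test on log2 normalised counts, BH adjustment across genes.
Users with real data can supply an external DE table instead (gene_id,
log2fc, p_value).

Candidate retained-intron genes are the intersection over two datasets:
`log2FC < −1` and `p < 0.05` (raw p, mirroring the procedure this rule
operationalises; q-values are emitted alongside) in both, AND gene-level
efficiency delta < 0 computed from confident introns in both.  No
multiplicity correction is applied to the efficiency-delta component;
output is sorted by the sum of per-table ranks.

The PSI–expression correlation is plain Pearson on paired per-sample
vectors (≥ 10 pairs; zero variance yields an undefined r, flagged).

## Synthetic data

The simulator emulates a two-condition × three-replicate knockdown study:
per-intron retention fractions that rise in the knockdown condition,
read depth in the 50–200× range over expressed transcripts, uniform
fragment start positions, no sequencing error.  Genes are laid out on one
toy chromosome with alternating strands; each gene has equal-length exons
(default 200 nt) separated by introns (default 150 nt).

Per gene, condition and replicate a pool of `molecules_per_gene` (default
300) pre-mRNA molecules draws retention patterns, each intron
independently Bernoulli(ψ).  Fragments are Poisson per molecule with rate
proportional to the number of valid start positions, starts uniform —
i.e. uniform fragmentation over the entire molecule pool, so longer
(retention) molecules emit proportionally more reads.  This is the
sampling model under which coverage-ratio estimators target the
*molecular* retention fraction; a fixed-reads-per-gene scheme would
underestimate ψ by ~0.05 at ψ = 0.5.  Reads are emitted directly as
sorted, primary, MAPQ-60 SAM alignments (alignment is out of scope and
error-free alignments isolate the quantification logic); single-end only.
Depth is *coverage*: a value of 100 means each expressed base is covered
by ~100 reads.

Replicate noise (`dispersion`, default 0.1): ψ perturbed on the logit
scale with this standard deviation (ψ of exactly 0/1 untouched), and
per-gene depth scaled by a mean-1 gamma variate with this coefficient of
variation, giving overdispersed (negative-binomial-like) gene counts.
`depth_multipliers` scales per-gene expression per condition — the hook
used to plant differentially expressed target genes.

The truth table records, per intron and sample, the realized molecular
retention fraction and the emitted read composition (junction-spanning
reads, intron-body reads, and per-boundary coverage counts); the
boundary-informative read fraction converges to ψ.

What the simulator does **not** model — sequencing errors and indels,
soft-clipping, multi-mapping, transcript-level isoform structure beyond
independent per-intron retention, co-retention correlation, 3' bias,
paired-end fragments — bounds what passing tests show: they validate the
counting and statistical machinery on clean alignments, not robustness to
alignment artifacts in real libraries.

A count-level companion (`simulate_intron_counts`) draws boundary and
junction counts directly from the same Poisson rates; repeat studies of
test power and size use it (250 read-level repeats would cost ~10^8
reads for no additional insight into the test itself).  Its agreement
with the read-level generator is itself under test.

## Study scales and numerical choices

- Parameter recovery: retention grid {0.1, 0.3, 0.5, 0.7, 0.9}, depth
  200, six replicates pooled.  Binomial propagation gives
  sd(ψ̂) ≈ 0.0125 at ψ = 0.5 at that pooled depth, so the ±0.05 recovery
  check sits at 4σ per intron; the efficiency check uses an exact-binomial
  99.9% interval at the realized informative count (family-wise ~1% over
  the 10 grid introns).
- Large-depth limit: depth 2000, three replicates, six introns per grid
  value; ψ_IR is checked as a per-grid-value mean within 2 percentage
  points, the efficiency limit at ψ = 0.5 where the odds ratio is stable.
  With 300 molecules per gene the realized molecular fraction itself has
  sd ≈ 0.017 pooled, which dominates the remaining spread.
- Power/size of the global shift test: 200 introns, ψ 0.2 → 0.4, 3 vs 3
  at depth 100; 50 repeats for power, 200 for size (count-level).
- Candidate recovery: twin 100-gene studies, 8 targets (4-fold
  expression drop, ψ 0.1 → 0.5), depth 80, read length 75, exons 120 nt.
- Motif enrichment: add-one empirical p over ≥ 100 dinucleotide-
  preserving shuffles (Altschul–Erikson random-last-edge Eulerian walk),
  so p ∈ (0, 1] by construction.  PWM columns receive a 1e-6
  pseudo-probability before log-odds so indicator matrices keep finite
  scores, and thresholds are *relative*: (score − min)/(max − min) ≥ t,
  making t = 1 exactly the IUPAC scan of an indicator PWM and t = 0 every
  window.
- Determinism: all randomness flows through numpy Generators seeded from
  the study seed; SAM records are sorted with a stable key and floats are
  written with a fixed format, so identical configs give byte-identical
  outputs.

## Known limitations

- The denominator of the efficiency statistic is intronic-base coverage,
  so efficiency can exceed 1; ψ_IR is provided as the bounded companion
  and both are always emitted side by side.
- Gene-level aggregation is the package's documented choice (pooled
  ratio); other aggregations (median of intron ratios, TPM-weighted) are
  not implemented.
- Strand is taken from annotation, not inferred from XS tags; junction
  matching is exact (no fuzzy ends).
- The expression stage is not a replacement for a dispersion-modelling DE
  engine at small replicate counts with real overdispersion.
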