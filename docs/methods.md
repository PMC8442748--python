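# Methods

## The mapping problem

A single fully penetrant recessive nuclear gene controls a male-sterility
phenotype in an inbred line. Crossing a sterile plant to a normal inbred,
selfing the F1, and pooling DNA from the two phenotype classes of the F2
gives two bulks whose allele frequencies agree everywhere except near the
trait locus. `bsamap` implements the comparison of those pooled frequencies
(bulked-segregant analysis, BSA-seq): per-site association statistics,
window smoothing, threshold rules, candidate-region extraction, and
codon-level annotation of variants in candidate genes.

## Statistics

**SNP index.** For a pool at a biallelic site, the fraction of reads
carrying the sterile-parent allele. Orientation comes from the parent
genotype calls, which must be homozygous and different (the inbred-parent
assumption); sites violating it raise an orientation error. Zero-depth
pools give a missing value.

**Delta-SNP index.** Sterile-bulk index minus fertile-bulk index. For the
F2 recessive design the sterile bulk is all `aa` (expected index 1) and the
fertile bulk is `AA:Aa = 1:2` (expected index 1/3), so the expected delta
at the causal locus is 2/3 — the theoretical threshold, 0.667 to three
decimals. `mendel.expected_bulk_freq` generalises the class expectations to
incomplete penetrance and backcross designs by genotype enumeration.

**Euclidean distance.** With pool frequencies p and q, the distance between
the frequency vectors (p, 1-p) and (q, 1-q); for biallelic sites this
equals sqrt(2)|p-q|, and the two-term definition is evaluated literally so
the closed form can serve as an independent check. The statistic is raised
to the fifth power before fitting to suppress background noise; the
exponent is conventional for ED scans, configurable, and no conclusion in
the test suite depends on its value.

## Filtering

Four rules, applied in a fixed order so the per-rule removal counts are
reproducible: (1) multi-allelic sites; (2) sites with fewer than four
supporting reads; (3) sites where both pools show the same inferred
genotype; (4) sites where the allele fixed in the recessive bulk is not
carried by the recessive parent. Two points required operational choices:

- *Pool genotype call (rule 3).* A pool is called ref-fixed / het-like /
  alt-fixed by its alt-read fraction against a (0.2, 0.8) band. The band is
  wide enough that at ~34x a truly fixed pool essentially never leaves its
  class, yet a 50:50 pool essentially never reaches one.
- *Read support (rule 2).* "Fewer than four reads" can be read per pool or
  per allele. The default removes sites where either bulk's total depth is
  below 4; `support_mode="allele"` instead removes sites whose combined
  alternate-allele support is positive but below the cutoff.

Filtering is monotone (output is a subset of input) and idempotent; both
are property-tested.

## Smoothing, thresholds, regions

The fitted track is a physical sliding-window mean: default 1 Mb window
advanced by 10 kb, each window the half-open interval [c - w/2, c + w/2),
windows with fewer than 3 usable sites flagged missing. A windowed mean was
chosen over loess because it is transparent, fast, and exactly checkable
against hand arithmetic; fitted values always lie in the convex hull of the
raw values in the window.

Threshold rules: `theoretical` (the 2/3 design expectation; default for
delta scans), `percentile:q` (genome-wide percentile of fitted values,
linear interpolation; the study design uses q = 99), `fixed:x` (e.g. the
relaxed 0.56 used to localise regions more precisely), and `median3sd`
(median + 3 sample standard deviations, n-1 denominator; default for ED
scans). Percentiles are genome-wide by default — the per-chromosome
alternative only changes which windows clear the bar in multi-peak
genomes, and genome-wide matches the single-causal-locus design.

Candidate regions are maximal runs of consecutive non-missing windows whose
fitted value strictly exceeds the threshold (ties excluded); missing windows
break runs. Region bounds are the outermost window boundaries clipped to
covered site positions. Coordinates are 1-based inclusive internally; BED
output is 0-based half-open. Region extraction is tested against an
exhaustive interval oracle that checks every interval for validity and
maximality.

## Codon-effect annotation

Single-base codon substitutions are classified with the standard genetic
code (NCBI translation table 1; plant nuclear genes need no other):
synonymous, non-synonymous, stop_gained, stop_lost, and start_lost (only
for annotated initiation codons). For comparison against published
two-label tables the extended labels collapse into "non-synonymous".
The classifier is exhaustively verified against direct translation of all
576 single-base codon changes. Published "aTc/aGc"-style notation is parsed
with the mutated base taken from the upper-case letter, falling back to the
positional difference when the case is uniform. Gene-model annotation
(VCF + GFF3 + FASTA) is strand-aware: minus-strand codons are
reverse-complemented before lookup, and plus/minus encodings of the same
biological change give the same call.

## Mendelian checks

`expected_ratio` enumerates phenotype-class weights (F2 recessive 3:1;
backcross 1:1; penetrance p rescales the recessive class, e.g. p = 0.5
gives 7:1). `chi_square_gof` is the Pearson statistic with df = 1 against
the ratio-implied expected counts, p-value from the chi-square law, no
continuity correction by default (a Yates flag exists); it is validated
against an independent multinomial goodness-of-fit routine, not against any
published chi-square value, because the underlying plant counts of the
original families are not available.

## The simulator

The generator reproduces the statistical structure the analysis assumes,
at desk scale:

- **Genome.** Eleven chromosomes of 10 Mb with 2000 SNPs genome-wide at
  fixed uniform-random positions; the causal locus sits on chromosome 6
  near 2.37 Mb, echoing the candidate gene's real position. The real
  genome's ~30 Mb chromosomes are scaled down ~3x; SNP density
  (~0.2 SNP/kb) is far below the real ~0.5 SNP/kb, which mainly reduces
  sites per window.
- **Meiosis.** Haldane model: Poisson crossover count per chromosome per
  gamete, uniform breakpoints, no interference. The default map length is
  0.4 Morgans per 10 Mb chromosome (4 cM/Mb), matching the watermelon
  genome's map density, so linkage decay across the 1 Mb fitting window
  behaves as in the real data. The true local recombination landscape of
  the mapped region is unknown; the uniform rate is an explicit
  simplification.
- **Phenotype and bulks.** Sterile iff homozygous for the sterile-parent
  allele at the causal locus (full penetrance). Bulks are disjoint random
  draws of 30 plants per phenotype class from an F2 of 200; if a class
  falls short (possible at small population sizes under the 1/4 sterile
  rate), additional plants are simulated in batches of n/4 until both
  bulks are attainable — the resampling rule mirrors growing more plants.
- **Sequencing.** Per site and pool, total depth ~ Poisson(34); each read
  carries the sterile-parent allele with probability f(1-e) + (1-f)e, where
  f is the bulk's true pooled frequency and e = 0.01 the per-read flip
  probability. This pool-seq approximation ignores read length, mapping
  bias, GC effects and duplicate reads; depths are independent across
  sites.
- **Output.** A VCF 4.2 with samples parent_sterile, parent_fertile,
  bulk_sterile, bulk_fertile (GT + AD), and a truth TSV (causal locus,
  per-site true frequencies) read only by tests.

Equal seeds give byte-identical output. What passing simulation tests does
*not* show: robustness to mis-phenotyping, segregation distortion,
structural variation, mapping artefacts, or non-uniform recombination —
none of which the generator emulates.

## Problem sizes and numerical choices

The stochastic checks run 50 simulated experiments at the default
conditions (200 F2 plants, 30+30 bulks, 2000 SNPs, 34x, 1% error) — about
half a minute — and evaluate (a) the fitted delta at the causal locus
against the relaxed 0.56 cutoff, (b) containment of the causal locus in the
top-peak region, and (c) top-peak chromosome agreement between the delta
and ED scans. The residual failure mode for (a) is real: a fertile bulk
whose sampled AA:Aa composition drifts above 1:2 lowers the causal delta to
~0.52 in a few percent of experiments, exactly as it would in the field.

Percentiles use numpy's linear-interpolation convention; the sample SD uses
the n-1 denominator; thresholds are strict inequalities; NaN marks missing
values everywhere and is never compared ordered. Degenerate inputs (empty
tracks, zero-depth pools, identical parents, zero-SNP layouts) raise typed
errors rather than propagating silently.

## Known limitations

Indels are out of scope (the design maps with SNPs). The ED scan supports
only biallelic sites (rule 1 removes others upstream). Promoter/UTR/splice
effects are not predicted; variants outside CDS are simply non-coding.
Published genome-scale counts (e.g. total SNP numbers or megabase region
sizes of the original experiment) are properties of the full 63 Gbp
dataset and are not reproduction targets at desk scale.
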