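# Methods

## The measurement model

At a phased heterozygous SNP covered by `n` allele-informative reads, the
reference-allele count is modeled as Binomial(`n`, `m`), where `m` is the
expected reference fraction for that site. Under unbiased alignment and
balanced expression `m` would be 0.5; in practice residual, genotype-specific
alignment effects shift it slightly, so `m` is estimated empirically as the
median observed reference fraction of all testable SNPs sharing the site's
*ordered genotype* — the (reference base, alternate base) pair, 12 possible
values — within one library. A site is classified ASE only when both an
effect-size and a significance criterion hold:

- |observed fraction − `m`| > 0.15, and
- two-sided exact binomial p ≤ 0.05 for the reference count against `m`.

The conjunction is deliberate: at high depth, tiny deviations are
statistically significant but biologically negligible; at low depth, large
deviations arise from sampling alone. Sites need ≥ 10 unique, de-duplicated
reads (total depth, third alleles included) to be testable at all.

**Two-sided convention.** The binomial p-value uses the minimum-likelihood
method: the sum of Binomial(n, p) point probabilities over every outcome no
more probable than the observed count. This is the common default in
scientific software (it matches `scipy.stats.binomtest`) and is well defined
for asymmetric expectations; a tail-doubling alternative is available via
`method="double"` for sensitivity analysis. Our implementation enumerates
the pmf directly and is cross-checked against independent enumeration and
against scipy in the test suite.

**Reference fraction denominator.** The observed fraction is
ref/(ref+alt); bases matching neither allele (sequencing errors, rare third
alleles) are tallied separately but count toward the testability depth.
Both choices are configurable.

## Diploid alignment selection

Haplotype references are built by substituting phased SNP alleles into the
universal reference — heterozygous alleles to their haplotype, homozygous
alternate alleles to both. Indels are excluded, so all three references are
coordinate-identical and alignments are directly comparable. Haplotype A is
labeled "maternal" and B "paternal" purely as labels; true parental origin
is unknown.

Selection per read pair follows three ordered rules: (1) a fully mapped
pair beats any candidate with unmapped mates; (2) among equally mapped
candidates the smallest NM sum wins; (3) ties resolve to universal, then
maternal before paternal (the final tiebreak is this package's
determinism choice — the source rules specify only the universal tie).
Within one origin, a multi-mapped read contributes its smallest-NM
placement and is flagged for removal downstream. Post-merge filtering
removes PCR duplicates (identical contig, unclipped start, strand and mate
unclipped start; highest MAPQ retained), multi-mapped reads (secondary
records or NH > 1), MAPQ < 9, and mitochondrial alignments. The MAPQ used
is the chosen origin's record. Duplicate marking is re-implemented here with
the standard coordinate criterion rather than delegated to an external
tool.

## WGS heterozygosity heuristics

Imputed genotypes are verified against WGS pileups built from reads with
aligned length ≥ 34 (CIGAR M total), ≤ 4 MD-tag mismatches, SM tag > 10 and
non-duplicate status. The SM tag is aligner-specific (BWA); when absent the
read fails the filter by default, configurable to ignore. The het call is
depth-stratified on ref+alt of called alleles: alt > 3 at depth ≤ 12,
alt > 4 at depth 13–30, alt ≥ 25% at depth ≥ 31. Sites with called-allele
depth below 8 (a plumbing threshold, configurable) are "untestable" rather
than failed. Indel heterozygosity uses supporting/informative ∈ [0.2, 0.7]
with *inclusive* bounds (the source rule does not specify open or closed;
inclusive is this package's documented choice), after removing calls
≥ 200 bp, in homopolymer context (a maximal single-base run ≥ 7 adjacent to
or containing the indel interval, computed on the reference) or overlapping
annotated simple repeats.

## QC filtering

Testable SNPs are annotated with: distance to the nearest un-phased
heterozygous indel, measured to the nearest edge of the reference-affected
interval (not the VCF anchor base); distance to the nearest un-phased SNP;
the count of un-phased het SNPs within ±100 bp (phased SNPs can be included
for the proximal-heterozygous diagnostic, but the removal rule counts
un-phased only by default); per-position alignability from BED/bedGraph
intervals (uncovered positions score 0); and transcript feature
(coding exonic / intronic / 3'UTR / 5'UTR / intergenic, or "multiple" when
overlapping transcripts imply more than one label — such SNPs are dropped
from feature-level analyses). Removal: indel distance ≤ 100 bp (inclusive),
≥ 4 proximal un-phased SNPs, or alignability < 1. Binned diagnostics report
per-bin ASE proportion with a two-sided exact binomial test against the
global proportion (the comparison test is this package's choice; distance
bins default to 0–10, 10–100, 100–1k, 1k–10k, >10k bp).

## Gene and isoform aggregation

QC-passing testable SNPs are grouped by annotated gene span (not
exon-restricted; exonic status is tracked separately for the
two-exonic-SNP replication criterion). Haplotype counts are summed
independently across member SNPs and tested two-sided against an expected
proportion of 0.5 — haplotype sums mix ordered genotypes, and diploid
selection removes the bias the per-genotype medians corrected for; a pooled
median alternative is configurable. Genes rank by p-value, ties broken by
absolute haplotype imbalance then gene id. Phase concordance is true when
all non-balanced member SNPs lean toward the same haplotype; exactly
balanced SNPs are neutral. Replicate analytics treat per-replicate call
sets separately and report per-replicate flags plus pooled gene results.
SNP-to-isoform assignment places each testable SNP on every transcript
whose exons contain it; transcripts without testable exonic SNPs are
dropped, and per-transcript direction tallies expose isoform-discordant
imbalance.

## Synthetic data: what it emulates and what it does not

The generator produces contigs of i.i.d. uniform bases carrying
non-overlapping gene models (fixed geometry: 400 bp exons, 300 bp introns,
one full transcript plus an exon-skipping isoform for genes with ≥ 3
exons). SNPs are planted at a configurable per-base rate (default 0.002,
80% heterozygous, emulating a dense phased callset); a configurable
fraction of het SNPs is withheld from phasing, and indels land only outside
exons so haplotype references stay coordinate-identical. Reads are 100 bp
pairs drawn per exonic het SNP (R1 covering the SNP, R2 downstream in the
same exon with jittered fragment length), from haplotype A with probability
equal to the gene's configured allelic ratio, with substitution errors
only.

Alignment is emulated, not performed: a mate is mapped in an alignment
space iff its true mismatch count there is within a bounded tolerance
(default 1), and NM/MD tags carry exact counts. This bounded tolerance is
what reproduces reference bias — a variant-carrying read near other
variation exceeds the tolerance against the universal reference but not
against its own haplotype. Consequences to keep in mind when interpreting
passing tests: there is no splicing across junctions, no soft clipping, no
indel-containing reads, no quality-score structure, no fragment-length or
GC bias, and duplicates arise only from coordinate collisions. The tests
therefore validate the decision rules and their composition, not robustness
to the full messiness of real libraries.

Direct binomial count draws (`simulate_site_counts`) bypass reads entirely
for sampling-behaviour studies, and WGS pileups are simulated as
binomial(depth, 0.5) at het sites for the verification stage.

## Numerical and scale choices

- Exact binomial p-values are memoized; a 1e-12 relative slack guards the
  minimum-likelihood outcome comparison against last-ulp pmf asymmetry.
- Empty ordered-genotype bins fall back to the library-wide median — toy
  libraries cannot populate all 12 bins.
- Reported experiment sizes (100,000 balanced sites for classifier
  operating points; ~50 clustered SNPs at ~600× for the reference-bias
  experiment; 21 genes at ~300 haplotype reads each for ratio recovery; 10
  seeded replicate pairs of 1,500 sites) were chosen to put Monte-Carlo
  error well inside 3-SE assertion bands while keeping the whole suite in
  the tens of seconds.
- Determinism: every generator draws from `numpy.random.default_rng`
  seeded from the configuration; identical configurations produce
  byte-identical fixture files and pipeline outputs.

## Known limitations

- Hemizygous and sex-chromosome sites are treated like any other contig in
  haplotype construction; the handling on real data deserves care.
- Personalized references are SNP-only; indel-aware diploid genomes (and
  the coordinate lift-over they require) are out of scope.
- No overdispersion model: biological replicates with extra-binomial
  variance would need a beta-binomial extension.
- Isoform abundance estimation is consumed, not computed; isoform-level
  conclusions here rest on exonic SNP membership and direction patterns.
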