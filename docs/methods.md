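# Methods

## Data model

A call set is a list of `SiteRecord`s (one biallelic SNV each: chromosome,
1-based position, REF/ALT base, site quality, the INFO metrics the hard
filters consume, FILTER labels, optional functional class and coding impact)
paired with a `GenotypeMatrix` of ALT-allele dosages (0/1/2 diploid, 0/1
haploid, −1 missing) and optional per-call read depths. Rows follow the site
list, columns a fixed sample order. All coordinates are VCF-style 1-based
inclusive internally; BED input/output converts at the boundary.

Every sample is treated as diploid on every nuclear chromosome, including X.
A cohort of mixed sex genotyped as diploid on X is how joint callers emit
such panels by default, and no hemizygous handling is attempted; X enters or
leaves individual statistics only through the autosome restriction described
below. Mitochondrial genotypes are haploid.

## Hard filters

Each criterion is an independent failure expression evaluated with strict
comparisons exactly as written: `DP < 10`, `QUAL < 50` (the QUAL column, not
an INFO key), `QD < 1.5`, `SB > -0.1`, and the conjunction
`MQ0 >= 4 && MQ0/(1.0*DP) > 0.1`. A site collects one label per failed
criterion; PASS means an empty set, so filtering is idempotent and labels
are additive. An absent metric simply skips that criterion (logged once per
call) rather than failing the site.

The SNV-cluster criterion marks every member of any run of ≥ `cluster_size`
(default 3) loaded SNVs that fits in an inclusive `window`-bp span (default
10), i.e. positions `p_i .. p_j` with `p_j − p_i ≤ window − 1` on one
chromosome. The window size matches the upstream tool's parameter; the
cluster size is that tool's documented default.

## Allele counts, SFS, singletons

`ac` sums dosages over called samples; `an` counts two alleles per called
sample, so missing genotypes shrink `an` and a site is a singleton iff
`ac = 1` regardless of `an` (the motivating panel is PCR-free high-coverage
data with essentially no missingness, so this is an edge-case extension, not
a calibrated choice). Frequencies are printed half-up at 4 decimals and
percentages at 1 decimal, matching the conventions of published tables.

The singleton fraction uses autosomal sites as its default denominator
because the reference spectrum it accompanies is autosome-restricted;
`autosomes_only=False` switches to all sites. Chromosomes are recognised as
autosomes when their name (after stripping `chr`/`ECA` prefixes) is numeric.

Reference-private candidates require `ac = an` with a full call (`an = 2N`):
a site fixed ALT in the panel most plausibly marks an allele unique to the
reference individual.

## Collapsed-duplication scan

Candidates are all-heterozygous MAF = 0.5 sites, with MAF = 0.5 read
exactly (`2·ac = an`, no missing calls); balanced homozygotes
(e.g. dosages 2,2,0,0) are MAF = 0.5 but *not* all-heterozygous, and the
scan clusters only the all-heterozygous subset. Clustering is greedy
single-linkage with gap ≤ 10 kb, retaining clusters of ≥ 5 sites; smaller
runs are tallied as sub-threshold candidates, mirroring the dispersed
few-hundred-bp all-het runs such panels contain. The depth verdict compares
the mean per-call depth inside the interval against the median over sites
within 50 kb flanks (median, because flanks can contain other artifact
runs); ratio ≥ 1.6 ⇒ `duplication`. The 1.6 threshold sits between the 1×
background and the 2× collapsed-copy expectation with headroom for the
dilution caused by genuine 1× segregating sites inside the interval (at an
8× planted site-rate multiplier the expected region mean is ≈ 1.9× flank).
With no flank sites the chromosome-wide median substitutes and the call is
downgraded to `ambiguous` with `flank_fallback` set. Flagged sites are never
removed from the call set.

## Mitochondrial founder-line verification

Haplotypes are haploid allele vectors over the mito variant positions;
diploid-coded records are accepted only if every call is homozygous, and a
heterozygous call is an error naming sample and site. Each founder group's
reference is its per-site majority consensus (ties → REF, flagged), chosen
over a medoid because one erroneous member then shifts the reference at no
site rather than wholesale. Verdicts by Hamming distance to the own-group
consensus: 0 `consistent`, 1..`max_private` `mutation_drift`,
larger `lineage_discrepancy`.

`max_private` defaults to 5. Private mutations accumulate as roughly
Poisson(λ ≈ 0.3) per sample over ~30 generations, so natural drift
distances of 3 occur in roughly a third of 100-sample cohorts while
distances ≥ 6 essentially never do (P ≈ 10⁻⁶ per sample); founder lineages
differ at tens of positions. Any threshold well inside that gap behaves
identically on true errors; 5 keeps the natural-drift tail on the correct
side. The parameter is exposed on the CLI for cohorts with different
mutation loads.

## Substitution classes, spacing, density

Substitution classes are strand-symmetric: an ordered REF>ALT pair and its
reverse complement collapse, giving six classes; the four-way rollup keeps
A:T and G:C transversions separate, merges both transition classes, and
merges A>C/T>G with C>A/G>T. Mean spacing is `round(total bp / n SNVs)`
half-up.

Functional-class density divides the class's site count by the **whole
chromosome length** (× 1000, i.e. sites per kb). This makes the reported
magnitudes comparable to the published per-chromosome tables, where exon
densities are two orders below intergenic ones — a signature of whole-length
scaling; the per-feature-bp alternative is emitted as an extra column when
the annotation is supplied. Precedence for sites under several features:
exon > 5′-UTR > 3′-UTR > intron > upstream > downstream, else intergenic.
Coding impact classes (synonymous, non-synonymous, start/stop gained/lost)
are consumed from annotation input, never recomputed from codons.

## Synthetic data generator

The generator emulates the genotype-level structure of a cohort call set;
its defaults are the study conditions of the motivating panel: 101 samples
(58 male / 43 female, the published birth-year cohort distribution), one SNV
per 198 bp, transitions:transversions 2:1, ~37× coverage (tests and the
acceptance script use 20× where they exercise the depth-based scan), and a
mitochondrial genome of 16,660 bp with 335 variant sites. The desk-scale
default genome is 18 Mb over three autosomes plus X, with one
chromosome-start duplication region (250 kb at an 8-fold site rate) standing
in for a pericentromeric collapsed repeat; the methods are linear in genome
size, so nothing but runtime changes at full scale.

Per segregating site an ALT count `k` is drawn from normalized spectrum
weights (neutral `1/i` by default; `singleton_boost` rescales the `k = 1`
class) and **exactly** `k` ALT alleles are placed on the 2N haplotypes by
uniform choice without replacement. The realized SFS therefore equals the
drawn multiset with no binomial noise, which is what makes the exactness
tests meaningful. The published spectrum is known here only through its
singleton bin and the MAF-0.5 artifact blip, so the neutral default is a
stand-in shape, not an estimate. Reference-private sites are all-ALT
genotypes apportioned across chromosomes by largest remainder; duplication
artifacts are all-heterozygous sites at rate `snv_rate × multiplier` inside
the planted intervals with depth Poisson(2 × coverage) against
Poisson(coverage) elsewhere — the simplest model with the observed
"approximately twice" signature.

QUAL/INFO metrics are drawn in benign ranges, then each numeric filter
criterion is independently forced to fail on a `fail_fraction` (default 2%)
of *segregating* sites; planted reference-private and duplication sites keep
benign metrics so recovery properties act on the full planted truth.
Cluster failures arise naturally from the dense duplication regions.

Mitochondrial founder haplotypes are Bernoulli(0.35) vectors kept pairwise
≥ n_sites/10 apart; each sample inherits its founder's haplotype plus
Poisson(0.3) private flips, and an `error_rate` fraction of samples (3%
default) receive a different founder's haplotype under their recorded label
— the injected pedigree errors the verification stage must find.

One master seed is split into named substreams
(`SeedSequence(seed, spawn_key=(crc32(label),))`, one per chromosome plus
`meta` and `mito`), so outputs are byte-reproducible and each chromosome's
stream does not depend on the others. The ledger records every site's class
and drawn ALT count, singleton carriers, planted intervals, lineage
assignments, private-mutation positions, and injected errors.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: linkage disequilibrium and recombination
structure, indels and multi-allelic sites, alignment-level artifacts other
than the collapsed-duplication genotype signature, genotype missingness,
base-composition and mutation-rate heterogeneity along the genome, and
realistic QUAL/INFO correlation structure (metrics are drawn independently
per site).

## Numerical conventions and degenerate inputs

Rounding of reported frequencies/percentages is decimal half-up, never
binary bankers' rounding. Written float fields carry two decimals, and
reading restores the shortest decimal that round-trips single precision, so
write → read is exactly lossless. Ties in the mito consensus go to REF and
are flagged. Empty inputs yield empty tables rather than errors; a cluster
scan on one site, a depth test without FORMAT DP, a chromosome with more
requested sites than positions, and mito site counts beyond the genome
length all raise with specific messages. Reports are byte-deterministic
given identical inputs and configuration (sorted JSON keys, no timestamps).

## Problem sizes

The test suite and acceptance script run the 101-sample panel at ~1e5
nuclear sites and 335 mito sites, the scale at which the published
worked-example ratios and all recovery properties are checked; smaller
12-sample panels cover I/O round-trips and end-to-end determinism.
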