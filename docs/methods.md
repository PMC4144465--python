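# Methods

## The error model

The package treats a Mendelian inheritance error (MIE) as evidence of a
genotyping error: with a human per-generation point-mutation rate around
10⁻⁸ per base, a multi-sample call set in which thousands of sites
violate Mendelian transmission is exhibiting caller error, not biology.
The unit of detection is the (nuclear family, child) pair at one
biallelic autosomal site, checked single-locus:

* **Both parents genotyped.** Genotypes are alt-allele dosages
  {0, 1, 2}. A parent with dosage 0 contributes only reference gametes,
  dosage 2 only alternate gametes, dosage 1 either. The child is
  consistent iff its dosage equals some sum of one gamete per parent.
* **One parent genotyped (duo).** The only single-locus impossibility is
  opposite homozygotes (parent 0 with child 2 or vice versa) — a
  heterozygous parent can produce any child, and the missing parent can
  contribute anything. Duo checking is on by default (it strictly
  increases sensitivity and has zero false positives under the model)
  and can be disabled for trio-only semantics.
* **Child missing, or both parents missing.** Unchecked.

These rules are equivalent to exhaustive gamete enumeration, and the
test suite asserts that equivalence over all 4×4×4 genotype/missing
combinations, along with parent symmetry and the property that masking
any genotype can never create an error.

Each inconsistent child contributes one error, so a variant's count can
exceed the number of families when several children conflict (observed
per-variant counts in large call sets run well past the family count).
An optional per-family cap mimics stricter tools that count at most one
error per family per site. Sex chromosomes are out of scope; the rules
are autosomal.

Half-missing diploid calls ("0/.") are treated as fully missing rather
than as half-evidence: fabricating a transmission constraint from a
partial call risks false errors, and such calls are rare.

An externally supplied MIE count (VCF INFO, default key `MIE`) — as
produced by haplotype- and recombination-aware extended-pedigree
callers — is carried as a second detection source for every downstream
statistic but never recomputed: that class of algorithm is a different
method with different power, and conflating the two columns would make
the comparison between them meaningless.

## Filter cascade

Stages run in a fixed order with counts logged after each: (1) the
caller's FILTER column gate (a record passes only with `PASS` or `.`;
named failures such as a negative-score `SVM` flag or an `INDEL5`
proximity flag drop it); (2) multi-allelic exclusion; (3) an optional
strict threshold on the INFO quality score. The FILTER-column score
flag and the INFO-score threshold are deliberately modeled as separate
mechanisms: the former encodes the caller's own fixed rule, the latter
is the user-swept cutoff. Under an active threshold, records with no
score are dropped — unknown quality fails a quality gate — with a
config flag to retain them instead.

Summary ratios (mean MIE/variant) and percents are computed as exact
integer quotients and rounded half-up at the precision being displayed
(two decimals by default), because published QC tables round half-up
and a banker's-rounding `round()` would disagree at ties.

Threshold sweeps subset the per-variant MIE counts computed once on the
unfiltered set rather than recomputing errors per threshold; since the
single-locus verdict at a site does not depend on which other sites
survive, the two procedures are equivalent, and subsetting keeps the
sweep O(thresholds × variants).

## Spatial statistics

Bins contain a fixed number of consecutive variants (1000 by default)
rather than a fixed basepair width, so bin MIE sums share a common
denominator of checking opportunities and are directly comparable; the
genomic span of each bin is reported alongside. Conservation (bin sums
total the per-variant total) is asserted by tests.

The Wald-Wolfowitz runs test dichotomizes the bin sums around their
median (values exactly at the center are dropped — the common
convention), counts maximal same-sign runs R, and uses the normal
approximation

    E[R] = 1 + 2n₁n₂/n,   Var[R] = 2n₁n₂(2n₁n₂ − n)/(n²(n−1)),  n = n₁+n₂

without continuity correction, two-sided. The exact null distribution
of R (closed-form combinatorial) is implemented as a verification mode;
the suite checks it against brute-force enumeration of all
C(n₁+n₂, n₁) arrangements and confirms the normal approximation tracks
the exact tail (p ≤ 0.2) within 0.1 on length-12 series. Degenerate
series (all values on one side, or n₁ = n₂ = 1 where the null has no
spread) return a no-test result with an explanatory status rather than
NaN arithmetic. Calibration: on i.i.d. series of length 100 the
measured type-I error at α = 0.05 is within 3 binomial SEs of nominal
over 2,500 replicates.

**Peak calling.** Bins with MIE sum above mean + k·SD are merged with
adjacent qualifying bins and numbered along the chromosome. The
threshold uses the population SD of the bin sums (ddof = 0). The
default k = 3 was chosen on the generator's standard scenario
(100 bins, 3 planted elevated regions): because the elevated bins are
themselves part of the series, they inflate the SD, and k = 4 places
the threshold at or above the peak height whenever peaks occupy a few
percent of bins — on a series of ~100 bins it structurally cannot call
the planted peaks, while k = 3 recovers all three with no false bins
on every seed tested. On much longer series (thousands of bins, peaks
a fraction of a percent) larger k is reasonable; the parameter is
exposed as `--peak-sd`.

## Repeat enrichment

A variant at 1-based position p overlaps a 0-based half-open interval
[s, e) iff s ≤ p−1 < e; the conversion happens only inside the overlap
query, so both the VCF and the BED keep their native conventions
everywhere else. Membership is point-in-interval on POS regardless of
repeat class (the analyzed variants are SNVs; indel span overlap is not
modeled). Chromosome labels are normalized across the "chr" prefix with
a warning.

The 2×2 association test defaults to Pearson chi-square without
continuity correction — at QC sample sizes (10⁵–10⁶ variants) the
correction is irrelevant and the uncorrected statistic is the common
large-sample default — switching automatically to Fisher's exact test
with a warning when any expected cell is below 5. Both tests are always
available; the odds ratio is (a·d)/(b·c). Coverage computations merge
overlapping intervals first so double-annotated bases count once;
class composition merges within class, pools unlabeled intervals under
"other", and reports percents of summed per-class bases.

## Synthetic data generator

The generator emulates the statistical regime of a family-based WGS
call set on one chromosome. Founders draw genotypes from Hardy-Weinberg
proportions at per-variant alt frequencies ~ Beta(0.8, 2) (skewed
toward rare alternates, as site-frequency spectra are); each child
receives one uniformly chosen allele per parent. Genotyping errors flip
a called dosage to a uniformly chosen different dosage — the simplest
mechanism with no directional assumption — with per-genotype
probability:

| context            | default rate | rationale |
|--------------------|--------------|-----------|
| background         | 0.001        | ~0.03–0.04 detected MIEs/variant over 30 trios, the order seen in cleaned WGS |
| repeat intervals   | 0.01         | 10× elevation; drives enrichment OR ≫ 1 |
| planted peak regions | 0.08       | produces unmistakable bin-series peaks |
| multi-allelic sites | 100× background (cap 0.5) | echoes the extreme error load of nonbinary calls |

Defaults: 30 trio families, 100,000 variants on 30 Mb (so the default
1000-variant bin spans ~300 kb and the series has 100 bins), three
planted 300 kb peak regions (≈ one bin each) that are also repeat-dense
(70% covered), ~30% genome-wide repeat coverage in five RepeatMasker
classes with realistic proportions (SINE 31.5%, LINE 29%, LTR 13.8%).
Repeat intervals are placed with regionally varying intensity
(per-block Dirichlet(1.0) weights over 20 blocks of 1.5 Mb): real repeat
density varies smoothly along chromosomes, and this is what gives bin
series their autocorrelation — without it the runs test would have
nothing to detect outside the peaks.

Per-variant SVM-like scores are Normal(1.0, 1.5) at variants carrying
at least one injected error and Normal(5.0, 1.5) at clean variants, so
a threshold sweep over 2–4 removes error-enriched variants
preferentially; scores below zero set the caller-style `SVM` FILTER
flag, and 1% of variants get an `INDEL5` flag. The external
(extended-pedigree style) INFO count flags each injected error
independently with probability 0.9 — more sensitive than single-locus
checking, as such callers are.

The truth table records, per variant, the injected error count and an
*obligate-error* indicator: whether the observed genotypes contain a
single-locus inconsistency, computed inside the generator by direct
gamete enumeration, independent of the detection engine, so
engine-versus-truth tests are not circular.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: linkage disequilibrium and recombination
(variants are independent), read-level error mechanisms (errors are
genotype flips, not misalignments), population structure, reference
bias, sex chromosomes, and indels. The planted-peak recovery results
show the pipeline detects clustering of the magnitude planted; they do
not calibrate how sharp real error clusters are.

**Detectability.** Not every genotyping error creates a Mendelian
inconsistency — e.g. flipping a het child of two hets is undetectable —
which is why flagged MIE counts undercount true errors.
`expected_detectable_fraction` computes, for trio families, the exact
probability (by enumeration over HWE parent pairs, transmissions, flip
targets) that a single uniform flip is detectable at a given allele
frequency, averaged by Monte Carlo over the configured frequency
distribution. At fixed allele frequency 0.5 the value is 5/12 ≈ 0.417;
in the monomorphic limits it is 2/3. The suite confirms the engine's
realized detection rate on simulated single-error variants matches the
enumeration within Monte-Carlo error.

## Numerical and interface choices

* VCF INFO keys for the score and external MIE count are configurable
  (defaults `SVM`, `MIE`) since INFO layouts are caller-specific.
* All file readers accept plain or gzip input; multi-allelic records
  are parsed and flagged at read time, excluded only by the filter
  stage (exclusion is an analysis decision, not a parsing one).
* Score thresholds are strict (`>`); survivor counts across an
  ascending sweep are guaranteed weakly decreasing, but the error
  metrics are only expected to fall when the score is informative —
  that is a property of the data, asserted for the generator, not in
  general.
* Report bundles are TSV + JSON; rerunning with the same manifest and
  inputs is byte-identical (the timestamp lives only in the manifest
  copy). All simulation randomness flows from a single integer seed
  through `numpy.random.default_rng`.
* Problem sizes in the test suite: the standard scenario (100k variants,
  30 trios) is simulated once per session; structural tests use a 4k
  variant scenario. The runs-test calibration uses 2,500 i.i.d. series
  of length 100.

## Known limitations

* Single-locus checking cannot see errors that extended-pedigree,
  haplotype-aware methods catch; the pipeline reports both columns and
  their overlap without asserting either as truth.
* The chi-square/Fisher enrichment treats variants as independent;
  clustered errors violate this mildly, so the p-values are best read
  as orderings rather than exact tail probabilities.
* Peak calling with a global mean+k·SD threshold assumes a roughly
  stationary background; a strongly trending background would need a
  local baseline, which is not implemented.
* Duos contribute only opposite-homozygote errors, so call sets rich in
  single-parent families have lower detection power per genotype.
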