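# mendelqc

Family-based quality control for whole-genome sequencing call sets.

In pedigree data, a child's genotype that cannot be produced from its
parents' genotypes under Mendelian transmission — a **Mendelian
inheritance error (MIE)** — is, given how rare true de novo mutation is,
almost always a genotyping error. `mendelqc` turns that observation into
a QC pipeline for multi-sample VCFs: it detects MIEs from genotypes plus
a pedigree, characterizes where errors concentrate along the chromosome,
tests whether they are enriched in repetitive sequence, and quantifies
how much a caller-supplied quality score can reduce them. It is aimed at
statistical geneticists cleaning family-based WGS data before
association or linkage analysis.

## What it computes

**MIE detection.** An arbitrary pedigree is dissected into nuclear
families (a parent pair, or a single known parent, with their shared
children). At each biallelic site every (family, child) pair is checked
single-locus: with both parents present the child must be constructible
from one gamete per parent; with one parent the only impossible
configuration is opposite homozygotes. The per-variant count of
inconsistent (family, child) pairs is the *native* MIE count. An
externally computed count carried in VCF INFO (e.g. from a
haplotype-aware extended-pedigree caller) is read as an alternative
detection source, never recomputed.

**Filter cascade.** Records are filtered in a fixed order — caller
FILTER gate, multi-allelic exclusion, then a strict quality-score
threshold (`score > t`) — with a count and percent reduction logged at
each stage. Per-dataset summaries report n variants, total MIEs, mean
MIE/variant, the per-variant MIE range, and the count/percent of
variants with at least one MIE, at table precision with half-up
rounding. A threshold sweep produces one summary row per cutoff.

**Spatial statistics.** Per-variant MIE counts are summed in bins of
1000 consecutive variants. Randomness of the bin series is tested with
the Wald-Wolfowitz runs test: with n₁ bins above and n₂ below the
median and R observed runs,

    E[R] = 1 + 2n₁n₂/(n₁+n₂),   Var[R] = 2n₁n₂(2n₁n₂−n₁−n₂) / ((n₁+n₂)²(n₁+n₂−1))

and z = (R−E[R])/√Var[R] is referred to the standard normal (two-sided).
Bins whose MIE sum exceeds mean + k·SD (k = 3 by default) are merged
into peaks.

**Repeat enrichment.** Each variant is classified by whether its
position falls in a repeat-annotation interval (RepeatMasker-style BED);
the 2×2 table of MIE status × repeat membership is tested by Pearson
chi-square (or Fisher's exact), with odds ratio (a·d)/(b·c). Helpers
report the repeat-covered percent of called peaks and the SINE/LINE/LTR
class composition of a track.

**Synthetic data.** A seeded generator produces pedigree-structured
VCF/PED/BED files with Hardy-Weinberg founders, Mendelian transmission,
injected genotyping errors (elevated in repeats and in three planted
peak regions), an error-anticorrelated SVM-like score, and a ground
truth table — so every stage of the pipeline is testable end to end
without access-restricted data.

## Worked example

Simulate the standard scenario (30 trios, 100,000 variants on a 30 Mb
chromosome, three planted high-error regions) and run the pipeline:

```
$ mendelqc simulate --seed 7 --out-prefix demo
$ mendelqc run --vcf demo.vcf --ped demo.ped --repeats demo.repeats.bed --out qc
```

`qc/runs_test.json` shows the bin series is far from random — 27 runs
where 48 were expected (z = −4.36, p = 1.3×10⁻⁵), i.e. errors cluster:

```
{"n_runs": 27, "n_above": 47, "n_below": 47, "expected_runs": 48.0,
 "z_score": -4.355, "p_value": 1.33e-05, "status": "ok"}
```

`qc/peaks.tsv` locates the three clusters (all three planted regions,
nothing else), each far above the mean+3·SD threshold of 1456.5 MIEs
per 1000-variant bin, and 54–80% repeat-covered:

```
peak  bin_start  bin_end  start_pos  end_pos   total_mie  pct_repeat
1     24         24       7717513    8097801   2376       80.22
2     46         46       14838465   15197312  2459       53.86
3     69         69       22302353   22670749  2581       77.36
```

`qc/qc_summary.tsv` shows why multi-allelic sites are excluded: the 134
nonbinary variants average 8.44 MIEs each (100% carry at least one)
against 0.34 for biallelic sites:

```
label               n_variants  n_mie  mie_per_variant  pct_variants_with_mie
PASS_external       93512       33223  0.36             16.57
nonbinary_external  134         1131   8.44             100.0
binary_external     93378       32092  0.34             16.45
binary_native       93378       17769  0.19             11.37
```

MIE-bearing variants sit overwhelmingly in repeats
(`qc/enrichment_test.json`: χ² = 18517, OR = 14.9, p < 10⁻³⁰⁰), and the
score sweep (`qc/svm_sweep.tsv`) shows the error rate falling more than
seven-fold across thresholds 2 → 4 while only 28% of variants are lost:

```
label     n_variants  n_mie  mie_per_variant  pct_variants_with_mie
SVM >2    80810       5912   0.07             4.45
SVM >2.5  76723       3774   0.05             2.98
SVM >3    71831       2155   0.03             1.85
SVM >3.5  65755       1129   0.02             1.07
SVM >4    57967       548    0.01             0.59
```

The same stages are available individually (`mendelqc mendel`,
`filter`, `spatial`, `enrich`) and as library functions.

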