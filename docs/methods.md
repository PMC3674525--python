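# Methods

## The problem

Case and control samples in genome-wide association studies are often
genotyped in separate batches.  Systematic calling differences between
batches — a cluster called homozygous in one batch and heterozygous in the
other — create genotype errors that are *correlated with phenotype* yet
invisible to standard single-SNP quality control: allele frequencies shift
only slightly, missing rates stay low, and Hardy–Weinberg equilibrium is
barely disturbed.  Such errors manufacture spurious rare two-locus genotype
(and haplotype) combinations concentrated in one phenotype group, which
inflate multi-SNP analyses downstream.

## The two-locus statistic

For phenotype vector *y* (0/1 case–control or continuous) and minor-allele
dosage columns *x*ᵢ, *x*ⱼ of two adjacent SNPs, three nested ordinary
least-squares models are fitted on the pair's complete cases:

* null: y = µ + e
* single: y = µ + xᵢαᵢ + e
* pair: y = µ + xᵢαᵢ + xⱼαⱼ + e

With normal residuals and the ML variance estimate, each log-likelihood-ratio
is a closed form of the residual sums of squares,
LR = n·ln(RSS_reduced / RSS_full).  The QC statistic is the difference

  LR\*\*\* = LR(pair vs null) − LR(single vs null),

which is asymptotically χ²₁ when the two SNPs are uncorrelated and there is
no artifact.  Genuine additive association at both SNPs contributes to both
terms and largely cancels; a batch artifact that creates a rare two-locus
combination in one group inflates only the pair term.  The genome-wide scan
slides over adjacent pairs (never across chromosome boundaries); a SNP
without a neighbour in the scan direction is emitted unpaired rather than
dropped.

Numerical conventions: all three fits are restricted to individuals
non-missing at *both* SNPs, which guarantees LR\*\*\* ≥ 0 by nesting;
constant or collinear genotype columns are dropped by the rank-revealing
solver (relative tolerance 1e-10), so a duplicated SNP gives LR\*\*\* = 0
exactly and p = 1; a perfect fit (RSS = 0) maps to an infinite LR rather
than an error.

`lr_adjusted` exposes `adjust_for` to select which single-locus LR is
subtracted.  The scan reports the focal SNP's own LR subtracted (the
definition above).  The power harness instead scores a suspect SNP by the
record in which it is the *added* locus — LR(i, j) − LR(j) with j the
presumed-clean neighbour — because the suspect's own single-locus LR
absorbs most of the artifact signal, leaving little power to the
difference, and subtracting a contaminated single-locus fit also disturbs
the null calibration.  Both forms are χ²₁ under the null.

## Comparator tests

* **ssa** — the single-locus LR above, χ²₁.
* **hap** — two-SNP haplotype omnibus test.  Haplotype frequencies are
  estimated by an expectation–maximization algorithm in which only double
  heterozygotes are phase-ambiguous; the iteration updates the expected
  cis/trans split until the largest frequency change is below 1e-8 (cap
  1,000 iterations).  Phase is then resolved with the *pooled* frequencies
  and the fractional case/control haplotype counts are compared with a
  Pearson χ² on the 2 × H table, df = H − 1 (haplotypes with pooled
  frequency below 1e-6 are excluded from the table and the df).  A
  group-wise-EM likelihood-ratio variant was rejected as grossly
  anti-conservative: with phase estimated separately per group the two
  groups can settle in different phase modes, inflating the statistic
  under the null.
* **ldc** — LD contrast.  The genotypic (dosage) Pearson correlation r is
  computed per group, Fisher-z transformed, and the squared standardized
  difference tested against χ²₁ with SE = √(1/(n₁−3) + 1/(n₂−3)).  This is
  a deliberate simplification of the full composite-LD variance treatment;
  its power runs a little below the more elaborate estimator but its null
  calibration is exact enough for the comparison (permutation type-I error
  ≈ 0.05).

## Synthetic data

Replicates come from a neutral constant-size coalescent with recombination
(msprime, binary mutation model), emulating the study conditions: a 2-Mb
region with θ = ρ = 4·Ne·rate·L = 800 (Ne = 10,000, both per-bp rates
1e-8), 10,000 diploid individuals formed by pairing consecutive haplotypes.
Higher-LD settings reduce θ = ρ to 560, 320 or 80.  From each replicate 109
SNPs with panel MAF > 0.05 are selected *at random inside a centred window*
whose span is (109 − 1) × 0.01 Mb, so the average marker interval is
~0.01 Mb; the window grows geometrically (×1.2) when it holds too few
qualifying sites, and a replicate without 109 qualifying sites anywhere is
rejected and redrawn under an incremented seed.  Random-in-window selection
(rather than an even grid) matters: the variability of adjacent gaps is
what yields the intended mean adjacent-pair haplotype r² of ≈0.20 at
θ = ρ = 800 rising to ≈0.33 at θ = ρ = 80 (the acceptance suite recomputes
the full progression); an even grid under-shoots those LD levels by about
a third.  1,000 cases and 1,000 controls are then drawn
uniformly without replacement — no causal variants, so any association
signal is artifact by construction.  Selection MAF is computed on the full
panel (selection precedes sampling).  The average MAF of selected SNPs is
≈ 0.2.

What the generator does *not* emulate: genotype-calling intensity clusters,
plate/batch layout, missingness processes, demographic structure, or causal
disease loci.  Passing the power study therefore shows the statistic
detects the simulated corruption patterns at realistic LD and allele
frequencies — not that it detects every real-world artifact class.

## Error models

Corruption targets every 10th SNP (10 of 109).  A fraction of one phenotype
group (10%, the group chosen by fair coin per SNP) or of both groups in
opposite directions (5% each) is selected uniformly; only selected
individuals whose genotype matches the rule's source state are altered:

| model | rule | expected rate at MAF 0.2 |
|---|---|---|
| 1 | het → hom major, 10% of one group | ≈ 1.6% |
| 2 | hom major → het, 10% of one group | ≈ 3.2% |
| 3 | het → hom minor, 10% of one group | ≈ 1.6% |
| 4 | hom minor → het, 10% of one group | ≈ 0.2% |
| 5 | het → hom major in 5% of one group, hom major → het in 5% of the other | ≈ 2.4% |
| 6 | het → hom minor in 5% of one group, hom minor → het in 5% of the other | ≈ 0.9% |

The realized rate is fraction × P(source genotype) / 2 of all analyzed
genotypes, e.g. 0.10 × 0.64 / 2 ≈ 3% for model 2 — selecting individuals
first (rather than 10% of rule-eligible genotypes) is what reproduces these
rates.

## Evaluation

Type-I error is the rejection fraction of error-free test SNPs (each
10th SNP and its neighbour; ~20 per replicate) at the *nominal* χ² 0.05
threshold.  Power is the fraction of corrupted SNPs whose statistic exceeds
the *empirical* 95th percentile (type-7 quantile) of the matching
error-free arm's statistics, which puts all four methods on an equal
footing.  Standard study sizes here: 100 replicates per arm — 2,000 null
tests and 1,000 power tests per LD setting — giving binomial SEs of ≈0.005
on a 0.05 rate and ≈0.014 on a 0.74 rate.

Diagnostics for real-data-style scans: the genomic-control inflation
factor λ = median(χ²₁ statistics)/0.4549; QQ-plot deviation counting
(expected −log₁₀p at rank k of m is −log₁₀(k/(m+1)); points whose observed
−log₁₀p exceeds expectation by more than 0.2 define a horizontal cut at the
smallest such observed value, and everything on or above it is counted);
the exact Hardy–Weinberg test (full enumeration over heterozygote counts
with fixed allele margins); QC filtering in the order individual
missingness → MAF → SNP missingness → HWE; and a two-sided Fisher exact
test for case/control differential missingness.

## Known limitations and numerical notes

* High-LD deflation of LR\*\*\* is driven by pairs in *complete*
  association (the statistic is exactly 0 for duplicated columns).  Pairs
  at very high but imperfect LD — a handful of recombinant carriers —
  actually inflate the small-sample statistic above its χ²₁ reference, so
  the net high-LD effect over coalescent replicates is a mild deflation,
  not a monotone one in r².
* The hap and ldc formulations are reconstructions of the behaviour of the
  2010-era tools they stand in for (PLINK's haplotype omnibus, the
  composite-LD contrast), not bit-compatible reimplementations; as built
  here the haplotype omnibus runs somewhat more powerful and the LD
  contrast somewhat less powerful, so their power comparisons carry a
  small formulation allowance.
* The linear model treats a binary phenotype with normal-errors least
  squares; this is intentional (it is what makes the scan fast) and the
  statistic's null behaviour is verified by simulation, but p-values for
  heavily unbalanced designs or tiny samples should not be over-read.
* λ agreement between forward and reverse scan orientations is limited by
  Monte-Carlo error of the two medians (≈ 3.3/√m each); the near-exact
  agreement seen on genome-wide data needs m in the hundreds of thousands,
  so desk-scale checks use an MC-error-based band.
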