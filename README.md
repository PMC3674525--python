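# lmqc

**Two-locus linear-model quality control for GWAS genotypes.**

`lmqc` detects SNPs whose genotypes carry batch-effect calling errors —
systematic miscalls that differ between the batches in which cases and
controls were genotyped.  Such errors routinely pass standard single-SNP QC
(call rate, MAF, Hardy–Weinberg) because they barely move marginal allele
frequencies; what they do create is spurious rare two-locus genotype
combinations concentrated in one phenotype group.  The package targets
analysts running genotype QC on case–control GWAS data, and methodologists
who want to benchmark QC statistics on simulated batch artifacts.

## The statistic

For adjacent SNPs *i*, *j* with minor-allele dosage columns x<sub>i</sub>,
x<sub>j</sub> and phenotype y, three nested least-squares models are fitted
on the pair's complete cases (null: y = µ + e; single:
y = µ + x<sub>i</sub>α<sub>i</sub> + e; pair:
y = µ + x<sub>i</sub>α<sub>i</sub> + x<sub>j</sub>α<sub>j</sub> + e).
With normal residuals each likelihood ratio is a closed form of the
residual sums of squares, LR = n·ln(RSS₀/RSS₁), and the QC statistic is

    LR*** = LR(pair) − LR(single)   ~  χ²(1)  under the null,

which cancels genuine additive association but not haplotype-level
artifacts.  A sliding-window scan emits LR\*\*\* for every adjacent pair
genome-wide, plus the genomic-control inflation factor λ and a count of
QQ-plot points deviating by more than 0.2 on the −log₁₀p scale.

Also included: the comparator tests used in the power study (single-SNP
association `ssa`, EM-haplotype omnibus `hap`, LD-contrast `ldc`), a
coalescent simulator of case–control panels (msprime backend), the six
batch-effect corruption models, and the type-I-error / power evaluation
harness.  See `docs/methods.md` for the science.

## Worked example

Simulate one replicate under error model 2 (hom-major miscalled as het in a
random 10% of one group at every 10th SNP), then scan it:

```sh
$ lmqc simulate --theta 800 --rho 800 --sites 109 --n 10000 \
      --cases 1000 --controls 1000 --error-model 2 --seed 42 --out rep42
wrote rep42.ped / rep42.map (2000 individuals, 109 SNPs)

$ lmqc scan --ped rep42.ped --map rep42.map --out rep42.scan.tsv
qc.individuals_removed_missing  0
qc.snps_removed_maf     0
qc.snps_removed_missing 0
qc.snps_removed_hwe     0
qc.snps_kept    109
qc.empty_result False
lambda  1.44793
qq_deviating_points     40
```

Every corrupted SNP sails through the standard per-SNP filters (nothing is
removed), but the two-locus scan is grossly inflated: λ = 1.45 against the
λ ≈ 1 of an error-free replicate, with 40 QQ points deviating beyond 0.2 —
the batch artifact is visible genome-wide even though no single SNP looks
suspicious on its own.  The per-SNP table (`rep42.scan.tsv`) carries
`chrom, snp_id, pos, partner_id, n_complete, lr_single, p_single, lr_pair,
lr_adj, p_adj`; sorting it by `lr_adj` puts corrupted SNPs or their scan
partners at the top.

The same machinery is available as a library.  On an *error-free*
replicate the top of the table is unremarkable — adjusted statistics on
the χ²₁ scale with tiny single-SNP LRs:

```python
from lmqc import SimulationConfig, simulate_replicate, scan, scan_table

rep = simulate_replicate(SimulationConfig(seed=42))
table = scan_table(rep.genotypes, scan(rep.genotypes, rep.phenotype))
print(table.nlargest(3, "lr_adj")[["snp_id", "lr_single", "lr_adj"]])
#    snp_id  lr_single    lr_adj
# 10  snp11   0.002662  8.224844
# 49  snp50   0.083156  6.851432
# 42  snp43   1.188395  4.713601
```

`lmqc evaluate --config study.yaml --out study.tsv` runs a full
type-I/power study from a flat key-value config.

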