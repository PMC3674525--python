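"""Type-I error / power studies and data-quality diagnostics.

The study harness simulates case-control replicates, optionally corrupts
every 10th SNP under one of the batch-effect error models, scores the
designated test SNPs with the four methods (ssa, lmq, hap, ldc) and
summarises rejection rates.  Power uses empirical 5% null thresholds
from matching error-free simulations so the four methods are compared on
an equal footing; type-I error uses the nominal chi-square threshold.

Also here: the genomic-control inflation factor, QQ-plot deviation
counting, the exact Hardy-Weinberg test, standard SNP/individual QC
filters and the differential-missingness (case vs control) test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .comparators import hap_association, ldc_test, ssa_test
from .core import MISSING, GenotypeMatrix, lr_adjusted
from .errors import ErrorModelSpec, corrupt_replicate, realized_error_rate
from .simulate import SimReplicate, SimulationConfig, simulate_replicate

METHODS = ("ssa", "lmq", "hap", "ldc")

CHI2_1_MEDIAN = float(stats.chi2.median(1))  # 0.454936...


@dataclass
class PowerStudyResult:
    method: str
    ld_setting: float           # the theta = rho value
    error_model: int            # 0 = none
    n_tests: int
    rate: float
    threshold_used: float
    threshold_kind: str         # nominal_chisq | empirical_null


@dataclass(frozen=True)
class QcThresholds:
    maf_min: float = 0.01
    snp_missing_max: float = 0.05
    hwe_p_min: float = 0.0001
    individual_missing_max: float = 0.01

    def __post_init__(self) -> None:
        for v in (self.maf_min, self.snp_missing_max,
                  self.hwe_p_min, self.individual_missing_max):
            if not (0 < v < 1):
                raise ValueError("QC thresholds must lie in (0, 1)")


# ---------------------------------------------------------------------------
# study harness
# ---------------------------------------------------------------------------

def _score_snp(rep: SimReplicate, i: int, methods) -> dict[str, tuple[float, float]]:
    """statistic and p-value of each method for test SNP i (paired with i+1)."""
    g = rep.genotypes
    j = i + 1 if i + 1 < g.n_snps else i - 1
    y = rep.phenotype
    gi, gj = g.column(i), g.column(j)
    out: dict[str, tuple[float, float]] = {}
    if "ssa" in methods:
        r = ssa_test(y, gi)
        out["ssa"] = (r.statistic, r.p_value)
    if "lmq" in methods:
        # score the record in which the test SNP is the locus *added* to
        # its (presumed clean) neighbour: LR(i,j) - LR(j).  A corrupted
        # SNP's own single-locus LR would absorb the artifact signal.
        rec = lr_adjusted(y, gi, gj, snp_index=i, partner_index=j,
                          adjust_for="j")
        out["lmq"] = (rec.lr_adj, rec.p_adj)
    if "hap" in methods:
        r = hap_association(y, gi, gj)
        out["hap"] = (r.statistic, r.p_value)
    if "ldc" in methods:
        cases = y.values == 1
        ctrls = y.values == 0
        r = ldc_test(gi[cases], gj[cases], gi[ctrls], gj[ctrls])
        out["ldc"] = (r.statistic, r.p_value)
    return out


@dataclass
class StudyData:
    """Raw per-test statistics and per-replicate summaries from a study arm."""
    config: SimulationConfig
    error_model: int
    statistics: dict[str, np.ndarray]
    p_values: dict[str, np.ndarray]
    mean_r2_adjacent: float          # panel haplotype r^2, averaged over replicates
    mean_maf: float
    error_rates: np.ndarray          # per corrupted SNP; empty for null arms

    @property
    def n_tests(self) -> int:
        return next(iter(self.statistics.values())).size


def run_study(
    config: SimulationConfig,
    n_replicates: int,
    methods=METHODS,
    error_spec: ErrorModelSpec | None = None,
    base_seed: int = 0,
) -> StudyData:
    """Simulate ``n_replicates`` and score the designated test SNPs.

    Error-free arms score every 10th SNP *and* its adjacent neighbour
    (20 test SNPs per 109-SNP replicate); corrupted arms score the 10
    corrupted SNPs, each paired with its neighbour.
    """
    stride = (error_spec.error_snp_stride if error_spec is not None else 10)
    stats_acc: dict[str, list[float]] = {m: [] for m in methods}
    p_acc: dict[str, list[float]] = {m: [] for m in methods}
    r2, mafs, err_rates = [], [], []
    for k in range(n_replicates):
        cfg = replace(config, seed=base_seed + 1009 * k + 1)
        rep = simulate_replicate(cfg)
        r2.append(float(rep.panel_r2_adjacent.mean()))
        mafs.append(float(rep.panel_maf.mean()))
        error_idx = np.arange(stride - 1, rep.genotypes.n_snps, stride)
        if error_spec is not None:
            rng = np.random.default_rng(
                np.random.SeedSequence([base_seed + k, error_spec.model_id, 0xe7]))
            corrupted = corrupt_replicate(rep, error_spec, rng)
            err_rates.extend(
                realized_error_rate(rep, corrupted)[corrupted.truth_error_snps])
            test_snps = corrupted.truth_error_snps
            rep = corrupted
        else:
            neighbours = np.clip(error_idx + 1, 0, rep.genotypes.n_snps - 1)
            test_snps = np.unique(np.concatenate([error_idx, neighbours]))
        for i in test_snps:
            scored = _score_snp(rep, int(i), methods)
            for m, (s, p) in scored.items():
                stats_acc[m].append(s)
                p_acc[m].append(p)
    return StudyData(
        config=config,
        error_model=error_spec.model_id if error_spec is not None else 0,
        statistics={m: np.asarray(v) for m, v in stats_acc.items()},
        p_values={m: np.asarray(v) for m, v in p_acc.items()},
        mean_r2_adjacent=float(np.mean(r2)),
        mean_maf=float(np.mean(mafs)),
        error_rates=np.asarray(err_rates),
    )


def empirical_threshold(null_statistics, alpha: float) -> float:
    """Upper-alpha empirical quantile (type-7 interpolation) of null statistics."""
    x = np.asarray(null_statistics, dtype=float)
    if x.size < 1.0 / alpha:
        raise ValueError(f"need at least {int(np.ceil(1 / alpha))} null statistics")
    return float(np.quantile(x, 1.0 - alpha))


def type_i_error(null_data: StudyData, method: str, alpha: float = 0.05) -> PowerStudyResult:
    """Rejection rate of error-free test SNPs at the nominal chi-square level.

    Works on p-values so that methods whose df varies (hap) are handled
    uniformly; for a fixed df this is identical to thresholding the
    statistic at the chi-square critical value.
    """
    p = null_data.p_values[method]
    p = p[np.isfinite(p)]
    return PowerStudyResult(
        method=method,
        ld_setting=null_data.config.theta,
        error_model=0,
        n_tests=p.size,
        rate=float(np.mean(p < alpha)),
        threshold_used=float(stats.chi2.isf(alpha, 1)),
        threshold_kind="nominal_chisq",
    )


def power_study(power_data: StudyData, null_data: StudyData, method: str,
                alpha: float = 0.05) -> PowerStudyResult:
    """Fraction of corrupted SNPs exceeding the empirical null threshold."""
    if power_data.config.theta != null_data.config.theta or \
            power_data.config.rho != null_data.config.rho:
        raise ValueError("null thresholds come from a different LD setting")
    thr = empirical_threshold(null_data.statistics[method], alpha)
    s = power_data.statistics[method]
    s = s[np.isfinite(s)]
    return PowerStudyResult(
        method=method,
        ld_setting=power_data.config.theta,
        error_model=power_data.error_model,
        n_tests=s.size,
        rate=float(np.mean(s > thr)),
        threshold_used=thr,
        threshold_kind="empirical_null",
    )


def replication_study(
    seed: int = 1,
    ld_settings=(800.0, 80.0),
    n_null: int = 100,
    n_power: int = 100,
    error_model: int = 2,
    methods=METHODS,
    config: SimulationConfig | None = None,
) -> dict[float, dict[str, StudyData]]:
    """Run the headline type-I / power study arms at the given LD settings.

    For each theta = rho setting, simulates ``n_null`` error-free
    replicates (type-I error, empirical thresholds, adjacent-pair r^2)
    and ``n_power`` replicates corrupted under ``error_model``.  All
    randomness derives from ``seed``.  Returns
    ``{theta: {"null": StudyData, "power": StudyData}}``.
    """
    base = config if config is not None else SimulationConfig()
    arm_seed = np.random.default_rng(seed)
    out: dict[float, dict[str, StudyData]] = {}
    for theta in ld_settings:
        cfg = replace(base, theta=float(theta), rho=float(theta))
        null = run_study(cfg, n_null, methods,
                         base_seed=int(arm_seed.integers(2**27)))
        power = run_study(cfg, n_power, methods,
                          error_spec=ErrorModelSpec(model_id=error_model),
                          base_seed=int(arm_seed.integers(2**27)))
        out[float(theta)] = {"null": null, "power": power}
    return out


def mean_adjacent_r2(config: SimulationConfig, n_replicates: int,
                     base_seed: int = 0) -> float:
    """Panel haplotype r^2 between adjacent selected SNPs, replicate-averaged."""
    vals = []
    for k in range(n_replicates):
        rep = simulate_replicate(replace(config, seed=base_seed + 1009 * k + 1))
        vals.append(float(rep.panel_r2_adjacent.mean()))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# genomic-control diagnostics
# ---------------------------------------------------------------------------

def inflation_factor(statistics) -> float:
    """Genomic-control lambda: median chi-square(1) statistic / 0.4549."""
    x = np.asarray(statistics, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no statistics supplied")
    return float(np.median(x) / CHI2_1_MEDIAN)


def qq_deviation_count(p_values, delta: float = 0.2) -> int:
    """Count QQ-plot points sitting above the excess-deviation line.

    Sorting p ascending, the expected -log10 p at rank k of m is
    -log10(k / (m + 1)).  Points whose observed -log10 p exceeds the
    expected one by more than ``delta`` define a horizontal line at the
    smallest such observed value; the count is the number of points on
    or above that line.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        return 0
    obs = -np.log10(np.sort(p))                  # rank 1 = smallest p first
    m = p.size
    exp = -np.log10(np.arange(1, m + 1) / (m + 1.0))
    exceed = (obs - exp) > delta
    if not exceed.any():
        return 0
    line = obs[exceed].min()
    return int(np.sum(obs >= line))


def qq_table(p_values):
    """Two-column (expected, observed) -log10 p table for QQ plotting."""
    import pandas as pd

    p = np.sort(np.asarray(p_values, dtype=float))
    m = p.size
    return pd.DataFrame({
        "expected_neglog10p": -np.log10(np.arange(1, m + 1) / (m + 1.0)),
        "observed_neglog10p": -np.log10(p),
    })


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def hwe_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact Hardy-Weinberg test p-value on genotype counts.

    Enumerates all heterozygote counts compatible with the observed
    allele margin and sums the conditional probabilities not exceeding
    the observed one.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        raise ValueError("empty genotype table")
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    rare = min(n_minor, n_major)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(n_het = h | margins), computed with log-gammas
    from scipy.special import gammaln

    hom_r = (rare - hets) // 2
    hom_c = (2 * n - rare - hets) // 2
    logp = (hets * np.log(2.0)
            + gammaln(n + 1) - gammaln(hets + 1) - gammaln(hom_r + 1)
            - gammaln(hom_c + 1)
            + gammaln(n_minor + 1) + gammaln(n_major + 1) - gammaln(2 * n + 1))
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[hets == n_het]
    if obs.size == 0:
        raise ValueError("heterozygote count incompatible with margins")
    return float(min(prob[prob <= obs[0] * (1 + 1e-12)].sum(), 1.0))


def qc_filter(genotypes: GenotypeMatrix, thresholds: QcThresholds = QcThresholds()):
    """Standard QC: individual missingness, then SNP MAF / missingness / HWE.

    Returns (filtered GenotypeMatrix, report dict).  An all-filtered
    result is returned empty and flagged in the report, not raised.
    """
    report: dict[str, int | bool] = {}
    ind_miss = genotypes.missing_rate_per_individual()
    keep_ind = ind_miss <= thresholds.individual_missing_max
    report["individuals_removed_missing"] = int((~keep_ind).sum())
    g = genotypes.subset(individuals=np.where(keep_ind)[0])

    maf = g.maf()
    keep = maf >= thresholds.maf_min
    report["snps_removed_maf"] = int((~keep).sum())

    snp_miss = g.missing_rate_per_snp()
    drop_miss = (snp_miss > thresholds.snp_missing_max) & keep
    report["snps_removed_missing"] = int(drop_miss.sum())
    keep &= ~drop_miss

    hwe_drop = np.zeros(g.n_snps, dtype=bool)
    for j in np.where(keep)[0]:
        col = g.column(j)
        counts = [int((col == c).sum()) for c in (0, 1, 2)]
        if sum(counts) == 0:
            continue
        if hwe_test(*counts) < thresholds.hwe_p_min:
            hwe_drop[j] = True
    report["snps_removed_hwe"] = int(hwe_drop.sum())
    keep &= ~hwe_drop

    report["snps_kept"] = int(keep.sum())
    report["empty_result"] = bool(keep.sum() == 0)
    return g.subset(snps=np.where(keep)[0]), report


def missingness_test(missing_cases: int, called_cases: int,
                     missing_controls: int, called_controls: int) -> float:
    """Two-sided Fisher exact test for differential missingness."""
    if missing_cases + called_cases == 0 or missing_controls + called_controls == 0:
        raise ValueError("a phenotype group has no genotyping attempts")
    table = [[missing_cases, called_cases], [missing_controls, called_controls]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
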