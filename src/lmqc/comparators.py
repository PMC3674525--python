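"""Reference tests used alongside the two-locus QC statistic.

Three comparators:

* ``ssa`` — single-SNP association, the one-locus linear-model LR.
* ``hap`` — two-SNP haplotype omnibus association with EM-estimated
  haplotype frequencies (group-wise vs pooled likelihood ratio).
* ``ldc`` — LD contrast: Fisher-z test of the difference in genotypic
  correlation between adjacent SNPs in cases vs controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (
    MISSING,
    DegenerateInputError,
    PhenotypeVector,
    chisq_sf,
    lr_single,
)

# haplotype order: (minor_i minor_j, minor_i major_j, major_i minor_j, major_i major_j)
_HAP_LABELS = ("mm", "mM", "Mm", "MM")

EM_TOL = 1e-8
EM_MAX_ITER = 1000
#: haplotypes with pooled frequency below this are excluded from df counting
HAP_FREQ_FLOOR = 1e-6


@dataclass
class HaplotypeFrequencies:
    freqs: np.ndarray  # 4 frequencies in _HAP_LABELS order
    log_likelihood: float
    n_iterations: int
    converged: bool


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str
    flagged: bool = False  # True when the test was undefined on this input


def ssa_test(y: PhenotypeVector, g_i: np.ndarray, subset=None) -> TestResult:
    """Single-SNP association via the one-locus linear-model LR."""
    stat = lr_single(y, g_i, subset)
    return TestResult(stat, 1, chisq_sf(stat, 1), "ssa")


# ---------------------------------------------------------------------------
# EM haplotype frequency estimation for a SNP pair
# ---------------------------------------------------------------------------

def _pair_counts(g_i: np.ndarray, g_j: np.ndarray, subset=None) -> np.ndarray:
    """3x3 table of joint dosage counts over complete cases."""
    gi = np.asarray(g_i)
    gj = np.asarray(g_j)
    mask = (gi != MISSING) & (gj != MISSING)
    if subset is not None:
        mask &= np.asarray(subset, dtype=bool)
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (gi[mask], gj[mask]), 1)
    return counts


def _loglik(counts: np.ndarray, p: np.ndarray) -> float:
    """Observed-data log-likelihood of the 3x3 dosage table.

    Genotype-pair probabilities assume random union of haplotypes
    (Hardy-Weinberg at the haplotype level).  p is in _HAP_LABELS order:
    p[0]=mm, p[1]=mM, p[2]=Mm, p[3]=MM where the first letter is the
    allele at SNP i (m=minor) and the second at SNP j.
    """
    mm, mM, Mm, MM = p
    prob = np.array([
        [MM * MM, 2 * MM * Mm, Mm * Mm],
        [2 * MM * mM, 2 * (mm * MM + mM * Mm), 2 * Mm * mm],
        [mM * mM, 2 * mM * mm, mm * mm],
    ])
    with np.errstate(divide="ignore"):
        lp = np.where(counts > 0, np.log(np.maximum(prob, 1e-300)), 0.0)
    return float(np.sum(counts * lp))


def em_haplotype_freqs(g_i, g_j, subset=None) -> HaplotypeFrequencies:
    """ML haplotype frequencies for a SNP pair by EM over phase.

    Only double heterozygotes are phase-ambiguous: they carry either
    {mm, MM} or {mM, Mm}.  All other genotype pairs resolve to a fixed
    pair of haplotypes, so EM reduces to iterating the expected split of
    the double-het class.
    """
    counts = _pair_counts(g_i, g_j, subset)
    n = counts.sum()
    if n < 2:
        raise DegenerateInputError("need >= 2 complete-case individuals")

    # fixed haplotype contributions from unambiguous genotype classes;
    # rows indexed by dosage at i, cols by dosage at j
    fixed = np.zeros(4)
    for a in range(3):
        for b in range(3):
            if (a, b) == (1, 1):
                continue
            c = counts[a, b]
            if c == 0:
                continue
            for h in _resolve_unambiguous(a, b):
                fixed[h] += c

    dh = counts[1, 1]  # double heterozygotes, 2 haplotypes each
    p = np.full(4, 0.25)
    it = 0
    converged = False
    for it in range(1, EM_MAX_ITER + 1):
        # E-step: expected phase of double hets
        w_cis = p[0] * p[3]          # mm / MM phase
        w_trans = p[1] * p[2]        # mM / Mm phase
        tot = w_cis + w_trans
        f_cis = 0.5 if tot <= 0 else w_cis / tot
        expect = fixed.copy()
        expect[0] += dh * f_cis
        expect[3] += dh * f_cis
        expect[1] += dh * (1 - f_cis)
        expect[2] += dh * (1 - f_cis)
        # M-step
        p_new = expect / (2.0 * n)
        delta = np.max(np.abs(p_new - p))
        p = p_new
        if delta < EM_TOL:
            converged = True
            break
    ll = _loglik(counts, p)
    return HaplotypeFrequencies(p, ll, it, converged)


def _resolve_unambiguous(a: int, b: int) -> list[int]:
    """Haplotype indices carried by an unambiguous dosage pair (a, b)."""
    # gametes at SNP i: a copies of minor among 2; likewise at j.
    # When either dosage is 0 or 2 the assignment of minor copies to
    # gametes is forced (up to exchangeable ordering).
    gametes_i = [1] * a + [0] * (2 - a)          # 1 = minor allele at i
    gametes_j = [1] * b + [0] * (2 - b)
    if a == 1 and b == 1:
        raise ValueError("double het is ambiguous")
    # if a == 1, the het SNP's minor copy pairs with a determined j gamete
    # because both j gametes are identical (b in {0,2}), and vice versa.
    idx = {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}
    return [idx[(gi, gj)] for gi, gj in zip(gametes_i, gametes_j)]


def _fractional_hap_counts(g_i, g_j, subset, pooled_freqs: np.ndarray) -> np.ndarray:
    """Expected haplotype counts in a subset, phase resolved with pooled freqs."""
    counts = _pair_counts(g_i, g_j, subset)
    hap = np.zeros(4)
    for a in range(3):
        for b in range(3):
            if (a, b) == (1, 1):
                continue
            for h in _resolve_unambiguous(a, b):
                hap[h] += counts[a, b]
    dh = counts[1, 1]
    w_cis = pooled_freqs[0] * pooled_freqs[3]
    w_trans = pooled_freqs[1] * pooled_freqs[2]
    f_cis = 0.5 if w_cis + w_trans <= 0 else w_cis / (w_cis + w_trans)
    hap[[0, 3]] += dh * f_cis
    hap[[1, 2]] += dh * (1 - f_cis)
    return hap


def hap_association(y: PhenotypeVector, g_i, g_j, subset=None) -> TestResult:
    """Omnibus haplotype association test for a SNP pair.

    Haplotype frequencies are estimated by EM on the pooled sample;
    double-het phase is then resolved with the pooled frequencies and
    the resulting fractional case/control haplotype counts compared in a
    Pearson chi-square with (number of observed haplotypes - 1) df —
    the classic pooled-phasing omnibus test.  Requires a binary
    phenotype.
    """
    if not y.is_binary:
        raise DegenerateInputError("haplotype test needs a binary phenotype")
    yv = y.values
    base = np.isfinite(yv)
    if subset is not None:
        base &= np.asarray(subset, dtype=bool)
    pooled = em_haplotype_freqs(g_i, g_j, subset=base)
    rows = []
    for label, grp_mask in (("case", yv == 1), ("control", yv == 0)):
        m = base & grp_mask
        cc = (np.asarray(g_i) != MISSING) & (np.asarray(g_j) != MISSING) & m
        if cc.sum() < 2:
            raise DegenerateInputError(f"{label} group has < 2 usable individuals")
        rows.append(_fractional_hap_counts(g_i, g_j, m, pooled.freqs))
    table = np.asarray(rows)
    keep = table.sum(axis=0) > 2.0 * HAP_FREQ_FLOOR * table.sum()
    table = table[:, keep]
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    stat = float(np.sum((table - expected) ** 2 / np.maximum(expected, 1e-300)))
    df = max(table.shape[1] - 1, 1)
    return TestResult(stat, df, chisq_sf(stat, df), "hap")


# ---------------------------------------------------------------------------
# LD contrast
# ---------------------------------------------------------------------------

def _genotypic_r(g_i: np.ndarray, g_j: np.ndarray) -> tuple[float, int]:
    gi = np.asarray(g_i, dtype=float)
    gj = np.asarray(g_j, dtype=float)
    mask = (np.asarray(g_i) != MISSING) & (np.asarray(g_j) != MISSING)
    gi, gj = gi[mask], gj[mask]
    n = gi.size
    if n < 5 or np.unique(gi).size < 2 or np.unique(gj).size < 2:
        return np.nan, n
    return float(np.corrcoef(gi, gj)[0, 1]), n


def ldc_test(g_i_cases, g_j_cases, g_i_controls, g_j_controls) -> TestResult:
    """LD-contrast test of case/control difference in pairwise LD.

    Genotypic (dosage) Pearson correlation per group, Fisher z-transform,
    and a 1-df chi-square on the standardized difference with asymptotic
    SE sqrt(1/(n1-3) + 1/(n2-3)).
    """
    r1, n1 = _genotypic_r(g_i_cases, g_j_cases)
    r2, n2 = _genotypic_r(g_i_controls, g_j_controls)
    if not np.isfinite(r1) or not np.isfinite(r2) or min(n1, n2) < 5:
        return TestResult(np.nan, 1, np.nan, "ldc", flagged=True)
    r1 = np.clip(r1, -1 + 1e-12, 1 - 1e-12)
    r2 = np.clip(r2, -1 + 1e-12, 1 - 1e-12)
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    stat = float(z * z)
    return TestResult(stat, 1, chisq_sf(stat, 1), "ldc")
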