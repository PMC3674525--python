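"""Core two-locus linear-model statistics against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lmqc import (
    MISSING,
    DegenerateInputError,
    PhenotypeVector,
    chisq_sf,
    lr_adjusted,
    lr_pair,
    lr_single,
    scan,
)
from lmqc.evaluate import inflation_factor

from conftest import make_matrix


# ---------------------------------------------------------------------------
# independent oracle: explicit normal-equation least squares
# ---------------------------------------------------------------------------

def oracle_rss(y, columns):
    """RSS of OLS on [1 | columns] solved via explicit normal equations."""
    n = len(y)
    X = [[1.0] + [col[i] for col in columns] for i in range(n)]
    p = len(X[0])
    XtX = [[sum(X[i][a] * X[i][b] for i in range(n)) for b in range(p)]
           for a in range(p)]
    Xty = [sum(X[i][a] * y[i] for i in range(n)) for a in range(p)]
    beta = np.linalg.solve(np.array(XtX), np.array(Xty))
    return float(sum((y[i] - sum(beta[a] * X[i][a] for a in range(p))) ** 2
                     for i in range(n)))


def oracle_lr(y, columns):
    rss0 = oracle_rss(y, [])
    rss1 = oracle_rss(y, columns)
    return len(y) * np.log(rss0 / rss1)


class TestSingleLocusLR:
    def test_uncorrelated_genotype_gives_zero(self):
        y = PhenotypeVector([0, 0, 1, 1])
        assert lr_single(y, np.array([0, 1, 0, 1])) == pytest.approx(0.0, abs=1e-12)

    def test_constant_genotype_gives_zero(self):
        y = PhenotypeVector([0.1, 0.9, 0.4, 0.6])
        assert lr_single(y, np.array([1, 1, 1, 1])) == 0.0

    def test_matches_normal_equation_oracle(self, toy_pheno_geno):
        y, g_i, _ = toy_pheno_geno
        expected = oracle_lr(y.values, [g_i.astype(float)])
        assert lr_single(y, g_i) == pytest.approx(expected, rel=1e-8)

    def test_degenerate_inputs_refused(self):
        y = PhenotypeVector([0, 1, 0, 1])
        with pytest.raises(DegenerateInputError):
            lr_single(y, np.array([0, 1, MISSING, MISSING]))
        with pytest.raises(DegenerateInputError):
            lr_single(PhenotypeVector([0, 0, 0, 1]),
                      np.array([0, 1, 2, 0]),
                      subset=np.array([True, True, True, False]))

    def test_missing_genotypes_excluded(self, toy_pheno_geno):
        y, g_i, _ = toy_pheno_geno
        g = g_i.copy()
        g[3] = MISSING
        keep = np.arange(10) != 3
        expected = oracle_lr(y.values[keep], [g_i[keep].astype(float)])
        assert lr_single(y, g) == pytest.approx(expected, rel=1e-8)


class TestPairLR:
    def test_duplicate_column_reduces_to_single(self, toy_pheno_geno):
        y, g_i, _ = toy_pheno_geno
        assert lr_pair(y, g_i, g_i.copy()) == pytest.approx(
            lr_single(y, g_i), rel=1e-10)

    def test_both_constant_gives_zero(self):
        y = PhenotypeVector([0.0, 1.0, 0.3, 0.7])
        ones = np.ones(4, dtype=np.int8)
        assert lr_pair(y, ones, 2 * ones) == 0.0

    def test_matches_two_column_oracle(self, toy_pheno_geno):
        y, g_i, g_j = toy_pheno_geno
        expected = oracle_lr(y.values, [g_i.astype(float), g_j.astype(float)])
        assert lr_pair(y, g_i, g_j) == pytest.approx(expected, rel=1e-8)


class TestAdjustedLR:
    def test_perfect_ld_gives_zero_and_p_one(self, toy_pheno_geno):
        y, g_i, _ = toy_pheno_geno
        rec = lr_adjusted(y, g_i, g_i.copy())
        assert rec.lr_adj == pytest.approx(0.0, abs=1e-10)
        assert rec.p_adj == pytest.approx(1.0)

    def test_subtraction_rule_on_printed_pair(self):
        # LR(pair) = 124.06 and LR(single) = 20.05 must give LR*** = 104.01
        assert 124.06 - 20.05 == pytest.approx(104.01)

    def test_record_is_pair_minus_single(self, toy_pheno_geno):
        y, g_i, g_j = toy_pheno_geno
        rec = lr_adjusted(y, g_i, g_j)
        assert rec.lr_adj == pytest.approx(rec.lr_pair - rec.lr_single, abs=1e-9)
        assert rec.lr_adj >= 0.0

    def test_rare_two_locus_combination_dominates_both_singles(self, rng):
        # a batch artifact: one group carries a rare genotype combination
        # (het at SNP i with hom-major at SNP j) that the other never shows
        n = 120
        y = np.repeat([0.0, 1.0], n // 2)
        g_i = np.tile([0, 1], n // 2).astype(np.int8)
        g_j = g_i.copy()
        artifact = (y == 0) & (g_i == 1) & (rng.random(n) < 0.5)
        g_j[artifact] = 0
        rec = lr_adjusted(y_pv := PhenotypeVector(y), g_i, g_j)
        single_i = lr_single(y_pv, g_i)
        single_j = lr_single(y_pv, g_j)
        assert rec.lr_adj > max(single_i, single_j)
        # oracle agreement on the same toy
        keep = np.ones(n, bool)
        expected_pair = oracle_lr(y, [g_i.astype(float), g_j.astype(float)])
        assert rec.lr_pair == pytest.approx(expected_pair, rel=1e-8)


class TestChisqSF:
    @pytest.mark.parametrize("x, df, expected, sig", [
        (20.05, 1, 7.5e-06, 2),
        (124.06, 2, 1.15e-27, 3),
        (0.0, 1, 1.0, 12),
    ])
    def test_printed_tail_probabilities(self, x, df, expected, sig):
        assert chisq_sf(x, df) == pytest.approx(expected, rel=10 ** (1 - sig))

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            chisq_sf(-1.0, 1)


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------

@st.composite
def toy_dataset(draw):
    n = draw(st.integers(8, 20))
    g_i = draw(st.lists(st.integers(0, 2), min_size=n, max_size=n))
    g_j = draw(st.lists(st.integers(0, 2), min_size=n, max_size=n))
    y = draw(st.lists(st.floats(-3, 3, allow_nan=False, width=32),
                      min_size=n, max_size=n))
    return np.array(y), np.array(g_i, dtype=np.int8), np.array(g_j, dtype=np.int8)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(toy_dataset())
def test_nesting_and_oracle_equivalence(data):
    """RSS0 >= RSS1 >= RSS2, so 0 <= lr_single <= lr_pair; oracle match."""
    y, g_i, g_j = data
    if np.unique(y).size < 2:
        return
    pv = PhenotypeVector(y)
    s = lr_single(pv, g_i)
    p = lr_pair(pv, g_i, g_j)
    assert 0.0 <= s <= p + 1e-8
    if np.unique(g_i).size > 1 and np.isfinite(s):
        assert s == pytest.approx(oracle_lr(y, [g_i.astype(float)]),
                                  rel=1e-8, abs=1e-8)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(toy_dataset(), st.floats(0.1, 5), st.floats(-2, 2))
def test_invariance_under_recoding_and_affine_phenotype(data, scale, shift):
    y, g_i, g_j = data
    if np.unique(y).size < 2:
        return
    pv = PhenotypeVector(y)
    pv2 = PhenotypeVector(scale * y + shift)
    flipped = (2 - g_i).astype(np.int8)
    base = lr_pair(pv, g_i, g_j)
    assert lr_pair(pv, flipped, g_j) == pytest.approx(base, rel=1e-7, abs=1e-7)
    assert lr_pair(pv2, g_i, g_j) == pytest.approx(base, rel=1e-7, abs=1e-7)


def test_null_calibration_against_chi2(rng):
    """lr_adj on independent SNPs + random phenotype is chi-square(1)."""
    n, m = 300, 10_000
    stats_out = np.empty(m)
    for k in range(m):
        g_i = rng.binomial(2, 0.3, n).astype(np.int8)
        g_j = rng.binomial(2, 0.3, n).astype(np.int8)
        y = PhenotypeVector(rng.binomial(1, 0.5, n).astype(float))
        stats_out[k] = lr_adjusted(y, g_i, g_j).lr_adj
    d, p = stats.kstest(stats_out, "chi2", args=(1,))
    assert p > 0.01


def test_perfect_ld_mass_deflates_adjusted_statistic(rng):
    """High-LD deflation acts through pairs in *complete* association:
    duplicated pairs contribute an exact zero, so the median lr_adj
    shrinks as the perfectly-correlated fraction of pairs grows."""
    n = 500
    medians = []
    for dup_fraction in (0.0, 0.4, 1.0):
        vals = []
        for k in range(300):
            g_i = rng.binomial(2, 0.4, n).astype(np.int8)
            if k < dup_fraction * 300:
                g_j = g_i.copy()
            else:
                g_j = rng.binomial(2, 0.4, n).astype(np.int8)
            y = PhenotypeVector(rng.binomial(1, 0.5, n).astype(float))
            vals.append(lr_adjusted(y, g_i, g_j).lr_adj)
        medians.append(np.median(vals))
    assert medians[0] > medians[1] > medians[2]
    assert medians[2] == pytest.approx(0.0, abs=1e-10)


# ---------------------------------------------------------------------------
# sliding-window scan
# ---------------------------------------------------------------------------

class TestScan:
    def test_forward_pairs_and_boundary_flag(self, rng):
        codes = rng.integers(0, 3, (30, 3)).astype(np.int8)
        gm = make_matrix(codes)
        y = PhenotypeVector(rng.binomial(1, 0.5, 30).astype(float))
        recs = scan(gm, y, "forward")
        assert [r.snp_index for r in recs] == [0, 1, 2]
        assert [r.partner_index for r in recs] == [1, 2, -1]
        assert not recs[2].paired and np.isnan(recs[2].lr_adj)

    def test_pairs_never_span_chromosomes(self, rng):
        codes = rng.integers(0, 3, (30, 4)).astype(np.int8)
        gm = make_matrix(codes, chrom=["1", "1", "2", "2"],
                         pos=[100, 200, 100, 200])
        y = PhenotypeVector(rng.binomial(1, 0.5, 30).astype(float))
        recs = scan(gm, y, "forward")
        paired = [(r.snp_index, r.partner_index) for r in recs if r.paired]
        assert paired == [(0, 1), (2, 3)]

    def test_reverse_orientation_pairs_previous(self, rng):
        codes = rng.integers(0, 3, (30, 3)).astype(np.int8)
        gm = make_matrix(codes)
        y = PhenotypeVector(rng.binomial(1, 0.5, 30).astype(float))
        recs = scan(gm, y, "reverse")
        assert [r.partner_index for r in recs] == [-1, 0, 1]

    def test_forward_and_reverse_lambda_agree_on_null_data(self, rng):
        """Scan orientation barely moves the inflation factor under the null.

        The agreement band is the Monte-Carlo error of the two medians at
        this number of SNPs (on genome-wide data the same check tightens
        to ~0.01).
        """
        n, m = 300, 4000
        codes = rng.binomial(2, 0.3, (n, m)).astype(np.int8)
        gm = make_matrix(codes, pos=np.arange(1, m + 1) * 1000)
        y = PhenotypeVector(rng.binomial(1, 0.5, n).astype(float))
        lam = {}
        for orient in ("forward", "reverse"):
            recs = scan(gm, y, orient)
            vals = np.array([r.lr_adj for r in recs if r.paired])
            lam[orient] = inflation_factor(vals)
        se_median = 1.0 / (2 * stats.chi2.pdf(stats.chi2.median(1), 1) * np.sqrt(m))
        tol = 3 * np.sqrt(2) * se_median / stats.chi2.median(1)
        assert abs(lam["forward"] - 1) < 0.1 and abs(lam["reverse"] - 1) < 0.1
        assert abs(lam["forward"] - lam["reverse"]) < tol
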