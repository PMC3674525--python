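"""Two-locus linear-model QC statistics.

The statistic of interest contrasts the fit of a two-SNP additive linear
model against the nested single-SNP model for a pair of adjacent SNPs:

    LR(i)    = n * ln(RSS0 / RSS1)      single-SNP vs intercept-only
    LR(i,j)  = n * ln(RSS0 / RSS2)      two-SNP vs intercept-only
    LR***(i) = LR(i,j) - LR(i)

where the RSS come from ordinary least squares on the same complete-case
subset of n individuals.  Under the null of no genotyping artifact and
uncorrelated SNPs, LR*** is asymptotically chi-square with one degree of
freedom; batch-effect miscalls that manufacture rare two-locus genotype
combinations in one phenotype group inflate it far beyond either
single-SNP statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

MISSING: int = -1

#: relative tolerance at which a design column counts as collinear
COLLINEAR_RTOL: float = 1e-10


class DegenerateInputError(ValueError):
    """Raised when a model fit is requested on unusable data."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeVector:
    """Per-individual trait values: 0/1 for case-control or continuous."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise DegenerateInputError("phenotype needs >= 2 individuals")
        finite = self.values[np.isfinite(self.values)]
        if np.unique(finite).size < 2:
            raise DegenerateInputError("phenotype is constant; nothing to fit")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def is_binary(self) -> bool:
        u = np.unique(self.values[np.isfinite(self.values)])
        return u.size == 2 and set(u) <= {0.0, 1.0}


@dataclass
class GenotypeMatrix:
    """N x M minor-allele dosage codes with SNP metadata.

    ``codes`` entries are 0 (hom major), 1 (het), 2 (hom minor) or
    :data:`MISSING`.  SNPs are kept sorted by chromosome and position.
    """

    codes: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    alleles: np.ndarray  # M x 2, (minor, major)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=object)
        ok = np.isin(self.codes, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.unique(self.codes[~ok])
            raise ValueError(f"invalid genotype codes {bad!r}")
        for c in np.unique(self.chrom):
            p = self.pos_bp[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not sorted on chromosome {c}")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.codes[:, j]

    def missing_rate_per_snp(self) -> np.ndarray:
        return (self.codes == MISSING).mean(axis=0)

    def missing_rate_per_individual(self) -> np.ndarray:
        return (self.codes == MISSING).mean(axis=1)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP among non-missing calls.

        The stored coding is minor-allele dosage, so this is simply the
        mean dosage / 2 — except that after subsetting individuals the
        'minor' allele may exceed 0.5; the folded frequency is returned.
        """
        called = self.codes != MISSING
        with np.errstate(invalid="ignore"):
            f = np.where(
                called.sum(axis=0) > 0,
                np.where(self.codes == MISSING, 0, self.codes).sum(axis=0)
                / (2.0 * np.maximum(called.sum(axis=0), 1)),
                np.nan,
            )
        return np.minimum(f, 1.0 - f)

    def subset(self, individuals=None, snps=None) -> "GenotypeMatrix":
        ind = slice(None) if individuals is None else np.asarray(individuals)
        snp = slice(None) if snps is None else np.asarray(snps)
        return GenotypeMatrix(
            codes=self.codes[ind][:, snp],
            snp_ids=self.snp_ids[snp],
            chrom=self.chrom[snp],
            pos_bp=self.pos_bp[snp],
            alleles=self.alleles[snp],
        )


@dataclass
class LinearFit:
    rss: float
    n_used: int
    df_model: int
    dropped_collinear: bool = False


@dataclass
class PairScanRecord:
    snp_index: int
    partner_index: int  # -1 when unpaired (single-SNP chromosome end)
    lr_single: float
    lr_pair: float
    lr_adj: float
    p_single: float
    p_adj: float
    n_complete: int

    @property
    def paired(self) -> bool:
        return self.partner_index >= 0


# ---------------------------------------------------------------------------
# least-squares likelihood ratios
# ---------------------------------------------------------------------------

def _fit_rss(y: np.ndarray, columns: Sequence[np.ndarray]) -> LinearFit:
    """OLS residual sum of squares for [1, columns...] via lstsq.

    Rank-deficient designs are fine: lstsq minimises over the column
    space, so a collinear column simply contributes no model df.
    """
    n = y.size
    X = np.column_stack([np.ones(n), *columns]) if columns else np.ones((n, 1))
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=COLLINEAR_RTOL)
    fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))
    return LinearFit(
        rss=max(rss, 0.0),
        n_used=n,
        df_model=max(rank - 1, 0),
        dropped_collinear=rank < X.shape[1],
    )


def _lr_from_rss(n: int, rss_reduced: float, rss_full: float) -> float:
    """n * ln(RSS_reduced / RSS_full), guarded for perfect fits."""
    if rss_full <= 0.0:
        return np.inf if rss_reduced > 0.0 else 0.0
    lr = n * np.log(rss_reduced / rss_full)
    return float(max(lr, 0.0))  # clip sub-tolerance negatives


def _usable(y: np.ndarray, gs: Sequence[np.ndarray], subset=None) -> np.ndarray:
    mask = np.isfinite(y)
    for g in gs:
        mask &= np.asarray(g) != MISSING
    if subset is not None:
        mask &= np.asarray(subset, dtype=bool)
    return mask


def _check_degenerate(y: np.ndarray, mask: np.ndarray) -> None:
    if mask.sum() < 3:
        raise DegenerateInputError("fewer than 3 usable individuals")
    if np.unique(y[mask]).size < 2:
        raise DegenerateInputError("phenotype constant on subset")


def lr_single(y: PhenotypeVector, g: np.ndarray, subset=None) -> float:
    """Log-likelihood ratio of the one-SNP additive model vs intercept-only.

    Returns 0 when the genotype column is constant on the subset (no
    model degree of freedom).
    """
    yv = y.values
    mask = _usable(yv, [g], subset)
    _check_degenerate(yv, mask)
    ys, gs = yv[mask], np.asarray(g, dtype=float)[mask]
    if np.unique(gs).size < 2:
        return 0.0
    null = _fit_rss(ys, [])
    one = _fit_rss(ys, [gs])
    return _lr_from_rss(ys.size, null.rss, one.rss)


def lr_pair(y: PhenotypeVector, g_i: np.ndarray, g_j: np.ndarray, subset=None) -> float:
    """LR of the two-SNP additive model vs intercept-only.

    Fitted on individuals non-missing at both SNPs; a genotype column
    collinear with the rest of the design is dropped by the rank-aware
    solver, so duplicated SNPs reduce to the single-SNP statistic.
    """
    yv = y.values
    mask = _usable(yv, [g_i, g_j], subset)
    _check_degenerate(yv, mask)
    ys = yv[mask]
    gi = np.asarray(g_i, dtype=float)[mask]
    gj = np.asarray(g_j, dtype=float)[mask]
    cols = [c for c in (gi, gj) if np.unique(c).size > 1]
    if not cols:
        return 0.0
    null = _fit_rss(ys, [])
    two = _fit_rss(ys, cols)
    return _lr_from_rss(ys.size, null.rss, two.rss)


def chisq_sf(x: float, df: int) -> float:
    """Upper-tail chi-square probability."""
    if x < 0:
        raise ValueError("chi-square statistic must be non-negative")
    if df not in (1, 2, 3):
        raise ValueError("df must be 1, 2 or 3")
    return float(stats.chi2.sf(x, df))


def lr_adjusted(
    y: PhenotypeVector,
    g_i: np.ndarray,
    g_j: np.ndarray,
    subset=None,
    snp_index: int = 0,
    partner_index: int = 1,
    adjust_for: Literal["i", "j"] = "i",
) -> PairScanRecord:
    """Adjusted two-locus statistic LR*** for SNP_i paired with SNP_j.

    All three fits (null, single, pair) are restricted to the pair's
    complete-case subset so the models are nested and LR*** >= 0.
    ``adjust_for`` selects which single-locus LR is subtracted; the
    conventional choice is the focal SNP i.
    """
    yv = y.values
    mask = _usable(yv, [g_i, g_j], subset)
    _check_degenerate(yv, mask)
    single_col = g_i if adjust_for == "i" else g_j
    single = lr_single(y, single_col, subset=mask)
    pair = lr_pair(y, g_i, g_j, subset=mask)
    adj = max(pair - single, 0.0)
    return PairScanRecord(
        snp_index=snp_index,
        partner_index=partner_index,
        lr_single=single,
        lr_pair=pair,
        lr_adj=adj,
        p_single=chisq_sf(single, 1),
        p_adj=chisq_sf(adj, 1),
        n_complete=int(mask.sum()),
    )


# ---------------------------------------------------------------------------
# sliding-window scan
# ---------------------------------------------------------------------------

def scan(
    genotypes: GenotypeMatrix,
    y: PhenotypeVector,
    orientation: Literal["forward", "reverse"] = "forward",
) -> list[PairScanRecord]:
    """Adjacent-pair scan over every SNP, one record per SNP.

    Forward pairs each SNP with its next neighbour on the same
    chromosome (pter to qter); reverse with its previous neighbour.
    Pairs never span chromosomes; a SNP without a neighbour in the scan
    direction gets an unpaired record (lr_pair/lr_adj are NaN).
    """
    if y.n != genotypes.n_individuals:
        raise ValueError("phenotype length != genotype rows")
    records: list[PairScanRecord] = []
    step = 1 if orientation == "forward" else -1
    chroms = genotypes.chrom
    for i in range(genotypes.n_snps):
        j = i + step
        if 0 <= j < genotypes.n_snps and chroms[j] == chroms[i]:
            records.append(
                lr_adjusted(y, genotypes.column(i), genotypes.column(j),
                            snp_index=i, partner_index=j)
            )
        else:
            gi = genotypes.column(i)
            mask = _usable(y.values, [gi])
            try:
                single = lr_single(y, gi, subset=mask)
                p_single = chisq_sf(single, 1)
            except DegenerateInputError:
                single, p_single = np.nan, np.nan
            records.append(PairScanRecord(
                snp_index=i, partner_index=-1,
                lr_single=single, lr_pair=np.nan, lr_adj=np.nan,
                p_single=p_single, p_adj=np.nan,
                n_complete=int(mask.sum()),
            ))
    return records


def scan_table(genotypes: GenotypeMatrix, records: Iterable[PairScanRecord]):
    """Tidy per-SNP results table (pandas DataFrame)."""
    import pandas as pd

    rows = []
    for r in records:
        i = r.snp_index
        rows.append({
            "chrom": genotypes.chrom[i],
            "snp_id": genotypes.snp_ids[i],
            "pos": int(genotypes.pos_bp[i]),
            "partner_id": genotypes.snp_ids[r.partner_index] if r.paired else ".",
            "n_complete": r.n_complete,
            "lr_single": r.lr_single,
            "p_single": r.p_single,
            "lr_pair": r.lr_pair,
            "lr_adj": r.lr_adj,
            "p_adj": r.p_adj,
        })
    return pd.DataFrame(rows)
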