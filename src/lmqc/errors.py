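"""Batch-effect genotype corruption models.

Six corruption rules emulate systematic miscalls that differ between
genotyping batches (and hence, when cases and controls were genotyped
separately, between phenotype groups).  With minor-allele dosage coding
(0 = hom major, 1 = het, 2 = hom minor):

====== ===========================================================
model  rule
====== ===========================================================
1      het -> hom major in a random 10% of one group
2      hom major -> het in a random 10% of one group
3      het -> hom minor in a random 10% of one group
4      hom minor -> het in a random 10% of one group
5      het -> hom major in 5% of one group, hom major -> het in 5%
       of the other
6      het -> hom minor in 5% of one group, hom minor -> het in 5%
       of the other
====== ===========================================================

Individuals are selected first (a fraction of the whole group); only
those whose genotype matches the rule's source state are altered, so
the realized per-SNP error rate is fraction x P(source genotype).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .simulate import SimReplicate

#: (source code, target code) of the primary rule per model
_RULES: dict[int, tuple[int, int]] = {
    1: (1, 0),
    2: (0, 1),
    3: (1, 2),
    4: (2, 1),
    5: (1, 0),   # paired with (0, 1) in the opposite group
    6: (1, 2),   # paired with (2, 1) in the opposite group
}


@dataclass(frozen=True)
class ErrorModelSpec:
    model_id: int
    fraction: float | None = None       # default 0.10 (models 1-4) / 0.05 (5-6)
    target_group: Literal["cases", "controls", "random_one", "both"] | None = None
    error_snp_stride: int = 10

    def __post_init__(self) -> None:
        if self.model_id not in _RULES:
            raise ValueError(f"unknown error model {self.model_id}")
        frac = self.fraction if self.fraction is not None else self.default_fraction
        if not (0 < frac <= 1):
            raise ValueError("fraction must be in (0, 1]")

    @property
    def two_sided(self) -> bool:
        return self.model_id in (5, 6)

    @property
    def default_fraction(self) -> float:
        return 0.05 if self.two_sided else 0.10

    @property
    def effective_fraction(self) -> float:
        return self.fraction if self.fraction is not None else self.default_fraction

    @property
    def effective_target(self) -> str:
        if self.target_group is not None:
            return self.target_group
        return "both" if self.two_sided else "random_one"


def _alter(codes: np.ndarray, snp: int, members: np.ndarray, frac: float,
           source: int, target: int, rng: np.random.Generator) -> int:
    """Select frac of `members`, flip those in the source state; return count."""
    k = int(round(frac * members.size))
    if k == 0:
        return 0
    selected = rng.choice(members, k, replace=False)
    hit = selected[codes[selected, snp] == source]
    codes[hit, snp] = target
    return hit.size


def apply_error_model(rep: SimReplicate, snp_index: int, spec: ErrorModelSpec,
                      rng: np.random.Generator) -> int:
    """Corrupt one SNP in place; returns the number of altered genotypes."""
    if rep.phenotype is None:
        raise ValueError("phenotype must be assigned before corruption")
    if not 0 <= snp_index < rep.genotypes.n_snps:
        raise ValueError("snp_index out of range")
    codes = rep.genotypes.codes
    y = rep.phenotype.values
    cases = np.where(y == 1)[0]
    controls = np.where(y == 0)[0]
    frac = spec.effective_fraction
    src, tgt = _RULES[spec.model_id]

    if spec.two_sided:
        # opposite directions in the two groups, assignment randomized per SNP
        groups = [cases, controls]
        if spec.effective_target == "both" and rng.random() < 0.5:
            groups = [controls, cases]
        n = _alter(codes, snp_index, groups[0], frac, src, tgt, rng)
        n += _alter(codes, snp_index, groups[1], frac, tgt, src, rng)
        return n

    if spec.effective_target == "cases":
        grp = cases
    elif spec.effective_target == "controls":
        grp = controls
    else:  # random_one: fair coin per error SNP
        grp = cases if rng.random() < 0.5 else controls
    return _alter(codes, snp_index, grp, frac, src, tgt, rng)


def corrupt_replicate(rep: SimReplicate, spec: ErrorModelSpec,
                      rng: np.random.Generator) -> SimReplicate:
    """Corrupt every ``stride``-th SNP of a copy of the replicate.

    Error SNPs sit at 0-based indices stride-1, 2*stride-1, ... (10 of
    109 SNPs at the default stride); their indices are recorded in
    ``truth_error_snps``.
    """
    stride = spec.error_snp_stride
    if stride > rep.genotypes.n_snps:
        raise ValueError("stride exceeds SNP count")
    out = copy.deepcopy(rep)
    targets = np.arange(stride - 1, out.genotypes.n_snps, stride)
    for snp in targets:
        apply_error_model(out, int(snp), spec, rng)
    out.truth_error_snps = targets
    return out


def realized_error_rate(original: SimReplicate, corrupted: SimReplicate) -> np.ndarray:
    """Per-SNP fraction of analyzed genotypes that differ after corruption."""
    a, b = original.genotypes.codes, corrupted.genotypes.codes
    if a.shape != b.shape:
        raise ValueError("replicate shapes differ")
    return (a != b).mean(axis=0)
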