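"""Coalescent simulation of case-control SNP panels.

Replicates are drawn from a neutral constant-size Fisher-Wright model
with recombination (Hudson's ms semantics, generated with msprime).  The
default configuration emulates the power-study conditions: a 2-Mb region
with population-scaled rates theta = rho = 4*Ne*rate*L = 800
(Ne = 10,000, rate = 1e-8 per bp per generation), 10,000 diploid
individuals, 109 selected SNPs with MAF > 0.05 at an average marker
interval of ~0.01 Mb, and 1,000 cases plus 1,000 controls sampled at
random (no causal variants: the disease model is null by construction).

Site selection: 109 sites are drawn at random among MAF-qualifying sites
inside a window centred on the region whose span is
(n_sites - 1) * target interval; the window grows geometrically if it
holds too few qualifying sites.  This reproduces the intended mean
adjacent-pair LD levels (r^2 ~ 0.20 at theta=rho=800 rising to ~0.33 at
theta=rho=80).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import msprime
import numpy as np

from .core import GenotypeMatrix, PhenotypeVector


class ReplicateRejected(RuntimeError):
    """Raised when a draw lacks enough MAF-qualifying segregating sites."""


@dataclass(frozen=True)
class SimulationConfig:
    theta: float = 800.0          # 4 * Ne * mu * region_bp
    rho: float = 800.0            # 4 * Ne * r * region_bp
    region_bp: float = 2_000_000.0
    n_sites: int = 109
    maf_min: float = 0.05
    target_interval_bp: float = 10_000.0
    n_individuals: int = 10_000   # diploid panel size
    n_cases: int = 1_000
    n_controls: int = 1_000
    ne: float = 10_000.0          # only sets the time scale; theta/rho govern LD
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_cases + self.n_controls > self.n_individuals:
            raise ValueError("cases + controls exceed panel size")
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if self.theta <= 0 or self.rho <= 0:
            raise ValueError("theta and rho must be positive")

    @property
    def mutation_rate(self) -> float:
        return self.theta / (4.0 * self.ne * self.region_bp)

    @property
    def recombination_rate(self) -> float:
        return self.rho / (4.0 * self.ne * self.region_bp)


@dataclass
class SimReplicate:
    genotypes: GenotypeMatrix          # analyzed individuals only
    phenotype: PhenotypeVector         # 1 = case, 0 = control
    positions_bp: np.ndarray
    panel_maf: np.ndarray              # MAF of selected SNPs in the full panel
    panel_r2_adjacent: np.ndarray      # haplotype r^2 between adjacent selected SNPs
    truth_error_snps: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    config: SimulationConfig | None = None


def simulate_haplotypes(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Haplotype panel (sites x 2N int8 matrix) and site positions in bp."""
    seed = int(config.seed) % (2**31 - 2) + 1
    ts = msprime.sim_ancestry(
        samples=config.n_individuals,
        ploidy=2,
        sequence_length=config.region_bp,
        recombination_rate=config.recombination_rate,
        population_size=config.ne,
        random_seed=seed,
    )
    mts = msprime.sim_mutations(
        ts, rate=config.mutation_rate, random_seed=seed + 2**19,
        model=msprime.BinaryMutationModel(),
    )
    H = mts.genotype_matrix().astype(np.int8)
    return H, mts.sites_position.copy()


def select_sites(haplotypes: np.ndarray, positions: np.ndarray,
                 config: SimulationConfig) -> SimReplicate:
    """Pick the analysis SNPs and form diploid genotypes (pre-phenotype).

    Genotype codes are minor-allele dosage, the minor allele being
    defined on the full haplotype panel; exact 50/50 sites keep the
    derived allele as minor.  Diploids pair consecutive haplotypes (ms
    convention).  Raises :class:`ReplicateRejected` when fewer than
    ``n_sites`` sites pass the MAF floor.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x5e1ec7]))
    freq = haplotypes.mean(axis=1)
    maf = np.minimum(freq, 1 - freq)
    qualifying = np.where(maf > config.maf_min)[0]
    if qualifying.size < config.n_sites:
        raise ReplicateRejected(
            f"{qualifying.size} qualifying sites < {config.n_sites}")

    half = config.target_interval_bp * (config.n_sites - 1) / 2.0
    centre = config.region_bp / 2.0
    while True:
        lo, hi = centre - half, centre + half
        in_win = qualifying[(positions[qualifying] >= lo) & (positions[qualifying] <= hi)]
        if in_win.size >= config.n_sites or half >= config.region_bp / 2.0:
            break
        half = min(half * 1.2, config.region_bp / 2.0)
    if in_win.size < config.n_sites:
        raise ReplicateRejected("window exhausted before finding enough sites")
    chosen = np.sort(rng.choice(in_win, config.n_sites, replace=False))

    H = haplotypes[chosen].astype(np.int8)           # n_sites x 2N
    # orient to minor-allele dosage on the panel
    flip = H.mean(axis=1) > 0.5
    H[flip] = 1 - H[flip]
    diplo = (H[:, 0::2] + H[:, 1::2]).astype(np.int8)  # n_sites x N

    Hf = H.astype(np.float64)
    r2 = np.array([
        np.corrcoef(Hf[k], Hf[k + 1])[0, 1] ** 2
        for k in range(config.n_sites - 1)
    ])

    pos = positions[chosen]
    # arbitrary biallelic labels: minor allele "A", major "G"
    alleles = np.array([("A", "G")] * config.n_sites, dtype=object)
    gm = GenotypeMatrix(
        codes=diplo.T,
        snp_ids=np.array([f"snp{k + 1}" for k in range(config.n_sites)], dtype=object),
        chrom=np.array(["1"] * config.n_sites, dtype=object),
        pos_bp=np.round(pos).astype(np.int64),
        alleles=alleles,
    )
    return SimReplicate(
        genotypes=gm,
        phenotype=None,  # filled by assign_case_control
        positions_bp=pos,
        panel_maf=H.mean(axis=1),
        panel_r2_adjacent=r2,
        config=config,
    )


def assign_case_control(rep: SimReplicate, config: SimulationConfig) -> SimReplicate:
    """Sample disjoint case and control sets; phenotype independent of genotype."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xca5e]))
    pick = rng.choice(config.n_individuals, config.n_cases + config.n_controls,
                      replace=False)
    y = np.concatenate([np.ones(config.n_cases), np.zeros(config.n_controls)])
    rep.genotypes = rep.genotypes.subset(individuals=pick)
    rep.phenotype = PhenotypeVector(y)
    return rep


def simulate_replicate(config: SimulationConfig, max_retries: int = 20) -> SimReplicate:
    """Full pipeline: coalescent draw, site selection, case/control sampling.

    A draw short of qualifying sites is rejected and rerun with the next
    seed; the returned replicate's config records the seed actually used.
    """
    cfg = config
    for _ in range(max_retries):
        try:
            H, pos = simulate_haplotypes(cfg)
            rep = select_sites(H, pos, cfg)
            return assign_case_control(rep, cfg)
        except ReplicateRejected:
            cfg = replace(cfg, seed=cfg.seed + 1_000_003)
    raise ReplicateRejected(f"no usable replicate after {max_retries} retries")
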