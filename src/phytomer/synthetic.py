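"""Synthetic inputs with the statistical structure the analyses assume.

Every downstream stage of the package is testable on these generators
alone.  Defaults emulate the study conditions of a replicated greenhouse
trial on an inbreeding cereal panel:

* internode profiles follow an 'inverse-S' cubic trend in scaled position
  plus compartment-specific offsets, genotype effects and residual noise;
* structured genotypes follow the Balding–Nichols model, whose Beta
  parameterisation gives a closed-form relation between the Beta shape and
  F_ST (enabling calibration tests), with near-complete homozygosity as in
  a strict selfer;
* divergent traits have specified between/within subpopulation variances;
* genome-wide p-value fields are uniform with enrichment concentrated in
  designated gene windows;
* LD-block genotypes carry a small pool of haplotypes per block (perfect
  within-block LD, independence across blocks).

A single seed per config drives one root RNG; every generator derives its
sub-streams deterministically from it, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .culm import compartment_sizes
from .types import GenotypeMatrix, InternodeProfile

__all__ = [
    "PhytomerSimConfig",
    "StructuredGenotypeConfig",
    "DivergentTraitConfig",
    "EnrichedPvalueConfig",
    "gen_phytomer_population",
    "gen_structured_genotypes",
    "gen_divergent_traits",
    "gen_enriched_pvalues",
    "gen_ld_blocks",
]

LENGTH_FLOOR_CM = 0.1  # lengths are physical; never emit a non-positive one


def _draw_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n distinct, sorted 1-based positions on [1, length] (no O(length) permutation)."""
    if n > length:
        raise ValueError("more SNPs than base pairs")
    pos = np.unique(rng.integers(0, length, size=int(n * 1.1) + 8))
    while pos.size < n:
        pos = np.unique(np.concatenate([pos, rng.integers(0, length, size=n)]))
    return np.sort(rng.choice(pos, size=n, replace=False)) + 1 if pos.size > n else pos + 1



@dataclass
class PhytomerSimConfig:
    """Parameters of the internode-profile simulator.

    The mean profile at scaled position x in [0, 1] (proximal -> distal) is
    ``base_intercept + base_slope*x + c0 + c1*x + c2*x^2 + c3*x^3`` plus the
    compartment offset; the default cubic is a smoothstep from ~3 cm
    proximal internodes to a ~28 cm peduncle, the inverse-S shape of a
    flowering culm.  Genotype effects (one draw per genotype, shared across
    replicates) and per-internode residuals are additive Gaussian, in cm.
    """

    n_genotypes: int = 200
    reps_per_genotype: int = 4
    node_number_range: tuple[int, int] = (5, 9)
    base_slope: float = 0.0
    base_intercept: float = 0.0
    cubic_coefficients: tuple[float, float, float, float] = (3.0, 0.0, 75.0, -50.0)
    compartment_shifts: tuple[float, float, float] = (1.0, -1.5, 0.5)  # distal/central/proximal
    genotypic_sd: float = 1.0
    residual_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genotypes < 1 or self.reps_per_genotype < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.node_number_range
        if not (3 <= lo <= hi <= 20):
            raise ValueError("node_number_range must lie within [3, 20]")
        if self.genotypic_sd < 0 or self.residual_sd < 0:
            raise ValueError("sd parameters must be >= 0")
        x = np.linspace(0.0, 1.0, 101)
        mean = self._trend(x)
        if np.any(mean + min(self.compartment_shifts) <= 0):
            raise ValueError("expected internode lengths must be positive over the position range")

    def _trend(self, x: np.ndarray) -> np.ndarray:
        c0, c1, c2, c3 = self.cubic_coefficients
        return (
            self.base_intercept
            + self.base_slope * x
            + c0 + c1 * x + c2 * x**2 + c3 * x**3
        )


def gen_phytomer_population(cfg: PhytomerSimConfig) -> list[InternodeProfile]:
    """Replicated internode-length profiles for a simulated panel.

    Each plant's expected internode length is the cubic trend in scaled
    position plus its compartment offset; a genotype effect (drawn once per
    genotype and reused across replicates) and an i.i.d. residual are added
    per internode, and lengths are floored at 0.1 cm.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.node_number_range
    node_numbers = rng.integers(lo, hi + 1, size=cfg.n_genotypes)
    geno_effects = rng.normal(0.0, cfg.genotypic_sd, size=cfg.n_genotypes)
    shifts_dcp = np.asarray(cfg.compartment_shifts, dtype=float)  # distal, central, proximal
    profiles: list[InternodeProfile] = []
    for g in range(cfg.n_genotypes):
        n = int(node_numbers[g])
        x = np.arange(n) / (n - 1)
        n_p, n_c, n_d = compartment_sizes(n)
        comp = np.concatenate(
            [np.full(n_p, shifts_dcp[2]), np.full(n_c, shifts_dcp[1]), np.full(n_d, shifts_dcp[0])]
        )
        mean = cfg._trend(x) + comp + geno_effects[g]
        for r in range(cfg.reps_per_genotype):
            lengths = mean + rng.normal(0.0, cfg.residual_sd, size=n)
            profiles.append(
                InternodeProfile(
                    plant_id=f"G{g:04d}_R{r}",
                    genotype_id=f"G{g:04d}",
                    lengths=np.maximum(lengths, LENGTH_FLOOR_CM),
                )
            )
    return profiles


@dataclass
class StructuredGenotypeConfig:
    """Balding–Nichols panel: subpopulations drifted to a target F_ST.

    Per SNP the ancestral frequency p is uniform on ``ancestral_freq_range``
    and each subpopulation frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) with
    F = ``target_fst`` (so Var = F p(1-p), the Balding–Nichols relation).
    ``selfing_homozygosity`` is the probability that an individual is fully
    inbred at a locus (two identical allele draws), emulating a strict
    selfer; the default 0.98 matches near-complete homozygosity.
    """

    n_subpops: int = 2
    n_per_subpop: int = 100
    n_snps: int = 5000
    target_fst: float = 0.1
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    selfing_homozygosity: float = 0.98
    chrom_length: int = 500_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_fst < 1.0):
            raise ValueError("target_fst must be in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_freq_range must lie inside (0, 1)")
        if not (0.0 <= self.selfing_homozygosity <= 1.0):
            raise ValueError("selfing_homozygosity must be in [0, 1]")
        if min(self.n_subpops, self.n_per_subpop, self.n_snps) < 1:
            raise ValueError("counts must be positive")


def gen_structured_genotypes(
    cfg: StructuredGenotypeConfig,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Structured biallelic genotypes plus subpopulation labels."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=cfg.n_snps)
    F = cfg.target_fst
    if F == 0.0:
        p_sub = np.tile(p_anc, (cfg.n_subpops, 1))
    else:
        shape = (1.0 - F) / F
        p_sub = rng.beta(p_anc * shape, (1.0 - p_anc) * shape, size=(cfg.n_subpops, cfg.n_snps))
        p_sub = np.clip(p_sub, 1e-9, 1.0 - 1e-9)  # frequencies stay in (0, 1)
    n_total = cfg.n_subpops * cfg.n_per_subpop
    dosage = np.empty((n_total, cfg.n_snps))
    labels = np.repeat([f"pop{k + 1}" for k in range(cfg.n_subpops)], cfg.n_per_subpop)
    for k in range(cfg.n_subpops):
        rows = slice(k * cfg.n_per_subpop, (k + 1) * cfg.n_per_subpop)
        p = p_sub[k]
        inbred = rng.random((cfg.n_per_subpop, cfg.n_snps)) < cfg.selfing_homozygosity
        homo = 2.0 * (rng.random((cfg.n_per_subpop, cfg.n_snps)) < p)
        outcross = (rng.random((cfg.n_per_subpop, cfg.n_snps)) < p).astype(float) + (
            rng.random((cfg.n_per_subpop, cfg.n_snps)) < p
        )
        dosage[rows] = np.where(inbred, homo, outcross)
    pos = _draw_positions(rng, cfg.n_snps, cfg.chrom_length)
    geno = GenotypeMatrix(
        accession_ids=[f"acc{k:04d}" for k in range(n_total)],
        chrom=np.full(cfg.n_snps, "1H", dtype=object),
        pos=pos,
        dosage=dosage,
        ref=np.full(cfg.n_snps, "A", dtype=object),
        alt=np.full(cfg.n_snps, "T", dtype=object),
    )
    return geno, labels


@dataclass
class DivergentTraitConfig:
    """Trait values with specified between/within subpopulation variances.

    If ``subpop_means`` is None, means are equally spaced and centred so
    that their variance (divisor k-1, matching the ANOVA between
    component) equals ``sigma2_between`` exactly; set ``draw_means`` to
    sample them N(0, sigma2_between) instead (then the realised between
    variance fluctuates around the target).
    """

    n_per_subpop: int = 100
    subpop_means: tuple[float, ...] | None = None
    sigma2_between: float = 4.0
    sigma2_within: float = 1.0
    n_subpops: int = 2
    draw_means: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2_between < 0 or self.sigma2_within < 0:
            raise ValueError("variances must be >= 0")
        if self.n_per_subpop < 1:
            raise ValueError("n_per_subpop must be positive")


def gen_divergent_traits(cfg: DivergentTraitConfig) -> tuple[np.ndarray, np.ndarray]:
    """Subpopulation-structured trait values plus labels."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.subpop_means is not None:
        means = np.asarray(cfg.subpop_means, dtype=float)
    elif cfg.draw_means:
        means = rng.normal(0.0, np.sqrt(cfg.sigma2_between), size=cfg.n_subpops)
    else:
        base = np.arange(cfg.n_subpops, dtype=float)
        base -= base.mean()
        sd = base.std(ddof=1)
        means = (
            base / sd * np.sqrt(cfg.sigma2_between)
            if cfg.sigma2_between > 0 and sd > 0
            else np.zeros(cfg.n_subpops)
        )
    k = means.size
    values = np.repeat(means, cfg.n_per_subpop) + rng.normal(
        0.0, np.sqrt(cfg.sigma2_within), size=k * cfg.n_per_subpop
    )
    labels = np.repeat([f"pop{j + 1}" for j in range(k)], cfg.n_per_subpop)
    return values, labels


@dataclass
class EnrichedPvalueConfig:
    """Genome-wide p-value field with enrichment inside gene windows.

    Background p-values are Uniform(0, 1); SNPs inside any window (0-based
    half-open intervals after flanking, on one simulated chromosome) are
    drawn as U^s with s = ``enrichment_strength`` — stochastically smaller
    for s > 1, exactly uniform at s = 1.
    """

    n_snps: int = 20_000
    gene_windows: tuple[tuple[int, int], ...] = field(default_factory=tuple)
    enrichment_strength: float = 5.0
    chrom_length: int = 500_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.enrichment_strength < 1.0:
            raise ValueError("enrichment_strength must be >= 1")
        for s, e in self.gene_windows:
            if not (0 <= s < e <= self.chrom_length):
                raise ValueError(f"window ({s}, {e}) falls off the simulated chromosome")


def gen_enriched_pvalues(cfg: EnrichedPvalueConfig):
    """GWAS-like table (snp, chrom, pos, p) with window-concentrated signal."""
    import pandas as pd

    rng = np.random.default_rng(cfg.seed)
    pos = _draw_positions(rng, cfg.n_snps, cfg.chrom_length)
    inside = np.zeros(cfg.n_snps, dtype=bool)
    for s, e in cfg.gene_windows:
        inside |= (pos > s) & (pos <= e)  # BED half-open vs 1-based positions
    p = rng.random(cfg.n_snps)
    p[inside] = p[inside] ** cfg.enrichment_strength
    return pd.DataFrame(
        {
            "snp": [f"1H_{q}" for q in pos],
            "chrom": "1H",
            "pos": pos,
            "p": p,
            "in_window": inside,
        }
    )


def gen_ld_blocks(
    n_accessions: int,
    blocks: list[tuple[int, int, int]],
    seed: int = 0,
    chrom: str = "1H",
    gap_bp: int = 1_000_000,
) -> GenotypeMatrix:
    """Fully homozygous genotypes built from per-block haplotype pools.

    ``blocks`` lists ``(span_bp, n_snps, n_haplotypes)``; within a block each
    accession carries one of the pooled haplotypes (perfect within-block LD
    up to haplotype sharing) and block assignments are independent across
    blocks.
    """
    rng = np.random.default_rng(seed)
    chroms, positions, cols = [], [], []
    start = 0
    for span, n_snps, n_hap in blocks:
        if n_hap < 2:
            raise ValueError("need >= 2 haplotypes per block")
        # haplotypes over {0, 2}: resample any monomorphic column so every
        # SNP segregates in the pool, then ensure the haplotypes are distinct
        while True:
            haps = 2.0 * (rng.random((n_hap, n_snps)) < 0.5)
            mono = haps.std(axis=0) == 0
            while mono.any():
                haps[:, mono] = 2.0 * (rng.random((n_hap, int(mono.sum()))) < 0.5)
                mono = haps.std(axis=0) == 0
            if len({tuple(h) for h in haps}) == n_hap:
                break
        assign = rng.integers(0, n_hap, size=n_accessions)
        cols.append(haps[assign])
        pos = _draw_positions(rng, n_snps, span) + start
        positions.append(pos)
        chroms.append(np.full(n_snps, chrom, dtype=object))
        start += span + gap_bp
    return GenotypeMatrix(
        accession_ids=[f"acc{k:04d}" for k in range(n_accessions)],
        chrom=np.concatenate(chroms),
        pos=np.concatenate(positions),
        dosage=np.hstack(cols),
    )
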