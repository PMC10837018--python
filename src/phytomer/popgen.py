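"""Phenotypic vs. genetic differentiation among subpopulations.

The selection scan logic: under neutrality, the between-subpopulation
share of additive trait variance (P_ST, the phenotypic stand-in for Q_ST)
should match the genome-wide allele-frequency differentiation (F_ST,
Weir–Cockerham estimator).  P_ST >> F_ST — operationally, the lower
bootstrap confidence bound of P_ST exceeding the genome-wide weighted
F_ST of the pair — indicates divergent selection.

For a strictly selfing diploid all loci are effectively homozygous, so
P_ST = sigma2_GB / (sigma2_GB + sigma2_GW) without the factor-of-2
adjustment of the within component used for outcrossers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import GenotypeMatrix

__all__ = [
    "FstResult",
    "PstResult",
    "weir_cockerham_fst",
    "compute_pst",
    "bootstrap_pst",
    "pst_fst_verdict",
    "nucleotide_diversity",
    "group_allele_frequency",
    "relative_phenotype_change",
]


@dataclass
class FstResult:
    pair: tuple[str, str]
    a: np.ndarray  # among-population variance component per SNP
    b: np.ndarray  # among individuals within populations
    c: np.ndarray  # within individuals
    per_snp: np.ndarray
    weighted: float  # ratio of sums: sum(a) / sum(a+b+c)
    used: np.ndarray  # boolean mask of usable SNPs


@dataclass
class PstResult:
    pair: tuple[str, str]
    sigma2_GB: float
    sigma2_GW: float
    pst: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    n_boot: int = 0
    n_degenerate: int = 0


def weir_cockerham_fst(
    geno: GenotypeMatrix, labels: np.ndarray, pair: tuple[str, str]
) -> FstResult:
    """Weir–Cockerham (1984) two-population diploid F_ST.

    Per SNP the variance components a (among populations), b (among
    individuals within populations) and c (within individuals) are computed
    from sample sizes, allele frequencies and observed heterozygosity; the
    genome-wide estimate is the weighted ratio of sums sum(a)/sum(a+b+c).
    SNPs monomorphic across the pooled pair, or with fewer than two
    non-missing accessions in either population, are skipped.  Per-SNP
    estimates may be negative (the estimator is unbiased, not truncated).
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need >= 2 subpopulations in labels")
    masks = [labels == g for g in pair]
    for g, m in zip(pair, masks):
        if m.sum() < 2:
            raise ValueError(f"subpopulation {g!r} has fewer than 2 accessions")
    d = geno.dosage
    r = 2  # populations in the comparison
    n_i = np.stack([np.sum(~np.isnan(d[m]), axis=0) for m in masks]).astype(float)
    with np.errstate(invalid="ignore"):
        p_i = np.stack([np.nanmean(d[m], axis=0) for m in masks]) / 2.0
        # heterozygote fraction among non-missing calls only
        h_i = np.stack(
            [np.sum(d[m] == 1.0, axis=0) / np.maximum(np.sum(~np.isnan(d[m]), axis=0), 1)
             for m in masks]
        )
    usable = np.all(n_i >= 2, axis=0)
    pooled = np.nansum(n_i * p_i, axis=0) / np.maximum(n_i.sum(axis=0), 1)
    usable &= (pooled > 0) & (pooled < 1)
    n_bar = n_i.mean(axis=0)
    nc = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
    p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
    s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (n_bar / nc) * (
            s2
            - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2.0
        per_snp = np.where(usable, a / (a + b + c), np.nan)
    if not usable.any():
        raise ValueError("all SNPs skipped: no usable sites for this pair")
    denom = (a + b + c)[usable].sum()
    return FstResult(
        pair=tuple(pair),
        a=np.where(usable, a, np.nan),
        b=np.where(usable, b, np.nan),
        c=np.where(usable, c, np.nan),
        per_snp=per_snp,
        weighted=float(a[usable].sum() / denom),
        used=usable,
    )


def _pst_point(values: np.ndarray, group_idx: list[np.ndarray]) -> tuple[float, float, float]:
    """One-way ANOVA method-of-moments variance components -> P_ST."""
    k = len(group_idx)
    groups = [values[g] for g in group_idx]
    n = np.array([len(g) for g in groups], dtype=float)
    N = n.sum()
    means = np.array([g.mean() for g in groups])
    grand = values[np.concatenate(group_idx)].mean()
    ssb = float((n * (means - grand) ** 2).sum())
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    n0 = (N - (n**2).sum() / N) / (k - 1)  # unbalanced-design coefficient
    s2_gw = msw
    s2_gb = max(0.0, (msb - msw) / n0)
    denom = s2_gb + s2_gw
    pst = s2_gb / denom if denom > 0 else np.nan
    return s2_gb, s2_gw, pst


def compute_pst(
    values: np.ndarray, labels: np.ndarray, pair: tuple[str, str]
) -> PstResult:
    """Point estimate of P_ST = sigma2_GB / (sigma2_GB + sigma2_GW).

    Variance components come from the one-way ANOVA method of moments; a
    negative between component is truncated to 0.  No factor-of-2
    adjustment of the within component (selfing diploid).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    idx = [np.flatnonzero(labels == g) for g in pair]
    for g, ix in zip(pair, idx):
        if ix.size < 2:
            raise ValueError(f"subpopulation {g!r} needs >= 2 accessions")
    s2_gb, s2_gw, pst = _pst_point(values, idx)
    return PstResult(pair=tuple(pair), sigma2_GB=s2_gb, sigma2_GW=s2_gw, pst=pst)


def bootstrap_pst(
    values: np.ndarray,
    labels: np.ndarray,
    pair: tuple[str, str],
    n_boot: int = 1000,
    seed: int | None = None,
) -> PstResult:
    """P_ST with a percentile bootstrap 95% CI.

    Accessions are resampled with replacement within each subpopulation.
    Degenerate resamples (zero total variance) are skipped and counted;
    more than 50% degenerate resamples is an error.
    """
    out = compute_pst(values, labels, pair)
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    idx = [np.flatnonzero(labels == g) for g in pair]
    rng = np.random.default_rng(seed)
    boots = []
    n_degenerate = 0
    for _ in range(n_boot):
        ridx = [ix[rng.integers(0, ix.size, size=ix.size)] for ix in idx]
        pooled = values[np.concatenate(ridx)]
        if pooled.std() == 0:
            n_degenerate += 1
            continue
        _, _, pst_b = _pst_point(values, ridx)
        boots.append(pst_b)
    if n_degenerate > n_boot / 2:
        raise ValueError(f"{n_degenerate}/{n_boot} degenerate bootstrap resamples")
    boots = np.asarray(boots)
    out.ci_lower = float(np.percentile(boots, 2.5))
    out.ci_upper = float(np.percentile(boots, 97.5))
    out.n_boot = n_boot
    out.n_degenerate = n_degenerate
    return out


def pst_fst_verdict(pst: PstResult, fst: FstResult) -> str:
    """'divergent_selection' iff the P_ST lower CI bound exceeds genome-wide F_ST."""
    if tuple(sorted(pst.pair)) != tuple(sorted(fst.pair)):
        raise ValueError(f"subpopulation pair mismatch: {pst.pair} vs {fst.pair}")
    if pst.ci_lower is None:
        raise ValueError("P_ST result has no bootstrap CI; run bootstrap_pst first")
    return "divergent_selection" if pst.ci_lower > fst.weighted else "drift_compatible"


def nucleotide_diversity(
    geno: GenotypeMatrix,
    regions: pd.DataFrame,
    labels: np.ndarray,
) -> pd.DataFrame:
    """Per-region, per-subpopulation nucleotide diversity (pi per bp).

    ``regions`` has columns chrom/start/end (0-based half-open, BED
    convention).  Per site, pi contributes [n/(n-1)] * 2 p (1-p) with n the
    non-missing allele count in the subpopulation; the sum over SNPs in the
    region is divided by the full region length in bp (invariant sites are
    assumed monomorphic and contribute zero).
    """
    if len(regions) == 0:
        raise ValueError("empty region list")
    labels = np.asarray(labels)
    rows = []
    for _, reg in regions.iterrows():
        on = (geno.chrom == reg["chrom"]) & (geno.pos > reg["start"]) & (
            geno.pos <= reg["end"]
        )
        length = int(reg["end"] - reg["start"])
        for g in pd.unique(labels):
            sub = geno.dosage[labels == g][:, on]
            n_alleles = 2.0 * np.sum(~np.isnan(sub), axis=0)
            with np.errstate(invalid="ignore"):
                p = np.nansum(sub, axis=0) / np.maximum(n_alleles, 1)
            ok = n_alleles >= 2
            per_site = np.where(
                ok, n_alleles / np.maximum(n_alleles - 1, 1) * 2.0 * p * (1.0 - p), 0.0
            )
            rows.append(
                {
                    "region": reg.get("name", f"{reg['chrom']}:{reg['start']}-{reg['end']}"),
                    "subpopulation": g,
                    "pi": float(per_site.sum()) / length,
                    "n_snps": int(on.sum()),
                    "length_bp": length,
                }
            )
    return pd.DataFrame(rows)


def group_allele_frequency(
    geno: GenotypeMatrix, labels: np.ndarray, snp_ids: list[str]
) -> pd.DataFrame:
    """Alt-allele frequency per group at the requested SNPs.

    Missing genotypes are excluded from the denominator; allele counts are
    reported alongside the frequencies.
    """
    labels = np.asarray(labels)
    cols = [geno.snp_index(s) for s in snp_ids]
    rows = []
    for g in pd.unique(labels):
        sub = geno.dosage[labels == g][:, cols]
        n_alleles = 2.0 * np.sum(~np.isnan(sub), axis=0)
        alt = np.nansum(sub, axis=0)
        for j, s in enumerate(snp_ids):
            rows.append(
                {
                    "snp": s,
                    "group": g,
                    "alt_freq": float(alt[j] / n_alleles[j]) if n_alleles[j] > 0 else np.nan,
                    "n_alleles": int(n_alleles[j]),
                }
            )
    return pd.DataFrame(rows)


def relative_phenotype_change(
    table: pd.DataFrame, labels: np.ndarray
) -> pd.DataFrame:
    """Per-subpopulation percent deviation from the whole-population mean.

    deviation = 100 * (group mean - overall mean) / overall mean, with a
    two-sided t-test of the group against the remaining accessions per
    trait.  A trait with overall mean 0 has an undefined percent change.
    """
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if groups.size < 2:
        raise ValueError("need >= 2 subpopulations")
    rows = []
    for trait in table.columns:
        vals = table[trait].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        overall = vals[ok].mean()
        if overall == 0:
            raise ValueError(f"trait {trait!r}: overall mean is 0, percent change undefined")
        for g in groups:
            in_g = ok & (labels == g)
            rest = ok & (labels != g)
            t, p = stats.ttest_ind(vals[in_g], vals[rest], equal_var=False)
            rows.append(
                {
                    "trait": trait,
                    "subpopulation": g,
                    "percent_change": 100.0 * (vals[in_g].mean() - overall) / overall,
                    "t": float(t),
                    "p": float(p),
                    "n": int(in_g.sum()),
                }
            )
    return pd.DataFrame(rows)
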