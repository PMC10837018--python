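"""GWAS summary-statistic post-processing.

Downstream of an association scan this module provides: sliding-window LD
pruning (PLINK indep-pairwise style), a family-covariate regression scan
for introgression-line panels, the Bonferroni-from-pruned-count threshold,
LD clumping of significant SNPs into bins, SNP-to-gene-window assignment,
Benjamini–Hochberg adjustment, and the lambda gene-set enrichment
statistic

    lambda = q99(-log10 BH-adjusted subset p) / q99(-log10 BH-adjusted genome p)

with a permutation null built from random same-size SNP subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import GenotypeMatrix

__all__ = [
    "ClumpConfig",
    "ClumpBin",
    "LambdaReport",
    "ld_prune",
    "il_family_gwas",
    "bonferroni_from_pruned",
    "clump",
    "snps_near_genes",
    "bh_adjust",
    "lambda_statistic",
    "lambda_null",
]


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, complete pairs only."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return np.nan
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return np.nan
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def ld_prune(
    geno: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.2,
) -> list[str]:
    """Sliding-window LD pruning; returns the kept SNP ids.

    Windows of ``window_snps`` advance by ``step_snps`` along each sorted
    chromosome.  Within a window, for any kept pair with r² above the
    bound the later SNP by position is removed, until no violating pair
    remains; the kept set satisfies the pairwise bound inside every window.
    """
    keep = np.ones(geno.n_snps, dtype=bool)
    for c in pd.unique(geno.chrom):
        idx = np.flatnonzero(geno.chrom == c)
        if np.any(np.diff(geno.pos[idx]) <= 0):
            raise ValueError(f"SNPs not sorted by position on {c}")
        start = 0
        while start < idx.size:
            window = idx[start : start + window_snps]
            live = window[keep[window]]
            if live.size > 1:
                r2 = _window_r2(geno.dosage[:, live])
                # greedy in position order: a violating pair drops the later SNP
                alive = np.ones(live.size, dtype=bool)
                for a in range(live.size):
                    if not alive[a]:
                        continue
                    viol = alive & (r2[a] > r2_max)
                    viol[: a + 1] = False
                    alive[viol] = False
                keep[live[~alive]] = False
            if start + window_snps >= idx.size:
                break
            start += step_snps
    return list(geno.snp_ids[keep])


def _window_r2(block: np.ndarray) -> np.ndarray:
    """Pairwise r2 matrix for a dosage block (complete pairs; NaN where undefined)."""
    if np.isnan(block).any():
        m = block.shape[1]
        out = np.full((m, m), np.nan)
        for a in range(m):
            out[a, a] = 1.0
            for b in range(a + 1, m):
                out[a, b] = out[b, a] = _pairwise_r2(block[:, a], block[:, b])
        return out
    sd = block.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(block.T)
    r2 = corr * corr
    bad = sd == 0
    r2[bad, :] = np.nan
    r2[:, bad] = np.nan
    np.fill_diagonal(r2, 1.0)
    return r2


def il_family_gwas(
    trait: np.ndarray,
    geno: GenotypeMatrix,
    families: np.ndarray,
    trait_label: str = "trait",
    p_cutoff: float = 1e-3,
) -> pd.DataFrame:
    """Per-SNP OLS of trait on dosage with family-indicator covariates.

    The introgression-line design confounds donor-family membership with
    genotype; including the family as a fixed covariate removes that
    structure (Frisch–Waugh residualisation is used internally).  SNPs
    whose dosage is collinear with family structure get a missing p-value
    with a reason; missing dosages are handled by per-SNP listwise
    deletion.  Significance is flagged at ``p_cutoff``.
    """
    trait = np.asarray(trait, dtype=float)
    families = np.asarray(families)
    fam_levels = pd.unique(families)
    if fam_levels.size < 1:
        raise ValueError("family labels required")
    rows = []
    n_fam = fam_levels.size
    fam_codes = pd.Categorical(families, categories=fam_levels).codes
    for j in range(geno.n_snps):
        x = geno.dosage[:, j]
        ok = ~np.isnan(x) & ~np.isnan(trait)
        xs, ys, fc = x[ok], trait[ok], fam_codes[ok]
        counts = np.bincount((xs > 0).astype(int) + (xs > 1).astype(int), minlength=3)
        # minor allele must be present in >= 2 accessions
        mac = min(counts[0] + counts[1], counts[2] + counts[1])
        rec = {
            "snp": geno.snp_ids[j],
            "chrom": geno.chrom[j],
            "pos": int(geno.pos[j]),
            "trait": trait_label,
        }
        if mac < 2:
            rec.update(beta=np.nan, se=np.nan, p=np.nan, reason="minor allele in < 2 accessions")
            rows.append(rec)
            continue
        # project out family means (equivalent to family fixed effects + intercept)
        fm_x = np.bincount(fc, weights=xs) / np.bincount(fc)
        fm_y = np.bincount(fc, weights=ys) / np.bincount(fc)
        rx = xs - fm_x[fc]
        ry = ys - fm_y[fc]
        sxx = float(rx @ rx)
        df = ys.size - len(np.unique(fc)) - 1
        if sxx < 1e-12 or df < 1:
            rec.update(beta=np.nan, se=np.nan, p=np.nan, reason="collinear with family structure")
            rows.append(rec)
            continue
        beta = float(rx @ ry) / sxx
        resid = ry - beta * rx
        sigma2 = float(resid @ resid) / df
        se = np.sqrt(sigma2 / sxx)
        tval = beta / se if se > 0 else np.inf
        p = 2.0 * float(stats.t.sf(abs(tval), df)) if np.isfinite(tval) else 0.0
        rec.update(beta=beta, se=se, p=p, reason="")
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < p_cutoff
    return out


def bonferroni_from_pruned(n_pruned: int) -> float:
    """Genome-wide threshold 1/n from the count of LD-pruned (independent) SNPs."""
    if n_pruned < 1:
        raise ValueError("n_pruned must be >= 1")
    return 1.0 / n_pruned


@dataclass
class ClumpConfig:
    """PLINK-style clumping parameters (p1/p2 thresholds, r2, flank)."""

    p1: float = 1e-5
    p2: float = 1e-4
    r2_min: float = 0.3
    flank_kb: float = 2500.0  # per side
    allow_overlap: bool = False
    drop_singletons: bool = True

    def __post_init__(self) -> None:
        if self.p1 > self.p2:
            raise ValueError("p1 must be <= p2")
        if not (0.0 < self.r2_min <= 1.0):
            raise ValueError("r2_min must be in (0, 1]")


@dataclass
class ClumpBin:
    index_snp: str
    member_snps: list[str]  # includes the index
    chrom: str
    start: int
    end: int
    trait: str | None = None
    min_p: float = field(default=np.nan)


def clump(
    gwas: pd.DataFrame, geno: GenotypeMatrix, cfg: ClumpConfig | None = None
) -> list[ClumpBin]:
    """Clump associated SNPs into LD bins around index SNPs.

    Index SNPs (p <= p1) are processed in ascending p order (ties broken by
    chrom, pos); each gathers members with p <= p2 within the flank and
    with r² >= r2_min to the index.  Without ``allow_overlap`` members are
    consumed and cannot seed or join later bins.  Singleton bins (index
    only) are discarded by default.
    """
    cfg = cfg or ClumpConfig()
    missing = [s for s in gwas["snp"] if not np.any(geno.snp_ids == s)]
    if missing:
        raise KeyError(f"SNPs absent from genotype matrix: {', '.join(map(str, missing[:10]))}")
    tbl = gwas.copy()
    tbl["_col"] = [geno.snp_index(s) for s in tbl["snp"]]
    idx_tbl = tbl[tbl["p"] <= cfg.p1].sort_values(["p", "chrom", "pos"])
    cand = tbl[tbl["p"] <= cfg.p2]
    consumed: set[str] = set()
    bins: list[ClumpBin] = []
    flank = cfg.flank_kb * 1000.0
    for _, ix in idx_tbl.iterrows():
        if not cfg.allow_overlap and ix["snp"] in consumed:
            continue
        near = cand[
            (cand["chrom"] == ix["chrom"])
            & (np.abs(cand["pos"] - ix["pos"]) <= flank)
            & (cand["snp"] != ix["snp"])
        ]
        members = [ix["snp"]]
        positions = [int(ix["pos"])]
        pvals = [float(ix["p"])]
        for _, m in near.iterrows():
            if not cfg.allow_overlap and m["snp"] in consumed:
                continue
            r2 = _pairwise_r2(
                geno.dosage[:, int(ix["_col"])], geno.dosage[:, int(m["_col"])]
            )
            if not np.isnan(r2) and r2 >= cfg.r2_min:
                members.append(m["snp"])
                positions.append(int(m["pos"]))
                pvals.append(float(m["p"]))
        if cfg.drop_singletons and len(members) == 1:
            consumed.add(ix["snp"])
            continue
        consumed.update(members)
        bins.append(
            ClumpBin(
                index_snp=ix["snp"],
                member_snps=members,
                chrom=str(ix["chrom"]),
                start=min(positions),
                end=max(positions),
                trait=ix.get("trait"),
                min_p=min(pvals),
            )
        )
    return bins


def snps_near_genes(
    positions: pd.DataFrame, genes: pd.DataFrame, flank_bp: int = 200_000
) -> np.ndarray:
    """Boolean mask of SNPs within ``flank_bp`` of any gene interval.

    ``positions`` needs chrom/pos (1-based); ``genes`` chrom/start/end
    (0-based half-open).  Boundaries are closed on both ends after
    flanking, and overlapping windows use union semantics (each SNP counted
    once).
    """
    if flank_bp < 0:
        raise ValueError("flank must be non-negative")
    inside = np.zeros(len(positions), dtype=bool)
    pos = positions["pos"].to_numpy()
    chrom = positions["chrom"].to_numpy()
    for _, g in genes.iterrows():
        lo = (g["start"] + 1) - flank_bp  # 1-based gene start
        hi = g["end"] + flank_bp  # 1-based inclusive gene end
        inside |= (chrom == g["chrom"]) & (pos >= lo) & (pos <= hi)
    return inside


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _neglog10_quantile(p: np.ndarray, quantile: float) -> float:
    return float(np.quantile(-np.log10(np.maximum(p, 1e-300)), quantile))


def lambda_statistic(
    subset_p: np.ndarray,
    genome_p: np.ndarray,
    quantile: float = 0.99,
    joint_adjust: bool = False,
) -> float:
    """Gene-set enrichment lambda from BH-adjusted p-value quantiles.

    Subset and genome-wide sets are BH-adjusted separately (so subset ==
    genome gives lambda = 1 exactly); ``joint_adjust`` pools them for a
    single adjustment instead.  Quantiles interpolate linearly between
    order statistics.
    """
    subset_p = np.asarray(subset_p, dtype=float)
    genome_p = np.asarray(genome_p, dtype=float)
    if subset_p.size == 0 or genome_p.size == 0:
        raise ValueError("both p-value sets must be non-empty")
    if joint_adjust:
        adj = bh_adjust(np.concatenate([subset_p, genome_p]))
        sub_adj, gen_adj = adj[: subset_p.size], adj[subset_p.size :]
    else:
        sub_adj = bh_adjust(subset_p)
        gen_adj = bh_adjust(genome_p)
    denom = _neglog10_quantile(gen_adj, quantile)
    if denom == 0:
        raise ValueError("degenerate flat genome: denominator quantile is 0")
    return _neglog10_quantile(sub_adj, quantile) / denom


@dataclass
class LambdaReport:
    lam: float
    subset_size: int
    null_lambdas: np.ndarray
    empirical_p: float
    quantile: float = 0.99


def lambda_null(
    genome_p: np.ndarray,
    subset_size: int,
    observed_lambda: float | None = None,
    subset_p: np.ndarray | None = None,
    n_iter: int = 1000,
    seed: int | None = None,
    quantile: float = 0.99,
) -> LambdaReport:
    """Permutation null for lambda from random same-size SNP subsets.

    Draws ``n_iter`` simple random subsets of the genome-wide p-values
    without replacement, computes lambda for each, and reports
    empirical_p = (1 + #{null >= observed}) / (n_iter + 1).
    """
    genome_p = np.asarray(genome_p, dtype=float)
    if subset_size > genome_p.size:
        raise ValueError("subset_size exceeds genome size")
    if observed_lambda is None:
        if subset_p is None:
            raise ValueError("provide observed_lambda or subset_p")
        observed_lambda = lambda_statistic(subset_p, genome_p, quantile=quantile)
    rng = np.random.default_rng(seed)
    # the genome-wide denominator is constant across null draws
    denom = _neglog10_quantile(bh_adjust(genome_p), quantile)
    if denom == 0:
        raise ValueError("degenerate flat genome: denominator quantile is 0")
    nulls = np.empty(n_iter)
    for it in range(n_iter):
        sub = rng.choice(genome_p, size=subset_size, replace=False)
        nulls[it] = _neglog10_quantile(bh_adjust(sub), quantile) / denom
    emp = (1.0 + np.sum(nulls >= observed_lambda)) / (n_iter + 1.0)
    return LambdaReport(
        lam=float(observed_lambda),
        subset_size=int(subset_size),
        null_lambdas=nulls,
        empirical_p=float(emp),
        quantile=quantile,
    )
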