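"""Graphical genotypes and allelic-stacking summaries.

A multi-megabase region with dense SNPs is compressed into a graphical
genotype: in each sliding window (default 10 Mb window, 1 Mb step) the
accessions are forced into two groups by k-means on their dosage vectors
— a biallelic, effectively homozygous panel carries essentially two local
haplotype classes — and each accession is painted major or minor per
window.  Accessions are then ordered by hierarchical clustering of their
window-label vectors.  Allelic stacking groups accessions by how many
designated (e.g. wild-donor) alleles they carry across a set of GWAS peak
SNPs and tests whether the trait responds additively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .types import GenotypeMatrix, GraphicalGenotype

__all__ = [
    "ld_r2_matrix",
    "graphical_genotype",
    "cluster_accessions",
    "allelic_stacking",
    "StackingSummary",
]


def ld_r2_matrix(geno: GenotypeMatrix, region: tuple[str, int, int]) -> pd.DataFrame:
    """Symmetric r² matrix for SNPs in ``region`` (chrom, start, end; 0-based half-open).

    Squared Pearson correlation of dosages over complete pairs; the
    diagonal is 1.  A monomorphic SNP's off-diagonal entries are missing.
    """
    chrom, start, end = region
    on = (geno.chrom == chrom) & (geno.pos > start) & (geno.pos <= end)
    if on.sum() < 2:
        raise ValueError("region must contain >= 2 SNPs")
    d = geno.dosage[:, on]
    ids = geno.snp_ids[on]
    m = d.shape[1]
    r2 = np.full((m, m), np.nan)
    np.fill_diagonal(r2, 1.0)
    for a in range(m):
        for b in range(a + 1, m):
            ok = ~np.isnan(d[:, a]) & ~np.isnan(d[:, b])
            if ok.sum() < 2:
                continue
            xa, xb = d[ok, a], d[ok, b]
            if xa.std() == 0 or xb.std() == 0:
                continue
            r = np.corrcoef(xa, xb)[0, 1]
            r2[a, b] = r2[b, a] = r * r
    return pd.DataFrame(r2, index=ids, columns=ids)


def graphical_genotype(
    geno: GenotypeMatrix,
    region: tuple[str, int, int],
    window_bp: int = 10_000_000,
    step_bp: int = 1_000_000,
    seed: int | None = None,
) -> GraphicalGenotype:
    """Sliding-window two-group clustering into a window x accession label matrix.

    Per window, accession dosage vectors (missing values imputed to the
    window allele-frequency mean) are clustered into two groups by k-means
    with 10 seeded restarts; the larger cluster is 'major' (ties go to the
    cluster containing the first accession in input order).  Windows with
    no SNPs are ``no_data``; windows whose accession vectors are all
    identical are flagged single-cluster and painted all-major.
    """
    chrom, start, end = region
    on_chrom = geno.chrom == chrom
    rng = np.random.default_rng(seed)
    win_rows, labels = [], []
    w_start = int(start)
    while w_start < end:
        w_end = min(w_start + int(window_bp), int(end))
        on = on_chrom & (geno.pos > w_start) & (geno.pos <= w_end)
        n_snps = int(on.sum())
        row = {"chrom": chrom, "start": w_start, "end": w_end, "n_snps": n_snps,
               "single_cluster": False, "imputed_frac": 0.0}
        if n_snps == 0:
            labels.append(np.full(geno.n_accessions, GraphicalGenotype.NO_DATA))
        else:
            d = geno.dosage[:, on].copy()
            miss = np.isnan(d)
            if miss.any():
                col_mean = np.nanmean(d, axis=0)
                d[miss] = np.take(col_mean, np.where(miss)[1])
                row["imputed_frac"] = float(miss.mean())
            if np.unique(d, axis=0).shape[0] < 2:
                row["single_cluster"] = True
                labels.append(np.full(geno.n_accessions, GraphicalGenotype.MAJOR))
            else:
                km = KMeans(
                    n_clusters=2, n_init=10,
                    random_state=int(rng.integers(0, 2**31 - 1)),
                ).fit(d)
                assign = km.labels_
                n1 = int((assign == 1).sum())
                n0 = geno.n_accessions - n1
                if n1 > n0 or (n1 == n0 and assign[0] == 1):
                    assign = 1 - assign  # major = larger cluster / first accession's
                labels.append(assign.astype(int))
        win_rows.append(row)
        if w_end >= end:
            break
        w_start += int(step_bp)
    return GraphicalGenotype(
        windows=pd.DataFrame(win_rows),
        labels=np.vstack(labels),
        accession_ids=list(geno.accession_ids),
        window_bp=int(window_bp),
        step_bp=int(step_bp),
    )


def cluster_accessions(gg: GraphicalGenotype):
    """Order accessions by complete-linkage clustering of their window labels.

    The distance between two accessions is the Hamming mismatch fraction
    over windows where both carry data (``no_data`` windows are ignored
    pairwise; a pair with no shared informative window gets distance 1).
    Returns ``(leaf_order, linkage_matrix)``.
    """
    L = gg.labels  # windows x accessions
    n = L.shape[1]
    if n < 2:
        raise ValueError("need >= 2 accessions")
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            ok = (L[:, a] != GraphicalGenotype.NO_DATA) & (
                L[:, b] != GraphicalGenotype.NO_DATA
            )
            D[a, b] = D[b, a] = (
                float(np.mean(L[ok, a] != L[ok, b])) if ok.any() else 1.0
            )
    Z = hierarchy.linkage(squareform(D, checks=False), method="complete")
    order = hierarchy.leaves_list(Z)
    return order, Z


def _compact_letters(groups: list, sig: dict[tuple, bool]) -> dict:
    """Compact letter display: groups not significantly different share a letter."""
    letters: dict = {g: "" for g in groups}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    sets: list[set] = []
    for g in groups:
        placed = False
        for s in sets:
            if all(not sig.get(tuple(sorted((g, h), key=str)), False) for h in s):
                s.add(g)
                placed = True
        if not placed:
            sets.append({g})
    # absorb: a group may belong to several letter sets
    for g in groups:
        for s in sets:
            if g not in s and all(
                not sig.get(tuple(sorted((g, h), key=str)), False) for h in s
            ):
                s.add(g)
    for s, letter in zip(sets, alphabet):
        for g in s:
            letters[g] += letter
    return {g: "".join(sorted(v)) for g, v in letters.items()}


@dataclass
class StackingSummary:
    group_stats: pd.DataFrame  # per stack-count: mean, sd, n, letters
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame
    trend_slope: float
    trend_r2: float
    trend_p: float
    n_excluded: int


def allelic_stacking(
    geno: GenotypeMatrix,
    peaks: pd.DataFrame,
    trait: np.ndarray,
) -> StackingSummary:
    """Trait response to the number of designated alleles carried at peak SNPs.

    ``peaks`` has columns ``snp`` and ``designated_allele`` ('alt' or
    'ref').  An accession carries a designated allele at a locus when it
    has at least one copy (a homozygous carrier counts once per locus, as
    appropriate for inbred lines).  Accessions with a missing genotype at
    any peak SNP are excluded (count reported).  Reports the one-way ANOVA
    across stack-count groups, Tukey–Kramer pairwise comparisons with a
    compact letter display, and the linear trend of trait on stack count
    to quantify additivity.
    """
    trait = np.asarray(trait, dtype=float)
    cols = [geno.snp_index(s) for s in peaks["snp"]]
    d = geno.dosage[:, cols]
    carries = np.zeros_like(d, dtype=bool)
    for j, allele in enumerate(peaks["designated_allele"]):
        if allele == "alt":
            carries[:, j] = d[:, j] >= 1
        elif allele == "ref":
            carries[:, j] = d[:, j] <= 1
        else:
            raise ValueError(f"designated_allele must be 'ref' or 'alt', got {allele!r}")
    complete = ~np.isnan(d).any(axis=1) & ~np.isnan(trait)
    n_excluded = int((~complete).sum())
    counts = carries[complete].sum(axis=1)
    y = trait[complete]
    groups = np.unique(counts)
    by_group = [y[counts == g] for g in groups]
    usable = [g for g, v in zip(groups, by_group) if v.size >= 2]
    if len(usable) < 2:
        raise ValueError("need >= 2 stacking groups with >= 2 accessions each")
    f, p = stats.f_oneway(*[v for v in by_group if v.size >= 2])
    tk = pairwise_tukeyhsd(y, counts)
    tk_df = pd.DataFrame(
        data=tk.summary().data[1:], columns=tk.summary().data[0]
    )
    sig = {
        tuple(sorted((g1, g2), key=str)): bool(rej)
        for g1, g2, rej in zip(tk.groupsunique[tk._multicomp.pairindices[0]],
                               tk.groupsunique[tk._multicomp.pairindices[1]],
                               tk.reject)
    }
    letters = _compact_letters(list(groups), sig)
    stats_df = pd.DataFrame(
        {
            "stack_count": groups,
            "mean": [v.mean() for v in by_group],
            "sd": [v.std(ddof=1) if v.size > 1 else np.nan for v in by_group],
            "n": [v.size for v in by_group],
            "letters": [letters[g] for g in groups],
        }
    )
    slope, intercept, r, p_trend, se = stats.linregress(counts.astype(float), y)
    return StackingSummary(
        group_stats=stats_df,
        anova_f=float(f),
        anova_p=float(p),
        tukey=tk_df,
        trend_slope=float(slope),
        trend_r2=float(r * r),
        trend_p=float(p_trend),
        n_excluded=n_excluded,
    )
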