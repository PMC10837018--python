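"""Culm internode-profile statistics.

The central phenotyping idea: an unconstrained, indeterminate shoot would
add internodes whose expected length increases linearly from the proximal
(i = 1) to the distal (i = n) end.  Real culms oscillate around that
expectation, so we quantify

* **AMP** — the oscillation amplitude, the summed absolute deviation of the
  observed internode lengths from the fitted linear expectation, divided by
  total culm length (dimensionless, height-independent);
* **trisection** — node-number-independent compartment means DIL/CIL/PIL
  (distal, central, proximal) via an optional moving average;
* derived whole-culm traits (INN, TIL, AIL, PL, PPL, ...);
* **repeatability** W² = sigma_g^2 / (sigma_g^2 + sigma_e^2 / n) from the
  mixed model y_ij = mu + g_i + r_j + e_ij (genotype random, replicate
  fixed, REML);
* genotype-level adjusted means (BLUE-like) from the two-way fixed model;
* the Lindeman–Merenda–Gold (LMG) relative-importance decomposition of R²;
* trait PCA and pairwise correlations.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import InternodeProfile

__all__ = [
    "LinearFit",
    "CulmTraitRecord",
    "VarianceComponents",
    "ImportanceDecomposition",
    "PatternComparison",
    "fit_linear_expectation",
    "compute_amp",
    "compartment_sizes",
    "trisect_profile",
    "derive_traits",
    "fit_pattern_models",
    "estimate_repeatability",
    "genotype_means",
    "relative_importance_lmg",
    "trait_pca",
    "correlate_traits",
]


class ProfileTooShortError(ValueError):
    """Raised when a profile has fewer than 3 internodes."""


@dataclass
class LinearFit:
    slope: float  # cm per position index
    intercept: float  # cm
    fitted: np.ndarray  # expected lengths, cm
    abs_residual_sum: float  # cm


@dataclass
class CulmTraitRecord:
    """Genotype/plant-level trait roster.

    INN: culm node number; TIL: total culm internode length (cm);
    AIL: average internode length (cm); PL: peduncle length (cm, the
    distal-most internode); PPL: 100*PL/TIL (%); DIL/CIL/PIL: compartment
    means (cm); AMP: oscillation amplitude (dimensionless).  Spike and
    phenology traits (SL, FRN, PRN, PD, DTH) are pass-through
    measurements; RIL = SL/FRN (cm) when both are given.  Missing
    measurements stay ``None``, never 0.
    """

    plant_id: str
    genotype_id: str
    INN: int
    TIL: float
    AIL: float
    PL: float
    PPL: float
    DIL: float
    CIL: float
    PIL: float
    AMP: float
    SL: float | None = None
    FRN: float | None = None
    PRN: float | None = None
    PD: float | None = None
    DTH: float | None = None
    RIL: float | None = None


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    replicate_effects: dict
    grand_mean: float
    n_reps: float
    W2: float
    lrt_p: float
    reml_loglik: float = field(default=np.nan, repr=False)


@dataclass
class ImportanceDecomposition:
    shares: pd.Series  # per-predictor LMG share of R^2
    total_r2: float
    ci_lower: pd.Series | None = None
    ci_upper: pd.Series | None = None
    n_boot: int = 0


@dataclass
class PatternComparison:
    r2_linear: float
    r2_cubic: float
    rss_linear: float
    rss_cubic: float
    f_stat: float
    f_p: float
    coef_linear: np.ndarray
    coef_cubic: np.ndarray
    n_points: int


def _require_fittable(profile: InternodeProfile) -> None:
    if profile.n < 3:
        raise ProfileTooShortError(
            f"profile {profile.plant_id}: need >= 3 internodes, got {profile.n}"
        )


def fit_linear_expectation(profile: InternodeProfile) -> LinearFit:
    """OLS of internode length on position index i = 1..n.

    The fitted line is the linear expectation L-hat_i of indeterminate
    growth; the sum of absolute residuals measures how strongly the real
    profile oscillates around it.
    """
    _require_fittable(profile)
    i = np.arange(1, profile.n + 1, dtype=float)
    slope, intercept = np.polyfit(i, profile.lengths, 1)
    fitted = slope * i + intercept
    return LinearFit(
        slope=float(slope),
        intercept=float(intercept),
        fitted=fitted,
        abs_residual_sum=float(np.abs(profile.lengths - fitted).sum()),
    )


def compute_amp(profile: InternodeProfile) -> float:
    """Oscillation amplitude: sum |L_i - L-hat_i| / TIL.

    Normalising by total culm internode length makes AMP independent of
    plant height (AMP(c*L) = AMP(L) for any c > 0).
    """
    fit = fit_linear_expectation(profile)
    til = float(profile.lengths.sum())
    if til <= 0:
        raise ValueError("TIL must be positive")
    return fit.abs_residual_sum / til


def compartment_sizes(n: int) -> tuple[int, int, int]:
    """Proximal/central/distal compartment sizes for an n-internode culm.

    n = 3q gives q/q/q.  One leftover internode goes to the central
    compartment (keeping the central intersection zone symmetric); two
    leftovers go to the proximal and distal ends.
    """
    if n < 3:
        raise ProfileTooShortError(f"need >= 3 internodes to trisect, got {n}")
    q, r = divmod(n, 3)
    if r == 0:
        return q, q, q
    if r == 1:
        return q, q + 1, q
    return q + 1, q, q + 1


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, edge-truncated to the available neighbours."""
    if window == 1:
        return x
    half = window // 2
    out = np.empty_like(x, dtype=float)
    for k in range(x.size):
        lo = max(0, k - half)
        hi = min(x.size, k + half + 1)
        out[k] = x[lo:hi].mean()
    return out


def trisect_profile(
    profile: InternodeProfile, smooth_window: int = 1
) -> tuple[float, float, float]:
    """Compartment mean lengths (DIL, CIL, PIL) after optional smoothing.

    ``smooth_window`` must be odd; 1 disables smoothing, in which case the
    count-weighted mean of the three compartments equals AIL exactly.
    """
    _require_fittable(profile)
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError(f"smooth_window must be a positive odd count, got {smooth_window}")
    smoothed = _moving_average(profile.lengths, smooth_window)
    n_p, n_c, n_d = compartment_sizes(profile.n)
    pil = float(smoothed[:n_p].mean())
    cil = float(smoothed[n_p : n_p + n_c].mean())
    dil = float(smoothed[n_p + n_c :].mean())
    return dil, cil, pil


def derive_traits(
    profile: InternodeProfile,
    spike_measurements: dict | None = None,
    smooth_window: int = 1,
) -> CulmTraitRecord:
    """Full per-plant trait record from a culm profile plus optional spike data.

    The peduncle is the distal-most culm internode.  Spike fields absent
    from ``spike_measurements`` are flagged ``None`` (absent), never zero.
    """
    if profile.axis_kind != "culm":
        raise ValueError("derive_traits expects a culm profile")
    _require_fittable(profile)
    spike = dict(spike_measurements or {})
    til = float(profile.lengths.sum())
    pl = float(profile.lengths[-1])
    dil, cil, pil = trisect_profile(profile, smooth_window=smooth_window)
    sl, frn = spike.get("SL"), spike.get("FRN")
    ril = (sl / frn) if (sl is not None and frn is not None and frn > 0) else None
    return CulmTraitRecord(
        plant_id=profile.plant_id,
        genotype_id=profile.genotype_id,
        INN=profile.n,
        TIL=til,
        AIL=til / profile.n,
        PL=pl,
        PPL=100.0 * pl / til,
        DIL=dil,
        CIL=cil,
        PIL=pil,
        AMP=compute_amp(profile),
        SL=sl,
        FRN=frn,
        PRN=spike.get("PRN"),
        PD=spike.get("PD"),
        DTH=spike.get("DTH"),
        RIL=ril,
    )


def fit_pattern_models(profiles) -> PatternComparison:
    """Linear vs cubic fit of internode length on scaled position.

    Positions are rescaled to [0, 1] per profile so culms with different
    node numbers share one trend.  An 'inverse-S' elongation pattern shows
    up as a significant nested F-test for the cubic over the linear fit.
    """
    xs, ys = [], []
    for p in profiles:
        _require_fittable(p)
        xs.append((np.arange(p.n) / (p.n - 1)))
        ys.append(p.lengths)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    degree = 3
    if np.unique(x).size < 5:
        warnings.warn(
            "fewer than 5 distinct positions: cubic degree capped at "
            f"{np.unique(x).size - 1}", stacklevel=2,
        )
        degree = int(np.unique(x).size - 1)
    c1 = np.polynomial.polynomial.polyfit(x, y, 1)
    c3 = np.polynomial.polynomial.polyfit(x, y, degree)
    f1 = np.polynomial.polynomial.polyval(x, c1)
    f3 = np.polynomial.polynomial.polyval(x, c3)
    tss = float(np.sum((y - y.mean()) ** 2))
    rss1 = float(np.sum((y - f1) ** 2))
    rss3 = float(np.sum((y - f3) ** 2))
    df_extra = degree - 1
    df_resid = y.size - (degree + 1)
    tiny = 1e-10 * max(tss, 1.0)
    if rss1 - rss3 <= tiny and rss3 <= tiny:  # both fits numerically perfect
        f_stat, f_p = 0.0, 1.0
    elif rss3 <= tiny:
        f_stat, f_p = np.inf, 0.0
    else:
        f_stat = max(0.0, ((rss1 - rss3) / df_extra) / (rss3 / df_resid))
        f_p = float(stats.f.sf(f_stat, df_extra, df_resid))
    r2 = lambda rss: 1.0 - rss / tss if tss > 0 else 1.0  # noqa: E731
    return PatternComparison(
        r2_linear=r2(rss1), r2_cubic=r2(rss3),
        rss_linear=rss1, rss_cubic=rss3,
        f_stat=float(f_stat), f_p=float(f_p),
        coef_linear=c1, coef_cubic=c3, n_points=int(y.size),
    )


# ---------------------------------------------------------------------------
# repeatability: y_ij = mu + g_i + r_j + e_ij, genotype random, replicate fixed


def _reml_profile(y, X, g_idx, n_groups, log_lam):
    """Profiled REML log-likelihood at variance ratio lam = sigma_g^2/sigma_e^2.

    V* = I + lam Z Z', Z the genotype incidence matrix.  Woodbury with
    Z'Z = diag(group sizes) keeps every evaluation O(N p^2).
    """
    lam = np.exp(log_lam)
    counts = np.bincount(g_idx, minlength=n_groups).astype(float)
    d = lam / (1.0 + lam * counts)  # shrinkage per genotype

    def vinv(M):  # V*^{-1} M for a column-stacked M
        gm = np.zeros((n_groups,) + M.shape[1:])
        np.add.at(gm, g_idx, M)
        return M - (d[:, None] * gm)[g_idx] if M.ndim == 2 else M - (d * gm.squeeze())[g_idx]

    XtVinvX = X.T @ vinv(X)
    XtVinvy = X.T @ vinv(y[:, None]).ravel()
    beta = np.linalg.solve(XtVinvX, XtVinvy)
    r = y - X @ beta
    rtVinvr = float(r @ vinv(r[:, None]).ravel())
    N, p = X.shape
    sigma2_e = rtVinvr / (N - p)
    logdetV = float(np.sum(np.log1p(lam * counts)))
    _, logdetXtVX = np.linalg.slogdet(XtVinvX)
    ll = -0.5 * (
        logdetV + (N - p) * np.log(sigma2_e) + logdetXtVX + (N - p)
    )
    return ll, beta, sigma2_e, lam * sigma2_e


def estimate_repeatability(data: pd.DataFrame, value_col: str = "value") -> VarianceComponents:
    """REML variance components and repeatability W² for one trait.

    ``data`` needs columns ``genotype``, ``replicate`` and the trait value.
    Replicate enters as a fixed effect, genotype as a random effect; the
    variance ratio is profiled in one dimension.  W² uses the mean number
    of replicates per genotype.  The p-value for sigma_g^2 > 0 comes from a
    REML likelihood-ratio test against the no-genotype-effect model,
    halved because the null pins the variance to the boundary (50:50
    chi-square mixture).
    """
    df = data.dropna(subset=[value_col])
    geno = pd.Categorical(df["genotype"])
    rep = pd.Categorical(df["replicate"])
    if len(geno.categories) < 2:
        raise ValueError("need >= 2 genotypes")
    reps_per_geno = df.groupby("genotype", observed=True).size()
    if (reps_per_geno < 2).all():
        raise ValueError("all genotypes have a single replicate: variance components inestimable")
    y = df[value_col].to_numpy(dtype=float)
    # fixed design: intercept + replicate dummies (first level as reference)
    X = np.column_stack(
        [np.ones(len(df))]
        + [(rep.codes == k).astype(float) for k in range(1, len(rep.categories))]
    )
    g_idx = np.asarray(geno.codes)
    n_g = len(geno.categories)

    obj = lambda ll: -_reml_profile(y, X, g_idx, n_g, ll)[0]  # noqa: E731
    res = optimize.minimize_scalar(obj, bounds=(-18.0, 18.0), method="bounded")
    ll_full, beta, s2e, s2g = _reml_profile(y, X, g_idx, n_g, res.x)
    ll_null, _, _, _ = _reml_profile(y, X, g_idx, n_g, -30.0)
    if ll_null >= ll_full:  # boundary optimum: no genotype variance
        ll_full, s2g = ll_null, 0.0
        _, beta, s2e, _ = _reml_profile(y, X, g_idx, n_g, -30.0)
    lrt = max(0.0, 2.0 * (ll_full - ll_null))
    lrt_p = 0.5 * float(stats.chi2.sf(lrt, 1)) if lrt > 0 else 1.0
    n_reps = float(reps_per_geno.mean())
    w2 = s2g / (s2g + s2e / n_reps) if (s2g + s2e) > 0 else 0.0
    rep_effects = {
        str(rep.categories[k]): (0.0 if k == 0 else float(beta[k]))
        for k in range(len(rep.categories))
    }
    return VarianceComponents(
        sigma2_g=float(s2g), sigma2_e=float(s2e),
        replicate_effects=rep_effects, grand_mean=float(beta[0]),
        n_reps=n_reps, W2=float(w2), lrt_p=lrt_p, reml_loglik=float(ll_full),
    )


def _check_connected(geno_codes, rep_codes, geno_labels, rep_labels):
    """Two-way design connectivity via union-find over genotype/replicate nodes."""
    n_g = len(geno_labels)
    parent = list(range(n_g + len(rep_labels)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for g, r in zip(np.asarray(geno_codes, dtype=int), np.asarray(rep_codes, dtype=int)):
        ra, rb = find(g), find(n_g + r)
        if ra != rb:
            parent[ra] = rb
    roots = {find(g) for g in range(n_g)}
    if len(roots) > 1:
        groups = {}
        for g in range(n_g):
            groups.setdefault(find(g), []).append(str(geno_labels[g]))
        raise ValueError(
            "disconnected genotype x replicate design; groups: "
            + "; ".join(",".join(v) for v in groups.values())
        )


def genotype_means(data: pd.DataFrame, value_col: str = "value") -> pd.Series:
    """Genotype-level adjusted means from the two-way additive fixed model.

    Equivalent to BLUEs under genotype + replicate fixed effects; balanced
    data reduce to arithmetic genotype means, and a constant shift of one
    replicate is absorbed by its replicate effect.
    """
    df = data.dropna(subset=[value_col])
    geno = pd.Categorical(df["genotype"])
    rep = pd.Categorical(df["replicate"])
    _check_connected(geno.codes, rep.codes, geno.categories, rep.categories)
    y = df[value_col].to_numpy(dtype=float)
    n_g, n_r = len(geno.categories), len(rep.categories)
    # sum-to-zero replicate coding -> genotype coefficient is already the
    # mean over replicate levels
    G = np.zeros((len(df), n_g))
    G[np.arange(len(df)), geno.codes] = 1.0
    R = np.zeros((len(df), n_r - 1)) if n_r > 1 else np.zeros((len(df), 0))
    for k in range(1, n_r):
        R[rep.codes == k, k - 1] = 1.0
    if n_r > 1:
        R[rep.codes == 0, :] = -1.0
    X = np.hstack([G, R])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(coef[:n_g], index=list(geno.categories), name=value_col)


# ---------------------------------------------------------------------------
# LMG relative importance


def _r2_from_subsets(y, Xc):
    """R^2 of y on every subset of the (centered) predictor columns."""
    p = Xc.shape[1]
    tss = float(y @ y)
    r2 = {}
    for mask in range(1 << p):
        if mask == 0:
            r2[mask] = 0.0
            continue
        cols = [k for k in range(p) if mask >> k & 1]
        coef, *_ = np.linalg.lstsq(Xc[:, cols], y, rcond=None)
        resid = y - Xc[:, cols] @ coef
        r2[mask] = 1.0 - float(resid @ resid) / tss
    return r2


def _lmg_shares(y, X):
    p = X.shape[1]
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    r2 = _r2_from_subsets(yc, Xc)
    fact = [float(np.prod(np.arange(1, k + 1))) if k else 1.0 for k in range(p + 1)]
    shares = np.zeros(p)
    for k in range(p):
        rest = [j for j in range(p) if j != k]
        for size in range(p):
            w = fact[size] * fact[p - size - 1] / fact[p]
            for combo in itertools.combinations(rest, size):
                mask = sum(1 << j for j in combo)
                shares[k] += w * (r2[mask | (1 << k)] - r2[mask])
    return shares, r2[(1 << p) - 1]


def relative_importance_lmg(
    data: pd.DataFrame,
    response: str,
    predictors: list[str],
    n_boot: int = 1000,
    seed: int | None = None,
) -> ImportanceDecomposition:
    """LMG decomposition of R² with percentile bootstrap CIs.

    The LMG share of predictor k is its sequential-R² increment averaged
    over all orderings of the predictors (exact subset enumeration, so at
    most 8 predictors).  Shares are non-negative and sum to the full-model
    R².  CIs resample accessions (rows) with replacement.
    """
    if len(predictors) > 8:
        raise ValueError("exact LMG enumeration supports at most 8 predictors")
    if len(predictors) < 1:
        raise ValueError("need at least one predictor")
    df = data.dropna(subset=[response, *predictors])
    n = len(df)
    if n <= len(predictors) + 2:
        raise ValueError("too few complete rows for the model")
    X = df[predictors].to_numpy(dtype=float)
    y = df[response].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise ValueError("rank-deficient predictor matrix")
    shares, total = _lmg_shares(y, X)
    out = ImportanceDecomposition(
        shares=pd.Series(shares, index=predictors), total_r2=float(total)
    )
    if n_boot and n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, len(predictors)))
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                boots[b], _ = _lmg_shares(y[idx], X[idx])
            except np.linalg.LinAlgError:  # pragma: no cover - degenerate resample
                boots[b] = np.nan
        lo = np.nanpercentile(boots, 2.5, axis=0)
        hi = np.nanpercentile(boots, 97.5, axis=0)
        out.ci_lower = pd.Series(lo, index=predictors)
        out.ci_upper = pd.Series(hi, index=predictors)
        out.n_boot = n_boot
    return out


def trait_pca(table: pd.DataFrame):
    """PCA on z-score standardized traits.

    Rows with any missing trait are dropped listwise (the count is
    reported); a constant column is an error.  Returns ``(loadings,
    scores, percent_variance, n_dropped)``; each component's sign is fixed
    so its largest-magnitude loading is positive.
    """
    if table.shape[1] < 3:
        raise ValueError("need >= 3 traits for PCA")
    complete = table.dropna(axis=0)
    n_dropped = len(table) - len(complete)
    sd = complete.std(axis=0, ddof=1)
    bad = sd[sd == 0].index.tolist()
    if bad:
        raise ValueError(f"constant trait column(s): {', '.join(map(str, bad))}")
    Z = (complete - complete.mean(axis=0)) / sd
    # eigen-decomposition of the sample correlation matrix (divisor n-1)
    U, s, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    eigvals = s**2 / (len(complete) - 1)
    percent = 100.0 * eigvals / eigvals.sum()
    loadings = Vt.T
    signs = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    loadings = loadings * signs
    scores = Z.to_numpy() @ loadings
    pcs = [f"PC{k + 1}" for k in range(loadings.shape[1])]
    return (
        pd.DataFrame(loadings, index=table.columns, columns=pcs),
        pd.DataFrame(scores, index=complete.index, columns=pcs),
        pd.Series(percent, index=pcs),
        n_dropped,
    )


def correlate_traits(table: pd.DataFrame, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Pearson r, R² and two-sided t-test p for the requested trait pairs."""
    rows = []
    for a, b in pairs:
        sub = table[[a, b]].dropna()
        if len(sub) < 3:
            raise ValueError(f"pair ({a}, {b}): need >= 3 complete observations")
        if sub[a].std() == 0 or sub[b].std() == 0:
            raise ValueError(f"pair ({a}, {b}): zero-variance input, correlation undefined")
        r, p = stats.pearsonr(sub[a], sub[b])
        rows.append({"trait_x": a, "trait_y": b, "r": r, "r2": r * r, "p": p, "n": len(sub)})
    return pd.DataFrame(rows)
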