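# Methods

This note documents the models, estimators and numerical choices behind
`phytomer`, the defaults and why they were chosen, and what the
synthetic-data generators do and do not emulate.

## Internode profiles and the oscillation amplitude

A profile is an ordered vector L₁ … Lₙ of internode lengths in cm,
indexed proximal (i = 1) to distal (i = n); every routine documents and
assumes this orientation. Unconstrained indeterminate growth predicts an
expected length that increases linearly with position, so the *linear
expectation* is the OLS fit of Lᵢ on the index i. We deliberately fit a
regression on position rather than the literal first-order recurrence
L̂ᵢ = a·L̂ᵢ₋₁ + b: with free (a, b) the recurrence traces an
affine/geometric trend whose fitting is ill-conditioned, while OLS on
index is the reproducible reading of "linearly increasing expected
length" and yields identical results on exactly linear profiles. The
oscillation amplitude AMP = Σ|Lᵢ − L̂ᵢ|/TIL is dimensionless and exactly
scale-invariant (residuals and TIL scale together), so it measures the
*shape* of the deviation, not plant height. AMP is computed per plant
and then averaged per genotype; computing it on genotype-mean profiles
would damp replicate-level oscillation and is not what we do.

Profiles with n < 3 raise `ProfileTooShortError`: a line through two
points leaves no residual and a trisection needs three compartments.

## Trisection (DIL / CIL / PIL)

Node numbers vary across accessions, so per-position comparisons do not
line up; instead each culm is cut into three contiguous compartments and
summarised by compartment means. The remainder rule is fixed: n = 3q
gives q/q/q; one leftover internode joins the central compartment
(keeping the central intersection zone symmetric); two leftovers join
the proximal and distal ends. An optional centred moving average
(odd window, edge-truncated) smooths the profile first; the default
window is 1 (no smoothing) because no particular window is canonical,
and with window 1 the count-weighted compartment means reproduce the
overall mean internode length exactly — a property the tests enforce.
The peduncle (PL) is defined as the distal-most culm internode, standard
barley morphology.

## Repeatability

For a trait measured on genotype i in replicate j we fit
y_ij = μ + g_i + r_j + ε_ij with replicate as a fixed effect and
genotype as a random effect, by REML. The variance ratio
λ = σ_g²/σ_ε² is profiled in one dimension (bounded search on log λ,
Woodbury identities over the genotype incidence structure keep each
evaluation linear in the data), which is robust for this single-variance
model and needs no general mixed-model machinery. Repeatability is
W² = σ_g²/(σ_g² + σ_ε²/n) with n the mean number of replicates per
genotype. Significance of σ_g² uses the REML likelihood-ratio test
against the no-genotype model with the p-value halved, because the null
pins the variance to the boundary of its parameter space (the usual
50:50 chi-square mixture). Note that truncation at zero gives Ŵ² a
small positive null mean (≈ 0.05 at 100 genotypes × 4 replicates); the
tests compare against a closed-form ANOVA oracle rather than against
zero.

Genotype-level adjusted means come from the two-way additive fixed
model (genotype + replicate, sum-to-zero replicate coding). Balanced
data reduce to arithmetic genotype means; a constant added to one
replicate shifts every adjusted mean by c/n_reps and leaves all genotype
contrasts untouched. Disconnected genotype × replicate designs are
rejected with the offending groups named (union-find connectivity).

## LMG relative importance

The LMG share of predictor k is its sequential-R² increment averaged
over all orderings of the predictors, computed by exact subset
enumeration (closed under 2^p subsets, limited to p ≤ 8 — far above the
four predictors used for the height decomposition TIL ~ INN + DIL +
CIL + PIL). Shares are non-negative and sum to the full-model R² to
numerical precision. Confidence intervals are percentile bootstrap over
accessions (default 1,000 resamples, seeded).

## Trait PCA and correlations

PCA operates on z-scored traits (sample sd, divisor n − 1) via SVD;
rows with any missing trait are dropped listwise and counted, constant
columns are an error naming the column, and each component's sign is
fixed so its largest-magnitude loading is positive (a deterministic
orientation; eigenvectors are otherwise sign-ambiguous). Pairwise trait
correlations are Pearson r with the two-sided t-test p.

## F_ST

The Weir–Cockerham (1984) two-population diploid estimator: per SNP the
components a (among populations), b (among individuals within
populations) and c (within individuals) are computed from sample sizes,
allele frequencies and observed heterozygosity, with missing genotypes
excluded per site and sites used only when both populations have ≥ 2
non-missing accessions and the pooled pair is polymorphic. The
genome-wide estimate is the weighted ratio of sums Σa/Σ(a+b+c) — the
"weighted" estimate of the standard VCF tooling — rather than the mean
of per-SNP ratios, which is biased by low-information sites; the
per-SNP values are kept (and may legitimately be negative). The test
suite holds the vectorised implementation to an independent scalar
transliteration of the component equations at 1e-12 on random fixtures.

## P_ST and the selection verdict

P_ST = σ²_GB/(σ²_GB + σ²_GW) with variance components from the one-way
ANOVA method of moments: σ²_GW = MSW and σ²_GB = (MSB − MSW)/n₀, n₀ the
standard unbalanced-design coefficient, negative between-components
truncated to 0. Method of moments (not REML) is used because it is the
closed-form, hand-checkable convention of the P_ST literature for this
design; the within component is *not* doubled because in a strictly
selfing diploid essentially all loci are homozygous and the additive
variance is not halved by heterozygosity. Confidence intervals resample
accessions with replacement within each subpopulation (percentile
2.5/97.5, default 1,000 resamples); wholly degenerate resamples (zero
total variance) are skipped and counted, with > 50% degenerate an
error. The verdict is `divergent_selection` iff the lower CI bound of
P_ST exceeds the genome-wide weighted F_ST of the same pair — the
P_ST ≫ F_ST rule — and `drift_compatible` otherwise. Under neutral
polygenic simulation the call rate stays near the nominal level, but
with only two subpopulations the between-population variance of any one
trait is a single drift realisation (χ²₁-like), so the verdict is a
screen, not a calibrated test; this is an intrinsic limit of
two-population Q_ST/P_ST comparisons, not of the implementation.

## Nucleotide diversity

Per subpopulation and region, π = Σ_sites [n/(n−1)]·2p̂(1−p̂) / L with n
the non-missing allele count at the site and L the full interval length
in bp; monomorphic sites contribute zero and invariant (non-genotyped)
sites are assumed monomorphic. π is additive over disjoint partitions
of a region when site sums are length-weighted. Intervals follow BED
(0-based half-open); VCF positions are 1-based; conversions happen only
at the parse boundary.

## GWAS post-processing

*Pruning* slides a window of 50 SNPs advanced by 5 along each sorted
chromosome; within a window any pair with r² above the bound loses its
later-by-position member until no violating pair remains, so the first
seen variant is retained. *The IL scan* regresses the trait on dosage
plus family indicator covariates (equivalently, Frisch–Waugh
residualisation on family means), with per-SNP listwise deletion of
missing dosages, a ≥ 2-carrier minor-allele requirement, and SNPs
collinear with family structure reported as missing with a reason —
this is what removes the donor-family confounding intrinsic to
introgression-line panels. The genome-wide threshold is 1/n over the
pruned (quasi-independent) SNP count. *Clumping* processes index SNPs
(p ≤ p1 = 1e-5) in ascending p order (ties by chrom, pos), gathering
members with p ≤ p2 = 1e-4 within ±2.5 Mb and r² ≥ 0.3 to the index;
without `allow_overlap` members are consumed; singleton bins are
dropped by default. *Gene windows* are closed on both ends after
flanking (a SNP exactly 200 kb from a gene edge is inside), with union
semantics across overlapping windows.

## λ gene-set enrichment

The subset ("reduced") and genome-wide p-value sets are BH-adjusted
*separately* — the two labels in the defining ratio are distinct
adjustments, and this choice makes λ exactly 1 when the subset equals
the genome; a pooled joint adjustment is available as an option.
Quantiles interpolate linearly between order statistics (the common
statistical default; the defining formula does not specify one). The
null distribution draws random subsets of the same size without
replacement and reports empirical_p = (1 + #{null ≥ observed})/(n_iter
+ 1). A genome whose adjusted p-values are all 1 has a zero denominator
and is rejected as degenerate. The 99th-percentile statistic is
computed per trait, not pooled across traits.

## Graphical genotypes

Within each sliding window (defaults 10 Mb window, 1 Mb step) accession
dosage vectors are clustered into exactly two groups — in an inbred
biallelic panel a local region carries essentially two haplotype
classes — using k-means with 10 restarts from a seeded RNG, best
within-cluster sum of squares winning; on fixtures of ≤ 12 accessions
the result matches the exhaustive best two-partition. Missing dosages
are mean-imputed within the window before clustering (the imputed
fraction is reported per window). The larger cluster is painted major,
ties resolved toward the cluster containing the first accession in
input order; empty windows are `no_data`, windows with a single
distinct vector are flagged single-cluster. Accessions are then ordered
by complete-linkage hierarchical clustering of Hamming distances
between their window-label vectors, ignoring `no_data` windows
pairwise. Complete linkage and Hamming distance are choices — the
clustering function itself does not prescribe them — made for
deterministic, tight clusters.

*Allelic stacking* counts, per accession, the designated (e.g.
wild-donor) alleles carried across the peak SNPs, one per locus
regardless of homozygosity (inbred lines); accessions missing any peak
genotype are excluded and counted. Groups are compared by one-way ANOVA
with Tukey–Kramer pairwise tests (studentized range; Kramer adjustment
for unequal group sizes) and a compact letter display, plus the linear
regression of trait on stack count to quantify additivity.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the analyses
assume, at defaults chosen to mirror a replicated greenhouse trial of a
selfing diversity panel:

- **Profiles**: mean length at scaled position x ∈ [0, 1] follows the
  cubic 3 + 75x² − 50x³ cm (a smoothstep from ~3 cm basal internodes to
  a ~28 cm peduncle — the inverse-S of a flowering culm), plus
  compartment offsets (+1.0/−1.5/+0.5 cm distal/central/proximal) that
  create the oscillation, a per-genotype N(0, 1 cm) effect shared
  across replicates, and N(0, 1 cm) per-internode residuals; lengths
  are floored at 0.1 cm (physical). Defaults: 200 genotypes × 4
  replicates, 5–9 nodes. Scaling positions to [0, 1] makes the trend
  node-number independent, matching the trisection logic.
- **Genotypes**: Balding–Nichols — subpopulation frequencies
  Beta(p(1−F)/F, (1−p)(1−F)/F) around a Uniform(0.1, 0.9) ancestral p,
  so Var = F·p(1−p) and the Weir–Cockerham estimate recovers F by
  construction (the calibration the tests exploit). Individuals are
  fully inbred at a locus with probability 0.98 (near-complete
  homozygosity of a strict selfer). Defaults: 2 × 100 accessions, 5,000
  SNPs, F = 0.1.
- **Traits**: subpopulation means are spaced to realise the requested
  between-group variance exactly (divisor k − 1), so generator moments
  match parameters rather than fluctuating χ²-style; Gaussian draws are
  available behind a flag.
- **P-value fields**: Uniform(0, 1) background with in-window values
  U^s, s ≥ 1 the enrichment strength (s = 1 reduces exactly to
  uniform); default s = 5 on 20,000 SNPs.
- **LD blocks**: per block a pool of distinct, everywhere-segregating
  haplotypes over {0, 2}; each accession carries one haplotype per
  block, independently across blocks — perfect within-block LD up to
  haplotype sharing, near-zero between-block r².

Every generator draws from a single `numpy` Generator seeded from its
config, and pipeline stages consume sub-seeds spawned deterministically
from the run seed, so equal seeds give bit-identical outputs.

What the generators do **not** emulate: recombination and LD decay
within blocks, allele-frequency spectra of real resequencing data,
selection, genotype-by-environment interaction, spatial field trends,
or phenotyping error structure beyond i.i.d. Gaussian noise. Passing
tests therefore certify the estimators and their calibration under the
assumed structure — not the biology of any particular panel.

## Problem sizes

Defaults throughout are desk-scale by design: 5,000-SNP panels, 200
accessions, 1,000 bootstrap/permutation iterations in production runs
and 200–300 in the Monte-Carlo test batteries (20–50 seeds each). These
sizes put every Monte-Carlo check within tight tolerance of its closed
form while the full suite runs in well under a minute.

## Known limitations

- The recurrence reading of the linear expectation and the exact
  moving-average window of the original trisection are not uniquely
  determined by their verbal descriptions; the choices above are fixed
  and documented, not claimed to be the only possible ones.
- The two-population P_ST ≫ F_ST verdict ignores the evolutionary
  (drift-realisation) variance of the between-group component; treat
  calls as screens.
- `graphical_genotype` forces k = 2; regions genuinely carrying three
  or more common haplotypes are painted by their best two-part merge.
- BH adjustment of the λ subset is internal to the subset: enrichment
  is measured relative to the subset's own size, which is the intended
  behaviour of the separate-adjustment definition.
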