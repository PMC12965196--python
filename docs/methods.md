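# Methods

This note documents the models, estimators and numerical choices behind
`landgen`, and what the synthetic-data generator does and does not
emulate.

## Genotypes and genetic distances

Genotypes are diploid dosages g ∈ {0, 1, 2} (copies of the alternate
allele) with −1 as the missing sentinel. VCF input goes through cyvcf2;
multi-allelic records are rejected by default or split into one biallelic
pseudo-SNP per alternate allele. PLINK ped/map text is read and written
directly; because ped/map does not record which allele is the reference,
the reader orients each locus alphabetically (first allele = dosage 0),
so round trips are exact whenever ref < alt lexicographically and loci
are polymorphic in the sample.

SNP filters follow common GBS practice for a high-selfing crop: sites
with **more than** 5 % heterozygous calls among non-missing genotypes are
removed (likely paralog collapse), and sites with MAF ≤ 0.05 are removed
(boundaries are strict in both cases: exactly 5 % heterozygotes is kept,
exactly 0.05 MAF is dropped).

Distances handle missing data pairwise-complete and rescale to the full
SNP count L (PLINK-style), keeping values comparable across pairs:

- **hamming** = Σ|g_i − g_j| over complete loci × L/L_complete
  (allele-count substitutions).
- **asd** — the quoted allele-sharing rule (two shared alleles 0, one 1,
  none 2; het–het 0) coincides per locus with |g_i − g_j| under dosage
  coding, so ASD is reported as the per-complete-locus mean, range
  [0, 2]. Hamming = L × ASD identically; both are provided because both
  conventions circulate.
- **euclidean** = sqrt(Σ(g_i − g_j)² × L/L_complete).
- **nei** = −ln I with Nei's standard genetic identity computed from
  per-individual allele frequencies {0, ½, 1}; a population-level
  measure applied to individuals, so values are coarse.
- **fst_wc_pairwise** — each individual is a "population" of one diploid.
  The Weir–Cockerham moment estimator is degenerate at n = 1 per group
  (its within-population individual level vanishes), so the defensible
  limit is used: the two-level allele ANOVA with per-locus
  MSB = (p_i − p_j)², MSW = p_i q_i + p_j q_j and
  θ = Σ(MSB − MSW) / Σ(MSB + MSW) across loci. Estimates are noisy, can
  be strongly negative (e.g. two identical heterozygotes), and are kept
  untruncated. The diagonal is NaN.
- **rousset** = θ/(1 − θ). The source convention is printed ambiguously
  in the literature this follows ("1/1 − F_ST"); the standard Rousset
  linearisation is used.

Pairs sharing zero non-missing loci give NaN with a warning.

## Climate covariates

Two fixed four-variable sets: temperature (seasonality, max of warmest
month, min of coldest month, mean of driest quarter) and moisture (annual
precipitation, precipitation of driest month, precipitation seasonality,
precipitation of warmest quarter). Precipitation of the driest month is
log(x + 1)-transformed (strongly right-skewed, zeros meaningful), then
every column is z-scored. Zero-variance columns are an error, since
standardisation is undefined.

## Travel-time model

Walking speed is Tobler's hiking function W(s) = 6·exp(−3.5·|s + 0.05|)
km/h, with s the **dimensionless gradient** dh/dx (not degrees — the
original formulation; the "−0.05° slope" phrasing found in applications
is treated as the gradient). Maximum 6 km/h at s = −0.05; flat ground
≈ 5.04 km/h. Sea travel emulates low-technology sailing at 1.54 m/s
(3 knots) = 5.544 km/h, 1.1× flat-land walking.

The conductance graph connects each raster cell to its 8 neighbours with
conductance = speed / geodesic distance between cell centres (reciprocal
hours). Distances use Vincenty's inverse on WGS-84, so diagonal steps and
latitude-dependent cell widths are exact rather than √2 shortcuts. Edges
are directed: the hiking function is anisotropic, and the uphill and
downhill edges of a slope differ. Land–sea transitions move at the
harmonic mean of the walking and sailing speeds (no explicit embarkation
model exists in the source workflow; the harmonic mean is the
slower-dominated choice and is configurable to the arithmetic mean).

Least-cost times come from Dijkstra on the edge-time matrix. The
pairwise travel-time matrix rounds coordinates to 0.25° first (co-located
samples share computed times), solves within-continent blocks from one
Dijkstra per unique source cell, and routes cross-continent pairs through
the waypoint minimising the summed two-leg time; unreachable waypoints
are excluded with a warning, fully unreachable pairs are +inf and are
dropped pairwise by downstream regressions. Because the symmetric
`PairwiseMatrix` container is the interchange type, the default output
averages the two directed times (`symmetrize="mean"`); `"none"` returns
the raw directed array.

Vincenty's iteration is run to 1e−12 with 200 iterations; the rare
non-convergent near-antipodal pairs fall back to the great-circle
distance on the authalic sphere and are flagged. Agreement with an
independent geodesic implementation is sub-metre on test pairs.

## MLPE model comparison

For pairwise response y_ij and predictor x_ij,
y_ij = β₀ + β₁x_ij + a_i + a_j + ε_ij with a ~ N(0, σ²_a) i.i.d. per
individual absorbs the non-independence of the m = n(n−1)/2 pairs.
The likelihood is maximised by ML (not REML — AICs must be comparable
across fixed-effect structures) over (log σ²_a, log σ²_e) with β profiled
out by GLS; the Woodbury identity reduces every solve to the n × n
matrix (σ²_e/σ²_a)I + ZᵀZ, so fits are fast at any m. Nelder–Mead from
two starts guards against local optima; σ²_a collapsing to the zero
boundary is flagged but kept. AIC = 2k − 2logLik with k = 4 (β₀, β₁,
σ²_a, σ²_e); fits are only ranked when they share the same response and
retained pair set, enforced through a stored pair-key. The SE of σ²_a
comes from the numerical Hessian of the profile likelihood via the delta
method.

The Mantel test uses the Spearman correlation of condensed upper
triangles, permuting rows and columns of one matrix jointly;
p = (#{r_perm ≥ r_obs} + 1)/(n_perm + 1), hence the 1/(n_perm + 1) floor.
Small-n exact enumeration over all n! permutations is available and is
used as the oracle in tests. The OLS R² over pairs is descriptive only
(pairs are not independent) and says so in its output.

## Hierarchical F-statistics

Allelic variance is partitioned over the nested hierarchy language
family > language > individual > allele by the method of moments on
allele indicators. Per locus, sums of squares between successive nesting
levels T_i − T_{i−1} (T_i = Σ_g S_g²/n_g with group allele counts n_g
from non-missing individuals only) are equated to their expectations;
the coefficient of σ²_j in E[T_i] is n for j at or above level i and
Σ_g Σ_{h⊆g} n_h²/n_g below, giving a small linear system solved per
locus (batched pseudo-inverse). Components are summed across loci before
forming ratios — the standard multi-locus ratio-of-sums — and slightly
negative components are kept untruncated for unbiasedness of the ratio.

A level with as many groups as its parent (e.g. one language per family)
has no replication; it is removed from the system and reported NaN. With
only the grouping level and individuals this construction *is* the
Weir–Cockerham estimator: the implementation reproduces the textbook
a/b/c components exactly on unbalanced data (tested).

Reported ratios: F(family/total) = σ²_F/σ²_T, F(language/total) =
(σ²_F + σ²_L)/σ²_T (cumulative, so languages ≥ families), and
F(language/family) = σ²_L/(σ²_T − σ²_F).

Samples are assigned to the geodesically nearest language point; exact
ties break by catalogue order and are flagged. The family filter keeps
families with strictly more than `min_languages` distinct assigned
languages (the wording being "more than five"; `strict=False` relaxes
to ≥).

## IBD sharing and its decay

Refined-IBD text (sample1, hap1, sample2, hap2, chrom, start, end, LOD,
cM) is parsed with per-line validation. Length bins are half-open —
[1, 3), [3, 5), [5, ∞) cM — because the printed convention "1–3, 3–5,
> 5" leaves boundaries unstated; sub-1 cM segments are discarded and
counts are conserved above 1 cM. Sharing x_ij = segment count / (4 ·
n_chromosomes): 2 × 2 haplotype pairs, chromosomes treated separately;
whether the source used the fixed 4-pair denominator or only observed
pairs is not printed, and the fixed denominator is adopted.

The decay model is log E[x_ij] = α_r + β_r d_ij over within-region pairs,
fitted as a Poisson GLM in the quasi-likelihood sense (the response is a
continuous mean count; IRLS accepts it). Prior weights default to the
pair's regional sample size, the most direct reading of "regional sample
sizes as weights"; `"none"` and scalar weights are available — a scalar
equal to 4·n_chromosomes is the exact precision of a mean count and gives
calibrated standard errors, which the tests use for CI checks. The
region-slope model is compared with the common-slope model by AIC and a
χ² likelihood-ratio test; regions with < 3 pairs are excluded with a
warning. Zero-sharing pairs stay in the regression.

For ordination, sharing maps to the distance 1/(1 + x) (equivalently
sqrt((1/(1+x))²)): monotone from [0, ∞) onto (0, 1], diagonal set to 0.

## Ordination and variance partitioning

PCNM eigenvectors: collapse duplicate locations (zero mutual distance),
truncate the distance matrix at the longest minimum-spanning-tree edge,
replace larger entries by 4× the threshold, Gower-centre −½D², keep
eigenvectors with positive eigenvalues, and propagate rows back to
duplicated samples. No forward selection is performed — all positive
vectors are used, matching workflows that report the full positive set.
Against vegan's `pcnm` the threshold, eigenvalue spectrum and vector
count agree to printed precision (frozen oracle test).

RDA is used through its coefficient of determination only: with Y centred
(not scaled — dosage units are commensurate) and X centred with collinear
columns dropped by pivoted QR, R² = ‖P_X Y‖²_F/‖Y‖²_F and R²_adj = 1 −
(1 − R²)(n − 1)/(n − m − 1). Variance partitioning fits all 2^k − 1
subset unions (k ≤ 4 sets: spatial eigenvectors, language-family
indicators with reference level dropped, temperature, moisture) and
solves the inclusion–exclusion system R_adj(S) = Σ_{T∩S≠∅} f_T for the
fraction components; by construction they sum to the full-model R²_adj,
are order-invariant, and can be slightly negative. Unique and shared
fractions match vegan's `varpart` indfract values on the frozen fixture.

Distance-based RDA converts the response distance matrix to principal
coordinates (Gower centring, positive eigenvalues kept, negative
magnitude logged; no Lingoes/Cailliez correction by default) and feeds
the coordinates to the same partitioning. On Euclidean self-distances
this reproduces plain RDA to < 1e−6 (tested).

## Wavelet dissimilarity

At focal location a and scale s km, the kernel over sample locations is
the difference of two Gaussians with bandwidths s and 2s, each normalised
to unit mass (zero total weight — a band-pass, Ricker-like filter). The
per-locus coefficient is the kernel-weighted sum of centred dosages
(missing calls mean-imputed per locus); dissimilarity(a, s) = ‖coeff‖₂
across loci / ‖kernel‖₂. Focal locations are the sample locations; the
scale grid is geometric by convention. Scales beyond the domain extent
are NaN with a warning. The exact kernel and normalisation of the method
this emulates are not published alongside it, so this implementation is a
documented, property-equivalent stand-in: it preserves band-pass
behaviour in scale (the arg-max scale tracks simulated patch size,
tested) rather than matching another code's numbers.

The null permutes the sample→location mapping (panmixia), recomputing
every curve; the global envelope uses conservative order-statistic
quantiles (2.5 %/97.5 % with lower/higher interpolation, so 19
permutations give min/max), and per-location three-state flags
(low/ns/high) compare each observed value with its own permutation
distribution at two-sided α. Flags are deterministic given the stored
draws.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical *structure* the analyses
consume, at desk scale (defaults: 150 samples, 800 SNPs, a 30 × 40 cell
1° raster ≈ 2 700 × 3 300 km, 6 language families × 8 languages, 10
chromosomes of 100 cM):

- **Landscape**: Gaussian-filtered noise (5-cell correlation length,
  0–2 500 m) with the largest connected low-lying component as a
  contiguous sea (default 20 % of cells).
- **Allele frequencies**: per locus, logit p follows a latent Gaussian
  field with exponential covariance exp(−d/migration_scale)
  (default 500 km, sd 1.5) around a Uniform(0.15, 0.85) base frequency —
  isolation by distance by construction. A fraction `language_effect`
  (0.15) of loci add N(0, 0.8) family-specific logit shifts;
  `climate_effect` (0.10) add ±0.8 logit clines along one climate
  variable.
- **Genotypes**: with probability F = 1 − het_rate/(2p(1−p)) (capped to
  [0, 1]) both alleles are copies of one draw, otherwise Binomial(2, p);
  the expected heterozygote fraction is ≈ `het_rate` (default 0.05, a
  selfing crop), then `missing_rate` (0.02) of calls are masked.
- **IBD segments**: simulated directly at segment level — per haplotype
  pair, chromosome and bin, counts are Poisson with log-mean log(rate) −
  d/decay (defaults: rates 0.05/0.02/0.01 per unit at d = 0 and decays
  1 500/900/600 km for the 1–3/3–5/> 5 cM bins, so recent ancestry decays
  fastest); lengths are drawn inside the bin (shifted exponential in the
  open bin) and positions mapped to bp through the linear 1 cM/Mbp map.
- **Determinism**: every stage draws from its own stream derived from
  `SimParams.seed`, so datasets are bit-reproducible and individual
  generators can be re-run independently.

Under these defaults the emulated study-level statistics land close to
the structure such analyses report on real landrace panels (global
Mantel r ≈ 0.4, pairwise R² ≈ 0.15–0.2, hierarchical F of a few percent
among families and ~13 % among languages) — a consequence of the chosen
effect sizes, stated here for orientation only; the tests assert
properties and parameter recovery, not these values.

Not emulated: realistic demography or coalescent linkage disequilibrium
(IBD is layered on independently of the SNPs), realistic climatology,
multilingual regions, river or desert-specific travel, and phasing/IBD
detection themselves (tables are parsed or simulated). Passing tests
therefore certify the estimators and their invariants, not the realism
of any particular biological scenario.

One generator interaction worth knowing: when the allele-frequency
correlation length is far below the domain extent, expected genetic
distance saturates with distance and the global Spearman Mantel
correlation weakens even though local isolation by distance is strong.
The recoverable monotone statistic in that regime is the OLS
isolation-by-distance slope, which the tests use for the
parameter-monotonicity checks.

## Problem sizes and numerics

Tests run the generator at 25–100 samples and 10–400 SNPs, grids up to
30 × 40 cells, 99–9 999 Mantel permutations and 100-replicate
calibration loops — sizes chosen so the full suite completes in about a
minute while every check retains power. Numerical tolerances: Vincenty
1e−12 rad with great-circle fallback; eigenvalue positivity cut
max(1e−8, 1e−8·λ₁); pivoted-QR rank tolerance 1e−9; MLPE convergence
1e−8/1e−10 (Nelder–Mead, two starts); MLPE variance floor flagged at
1e−8 of total variance. Ties: Spearman uses average ranks;
nearest-language ties break by catalogue order and are flagged;
half-open IBD bins place boundary lengths in the upper bin.
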