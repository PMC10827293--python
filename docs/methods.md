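# Methods

This note documents the models, estimators and numerical choices behind
driftscape, what the synthetic data generator does and does not emulate,
and the problem sizes at which the package's own test suite exercises the
methods.

## 1. f4 statistics and the clade test

For groups *A*, *B*, *C*, *D* with per-site derived-allele frequencies
p computed from (derived, called) allele counts, the f4-statistic is the
mean over usable sites of (p_A − p_B)(p_C − p_D). A pseudohaploid call
contributes one observed allele, a diploid call two; groups of size one
(individual-level tests) are allowed, in which case a site is usable only
where that individual has a call. An f4 *vector* over a right panel
(R₁ base, R₂ … R_k) uses a single complete-case mask — a site enters only
if every participating group has at least one called allele — so that all
components share one set of sites and one per-block bookkeeping.

**Block jackknife.** Sites are assigned to contiguous blocks of 5 Mb
physical span (configurable), never crossing chromosomes. Covariances use
the weighted delete-one-block (delete-m) jackknife of Busing and
colleagues: with block site counts m_b, total n, h_b = n/m_b, leave-one-out
estimates θ₍₋b₎ and pseudovalues τ_b = h_b θ̂ − (h_b − 1)θ₍₋b₎,

  Cov = (1/B) Σ_b (τ_b − θ̃)(τ_b − θ̃)ᵀ / (h_b − 1).

For equal blocks this reduces to the classic (B−1)/B scatter formula. The
implementation is validated against a literal leave-one-block-out
recomputation to 1e−10 relative.

**Clade test.** T = vᵀ Σ⁺ v with Σ⁺ a pseudoinverse at relative tolerance
1e−8; the effective degrees of freedom are rank(Σ) (k−1 in regular cases);
p is the upper χ² tail and d = −log₁₀(max(p, 1e−320)) — the floor keeps d
finite for clustering. The χ² form (rather than a Hotelling/F correction)
is adequate here because fixtures carry many blocks relative to the vector
dimension (≈ 600 blocks vs 7 dimensions): the measured type-I error of the
d > 1.3 cutoff under a panmictic null is 0.05 within Monte-Carlo error.
With few blocks (tens) the χ² tail would be anti-conservative; the block
count, not the site count, is the quantity to watch.

Tests with fewer than 500 usable sites error out; below 5,000 a warning is
emitted (both configurable). The two-component fit estimates
α̂ = (XᵀΣ⁺y)/(XᵀΣ⁺X) with y_j = f4(T, S₂; base, R_j),
X_j = f4(S₁, S₂; base, R_j), residual statistic (y − α̂X)ᵀΣ⁺(y − α̂X) on
k − 2 degrees of freedom, and errors out when XᵀΣ⁺X is numerically zero
(the sources form a clade and carry no contrast).

## 2. Outlier workflow

Defaults: clustering cutoff d = 1.3 (nominal p = 0.05); clade validity
threshold p = 0.01 for both within-region absorption and cross-region
sources (the same threshold is reused for model-competition rejection);
candidate rule: cluster size ≤ 2 **or** strictly below 5% of the region
total. The region total counts clustered individuals whose period falls in
the Bronze-Age-to-Early-Modern window; clustering itself spans Copper Age
up to (excluding) Present-day. Outlier proportions use the same window in
numerator and denominator.

Cluster-level tests pool member allele counts into one pseudo-population,
which is what gives the absorption and source steps more power than
individual-level tests. UPGMA uses scipy's average linkage; untestable
pairs (below the site minimum) are imputed at the maximum observed d + 1
and flagged. Model competition moves one rival source at a time into the
right set and drops a source whose model is then rejected — this
eliminates sub-optimal sources but deliberately does not pick a single
best one. Period prioritisation keeps same-period sources if any exist,
else those of the nearest earlier period; if only later-period sources
remain, none can be prioritised and all are kept. The sex check is a
Pearson chi-square (no continuity correction) of sex against
{non-outlier, outlier with source, outlier without source}, df = 2.

## 3. Spatial FST and the bootstrap

Hudson's estimator with unequal-sample-size correction is combined across
sites as a ratio of sums; a site requires at least two called alleles on
each side (the n−1 correction needs n ≥ 2), and negative multi-site values
are reported as-is (the estimator is unbiased around zero). Grid cells are
10° × 10°, anchored at (−180°, −90°), slid 1° north-east nine times; cells
need ≥ 2 samples. Distances are haversine at Earth radius 6371.0088 km
(or plain euclidean for simulated habitats). The grid does not wrap:
samples within half a cell of the antimeridian are excluded with a
warning, which is harmless for a Europe/Mediterranean study area.

Lowess uses statsmodels with span 0.67 and 3 robustifying iterations,
evaluated by interpolation on 100 equally spaced distances. The spatial
bootstrap groups populated cells into connected components of the overlap
graph (cells overlap when both coordinate intervals intersect with
positive length) and resamples components with replacement, a point
entering a replicate once per joint inclusion of its two components. With
spatially dense sampling the whole map can form one component; the
procedure then degenerates (a warning is emitted and bands narrow), which
is an inherent limitation of overlap-aware resampling rather than an
implementation artefact.

## 4. PCA and projection

Reference genotypes are mean-imputed (references are assumed high-quality,
so imputation touches little), monomorphic sites dropped, and each site
centred by its reference mean genotype μ and scaled by
sqrt((μ/2)(1 − μ/2)) — unit drift variance. Outlier screening runs up to
5 iterations, removing any reference beyond 6 standard deviations (per-PC
SD over currently retained references) on any of the first 10 PCs and
refitting from scratch. Loadings are sign-fixed so each column's
largest-magnitude entry is positive, making orientations reproducible.

Least-squares projection solves the normal equations restricted to a
sample's observed sites; with no missingness this equals the direct score
projection exactly. Pseudohaploid inputs are overdispersed relative to
diploid references (a single sampled allele doubles the sampling variance),
which inflates projected coordinates radially but preserves which side of
an axis a genome falls on; no shrinkage correction is applied. Samples
need ≥ 1,000 shared non-missing sites by default. Simulated cohorts use
plain (non-probabilistic) PCA via scikit-learn's arpack solver after a
MAF ≥ 0.01 filter, with the same 6-SD/5-iteration screen.

## 5. Continuous-space simulator

One population of exactly N diploids on the unit square, non-overlapping
generations. Per generation: competition c_i = Σ_j k_comp(d_ij) (self
excluded; Gaussian kernel, max distance 0.3, strength 3, σ = 0.1) sets
fitness 1.1 − c_i/N floored at zero; mothers are drawn proportional to
fitness; a father is drawn around each mother with weights from the mate
kernel (max distance 0.1, strength 1, σ = 0.02; a mother with no candidate
in range is redrawn, capped at 1,000 rounds); offspring genomes are built
with Poisson crossovers (rate r_per_bp × genome length per meiosis,
uniform positions) and symmetric site flips at mu_per_site; offspring are
placed at the mother's position plus an isotropic Gaussian displacement
(SD σ_disp), reflected at the habitat boundary.

Long-range dispersal replaces the displacement, with probability p_lr, by
a Gaussian with SD σ_lr rejection-sampled beyond
r99 = σ_disp·sqrt(2 ln 100), the radial 99% quantile of the base kernel —
so p_lr is the fraction of offspring that genuinely leave the local
neighbourhood.

**Initialisation.** Deep history is approximated by standing variation:
site frequencies drawn from the neutral SFS (density ∝ 1/x on
[1/2N, 1 − 1/2N]), alleles assigned exchangeably per haplotype, followed by
a burn-in with p_lr = 0. Generation 0 therefore has no spatial structure
by construction, and all spatial differentiation observed later is built
by the dispersal/mating kernels during burn-in. This replaces a
coalescent completion of the genealogy; it preserves the quantity under
study (spatial differentiation of segregating variation) but not the
fine-scale allele-frequency spectrum or linkage structure of a coalescent
history.

**Measurement.** Spatial FST is computed between cells of a fixed 10×10
habitat grid (MAF ≥ 0.01 at measurement time, ratio of sums throughout).
The summary "fst_max" is the pooled Hudson ratio over the farthest
*quartile* of cell-pair distances (fst_min: nearest quartile): the single
farthest equal-width band contains only the few corner-to-corner pairs and
fluctuates several-fold more between generations, which would swamp both
calibration and trend detection at desk-scale N. The band table itself is
still produced for FST–distance profiles.

**Calibration and scale.** The package defaults are desk scale (N = 2,000,
20k sites on 2×10⁷ bp, mutation and recombination 2.5×10⁻⁷ = 10⁻⁸
scaled ×25, 2,000 burn-in generations). Far-distance FST scales roughly as
1/(σ_disp²·N), so matching the empirical target FST ≈ 0.03 at small N
requires larger dispersal than at realistic N; the calibration grid search
therefore spans σ_disp ∈ {0.10, 0.14, 0.18} × N ∈ {500, 1,000}, where the
points (500, 0.14) and (1,000, 0.10) both achieve ≈ 0.030. The test suite
runs this grid at 2,000 sites and 600 burn-in generations (equilibrium of
the far-quartile FST is reached after roughly 300–400 generations at these
parameters), averaging the last five recorded snapshots to damp drift
fluctuation.

**Long-range scenarios.** The meaningful condition for the long-range
phenomenon is the *scale separation* σ_lr ≫ σ_disp (10× at the empirically
motivated parameterisation σ_disp = 0.02, σ_lr = 0.20, which the SimConfig
defaults retain). Desk-scale calibration inflates σ_disp, so scenario runs
set σ_lr = 10 × the calibrated σ_disp to preserve that separation;
keeping σ_lr = 0.20 against a calibrated σ_disp ≈ 0.1 would make
"long-range" jumps indistinguishable from base dispersal and abolish the
effect. Scenarios share one burned-in state per seed across
p_lr ∈ {0, 0.04, 0.08} (matched seeds); the endpoint is the mean of the
last five snapshots. Because mixing at desk scale equilibrates within a
few tens of generations, trajectories are step-then-plateau; declines are
therefore judged by final-versus-initial comparisons across seeds, with
the one-sided Mann–Kendall test reserved for the p_lr = 0 flatness
control, where its conservativeness is the desired property.

## 6. Synthetic data

Allele frequencies drift along a rooted tree under the Balding–Nichols
model: child ~ Beta(p(1−F)/F, (1−p)(1−F)/F), giving E = p and
Var = F·p(1−p); fixed frequencies stay fixed. Closed-form moments provide
the oracles: between two leaves with branch parameters F₁, F₂ from a
shared ancestor, the Hudson ratio-of-sums converges to (F₁+F₂)/2 (the
numerator collects both branch variances, the denominator stays at the
cross heterozygosity), and f4 expectations equal shared-branch overlaps.

The standard workflow fixture has six regional leaves (pendant drift
0.01–0.05) hanging from a backbone with 0.03 drift per segment, and eight
right populations on long branches (0.1–0.3) attached at *staggered*
backbone depths. The staggering is essential: if all rights were pure
outgroups to the regional clade, every pair of regional leaves would form
a formal clade with respect to the panel and the clade test would have no
power by construction. Root frequencies are Uniform(0.05, 0.95) to keep
sites informative after drift. Study individuals are pseudohaploid with
per-individual missingness Uniform(0.15, 0.85), emulating the wide
coverage spread of ancient genomes; reference individuals use 5%
missingness (references are typically high-quality). Sites are laid out
over 22 chromosomes of ≈135 Mb, giving ≈600 jackknife blocks of 5 Mb.
Planted migrants draw genotypes from a source leaf three backbone segments
away but carry sink-region metadata; ground truth is recorded per
individual.

What the generator does **not** emulate: linkage (sites are independent,
so the block jackknife is exercised structurally, not against real LD),
sequencing damage or contamination, reference bias, admixture gradients
within regions, or sampling-density imbalance. Passing recovery tests
therefore demonstrate the statistical machinery under the stated drift
model, not robustness to those real-data complications.

The null-calibration experiment (also the reproduction script) uses 1,000
replicate pairs at 20k sites with fixed 40% missingness per individual —
in the range of the per-sample coverage spread of pseudohaploid ancient
panels — drawn from one leaf whose frequencies (and the right panel) are
fixed per run, making each replicate an exact conditional null.

## 7. Problem sizes used by the test suite

Unit tests run at hundreds to tens of thousands of sites and N ≤ 500.
The study-level tests use: calibration grid 6 points × 600 generations at
2,000 sites; LRD scenarios 5 seeds × (600 + 3×120) generations; the
structured-PCA run N = 1,000 at 4,000 sites; clade-test calibration 1,000
replicates at 20k sites; end-to-end recovery on the 288-sample × 50k-site
fixture. These sizes were chosen so each experiment's Monte-Carlo error is
small against its acceptance band while the full suite stays in the tens
of minutes on one CPU; the full-scale parameterisation (N = 50,000,
10⁸ bp) is supported by the same code paths but not exercised routinely.

## 8. Known limitations

- The clade test's χ² calibration degrades when tests run with few
  nonempty blocks (very high-missingness pairs); the site minimum guards
  the worst cases but a Hotelling-style correction would be principled at
  low block counts.
- Exact numerical agreement with admixtools/qpAdm is not claimed: block
  layout, covariance weighting and inversion tolerances differ in
  unpublished details.
- The spatial bootstrap is degenerate under dense uniform sampling (one
  overlap component).
- Pseudohaploid overdispersion in PCA projection is uncorrected (no
  shrinkage adjustment).
- The simulator's desk-scale calibration trades dispersal scale against N;
  conclusions about absolute dispersal distances do not transfer across
  scales, only the calibrated FST regime and the dose–response ordering do.
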