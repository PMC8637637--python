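# Methods

## Model and estimation

### Latent-normal mixed correlations

Every binary or ordinal indicator is treated as a discretization of a
standard normal latent variable. Thresholds are the normal quantiles of the
(weighted) cumulative category proportions, τ_k = Φ⁻¹(Σ_{j≤k} p_j). Pairwise
correlations are then estimated in two steps: thresholds are fixed from the
univariate margins, and ρ maximizes the multinomial likelihood whose cell
probabilities are bivariate-normal rectangle probabilities (polychoric), or
the conditional ordinal-given-continuous likelihood after standardizing the
continuous member (polyserial). Two-step estimation rather than full joint
ML matches the dominant practice in the psychometric software this field
relies on; the efficiency loss is negligible at survey sample sizes.

Numerical choices:

* Rectangle probabilities use the Owen's-T identity for the bivariate normal
  CDF (`scipy.special.owens_t`), accurate to well below 1e−8 over
  |ρ| ≤ 0.999; the unit tests verify it against scipy's Genz algorithm.
* The 1-D likelihood is maximized by bounded scalar minimization on
  [−0.999, 0.999] with xatol 1e−6; estimates are clamped to ±0.999.
* Any contingency table containing a zero cell receives a +0.5 continuity
  correction on every cell before likelihood evaluation, preventing boundary
  divergence for perfectly concordant tables.
* Observation weights enter as fractional cell counts (polychoric) or
  weighted log-likelihood terms (polyserial).
* If the optimizer fails, the pair falls back to the Pearson correlation of
  the integer codes and the fallback is recorded in the method labels.

Pair dispatch: ordinal–ordinal → polychoric (binary is two-category
ordinal, counts use their sorted distinct values as categories);
ordinal–continuous → polyserial; continuous–continuous → Pearson. How a
continuous crowding variable should enter a "polychoric" matrix is genuinely
open; polyserial is the default, and a `continuous_handling="quintile"`
switch discretizes it into weighted quintiles for the fully-polychoric
alternative.

The assembled matrix is forced symmetric with unit diagonal. If its smallest
eigenvalue is negative (possible because pairwise estimates need not be
jointly consistent), negative eigenvalues are clipped to zero, the matrix is
reconstructed, and the diagonal rescaled to 1 — a minimal-change repair,
recorded (`psd_adjusted`, original smallest eigenvalue) so users can audit.

### Harmonized index

Eligible assets are those collected at every wave or missing from at most
one wave. For participants, a missing eligible-asset value is imputed by
carrying forward the household's preceding-wave value when it participated
there, otherwise by the wave's cross-sectional mode; at the first wave only
the mode rule can apply. Mode ties break toward the lower (less wealthy)
category, deterministically. A wave with no observed value at all falls back
to the nearest earlier wave's mode (logged). Non-participant waves remain
missing and are never scored.

Each participating household-wave is one pooled observation row. The index
is the leading eigenpair of the mixed correlation matrix: loadings are the
eigenvector scaled by √λ₁ and the variance share is λ₁/p. Eigenvector signs
are arbitrary, so the component is oriented to give a configured anchor
asset (by default the first asset declared `orientation_hint="positive"`) a
nonnegative loading.

Scoring maps asset values to numeric codes — binary 0/1, ordinal/count
integer ranks, continuous raw — z-scores every code against its pooled mean
and SD, forms the loading-weighted sum, and standardizes the result by the
pooled raw-score mean and SD. Pooled fitted scores therefore have mean 0 and
SD 1 by construction, and standardized scores are invariant to positive
rescaling of the loadings. Integer-coded standardized scoring is one of two
defensible conventions (the other scores through the estimated thresholds);
it is the dominant one and the rank-equivalence checks validate it against
per-wave cross-sectional practice. Pooled (rather than first-wave)
standardization fixes the score unit.

### Validation battery

* Per wave, a cross-sectional index is fitted with the same machinery on
  that wave alone: either the same common-asset set after deleting
  zero-variance assets, or all assets collected at the wave after a
  near-zero-variance filter (modal category share > 0.95 — the binary 95:5
  prevalence rule, generalized to ordinals as modal share). Agreement with
  the harmonized score is summarized by Spearman rank correlation over the
  wave's households; loading similarity by the Tucker coefficient of
  congruence φ = Σaᵢbᵢ/√(Σaᵢ²Σbᵢ²) with labels same (>0.95), high
  (0.90–0.95), moderate (0.85–0.89), low (<0.85).
* Urban/rural stratified cross-sectional indices are fitted when a stratum
  column is present. Any cell with fewer than 30 participants is suppressed
  (reported missing), not zeroed.
* Construct validity: per-wave Pearson (and, for robustness, Spearman)
  correlation of the index with external measures (schooling, height-for-age
  z at 24 months, adult BMI), restricted to households that participated in
  the adulthood (final) wave; cells report n and need ≥3 complete pairs.
* Distribution diagnostics: clumping fraction 1 − (#distinct values)/n, and
  advisory floor/ceiling truncation flags that fire when a single extreme
  distinct value holds >5% of households. The underlying practice is visual,
  so the per-wave histogram is always exported alongside the flags.

### Sensitivity suite

Every variant is compared to the benchmark by Spearman correlation over the
household-waves scored under both.

* Leave-out: each single asset, each single wave, optionally each
  (asset, wave) pair; drops leaving <2 assets or <2 waves are skipped with a
  log entry.
* Inverse-wave-size weighting: observation weight 1/n_wave in the
  correlation estimation; with equal wave sizes this reproduces the
  benchmark exactly.
* Alternate extractions: (i) PCA on the Pearson matrix of binarized
  indicators; (ii) single-factor EFA by iterated principal-axis factoring
  (SMC start, tolerance 1e−6, ≤100 iterations, Heywood communalities clamped
  to 1 and flagged) on the mixed matrix of raw codes or the Pearson matrix
  of binarized codes; (iii) MCA — SVD of the standardized residuals of the
  full disjunctive indicator matrix, first-dimension row principal
  coordinates, constant categories dropped, no inertia correction since only
  the first dimension is used. Binarization: ordinal top-category vs rest,
  crowding > 0.75 rooms per member, counts above the pooled median (an
  extension; the original convention had no counts on this path), binary
  unchanged. EFA on the polychoric matrix uses raw ordinals; the
  Pearson/MCA paths use binarized data.

## Synthetic cohort generator

Latent wealth follows w_ht = α_h + β_h·t + δ_t + ε_ht with household
intercept α ~ N(0, σ_α²), slope β ~ N(μ_β, σ_β²) over the 0-based wave
index, additive secular trend δ_t, and occasion noise ε ~ N(0, σ_ε²). A
binary asset j is owned when λ_j·w + √(1−λ_j²)·u > τ_jt; ordinal variables
use K−1 ordered cuts of the same latent; crowding is an affine map of its
latent value, rooms = clip(0.75 + 0.35·c*, 0.05, 2.0) — centred on the 0.75
rooms-per-member binarization cut, values in (0, 2]. Schooling is drawn once
per household with correlation ρ_s to the standardized intercept and mapped
to 0–18 years; haz/BMI and an urban/rural stratum are generated analogously
as construct-validity targets.

Defaults define the study conditions used throughout the tests and the
acceptance script: 2000 households, 5 waves (1990–2018), ten binary assets
with loadings 0.55–0.80 of which two are negative (−0.50, −0.55; the
radio/livestock pattern), one Low/Medium/High housing variable (λ = 0.70,
cuts −0.4/0.6), crowding loading 0.6, σ_α = 0.8 and σ_ε = 0.6 so wave-1
latent SD is 1, secular trend (0, 0.25, 0.5, 0.75, 1.0) SD units, binary
thresholds spread over [−0.3, 1.2] with a −0.05/wave diffusion drift on
positively-loaded assets, ρ_s = 0.5, and 10% per-wave monotone MCAR dropout
(a MAR option with a wealth-dependent logit is provided, since real cohorts'
attrition mechanisms are not identified — neither is privileged).

Seeding: one master seed feeds `numpy.random.SeedSequence`; child streams
are spawned in a fixed order (household effects, occasion noise, binary,
ordinal, crowding, schooling, externals, attrition), so output is
byte-reproducible and adding a stream cannot disturb earlier ones.

What the generator does *not* emulate: spatial clustering, household
splitting/merging and individual moves between households, item-level
informative missingness, asset-specific measurement error, and real cohorts'
idiosyncratic instrument changes. Passing recovery tests therefore shows the
machinery is correct under the stated latent model, not that any particular
real cohort satisfies that model.

## Problem sizes and tolerances in the test suite

Unit tests run on 500-household panels and targeted micro-panels; the
acceptance-style checks regenerate the full 2000-household default cohort.
Polychoric calibration uses 200 tables of n = 5000 across
ρ ∈ {−0.5, 0, 0.3, 0.6, 0.9} in 2×2 and 3×3 layouts, compared to a
grid-search likelihood oracle (coarse 0.01 grid refined to 0.001 around the
coarse maximizer; the profile likelihood is unimodal in ρ, so the two-stage
search attains the full fine-grid maximizer). Monte-Carlo assertions use
±3–3.5 standard-error bands; exact identities (eigen share, standardization,
weight invariance) are asserted at 1e−8–1e−12.

## Known limitations

* Two-step polychoric estimates are not guaranteed jointly PSD; the clipping
  repair changes off-diagonals slightly when triggered, and is therefore
  recorded rather than silent.
* Carry-forward imputation assumes short gaps; a household absent for many
  consecutive waves is effectively mode-imputed.
* The score scale is relative and cohort-specific by design: no absolute
  wealth calibration is attempted.
* Tucker congruence is computed over the shared surviving assets only; when
  the cross-sectional fit drops zero-variance assets the comparison excludes
  them.
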