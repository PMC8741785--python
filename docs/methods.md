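# Methods

## The model

A consumer's bulk isotope value is modelled as the sum of the local
environmental baseline and a trophic offset:

    δ_consumer(x) = δ_base(x) + λ · Δn + ε,

where δ_base is the soil isotope surface at the consumer's location x, λ the
trophic position, Δn the per-trophic-level discrimination factor, and ε the
non-spatial residual (individual variation, short-term weather response,
measurement error). The analysis inverts this: estimate δ_base by ordinary
kriging of soil point samples, deduct it, and treat what remains as the
ecological signal. The package's statistics then ask one question — does the
deducted (corrected) dataset carry a stronger, cleaner signal than the raw
one?

## Isoscape estimation

**Semivariogram.** The empirical semivariogram uses the classical Matheron
estimator, γ̂(h) = (1/2N(h)) Σ (z_i − z_j)², on 12 equal-width lag bins up to
half the maximum pairwise distance by default. Bins report the *mean pair
distance*, not the bin midpoint: on gridded or clustered geometries the
midpoint misstates where the pairs actually sit, which visibly biases the
short-lag fit. Empty bins are dropped.

**Model fit.** Spherical, exponential and Gaussian families are supported;
γ(0) = 0 by convention, with the nugget c0 entering as the h → 0⁺ limit.
Parameters (c0, c, a) minimize weighted least squares with Cressie weights
N(h)/h², via bounded trust-region least squares from four range starts
(0.25, 0.5, 0.9, 1.5 × the maximum lag); the best converged start wins and
total failure raises rather than returning silent defaults. A fit with
partial sill below 10⁻⁶ of the total sill is flagged as pure nugget (range
unidentified). Noise-free self-consistency (bins generated exactly from a
spherical model) recovers all three parameters to ≈ 10⁻¹³ relative error,
far inside the 1 % contract.

**Kriging.** Ordinary kriging is global: all samples enter every system.
With ~10² soil samples the augmented matrix is factorized once (LU) and
reused for every target, so there is no search neighbourhood and none of its
artefacts. Weights satisfy Σw = 1 by construction (checked to 1e-8 in
tests); with zero nugget the predictor interpolates exactly. Kriging
variances that come out very slightly negative (below ~10⁻⁶ of the sill, a
rounding effect when a target coincides with a sample) are clamped to zero
with a warning; substantially negative values raise. Duplicate sample
coordinates make the system singular and are rejected with a pointer to the
averaging helper (`dedupe_samples`). Rasters are written as ESRI ASCII grids
(NODATA −9999), one file per layer.

**Baseline at consumer locations.** The reference route kriges at the exact
coordinates from the fitted model; a raster route reads the containing cell
of a precomputed grid and records the approximation. Points outside the soil
sample bounding box are still predicted but flagged as extrapolation.

## Correction and aggregation

The correction is a plain element-wise deduction — no rescaling — so it is
lossless: uncorrected = corrected + baseline to machine precision, and any
constant shift of consumer and baseline together cancels. Trophic position is
λ = (δ¹⁵N_consumer − δ¹⁵N_base)/Δn as the deduction-only form; an additive
variant (adding the baseline's own trophic level) exists but is not the
default, since soil is here a reference surface rather than a diet item.

Repeated hair samples from one genotyped individual are collapsed to their
unweighted mean (avoiding pseudo-replication); the individual's sett, class
and coordinates come from its modal sett. A genotype spanning several land
classes is treated as a data error by default (override assigns the modal
class). Weather attachment takes the nearest station by Euclidean distance
(ties to the lowest station id) and averages the five daily variables over
days −14…−1 before collection, inclusive; any gap in that window is an error
naming the sample and missing dates.

## Evaluation statistics

* **OLS** of δ¹⁵N on δ¹³C; R² = 1 − SS_res/SS_tot (orientation-free for the
  simple regression, and invariant to constant shifts — so the correction can
  only change R² through a *spatially varying* baseline, which is exactly the
  claimed mechanism).
* **Weather PCA** on the correlation matrix of the five 14-day means —
  correlation, not covariance, because the variables mix °C, mm and hours.
  Signs are fixed by convention: PC1 positive with mean temperature, PC2
  positive with rainfall.
* **K-means** on z-scored (elevation, δ¹³C, δ¹⁵N) — unstandardized, metres
  would dominate. K is chosen by mean silhouette over k = 2…10 with 25
  restarts per k (the elbow/WSS curve is reported for inspection only);
  clustering quality is summarized by a land-class crosstab.
* **Penalized cubic regression spline** per isotope × covariate: 10 uniform-
  knot cubic B-splines, exact ∫(f″)² penalty (2-point Gauss per knot
  interval — exact for the piecewise-linear second derivatives), smoothing
  parameter by GCV on a 65-point log grid. The penalty null space is the
  linear functions, so λ → ∞ reproduces the OLS line and the spline's
  deviance explained can never fall below the OLS R². GCV ties (numerically
  perfect fits) resolve toward the heaviest smoothing, so exactly linear data
  collapse to effective df 1. The smooth is tested against the intercept-only
  model with a Wald-type F using the effective df (tr S − 1) as numerator df
  — an approximation in the spirit of standard GAM software, whose exact
  p-values are package-specific and not claimed. Unpenalized linear-term fits
  ("correlating" rather than smoothing) are reported alongside.

No multiple-testing correction is applied across the smooth table, matching
common practice for descriptive GAM tables.

## The synthetic study system

The generator emulates a regional survey: a 40 × 40 grid of 1 km cells
holding seven contiguous land-class patches (one Voronoi cell each, classes
A–G from lowland farmland to high uplands) with elevation = class mean +
smoothed noise; soil δ¹³C and δ¹⁵N as independent stationary Gaussian random
fields (exact Cholesky simulation of the cell-centre covariance; spherical,
nugget 0.05, partial sills 0.5 / 0.9 ‰², range 15 km; means −28 / +5 ‰);
115 soil point samples at distinct cell centres; five weather stations with
a linear Feb→Apr warming trend, station offsets, daily noise, and a snow
event (Feb 20 – Mar 5) that depresses temperature by 6 °C and cuts sunshine;
and 40 setts (excluding the highest class — mountains are not badger
habitat) × 2 genotyped individuals × 3 hair samples.

Consumer values invert the trophic model: per-individual
λ = λ(class) + N(0, 0.12) — individual foraging strategies are *trophic*
variation, moving both isotopes together along the enrichment slope — plus
per-isotope individual residuals (SD 0.15 ‰), a weather response
proportional to the 14-day temperature anomaly (0.15 / 0.20 ‰ per °C for
C / N), and measurement noise (SD 0.1 ‰, the usual analytical precision).
Class trophic levels put the lowland Lakelands/Central Lowlands highest
(λ 2.8 / 2.7) and uplands lowest (1.8–2.0), i.e. protein-richer lowland
diets. Δn defaults: 3.4 ‰ (N) and 1.0 ‰ (C), conventional literature values.
All generators are pure functions of (config, seed); the truth table records
each individual's λ, effects and exact baseline.

**What the generator does not emulate.** Real soils are not stationary
Gaussian fields (geology imposes trends and sharp boundaries), real tissue
integrates diet over a turnover window rather than a point date, hair traps
have capture biases, and genotyping has error; land-class patches are convex
here. Passing tests therefore demonstrate that the *method* behaves as
designed under its own assumptions — unbiased baseline recovery, calibrated
trophic-position estimates, a reproducible signal-sharpening effect — not
that any particular field dataset will show effects of the same size. With
the default conditions the corrected-vs-uncorrected R² improvement appears in
roughly 19 of every 20 replicates; the absolute R² levels are below those a
real survey might report because the synthetic per-isotope noise is applied
independently of class structure.

## Numerical choices and degenerate inputs

Fixed seeds make every stage bit-reproducible (rerunning the pipeline with
one config gives byte-identical reports; the run metadata records seed and a
config hash). Field simulation adds 10⁻¹⁰·sill of diagonal jitter for
factorization stability and raises on genuinely non-positive-definite
covariances — no eigenvalue clipping. A zero-total-sill model yields a
constant field. Constant response in a smooth returns deviance 0 with a
degenerate flag; fewer distinct x values than basis functions shrink the
basis with a warning. Sizes throughout (100-replicate Monte Carlo, 40 × 40
kriging grids, 25–200 K-means restarts) were chosen as the smallest that make
the Monte-Carlo contracts statistically meaningful.

## Known limitations

Global kriging scales as O(n³) in soil samples and is intended for ≤ a few
thousand points; anisotropy, universal/co-kriging and geographic projections
are out of scope (coordinates are planar metres). The smooth-term F test is
approximate; use it comparatively (uncorrected vs corrected), not as an exact
significance machine. Silhouette-based K selection favours coarse partitions
on smoothly varying data, so the selected K on synthetic data (typically 2:
upland vs lowland) is smaller than the K a more fragmented real landscape can
support.
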