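# isobase

Soil-isoscape environmental baselines for consumer stable-isotope data.

## The problem

Bulk δ¹³C and δ¹⁵N values of a consumer's tissue mix two signals: the
trophic signal (what the animal ate, and at what trophic level) and the
isotopic composition of the local environment underneath its food web. Over a
region with heterogeneous geology, land use and climate, the environmental
part varies in space and masks the ecological part. For omnivores sampled
across a whole region — here, European badgers (*Meles meles*) whose hair was
collected at setts spread over a mosaic of seven land classes — classical
mixing models struggle because food sources overlap isotopically and the
population spans many local baselines.

`isobase` implements the alternative: interpolate soil δ¹³C and δ¹⁵N point
samples into continuous **isoscapes** by ordinary kriging, read the kriged
**environmental baseline** at each consumer's location, and deduct it,

    δᶜᵒʳʳ = δ_consumer − δ_base(x, y),

estimating trophic position as

    λ = (δ¹⁵N_consumer − δ¹⁵N_base) / Δn,

with Δn the per-trophic-level discrimination factor (default 3.4 ‰ for N,
1.0 ‰ for C). Whether the deduction sharpens the ecological signal is then
quantified by paired statistics on the uncorrected and corrected datasets:
the δ¹⁵N ~ δ¹³C regression R², K-means clustering of (elevation, δ¹³C, δ¹⁵N)
with silhouette-based K selection, and penalized-spline smooths (GAM-style,
GCV-chosen smoothing) of each isotope against date, elevation and two weather
principal components (PC1 "Temperature", PC2 "Climate").

Because no field data ship with the package, a first-class synthetic module
generates the whole study system — landscape, spatially autocorrelated soil
fields, weather with a late-winter snow event, and genotyped repeated hair
samples — from the generative model the correction assumes, together with a
truth table so every stage has a recovery target.

## Worked example

The numbered scripts under `analysis/` run the study end to end and write
everything under `results/`:

```sh
python analysis/01_simulate.py     # soil/hair/weather/truth tables
python analysis/02_isoscape.py     # variograms, LOO-CV, kriged rasters
python analysis/03_correct.py      # baseline deduction + weather PCA
python analysis/04_evaluate.py     # uncorrected vs corrected comparison
python analysis/05_replicates.py   # 100-replicate Monte Carlo
```

Stage 2 reports the fitted variogram and the leave-one-out quality of the
baseline surface (seed 1):

```
d15N: spherical variogram nugget=0.068 partial_sill=1.024 range=24.0 km (WLS objective 7.04e-08, 12 bins)
  leave-one-out RMSE 0.501 permil, mean standardized error +0.011
```

i.e. the kriged δ¹⁵N isoscape predicts held-out soil samples to about half a
per-mil, with no systematic bias. Stage 4 prints the headline comparison:

```
hair (all samples): R^2 0.170 -> 0.370 (improved); K 2 -> 2
individual (genotype means): R^2 0.077 -> 0.258 (improved); K 2 -> 2
corrected F larger in 7/8 smooths
```

Deducting the baseline roughly doubles the covariance between the two
isotopes (the trophic signal both share) and raises the smooth-term F value
for 7 of the 8 isotope × covariate pairs — the corrected data show the
ecological trends more sharply. Stage 5 shows this is not one lucky seed:

```
hair: corrected R^2 higher in 95/100 replicates (mean 0.244 -> 0.463)
individual: corrected R^2 higher in 93/100 replicates (mean 0.178 -> 0.384)
```

The same pipeline is scriptable (`isobase simulate|isoscape|correct|evaluate|run`)
and drives real CSV tables with the documented headers
(`soil.csv: x,y,d13C,d15N`;
`hair.csv: sample_id,sett_id,x,y,date,d13C,d15N,genotype_id,land_class,elevation_m`;
`weather.csv: station_id,x,y,date,t_mean,t_max,t_min,rain_mm,sun_hrs`), with a
`column_map` config option to bridge arbitrary input headers.

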