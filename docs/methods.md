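# Methods

## Scope and model

`domcarbon` estimates carbon in forest dead organic matter (DOM): coarse
woody debris (CWD — standing snags and fallen logs, maximum diameter
≥ 10 cm), fine woody debris (FWD, 2–10 cm), and litter (< 2 cm woody
material plus leaf litter). The pipeline mirrors how a national assessment
is actually assembled: a few hundred field sites give the response data; the
forest inventory and climate network give wall-to-wall predictors; an
ensemble of regression models transfers the site signal to the grid; and
simple period regressions turn the per-period maps into change rates.

## Stage 1 — plot accounting

Dead-wood pieces that can be weighed contribute their oven-dry mass
directly. Pieces too large to weigh are measured and converted:

* volume *V = πd²L/4*, with *d* the mean of the middle and both end
  diameters for logs, or the DBH for snags, and *L* the log length or snag
  height;
* mass = volume × density ratio (oven-dry mass / green volume, kg m⁻³) for
  the piece's species and decay class (I intact … IV rotten heartwood).

Snags whose decay class has no tabulated ratio fall back to the same
species' class-II, then class-I ratio — the density of barely decayed
fallen wood is the best available proxy for standing dead stems. This
fallback order is configurable on `WoodDensityTable`.

Carbon concentrations default to 0.5 for every component and decay class;
a `CarbonConcentrationTable` can override any (component, class) pair.
Litter is censused on five 2 × 2 m subplots per plot; its density uses the
summed subplot area. Wood densities use the full plot area (default
20 × 20 m). Soil profiles integrate thickness × bulk density × carbon
fraction over 0–100 cm (six standard depth breaks); depth not covered by
any layer contributes zero and triggers a warning rather than imputation.
Tree above-ground biomass uses per-species power-law allometry
Σ aᵢ(D²H)^bᵢ over biomass components, × 0.5 for carbon. Stand age is the
age of the fifth-largest tree by DBH; with fewer than five aged trees the
smallest-DBH aged tree is used. Sites average their (typically three)
replicate plots arithmetically; derived pools are recomputed from the
averaged bases so additivity (cwd = snags + logs, dom = woody debris +
litter, ecosystem = agb + soil + dom) holds exactly.

Units: masses in kg internally, densities reported in Mg C ha⁻¹, lengths
and diameters in metres.

## Stage 2 — predictor surfaces

Provincial inventory volume per hectare *x* becomes biomass through
*BEF(x) = a + b/x* per forest type (decreasing in *x*; the asymptote *a* is
the high-stocking biomass per unit volume), × 0.5 for carbon. Each forest
cell of the 0.083° type raster receives the density of its (province,
inventory-type) stratum; combinations on the raster but missing from the
table fall back (logged) to the province's area-weighted all-type mean.
Because strata are painted constant, re-aggregating the map reproduces
provincial stocks by construction.

Climate interpolation defaults to ordinary kriging, implemented as
Gaussian-process regression with an exponential covariance (Matérn ν = ½)
and a fitted constant mean — exact at stations up to a 10⁻¹⁰ nugget kept
for numerical stability. Inverse-distance weighting (power 2) is the
deterministic alternative; its predictions are bounded by station extremes.
MAT is the mean of monthly means; MAP the sum of monthly precipitation;
both are computed per station before interpolation. Site values are
extracted by the nearest-cell rule, with NaN (not an error) outside the
raster extent. Cell areas are spherical (authalic radius) per cell
latitude.

## Stages 3–4 — ensemble upscaling and aggregation

Each DOM component is fitted separately on four predictors: MAT, MAP, AGB
carbon density, and forest type (one-hot encoded). One ensemble member =
one Random Forest of 100 trees (mtry = ⌈p/3⌉, unlimited depth) trained on
an independent random 70 % of sites and scored (R², RMSE) on the held-out
30 %. The member count — 500 in a full analysis, 50 in the default
synthetic runs — carries the Monte-Carlo spread, which is why each member
is a modest forest rather than a huge one. A constant holdout response
leaves R² flagged NaN rather than defined by convention.

All members predict all cells of every period identically, so temporal
differences reflect predictor change only. Predictions are clipped at zero
(tree averaging of non-negative responses cannot go below zero; the
contract is still enforced). Derived pools are summed per member before
any averaging, keeping reported means exactly additive. Per member, a
stratum's density is the cell-area-weighted mean over its cells, and its
stock is that density × the *inventory* area of the stratum — the raster
supplies spatial pattern, the inventory supplies areas. Regional and
national stocks sum strata; means and SDs are taken over members last.
Forest types absent from the one-hot vocabulary at prediction time encode
as all-zeros (logged), letting the trees fall back on the numeric
predictors.

Permutation importance (%IncMSE) permutes one predictor at a time on each
member's holdout set (the one-hot block as a unit, 3 repeats) and reports
the mean ± SD percentage MSE increase across members.

## Stage 5 — trends and comparisons

Change rates are OLS slopes of density or stock against the period
midpoints (1986 … 2006); the reported SD is the classical slope standard
error. A Monte-Carlo alternative — refitting the trend per ensemble member
— would capture between-member spread instead; the slope-SE route is the
default because it is deterministic given the period table. Constant series
return slope 0 with R² and p flagged NaN. Component shares of a total
slope are simple ratios × 100; the combined ecosystem sink adds component
rates with root-sum-square SDs (independence assumed). Group comparisons
use one-way ANOVA with Tukey-HSD pairwise tests compressed to a compact
letter display; letters are assigned deterministically from the largest
group mean downward, over maximal runs of mutually non-distinct groups in
that ordering.

## The synthetic world

`make_world` generates a study region at a configurable scale (default 200
sites, 40 × 40 cells at 0.083°, 5 provinces, 4 forest types, ~8 %
non-forest). True component surfaces are linear-plus-interaction in (AGB,
MAT, MAP) with forest-type offsets; signs follow the field pattern —
woody-debris pools increase with AGB, MAT and MAP, litter decreases with
MAT and MAP — and intercepts keep every surface positive over the covariate
ranges. National DOM density lands near 6 Mg C ha⁻¹ over ~130–155 Mha,
i.e. national-assessment magnitudes. The inventory grows area linearly at
0.9 %/yr and stand biomass at 1 %/yr; timber volumes are the exact BEF
inversion of the configured stratum densities, so stage 2 recovers them to
machine precision. Site observations multiply the true surface by mean-one
lognormal noise (σ = 0.20 by default).

Raw measurements are *decomposed from* the site targets through the same
rules stage 1 applies — log masses split between a weighed piece and a
volume-estimated one, snag volumes inverted from mass and density, litter
masses split over five subplots, tree heights scaled so allometric AGB
matches, soil concentrations scaled to the profile target, the
fifth-largest tree's age set to the stand age — making the stage-1 round
trip exact (observed < 10⁻⁹ relative), not merely close.

What the world does **not** emulate: realistic geography or vegetation
classes, spatial autocorrelation of residuals, within-stratum AGB texture
on the grid (strata are painted constant), measurement error in diameters
and depths, site-selection bias, or temporal climate change across periods
(climate is held fixed; the stock trend is driven by area and biomass
growth). Passing recovery tests therefore demonstrates the pipeline's
internal correctness and statistical machinery, not the field accuracy of
any real-world estimate.

## Numerical and design choices

* Problem sizes: default synthetic runs use 50 ensemble members on 200
  sites and a 40 × 40 grid — enough for stable national means (recovery
  ≈ 1 %) while a full pipeline run completes in well under a minute;
  multi-seed checks use the same scale.
* All randomness flows from one root seed; stages draw named substreams
  (SHA-256 of `"{seed}:{name}"`), so runs are bit-reproducible and stages
  are decoupled.
* Kriging adds a fixed 10⁻¹⁰ nugget; station-coincident cells are exact to
  ~10⁻⁵. Constant station fields short-circuit to a constant surface.
* Ties in stand-age DBH ranking follow sort order on descending DBH
  (stable; first-listed wins among equals).
* Degenerate inputs: empty wood components are 0; an empty litter census is
  an error (litter is never absent, only unmeasured); x ≤ 0 is a domain
  error for BEF; fewer than 3 stations or trend points is an error.
* Grids are xarray Datasets written as NetCDF; tables are plain CSV. No
  GeoTIFF writer is provided — NetCDF covers the gridded outputs.

## Limitations

Pixel SDs are between-member spread only; within-member tree variance is
not added. Validation splits are unstratified ("randomly divided"), so
rare forest types can be under-represented in some members. The trend model
is a straight line over five points — adequate for a change *rate*, silent
about its shape. Below-ground biomass is out of scope throughout.
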