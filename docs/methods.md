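# Methods

This note documents the models, conventions and numerical choices behind
`microgrid`, and what the synthetic-world tests do and do not demonstrate.

## Logger processing

Raw series are 15-minute temperature records on a strict 15-minute lattice;
gaps are missing rows, never irregular steps. Sensor bias is removed with a
fixed per-sensor offset estimated from a co-location period (≥ 3 sensors,
≥ 24 h of shared timestamps): the offset is the mean difference between the
focal sensor and the mean of the *other* sensors at the same instants, so a
calibration group's offsets sum to zero by construction. Plausibility
screening is deterministic rather than visual: readings outside
[−45, 60] °C and runs of more than 672 identical readings (7 days — a stuck
sensor) are flagged removed. Both thresholds are configurable.

Annual summaries use a 365-day window anchored at the first timestamp.
Calendar days are cut at a fixed UTC+1 boundary (no daylight saving); a day
must retain ≥ 90 % of its 96 readings to qualify, and annual statistics
require ≥ 90 % of the year's readings. Quantiles are linear-interpolation
("type 7"). These conventions vary across summarization packages and are
declared rather than inferred; all are parameters of `SummaryConfig`.
GDD5 is Σ max(0, T − 5 °C)/96 over the year, in °C·day.

## Terrain predictors

* **Slope/aspect** — Evans–Young second-order polynomial on the 3×3 window;
  aspect is the downslope azimuth in degrees clockwise from north, NaN on
  flats; edge cells are nodata.
* **TPI** — elevation minus the mean inside a circular window
  (cell-centre membership, focal cell included), standardized to unit SD per
  radius (100/250/500 m). Computed by FFT convolution.
* **Flow routing** — Freeman multiple flow direction: cells are processed in
  decreasing elevation order and distribute accumulated area to all lower
  8-neighbours with weights ∝ slope^convergence (default 1.0). Depressions
  are first filled by priority-flood to an epsilon gradient (10⁻⁴ m) so
  every interior cell drains; a no-fill mode exists for testing closed
  basins. Mass is conserved: outlet catchments sum to the raster area.
* **TWI** — ln(a / tan β) with specific area a = contributing area divided
  by a flow width equal to the cell size, and tan β floored at 10⁻³ to keep
  flats finite.
* **SAGA wetness index** — TWI on an iteratively *modified* catchment area:
  each pass lets a cell inherit the maximum neighbouring modified area
  damped by (1/suction)^(suction·tan β) (suction default 10), iterated to a
  10⁻³ relative tolerance (max 100 passes). The damping is ≈ 1 on flats and
  vanishes on steep slopes, so flat valley floors score wet (cold-air
  pooling proxy) while SAGAWI → TWI on steep terrain; a_mod ≥ a everywhere
  by construction.
* **DAH** — cos(202.5° − aspect)·arctan(slope in radians); 0 on flats;
  maximum heat surplus on south-west slopes.
* **Smoothing** — isotropic Gaussian with metre-specified SD (10 m, 25 m
  variants suffixed `_g10`/`_g25`), kernel truncated at 4σ. Fully valid
  rasters use a reflecting boundary, which keeps the operator
  mean-preserving; rasters with nodata use mask-weighted normalization.
* **Resampling/mosaicking** — coarsening samples a cubic B-spline surface
  through source cell centres; mosaics merge co-aligned rasters from high to
  low priority with linear distance feathering across a configurable border
  strip (default 25 m) measured from the higher-priority raster's edge.

## Canopy predictors

Vegetation height is the DSM−DTM difference floored at 0 (a DSM below the
terrain is sensor noise; deficits beyond 0.5 m raise an alignment warning),
median-aggregated to the target grid. Canopy density PRA2m is
100·(returns above 2 m)/(total returns), nodata where no returns.
Conifer/deciduous cover partition PRA2m by the coniferous canopy fraction,
so the two always sum to the density.

## Site stratification

Candidate plots are classified by exact Fisher–Jenks natural breaks
(dynamic programming over sorted values minimizing within-class SSD,
vectorized over split positions; ties broken toward the lowest first
break; intervals left-closed, right-open except the last) into 5 elevation
× 3 radiation × 3 wetness classes = 45 strata, optionally split open/closed
at the median canopy cover for 90. Selection draws a fixed number per
non-empty stratum without replacement (seeded), takes whole strata smaller
than the quota, and forces plots at both elevation extremes. Plots inside
(or on the boundary of) disturbance polygons are excluded beforehand.

## The boosted spatial GAM

Base learners are cubic P-splines with 20 interior knots on equidistant
knot vectors and a second-order difference penalty; the spatial term is a
10×10 tensor product of marginal P-splines of the coordinates with an
additive (Kronecker) penalty; the optional interaction tensor is 5×5.
Because B-spline rows sum to one, the column-centered design annihilates
the constant coefficient direction, which also spans the penalty null
space; every fit therefore works in a Helmert-reduced parametrization
(coefficients are mapped back to the full basis afterwards), which keeps
all systems positive definite without altering the model space.

Each learner's boosting-stage penalty is calibrated by bisection so its hat
trace equals 4 effective df — equal complexity is what makes componentwise
selection fair across univariate and tensor terms. Boosting starts from the
response mean, fits every learner to the current residuals, commits the
best one scaled by ν = 0.1, and the stopping iteration is the
minimum-squared-error point of an inner 10-fold random CV over the grid
{25, 50, …, 1000}. Learners ever selected before the stop — plus the
spatial tensor, which is never de-selected — go to the final refit.

The refit chooses per-term smoothing parameters by GCV,
n·RSS/(n − edf)², via cyclic coordinate descent on a log₁₀ λ grid from −8
to 7 (16 points), sweeping until no term improves (max 10 sweeps). Since
the stacked basis dimension (often ~470) exceeds the number of sites
(~150), all GCV quantities are evaluated in observation space through
Woodbury identities: with S_j = X_j P_j(λ)⁻¹ X_jᵀ cached per (term,
grid-λ), the hat matrix is S(I+S)⁻¹, residuals are (I+S)⁻¹y, per-term
edf = tr((I+S)⁻¹S_j), and coefficients β_j = P_j⁻¹X_jᵀ(I+S)⁻¹y. A ridge of
10⁻⁹ relative to the design scale (plus 10⁻¹² of the penalty scale at large
λ) spans the penalty null space; its shrinkage is orders of magnitude below
every reported tolerance. GCV rather than REML is used because it is
closed-form in this formulation; the two can differ slightly in the chosen
λ, so effective-df values should not be expected to match other software to
the second decimal.

Partial effects are classified on a 50-point grid over the training range:
monotone up/down, single interior maximum (∩) or minimum (∪), flat when the
range is below 10⁻⁴ of the curve scale; curves with more sign changes map
to the nearest class and are flagged. Extrapolation beyond a predictor's
training range continues the boundary value linearly (value plus boundary
derivative of the basis).

The DAH × PRA2m interaction is tested by refitting each spatial-CV
training set with and without the tensor (boosting selection is shared;
the interaction enters at the refit, mirroring a workflow where the
selection engine cannot express the term) and kept only if the mean fold
RMSE strictly decreases.

## Spatial cross-validation

Sites are binned into flat-topped hexagons by axial-coordinate rounding
(lattice origin at a configurable corner), hexagons are packed into k = 10
folds by a longest-processing-time greedy (sorted by descending site count,
each to the currently smallest fold; seeded shuffle breaks ties), so no
hexagon is ever split. The headline statistic is the unweighted mean of the
k fold RMSEs; the pooled RMSE over all held-out residuals is reported
alongside. Each fold's model is fit by the full pipeline including
variable selection.

## Gridding

Grid prediction evaluates the model chunk-by-chunk over a co-registered
raster stack; term effects are accumulated column-by-column in a fixed
order so the output is bit-identical regardless of chunk size. Any nodata
input makes the cell nodata. The uncertainty raster counts, per cell, the
predictors strictly outside their training [min, max] and divides by the
number of predictors — 0 inside the training envelope, 1 where every input
extrapolates. Zonal means aggregate valid fine cells per coarse cell;
grid comparisons report ME, MAE and RMSE with the grid-minus-reference sign
convention. Point extraction from grids is bilinear by default.

## Synthetic worlds

The generator fabricates what the pipeline would normally receive. Terrain
is spectral-synthesis fractal relief (power-law exponent 2.0) rescaled to
exactly span 561–1450 m a.s.l., with a sinuous incised valley and a ridge
so the wetness and position indices carry signal. Canopy is a smoothed
noise field thresholded at the disturbed-area quantile (default 30 %):
disturbed patches have density ~0–15 %, closed forest ~60–100 %, vegetation
height tracks density, and return counts are constructed so density is
exactly recoverable. The default world is 200×200 cells at 5 m with 150
sites chosen by the stratification module (45/90-strata scheme on a
candidate subgrid, topped up or thinned at random to hit the count), sized
so the full 20-world recovery experiment is a desk-scale run.

Logger series follow the stated additive model: a reference mean of 7 °C,
lapse −0.005 °C/m, +1.0 °C per DAH unit, a seasonal cosine of 9 °C
half-amplitude (coldest mid-January), a diurnal cosine of 5 °C
half-amplitude (warmest 14:00) damped by canopy density with buffer
coefficient 0.5, nocturnal cooling of 0.05 °C per SAGAWI unit weighted by
max(0, −diurnal shape), i.i.d. Gaussian reading noise (default 0.3 °C), and
per-level amplitude multipliers (soil 0.8 seasonal/0.15 diurnal,
near-ground 1.2 diurnal). An optional DAH×(1−PRA2m/100) interaction
coefficient (default 0 — the stated model is additive) exists to exercise
the interaction decision. Annual-mean ground truth is closed-form given the
sampled temporal-profile means; extremes and GDD truth are evaluated
densely at requested cells with the same UTC+1 day partition as the
summarizer.

Because reading noise averages to σ/√35040 in an annual summary, the
CV-calibration experiment ("RMSE in [0.8, 1.3]·σ on a correctly specified
world") applies its noise at the site-summary level, where the band
"irreducible plus model error" is actually defined. Likewise, the
selection-recovery check counts predictor *families* — the Gaussian-smoothed
DAH variants, and {TWI, SAGAWI} — as carriers of the same generative
signal: componentwise boosting picks whichever collinear member fits
marginally better, and treating that as a selection error would test the
correlation structure of the landscape, not the selector.

What passing these tests shows: the pipeline recovers known additive
structure from realistic terrain/canopy covariation at realistic noise, its
CV machinery is calibrated, and its interaction rule discriminates. What it
does not show: behaviour under snow-cover dynamics, sensor drift,
phenology-dependent canopy buffering, or non-additive physics absent from
the generator — real-data performance claims need real data.

## Numerical conventions and limitations

* Quantiles: type 7 everywhere; day boundary UTC+1; year = first timestamp
  + 365 days.
* tan β floor 10⁻³; depression-fill epsilon 10⁻⁴ m; SAGAWI tolerance 10⁻³
  relative, ≤ 100 passes.
* Boosting ties break toward the first learner; fold-packing ties by seeded
  shuffle; Fisher–Jenks ties toward the lowest first break.
* Rasters are plain-text ESRI ASCII grids with NaN-backed nodata; the CRS
  is an uninterpreted tag. GeoTIFF IO is not provided.
* Responses are Gaussian; no factor offsets; no buffered leave-one-out CV.
* Degenerate inputs: constant predictors are dropped with a warning before
  boosting; zero-variance responses yield intercept-only models; flat
  rasters refuse TPI standardization.
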