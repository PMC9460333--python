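# Methods

This note documents the models implemented in `esvgrid`, the parameter
choices that matter, and what the synthetic-data tests do and do not
establish about real landscapes.

## Gridding and areas

The fishnet is a square tessellation (default 1 × 1 km) snapped to the
raster's upper-left origin; the source study does not state its grid
origin, so alignment is a package convention. All areas come from pixel
counting on the native raster — class area = pixel count × pixel area —
which is exact integer arithmetic and avoids the sliver ambiguities of
polygon overlay. A cell is retained if it contains at least one valid
(masked-in, non-nodata) pixel; edge cells keep their true covered area
*S_j* < nominal, and no minimum-coverage threshold is applied by default
(`min_coverage` exposes one). Consequently Σ_j A_ij over cells equals the
masked class area exactly, a property the tests assert with zero
tolerance.

Confusion-matrix metrics use the convention **rows = mapped, columns =
reference** (producer accuracy column-wise, user accuracy row-wise); the
orientation is stated here because the literature uses both.

## Valuation

Class weights *P_i* for the land-use degree are urban 4, cropland 3,
water / grassland / woodland / wetland 2, unutilized 1 (wetland is valued
through its own equivalent column but carries the ecological-class weight
2). The degree index is implemented exactly as the area-weighted mean — no
×100 presentation factor.

The packaged equivalent table holds 11 service equivalents for 10 classes,
with urban land priced at zero. Two unit-equivalent values circulate in
the source arithmetic: the unrounded product 3406.50 CNY/ha × (3411/5734)
= 2026.43 CNY/ha, and the printed constant 2026.38 CNY/ha. The package
computes the former when given yields, but defaults the constant
`PAPER_UNIT_EQUIVALENT_VALUE = 2026.38` so published table arithmetic
reproduces; the displayed correction coefficient 0.60 is one-decimal
presentation rounding of 0.5949 and is never used in computation. Areas
are carried in km² and converted to hectares (×100) only at the valuation
boundary; intensities are CNY per km² of covered area, which makes a
cell's intensity invariant to uniform clipping (tested). Currency is CNY
throughout; exchange-rate conversion is out of scope.

## Moran suite

Weights are queen (8-neighbour) contiguity on the fishnet lattice,
row-standardized — the GeoDa default — with rook available by flag.
Isolated retained cells keep empty neighbour lists, are excluded from
local inference (NaN p-value, "ns" label) and are counted in the report.

Variance scaling is population-style (m₂ = Σ(x−x̄)²/n), which makes
mean(local I) = global I an exact identity under row-standardized weights;
the tests assert it at 1e-10. The bivariate statistic is the GeoDa
standardized-variable form I_xy = (1/S0) Σ w_ij z_x,i z_y,j (several
inequivalent definitions exist in the literature; this one reduces to the
univariate I at y = x, also asserted). The Moran scatterplot data
(standardized value vs spatial lag) is exposed; its regression slope
equals I for row-standardized weights.

Inference is purely by permutation — 999 draws by default, pseudo-p =
(k+1)/(M+1) with k the permuted statistics at least as extreme as the
observed one *in the observed tail* (full-vector permutation for global,
conditional permutation holding the focal value fixed for local). Because
the tail is chosen from the observed statistic, the null distribution of
this pseudo-p is not uniform: each fixed tail alone is conservative, but
the directional p satisfies P(p ≤ t) ≤ 2t. The property tests check
exactly that bound; users wanting strictly conservative one-sided tests
should fix the tail a priori. Analytical (normality/randomization)
variances are deliberately not implemented. Cluster labels take the
quadrant (H-H, L-L, H-L, L-H) when p < α, at significance tiers 0.05 and
0.01.

## Variogram and kriging

ESV intensity is natural-log transformed by default before variogram
estimation (the flag is exposed); zero intensities — fully urban cells —
are offset by half the smallest positive intensity with a warning, and no
lognormal-kriging back-transform correction is claimed: predictions are
reported in log space, with a naively exponentiated companion surface.

The empirical estimator is the classical binned Matheron form with default
bin width = grid spacing (1 km) and max lag = half the domain diagonal
(the source software's defaults are unknown). The spherical model is
fitted by pair-count-weighted nonlinear least squares (`scipy`
`least_squares`, parameters bounded at zero); R² and RSS are reported
unweighted against the binned estimates. Initialization: nugget from the
first bin, partial sill from the spread, range at half the max lag. On
simulated truth (c0 = 0.1, c = 0.9, a = 5.5 km, 100 × 100 cells of 1 km)
the mean fitted range over 20 seeds is within 20 % of truth; the nugget is
the least identifiable parameter at grid spacing ≈ 1 km because no pairs
exist below one lag, so short-range structure partially absorbs it.

Ordinary kriging solves the semivariance system with a Lagrange
multiplier per target on the 16 nearest data points (all points when
n ≤ k; the moving neighbourhood keeps n targets tractable). The model is
evaluated with γ(0) = 0, so kriging is an exact interpolator at data
locations (the "filtered-nugget" convention is not implemented); duplicate
data locations are rejected. Weight sums are 1 to 1e-10 and small systems
match a dense full-matrix solve to 1e-10 (both tested).

## Synthetic data

`generate_landscape` rank-thresholds one smoothed standard-normal field:
pixels are sorted by field value and assigned to classes in ascending
class-code order at the cumulative target proportions, with
largest-remainder rounding, so per-class pixel counts equal
round(target × N) within ±1 at any clumping level. `aggregation` is the
Gaussian smoothing σ in pixels (0 = independent pixels); Moran's I of any
class indicator rises monotonically with it (tested over 5 levels × 10
seeds). Default composition mirrors the study basin's first-level shares
(urban 4.13 %, cropland 27.20 %, grassland 36.2 %, woodland 28.51 %,
unutilized 3.07 %, water+wetland 0.89 %); the second-level splits are
package choices, set once: grassland 15/13/8.2 % (high/medium/low
coverage, descending like the published per-class values), woodland
5/23.51 % (shrub-dominated "other forestland", the basin's widespread
type), water/wetland 0.70/0.19 %.

Gaussian fields use circulant embedding on a doubled torus with the
covariance implied by the spherical variogram; slightly negative FFT
eigenvalues from an imperfect embedding are clamped to zero (a standard
approximation — empirical variance is within a few percent of the target),
and the nugget is added as independent white noise. Fixed seed ⇒
bit-identical output everywhere.

What the synthetic tests show: the pipeline arithmetic, the statistics and
their inference behave correctly on landscapes with known structure, and
the qualitative finding — positive spatial autocorrelation of land-use
degree and ESV intensity, negative bivariate correlation between them —
emerges whenever intensive-use classes are spatially clumped. What they do
not show: agreement with any basin-specific published value (cell count
18,790, OA 88.06 %, the basin Moran's I values 0.88/0.65/−0.43, the fitted
variogram R² 0.92 / range 5.5 km), all of which depend on the real basin
raster and boundary and are treated as reference only.

## Problem sizes

Default test and example sizes were chosen so a full suite run stays in
the one-minute range on a single core: landscapes up to 1000 × 1000 px,
fishnets up to ~1600 cells for permutation inference (999 draws), 20-seed
variogram recovery at 100 × 100 cells. The pipeline itself has been
exercised at 3600 cells with 199 permutations in under four seconds; cost
scales linearly in permutations and near-linearly in cells (sparse lags),
with the conditional-permutation LISA the dominant term.

## Known limitations

Single projected CRS in metres assumed end to end; no reprojection, no
vector land-use input, no anisotropic variograms, no co-kriging, no
Geary's C / Getis–Ord statistics, no distance-band weights. Raster I/O is
plain-text ESRI ASCII grid. The equivalent-factor method itself inherits
the usual caveats: values scale linearly with the regional yield ratio and
ignore within-class condition gradients.
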