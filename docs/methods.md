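# Methods

This note documents the model chain, the default parameters (with units and
the reasoning behind each default), the numerical choices, and what the
synthetic data can and cannot show.

## 1. Grid and areas

The domain is a regular latitude–longitude grid (default 35.25–69.25° N,
9.25° W–34.25° E at 0.5°, configurable). Cell areas are exact spherical-band
areas, A = R²·Δλ·(sin φ₂ − sin φ₁) with R = 6371 km; a 1° cell at the
equator is ≈ 1.236 × 10⁶ ha. Region masks are rectangular blocks (default
3 × 4) standing in for countries; they partition the domain, so regional
totals sum exactly to the domain total.

Worked examples in the tests and README use 10 × 10 or 20 × 20 cells at 1°.
These sizes are the package's own choice: large enough for quadrant
percentages and random-field statistics to be meaningful, small enough that
the full chain runs in about a second.

## 2. Scenario generator

Baseline land-use fractions come from a softmax of log-shares perturbed by
Gaussian random fields (white noise smoothed with a Gaussian kernel,
unit variance, correlation length 3 cells), which guarantees exact closure
(fractions sum to 1 per cell) with spatially coherent patterns.

The policy lever is the nitrogen input: Baseline 150 kg N ha⁻¹ yr⁻¹, policy
a fraction of it (default 0.5). Yield responds through a Michaelis–Menten
curve y = y_min + (y_max − y_min)·n/(k + n), defaults
(y_min, y_max, k) = (2, 8, 100) in t DM ha⁻¹ and kg N ha⁻¹: y(150) = 5.6,
y(75) ≈ 4.57, so halving N cuts yields by ≈ 18% — saturating, as agronomic
response curves are.

Two archetypes translate the yield loss into land-use change. Their
parameters are the study conditions of the generator, not fitted values:

* **abandonment** — a fraction (default 0.15, scaled by the policy strength)
  of each crop's area leaves production, split half to fallow and half to
  pasture. 15% is a moderate abandonment response for a price-driven
  land-rent model under an ~18% yield cut.
* **extensification** — a fraction (default 0.10, scaled likewise) of
  pasture converts to cropland, distributed over crops proportionally to
  their shares; stocking density drops by 10%, extensifying the remaining
  pasture.

## 3. Crosswalk

Economic categories map to two target nomenclatures via a shipped long-format
table: biodiversity (land-use × intensity) classes and plant functional
types (PFTs). Ambiguous categories carry split fractions: forest →
primary/secondary 0.5/0.5 (configurable), the extensification table's
"Other" crop → annual/perennial 0.8/0.2 and its pasture →
pasture/rangeland 0.8/0.2, grass → C3/C4 0.9/0.1 (temperate Europe is
C3-dominated). Fallow is counted as a zero-input annual crop for
biodiversity (minimal intensity) and natural C3 grass for carbon.
Mass is conserved exactly per category and per cell.

Crop management intensity is an ordered-logistic function of yield
(cutpoints 3 and 6 t DM ha⁻¹, slope 1 — placing the light band across the
yield range the Michaelis–Menten curve actually spans); pasture intensity is
the same family on stocking density (cutpoint 1 head ha⁻¹, slope 2).

## 4. Biodiversity projection

Class-level coefficients express each class relative to primary vegetation
on the scale of the underlying statistical model:

* species richness: log scale (Poisson log-link), relative value
  exp(c − c_primary);
* abundance: square-root scale, relative value (c/c_primary)²;
* compositional similarity: adjusted logit with ε = 0.01,
  data scale (invlogit(x) − ε)/(1 − 2ε); similarity classes are coarsened —
  only perennial crops keep the intensity dimension;
* BII = abundance% × similarity% / 100.

A cell's value is the fraction-weighted mean of class relative values
(ratio first, then weighting), so every indicator is affine in the fraction
vector — which is what makes the per-land-use breakdown exactly consistent
with the projected maps.

The default coefficients are synthetic but obey the orderings of published
field syntheses: primary ≥ secondary ≥ pasture ≥ cropland ≥ urban for
richness; across crop intensities the richness profile is hump-shaped
(minimal 0.68 < intense 0.74 < light 0.82) — minimally managed fields here
are fallow-like, nearly bare land, while light management retains structural
diversity; intense management removes it again. Pasture communities are rich
(0.96/0.90) but compositionally far from the reference forest community
(similarity 0.45 against 0.85 for cropland weeds-and-margins communities),
which is why BII and richness can move in opposite directions.
`fit_coefficients` demonstrates recovery of all coefficients from simulated
site-level survey data (Poisson GLM via statsmodels, least squares on the
transformed scales).

## 5. Carbon fields and dynamics

Each PFT has a configured mean density per indicator (NPP in tC ha⁻¹ yr⁻¹,
soil and biomass carbon in tC ha⁻¹); fields are mean × (1 + 0.15·G) with G a
unit Gaussian random field, floored at 5% of the mean. Grassland soils
(120 tC ha⁻¹) and forest soils (150) hold more carbon than cropland soils
(80); forest dominates biomass (120 vs ≈ 5 for crops). Crop means scale with
the relative yield at the scenario's N rate, damped by a per-indicator
nitrogen sensitivity (0.15 for NPP and soil, 0.3 for biomass): fertilization
raises photosynthetic capacity, but realized NPP and soil stocks are
co-limited by climate and soil, so the per-area N effect is deliberately
weak and land conversion dominates the scenario differences.

After land-use change, cell totals relax toward the new equilibrium with
e-folding times τ = 40 yr (soil) and 2 yr (NPP): c(t) = c_eq +
(c₀ − c_eq)e^(−t/τ). The reported Δ maps are means over the last 50 of 150
annual differences, with AR(1) interannual noise (lag-1 correlation 0.5,
marginal sd 1% of the local level).

## 6. Statistics

Per-cell significance uses a one-sample t-test on the annual differences
with an effective sample size n_eff = n(1 − r₁)/(1 + r₁). Two first-order
bias corrections keep the test calibrated in 50-year series: the raw lag-1
autocorrelation estimate gets Kendall's correction r₁ + (1 + 3r₁)/n
(applied only to positive estimates, so an uncorrelated or anti-correlated
series reduces exactly to the classical t-test), and the sample variance is
divided by 1 − 2r₁/((1 − r₁)(n − 1)). Measured type-I error under the AR(1)
null (r = 0.5, n = 50) is ≈ 0.05–0.07 across seeds.

## 7. LMDI breakdown

For each land use, ΔE splits exactly into an area effect
L(E_p, E_b)·ln(A_p/A_b) and an intensity effect L(E_p, E_b)·ln(e_p/e_b)
with e = E/A and L the logarithmic mean — additivity holds to machine
precision by construction. Levels and areas must be positive; values below
10⁻⁹ are floored with a warning; a land use present in only one scenario is
assigned its whole ΔE as area effect and flagged. BII is refused
(`BiiNotDecomposableError`): it is a product of two indicators and has no
well-defined area/intensity split. Richness breakdowns use
"intact-equivalent area" levels (area × fraction × relative richness, in
Mha), which makes the per-land-use rows sum exactly to the overall projected
change.

## 8. Numerical and I/O choices

* All randomness flows through `numpy.random.default_rng` with explicit
  seed lists (e.g. `[seed, 13]`), so every stage is independently
  reproducible and stages never share a stream.
* Rasters are NetCDF via xarray's `scipy` engine (no netCDF4/GDAL
  dependency); tables are CSV with a provenance header line carrying the
  seed and resolution.
* Closure and conservation are enforced at 10⁻⁹ absolute; aggregation is a
  plain weighted sum, checked against a brute-force loop in the tests.

## 9. What the synthetic data does and doesn't show

The generator is built to reproduce *structural* findings: the sign and
attribution of carbon and biodiversity changes under the two archetypes,
the dominance of grassland expansion in the abandonment soil-carbon gain,
the win–win / loss–loss contrast between archetypes, and the exactness
properties of the accounting. At the default study conditions the package
obtains ≈ 80% win–win cells under abandonment and ≈ 73% loss–loss under
extensification (soil carbon vs richness, 20 × 20 cells, seed 3).

It does **not** reproduce magnitudes of a full-scale coupled
economic/land-surface model chain: absolute EU totals depend on the
configured mean densities and domain size, regional masks are rectangular
stand-ins, crop price feedbacks, climate variability and nitrogen leaching
are absent, and the biodiversity coefficients are synthetic rather than
estimated from survey databases. The shipped `eu_annual_means.csv` reference
levels are used only for arithmetic consistency checks, never as calibration
targets for the generator.
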