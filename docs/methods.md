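# Methods

This note documents the models, estimators and numerical choices behind
the package, and what the synthetic study system does and does not
emulate.

## Hydrographic fields

Per-pixel summaries are taken over the full depth/time stack of current
and temperature samples: T is the unweighted arithmetic mean over all
(depth, time) entries; U averages per-sample magnitudes √(u²+v²)
(magnitudes first, then the mean); DS combines the sample standard
deviations of the two components as √(sd(u)² + sd(v)²) with the n−1
denominator. DS is translation-invariant (adding a constant current
changes nothing) and, unlike sd(U), responds to directional variability.
Depth-level averaging is unweighted even though oceanographic level
spacing is uneven; a thickness-weighted alternative would change T by a
few percent in stratified water columns and is deliberately not the
default (`depth_weighting: none`). Grids are cell-centre registered with
half-open cells; bathymetry is positive-down metres. Pixel areas use the
equirectangular approximation (res·111.32 km)²·cos(lat), adequate for
areas at the sub-degree resolutions used here.

## Colwell's predictability indices

Monthly series are classified into `s` equal-width magnitude classes over
the observed [min, max] (default s = 11; log-width bins available via
`binning="log_width"` because ecological software differs on the default
class-boundary transform). The maximum value is assigned to the top
class; a constant series occupies class 1 only. From the month × class
table with natural-log entropies: C = 1 − H(Y)/ln s,
M = (H(X) + H(Y) − H(XY))/ln s, P = C + M. The denominator uses the
configured s, not the number of occupied classes, because the state space
is fixed a priori. Missing months are dropped, not imputed. P = C + M is
an algebraic identity and is enforced to 1e−10 in tests. Note that the
finite-sample entropy bias inflates M for short series (a 6-year series
has bias ≈ 0.2 at s = 11); the synthetic generator therefore uses
19-year series, matching the satellite record length a chlorophyll
climatology would realistically provide.

## Life histories from metabolic theory

Shell volumes idealise shapes: spheres for initial and juvenile stages
(diameter = length); cylinder π(w/2)²L, cone (π/3)(w/2)²L,
parallelepiped Lwh, or semi-spheroid (2/3)π(w/2)²h for adults. The
semi-spheroid takes two equal equatorial semi-axes from the width and the
height as polar semi-axis. Literature size ranges collapse to midpoints
before volume computation.

Developmental time follows DT = (4/a₀)·e^{E/kT}·ΔS^α with E = 0.65 eV,
k the Boltzmann constant in eV/K, α = 0.25, ΔS = JS − IS in mm³ and T in
kelvin. The constant 4/a₀ is the slope of a least-squares fit of observed
developmental times on the metabolic term x = e^{E/kT}·ΔS^α, through the
origin by default — the slope *is* the constant, so no intercept is
estimated — with r² computed against the uncentred total sum of squares,
consistent with the zero-intercept model; a free-intercept option exists
because either convention is defensible. A species lacking a juvenile
volume gets a missing DT rather than an imputed one.

Fecundity uses the allometry ln Cx = −0.99 ln m₀ + 19.15 (m₀ the initial
embryo mass in grams) and C = Cx·M^0.75·e^{−E/kT}. Masses derive from
volumes at a nominal density of 1 g/L (1e−6 g/mm³); the density is a
config knob since tissue is ~1000× denser, but the default is kept at the
nominal value for continuity with the fecundity allometry's calibration.

## Potential distributions

A species' range is one or more lat/lon rectangles (multiple segments
encode constraints like "Atlantic only"); cells qualify if their centre
falls inside. The potential distribution intersects the range with an
inclusive depth filter on cell bathymetry and, optionally, a categorical
habitat-class filter; its area sums latitude-corrected pixel areas.
Filtering can only shrink a distribution, and areas are monotone in the
filters — both are property-tested. Range-mean environmental values are
plain means over occupied cells; depth-resolved variables can be averaged
only over levels inside the species' depth range.

## Proportion maps and reliability

Stacked occupancy masks give per-pixel richness and per-mode proportions
(undefined where richness is zero). Band summaries over 5° latitude bands
(25–70°) use three methodologies: *pooled* (one proportion from the
species present anywhere in the band), *pixel_mean* (mean ± sd of pixel
proportions over occupied pixels), and *filtered* (pixel_mean over pixels
passing both reliability screens). Empty bands are reported as missing,
never dropped silently.

N_min = ⌈((z_{1−α/2} + z_{power})/ΔP)²·P(1−P)⌉ is the normal-
approximation sample size for detecting an absolute deviation ΔP from
the reference proportion P; ΔP is absolute (0.30), which back-solves to
the canonical threshold of 20 species at P = 0.351. z quantiles are
1.95996 and 0.84162. Survey completeness per 0.5° occurrence pixel uses
Chao1 = S_obs + f1²/(2f2), with the classic fallback S_obs + f1(f1−1)/2
when f2 = 0 (the bias-corrected variant is available); pixels pass when
relative Chao1 < 1.2, and unsurveyed pixels fail rather than error.

The permutation test draws `n_perm` (default 100) species subsets of the
pixel's richness from the full pool *without replacement* and reports the
two-sided fraction of permuted proportions at least as far from the pool
reference as observed, counting ties as extreme (conservative). Under
null assembly its rejection rate at α = 0.05 calibrates to 0.05 within
Monte-Carlo error; the test suite checks this over 1000 simulated pixels
with richness 20–40 (a spread of sizes avoids lattice artefacts from the
hypergeometric support).

## Spatial regression

Proportions are logit-transformed with clipping at eps = 1e−3 (the
handling of exact 0/1 proportions is otherwise undefined). Candidate
predictor subsets must have all pairwise |Pearson r| < 0.65 and all
VIF < 3; subsets are enumerated exhaustively and the minimum-AIC spatial
fit wins, with ties (< 1e−9) broken toward the smaller subset.

All distances are haversine great-circle distances (R = 6371 km).
Correlograms use binary membership weights per distance bin (default
width 50 km); the patch size interpolates the first positive-to-negative
crossing of I(d) linearly between bin centres and is flagged missing when
no crossing exists. Weights are w_ij = 1/d_ij for 0 < d_ij ≤ patch size
(inverse-distance reading of "proportional to distance"; the exponent is
configurable), row-standardised; isolated rows stay all-zero and are
flagged; coincident points are an error.

The spatial lag model y = ρWy + Xβ + ε is estimated by maximum
likelihood: for given ρ, β and σ² concentrate out analytically and
ln|I − ρW| is evaluated exactly from the eigenvalues of W (fine at the
few-hundred-pixel scale of filtered maps). ρ is searched on the feasible
interval given W's spectrum; standard errors come from the numerical
Hessian of the profile likelihood over (ρ, β); significance of ρ is a
likelihood-ratio test against the ρ = 0 model, whose likelihood equals
OLS exactly (verified to 1e−6). Reported R² is the squared correlation
between observed values and the reduced-form prediction
(I − ρW)^{-1}Xβ; AIC counts β, ρ and σ².

## Trait structure and mode probability

Continuous traits are natural-log transformed and z-scored; mode and diet
enter as 0/1 dummies (all levels kept for PCA; regression designs drop a
reference level). PCA is an SVD of the centred matrix; loadings are
orthonormal and explained variance sums to one.

Mixed models use ML (not REML) throughout so likelihood-ratio tests
across models differing in random structure are valid. The linear mixed
model is a superfamily random intercept via statsmodels MixedLM; multiple
optimisers are tried and a boundary fit (group variance → 0) is accepted
with a warning — the boundary is an expected outcome, not a failure. R²
components follow the variance-partition convention: r2_fixed =
var(Xβ)/total, r2_group = σ²_group/total, with total = fixed + group +
residual. LRT p-values for the variance component use χ²(1), which is
conservative at the boundary (the 50:50 mixture convention would halve
them).

The binomial mixed model is a random-intercept logistic regression
estimated by Gauss–Hermite quadrature (21 nodes) over the group effect,
optimised with BFGS and a Nelder–Mead polish; it is implemented in-package
and cross-checked in the tests against lme4::glmer (nAGQ = 21) on shared
data. Observation weights multiply the log-likelihood contributions;
class weights are n/(k·n_c), summing to n. Predictions for accuracy use
the fixed effects plus empirical-Bayes (posterior-mode) group intercepts
at a 0.5 threshold; per-class accuracy is the recall of each class, and
total accuracy is their class-size-weighted mean. Complete separation is
flagged (fitted probabilities reproduce the outcome) rather than raised.

## The synthetic study system

The generator emulates the *structure* of the real study area — a
shallow, species-rich shelf strip along the western margin and a wide,
deepening offshore slope — not its geography or its real species. All
randomness flows from one seed through spawned substreams, so worlds are
bit-reproducible.

* Bathymetry: a cross-shelf ramp (~20–120 m over 4 columns) and a
  continuous slope (~160–900 m eastward), plus smooth noise.
* Temperature: linear poleward cooling (22 → 7 °C) plus smooth noise.
* Currents: stationary AR(1) series per pixel with prescribed means and
  standard deviations, so U and DS have known expectations (DS → 
  √(sd_u² + sd_v²) as the series lengthens).
* Chlorophyll: 19-year monthly sinusoid × lognormal noise. The seasonal
  amplitude varies only with longitude — a fixed mean plus a smooth,
  mean-centred zonal wiggle — so M_CHLA has zonal but *no meridional*
  structure, and is not monotone in longitude (decorrelating seasonality
  from the eastward-deepening bathymetry, which identification of the
  mode model requires). Centring the wiggle over the shelf columns keeps
  the realised pool composition near the reference share across seeds.
* Species: developmental mode is Bernoulli from the planted logistic
  model logit P(pelagic) = 5.0 − 0.0047·depth − 14.2·M_CHLA (negative
  depth and seasonality effects, mirroring the structure of the study's
  mode model; the intercept centres the pool near a 0.35 non-pelagic
  share under the synthetic covariate distribution). Pelagic species
  split planktotrophic : lecithotrophic at 51:10. Sizes are lognormal
  with mode-dependent shifts (non-pelagic largest initial volumes;
  planktotrophic the largest Gr1 ≈ 100), growth ratios clipped above 1 so
  IS ≤ JS ≤ AS always holds; DT and C follow the calibrated formulas at
  each species' range-mean temperature. Superfamily labels are assigned
  independently of mode by default (matching the finding of negligible
  phylogenetic signal in mode), with a coupling knob for power analyses.
* Ranges: shelf species span the full latitudinal extent and differ in a
  narrow cross-shelf column band; deep species occupy narrow offshore
  bands confined to high latitudes (range start uniform in 45–58° N).
  By default the shelf pool is therefore *stationary in latitude* — the
  exact null the artefact experiment requires. Setting
  `widespread_frac < 1` or `shelf_band_max_width` re-introduces
  latitudinally restricted shelf ranges and cross-shelf environmental
  variation respectively; the trait–environment recovery experiments use
  `shelf_band_max_width=1` to give species a spread of depth and
  seasonality exposures.
* Occurrences: per pixel and species present, detections are Poisson
  with mean equal to a sampling-effort field that declines exponentially
  poleward (scale 6 records/species at 25° N, e-folding 15°). High effort
  drives relative Chao1 → 1; low effort yields singleton-heavy pixels
  that fail the 1.2 screen.

The default world runs on a 90 × 20 grid of 0.5° pixels over 25–70° N.
Real analyses of this kind rasterise at hundreds of metres and bin
occurrences at 0.5°; running everything at 0.5° keeps the full pipeline
at seconds per world, and nothing in the method depends on the native
resolution beyond pixel counts. What passing tests show is therefore
that the *inferential machinery* behaves correctly under a controlled
data-generating process; they cannot show that real gastropod data meet
the generator's assumptions (independent detections, rectangular ranges,
a two-predictor mode model, superfamily-exchangeable species).

## The artefact experiment

`artefact_experiment(seed)` generates a world, stacks proportion maps,
derives N_min from the realised pool, applies the survey mask, and
summarises the non-pelagic proportion per band under `pixel_mean` and
`filtered`. Trends are tested with the Kendall rank correlation of band
proportion against band order — the Mann–Kendall statistic; a band
profile that is exactly constant is scored as "no trend" (p = 1) since
the correlation is undefined on ties. Expected behaviour, verified over
50 replicate worlds: `pixel_mean` shows a consistently positive,
usually significant poleward rise created purely by where the unreliable
pixels sit, and `filtered` shows no monotone trend in ≥ 90% of worlds.

## Known limitations

* Rectangular ranges and hard depth limits caricature real distributions;
  no occurrence-based distribution modelling is attempted.
* The SAR implementation is the lag model only (no error/CAR variants, no
  kriging), with dense matrices — appropriate up to a few thousand pixels.
* Superfamily random intercepts are a coarse stand-in for phylogeny; no
  branch-length-based comparative methods are possible or attempted.
* Chao1 completeness is a lower-bound heuristic: pixels can pass the
  screen by luck at very low effort, which is itself a small-sample
  artefact worth remembering when interpreting marginal survey regions.
* The equal-width Colwell classes follow the printed convention of the
  hydrological implementation the field uses; other binning conventions
  change M by up to ~0.05 on typical series.
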