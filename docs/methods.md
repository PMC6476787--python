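# Methods

`tundradiv` analyses hierarchical vascular-plant surveys along altitude
gradients: plots nested in stations, stations in 1 km transects, transects
in mountains, with transects placed in four elevation bands (700–900,
900–1100, 1100–1300, >1300 m; half-open intervals, lower edge inclusive).
This note documents the models and procedures, the defaults and why they
were chosen, the numerical decisions, and what the synthetic-data generator
does and does not emulate.

## Alpha diversity

* **Richness** is the species count of a 1 m² plot's presence set.
* **Cover** is a visually estimated proportion; models use
  `logit(p)` with `p` clamped to `[0.005, 0.995]`. The ε of 0.005 is half
  the 1% resolution of a visual estimate, so a recorded 0% or 100% maps to
  the nearest representable interior value. Clamped values are flagged.
* **Evenness** is the scaled Shannon index of station-pooled intercept
  counts: `J = H / ln S` with `H` the Shannon entropy in nats; `J = 0` is
  defined for single-species stations and barren stations are excluded
  (evenness of nothing is undefined). `J` is base-invariant, so nats are
  cosmetic.

## Beta diversity as distance to centroids

The plot × plot dissimilarity is the binary Bray–Curtis (Sørensen)
coefficient `1 − 2|a∩b|/(|a|+|b|)`. Two empty plots are defined to be
identical (distance 0) with a runtime warning — barren high-altitude plots
must not abort an analysis.

Sørensen does not satisfy the triangle inequality, so the dissimilarity
matrix is embedded by principal-coordinates analysis before any Euclidean
geometry: Gower-centre `−½D∘D`, eigendecompose, keep axes with
`|λ| > 1e−10·max|λ|`. Positive-eigenvalue axes are scaled by `√λ` (real
part), negative ones by `√(−λ)` (imaginary part). Keeping both parts makes
the signed reconstruction `Σ(Δreal)² − Σ(Δimag)²` reproduce the squared
input dissimilarities exactly (a tested identity), which standard
PCoA implementations that drop or correct negative eigenvalues do not.

A plot's beta diversity at a scale is its distance to the centroid (the
arithmetic group mean in both coordinate parts) of its group at that
scale: the five plots of its station, the 25 plots of its transect, or all
plots of its altitude band across mountains. One shared embedding serves
all three scales — distances between fixed points do not depend on the
grouping, so per-scale embeddings would change nothing while costing three
eigendecompositions. Negative squared distances, possible with imaginary
axes, are clamped to 0 and flagged, mirroring standard practice in
multivariate-dispersion analysis. Distances are computed per plot (one row
per plot per scale), which is what the trend models consume; a
`pooling="station"` option collapses each station to its pooled presence
set first, for analyses that want among-station distances instead.

## Altitude trend models

All responses are modelled against a centred altitude polynomial (degree 1
or 2) with nested random intercepts:

| response | family | random structure |
|---|---|---|
| logit cover | Gaussian | station ⊂ transect ⊂ mountain |
| richness | Poisson, log link | station ⊂ transect ⊂ mountain |
| evenness | Gaussian | transect ⊂ mountain |
| centroid distance | Gaussian | station ⊂ transect ⊂ mountain |

Centring the altitude before squaring tames the collinearity between the
linear and quadratic terms; the reported coefficients are back-transformed
to the raw-altitude parameterisation (delta-method standard errors), so a
quadratic fit's vertex is simply `−β₁/(2β₂)` metres. A vertex outside the
sampled range is reported with a warning, never "corrected".

Everything is ML, not REML, because the linear-vs-quadratic comparison is a
likelihood-ratio test between fixed-effect structures; coefficient p-values
are Wald-z approximations. Gaussian models go through statsmodels MixedLM
with variance components for the nested levels. The Poisson GLMM is fitted
by a Laplace-approximation ML routine implemented in this package: for
fixed random-effect SDs a damped joint Newton step finds the mode of fixed
effects and random effects, the Laplace marginal log-likelihood
`ℓ(y|η̂) − ½b̂ᵀD⁻¹b̂ − ½log|D| − ½log|ZᵀWZ + D⁻¹|` is evaluated, and the
SDs are profiled out by Nelder–Mead from two (four in thorough mode)
starts. In the zero-variance limit this reproduces the ordinary Poisson
GLM to ~1e−8 (a tested oracle).

The LRT enforces `ℓ(quadratic) ≥ ℓ(linear)`: a negative difference beyond
1e−6 triggers a refit in "thorough" mode (all MixedLM optimizers, extra
Nelder–Mead starts, best log-likelihood wins); Δℓ within convergence noise
clamps to χ² = 0. Thorough mode is also what makes estimates exactly
invariant to relabeling of mountains/transects/stations; the default
single-optimizer path can land in slightly different local optima
depending on label order, which is why it is not used for LRTs that come
out negative.

Beta diversity adds the scale factor and its interactions with the
altitude terms as fixed effects. The interaction is tested by a χ² LRT of
the full model against the additive one (4 df: two altitude terms × two
scale dummies); per-scale effects come from subset models. Pairwise scale
differences are contrasts of estimated marginal means at the mean altitude
with the Tukey studentized-range adjustment over the three comparisons,
using `df = n_obs − rank(fixed design)`.

### Calibration caveat

With altitude varying only between transects and ~11 transects, the χ²₁
reference for the quadratic-term LRT is anticonservative (about 11%
rejection at nominal 5% in simulation) — a small-sample property of
fixed-effect LRTs whose covariate varies at a sparsely replicated level,
not an estimation defect. The shipped calibration experiment therefore
draws altitude independently per station (60 observations, 3 mountains ×
4 transects × 5 stations), the regime the asymptotics assume, where the
measured type-I rate is ≈0.06. Inference on designs with few
altitude-bearing clusters should be read with this caveat.

## Nestedness (NODF)

For an ordered binary matrix, every ordered row pair (i above j) with
strictly decreasing fill contributes `100·overlap/fill(j)`; likewise
column pairs left-to-right; NODF is the sum over both divided by
`R(R−1)/2 + C(C−1)/2`. Zero-fill rows (barren plots, possible in null
draws) contribute 0 to every pair they join rather than being dropped, so
plot counts stay consistent across statistics. Orderings:

* **optimal** — rows by decreasing richness, columns by decreasing
  frequency, ties stable in input order (single-pass sort);
* **altitude** — rows ascending by altitude (ties by transect then plot
  label), columns by frequency; a `descending` flag provides the reversed
  diagnostic, since NODF under an imposed order is direction-sensitive;
* **altitude within mountain** — mountains in input order, ascending
  altitude inside each.

## Modularity (Barber's Q, BRIM)

`Q = (1/m) Σ_ij (B_ij − k_i d_j/m) δ(g_i, h_j)` over the bipartite
plot–species incidence. BRIM alternates exact label sweeps (each species to
its Q-maximising module given the plot modules, then the reverse) until the
gain drops below 1e−10; sweeps never decrease Q. The module count is
searched adaptively — start at 2, double while the best Q improves, then
bisect — capped at `min(R, C, 30)`. Each candidate count runs `n_restarts`
random starts (default 20) plus one start from reciprocal-averaging
quantile bins, plus any supplied partition; everything is deterministic
given the seed, and the winning restart is recorded.

Reciprocal averaging (correspondence analysis) is solved as the SVD of the
standardised residual matrix; scores are standard coordinates (zero
weighted mean, unit weighted variance), with the sign fixed so the
highest-altitude plot scores non-negatively. Disconnected incidence graphs
get per-component scores offset into disjoint ranges, with a warning.

Q is invariant to row order, so "altitude-sorted" modularity is
interpreted as seeding BRIM with the partition the altitude bands impose
(plots by band, optionally crossed with mountain; species by the band
holding most of their occurrences) alongside the usual restarts. The
band-imposed partition's own Q is available separately and is always a
lower bound on the optimised value.

## Null model and inference

The null model preserves species frequencies: each species' `d_j`
presences are placed in `d_j` distinct plots drawn uniformly,
independently per species. Column sums are conserved exactly; row sums are
free and rows may become empty (kept, see NODF above; an
`allow_empty_rows=False` option redraws until no plot is empty, off by
default). For each statistic,
1,000 draws (configurable) give the expectation and SD;
`Z = (obs − mean)/SD` (sample SD), and the empirical p is one-tailed in
the direction of the deviation with the add-one correction
`p = (extreme + 1)/(n_reps + 1)`, so the smallest attainable p at 1,000
draws is 1/1001. Optimal-ordering statistics are re-optimised on every
null draw (NODF re-sorted; BRIM re-run with 5 restarts per draw, the
dominant cost); altitude orderings re-apply themselves through the
unchanged row metadata.

## The synthetic survey generator

The generator emulates the field design exactly — 3 mountains × 4 bands ×
1 transect each (optionally dropping the last mountain's top transect for
the 11-transect layout), 5 stations per transect at nearly equal altitude
(SD 15 m), 5 plots per station, 125 intercept points per station — and
the statistical structure the analysis assumes:

* **Gaussian niches**: species s occupies a plot at altitude a with
  probability `max_occ_s · exp(−(a−μ_s)²/2σ_s²)` passed through a logit
  link with added nested random intercepts (mountain SD 0.2, transect SD
  0.3, station SD 0.5 on the logit scale), so occupancy stays in (0, 1)
  and plots within a station are positively correlated across species —
  the ingredient that makes richness heterogeneity, and hence nestedness,
  exceed the fixed-frequency null.
* **Pool structure**: 150 species; a `core_fraction` (default 0.25) get
  4× inflated niche widths and act as ubiquitous core species
  (nestedness knob); the rest are specialists whose widths shrink by
  `1/turnover_strength` (default 2; values ≥ ~4 give strongly
  band-aligned turnover, the modularity knob). Optima are uniform over the
  sampled range padded by 100 m; baseline widths are log-normal
  (median ≈ 150 m, log-SD 0.4). Occupancy maxima are uniform on
  (0.05, 0.95) — the heterogeneity that nestedness feeds on.
* **Cover** is an inverse-logit quadratic peaking at 850 m with value 0.6
  (curvature 6e−6 per m², logit noise SD 0.4) — a unimodal response with
  its maximum in the lower half of the gradient.
* **Intercept counts**: each of a station's 125 points touches a species
  with probability equal to the station's mean cover; the species is drawn
  proportionally to a per-species log-normal abundance weight (log-SD 1)
  among species present at the station; the rest are "no touch", so
  sparse high stations resemble field data.

One RNG stream per survey, split per mountain from the config seed, makes
output byte-identical across runs and invariant to generation order.

What the generator does **not** emulate: spatial autocorrelation within
stations (plots are exchangeable replicates), microhabitat covariates
(soil, snow, hydrology), interspecific interactions, detection error, and
taxonomic ambiguity (genus-level labels are ordinary taxa). Passing tests
therefore demonstrate that the estimators recover the structure this
generative model encodes, not that field data satisfy the model.

## Problem sizes used in tests and the acceptance run

The shipped test suite and acceptance script run everything at the survey's
own scale (275–300 plots, 150-species pool) except where an experiment
repeats fits many times: parameter-recovery experiments use 20 replicate
surveys, the LRT calibration uses 500 simulated datasets of 60
observations, power/pattern checks use 10–20 seeds, and null ensembles in
tests use 50–100 draws (the acceptance run uses the full 1,000). These
sizes are the package's own choices for tight, informative experiments.

## Known limitations

* Wald-z coefficient p-values and the Laplace approximation are both
  asymptotic; for 3 mountains the mountain-level variance is weakly
  identified and often estimated at ~0.
* The NODF "optimal" ordering is the single-pass richness/frequency sort;
  it is not guaranteed to be the global NODF maximiser over all
  permutations (no iterated re-sorting after tie-breaks).
* BRIM is a local optimiser; restarts plus the reciprocal-averaging start
  make it exact on small matrices (tested against enumeration) but give no
  global guarantee at survey scale.
* The empirical p is one-tailed by construction; two-sided users should
  double it.
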