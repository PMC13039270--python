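# Methods

## Model

Guild-level weekly species richness is treated as an over-dispersed count:
negative binomial (NB2, variance μ + μ²/θ) with log link. The linear
predictor stacks a *global* level — a cyclic cubic smooth of week, thin-plate
smooths of weekly mean temperature and precipitation, and an isotropic 2-D
thin-plate smooth of longitude/latitude — and a *guild* level: deviation
smooths of the same four covariates per guild, guild × habitat-cover random
slopes for the four fractional covers (crop, shrub, forest, grass), guild
random intercepts, and trap × guild random effects. A fixed offset
log(exposure_days / 7) makes the canonical 7-day trap week the unit of
effort; any other normalisation would only shift intercepts.

Global and guild terms are estimated jointly in one stacked penalized
design. The guild deviation smooths of a covariate share the wiggliness
smoothing parameter of the corresponding global smooth, so all guilds have
the same flexibility budget; data-rich guilds then inform how wiggly the
data-poor guilds are allowed to be. This was a genuinely open design point
(a two-pass scheme — global fit, then guild deviations — is also
conceivable); the joint fit was chosen because the shared-wiggliness
constraint is only well defined when both levels face a common penalty.
A single dispersion θ is shared across guilds (no evidence structure for
guild-specific dispersions at desk scale) and profiled during fitting.

## Bases and penalties

*Cyclic cubic regression splines* (season): coefficients are function values
at k = 6 equally spaced knots on [1, 53); the evaluation matrix is the
periodic natural interpolating cubic, so value, first- and second-derivative
continuity at the week-52/1 seam hold by construction, and the penalty is
the exact integrated squared second derivative (β'D'B⁻¹Dβ in the standard
banded parameterisation). The penalty null space is the constant function,
which the sum-to-zero constraint removes — the constrained seasonal penalty
is full rank and needs no extra shrinkage penalty.

*Thin-plate regression splines* (temperature, precipitation, space):
the full thin-plate smoother over up to 100 quantile-placed knots is
eigen-truncated to the k leading directions (Wood-style low-rank TPRS),
keeping the polynomial null space (constant + linear) exact. Covariates are
standardised to zero mean / unit SD first; for the spatial term this makes
the single isotropic 2-D smooth scale-free in lat/lon degrees. An isotropic
2-D smooth rather than a tensor product was chosen deliberately — with
standardised coordinates the degree-anisotropy argument for a tensor
product disappears, and the term count stays k = 6.

*Identifiability*: every smooth block is reparameterised onto the null
space of its training column sums (sum-to-zero constraint); the transform
is stored and reused verbatim at prediction time.

*Double penalty*: after the constraint, the remaining null-space directions
of each thin-plate penalty (one linear direction in 1-D, two in 2-D) get a
second penalty with its own smoothing parameter — one for the global block
and one shared across the six guild blocks of a family. This lets REML
shrink entire terms out of the model. Random-effect blocks (habitat slopes,
guild intercepts, trap × guild) are ridge-penalized, i.e. variance
components in the smooth-as-random-effect sense.

## Fitting

Inner loop: penalized IRLS (Fisher scoring weights w = μθ/(θ+μ)) with
step-halving on the penalized deviance, convergence at relative change
< 1e-8, cap 200 iterations. Outer loop: every smoothing parameter is
updated by the extended Fellner–Schall multiplicative step

  λ_j ← λ_j · [tr(S_λ⁻ S_j) − tr((X'WX + S_λ)⁻¹ S_j)] / (β̂' S_j β̂),

whose fixed point is the stationary point of the Laplace-approximate
restricted marginal likelihood; θ is profiled by bounded 1-D likelihood
maximisation each outer iteration. This optimizer was chosen over
numeric-gradient quasi-Newton because it needs one linear solve per
iteration instead of O(#λ) full refits — with 13 smoothing parameters and
~770 coefficients at the recovery scale that is the difference between
seconds and hours — and because each update is available in closed form
from quantities the fit already computes. Per-update log-λ steps are
clamped to ±4 and λ to [1e-7, 1e11]. Because the λ of a fully shrunk term
drifts geometrically toward the clamp without changing the fit, outer
convergence is judged on per-block EDF stability (max change < 0.02) rather
than on λ itself; fully-shrunk λ drift is expected behaviour, not
non-convergence. Coefficient uncertainty uses the Gaussian posterior
V = (X'WX + S_λ)⁻¹ at the converged fit (φ = 1 for NB); EDFs are
tr(V X'WX) summed per block. The fixed-λ path is checked against direct
numerical optimisation of the penalized NB log-likelihood, and the
selection path against mgcv's `gam(..., method="REML", select=TRUE)` during
development (seed-by-seed agreement of the shrinkage EDF distribution).

## Phenology

The average temperature trend is a cyclic penalized smooth of cross-site
weekly mean temperature with GCV-chosen λ on a 41-point log grid. Guild
trends predict weekly richness (offset 0, i.e. per standard trap week) with
week 1..52, temperature on that curve, precipitation and covers at training
means, spatial terms and trap effects excluded (zero); the reference values
are recorded on each trend object. Phenophase rules: threshold
τ = SR_min + 0.1·SR_max; start = first week ≥ τ, peak = earliest week
attaining SR_max (deterministic tie-break), end = last week ≥ τ. A flat
trend (SR_max = SR_min) is returned flagged `degenerate` instead of
raising. Intervals are 2.5/97.5 percentiles of phase positions across
posterior draws of the trend; the point estimate is the prediction at β̂
(the posterior mode under the Gaussian approximation). Host–parasitoid lags
are paired peak-week differences, with intervals from draw-wise pairing.

## Scenarios and grids

Habitat covers are near-compositional, so counterfactuals move all four
covers jointly between common configurations: either the four bundled
compositions (grass-dominated, agricultural mosaic, mixed mosaic, heavily
forested — kept verbatim as published to 3 significant figures, hence sums
of 0.96–0.99; the prediction-time sum check uses a 0.05 tolerance to admit
that rounding) or compositions reconstructed at evenly spaced quantiles of
PC1 of the observed centred cover matrix, clipped and renormalised. Grid
prediction repeats per guild, flags (never drops) cells outside the convex
hull of training coordinates, and supports term subsets for partial-effect
maps with non-focal terms set to zero.

## Synthetic data

The generator emulates the survey design: n_sites (default 200) uniform
over lat 55–69° N / lon 11–24° E; habitat compositions drawn from the four
cover archetypes with Dirichlet jitter, renormalised; weekly samples
(exposure 7 d) for weeks 14–43 ("April–October" on a fixed 52-week year)
and one sample per off-season month at the month's mid-week with the
month's length as exposure; sites above 66° N skip the off-season. Weekly
temperature is a latitude-shifted cosine climatology plus N(0, 1.5²)
anomalies; precipitation is Gamma(2, 2) noise with no effect on richness.
The log richness mean adds: guild baseline (saprophages winter-richest),
latitudinal gradient (−0.06 per degree), a cyclically wrapped Gaussian
seasonal bump (host peaks at weeks 22–24; parasitoid peak = host peak +
lag, defaults 1 week for phytophages and 5 for predators and saprophages),
a guild temperature response applied to the *temperature anomaly* (linear
or tanh-saturating), habitat slopes qualitatively matching the published
preferences (agricultural-mosaic responders vs grass/forest specialists),
and a N(0, 0.3²) site effect. Counts are gamma–Poisson draws, exact NB2
with real-valued θ (default 5). Applying the temperature response to
anomalies rather than raw temperature keeps the configured bump peak the
exact argmax of the noiseless truth curve — configured phenophases are then
exact ground truth — while still giving the model a real guild-specific
temperature signal; it also means simulated seasonality is *not* driven by
the temperature covariate, unlike (presumably) real communities.

What the generator does not emulate: metabarcoding detection error,
taxonomic mis-assignment, spatially autocorrelated habitat or temperature
fields beyond the latitude trend, multi-year dynamics, and guild-specific
dispersions. Passing recovery tests therefore demonstrates correctness of
the estimation machinery under the model's own assumptions, not robustness
to the messiness of real survey data.

## Problem sizes and numerical choices

Recovery tests use 100 sites × 30 in-season weeks × 6 guilds (18,000 rows,
~770 coefficients) with 20 replicates, and 500-observation single-guild
fits with 50 replicates for the shrinkage study; these sizes give stable
medians while keeping a full test run in minutes on one CPU. Posterior
draws: 200 for credible intervals in examples, 10,000 for covariance
calibration checks. Penalty matrices are symmetrised and eigenvalue-clipped
at zero; the normal equations get escalating diagonal jitter (from 1e-10 of
the mean diagonal) only if a Cholesky fails; linear predictors are clipped
to ±30 before exponentiation inside deviance evaluations.

## Known limitations

* A zero-effect covariate's term EDF falls below 0.5 in roughly 75–85% of
  replicate fits, not more: after the sum-to-zero constraint the thin-plate
  null space is a single linear direction — a one-level variance component —
  and REML leaves it at the boundary only when the spurious slope's t² is
  below ~2 (probability ≈ 0.84 under the null, independent of n). The
  *typical* EDF of a null term is ~0.001–0.01 ("penalised out"); the cap on
  the shrinkage *rate* is a property of REML selection itself, reproduced
  exactly by mgcv's `select=TRUE` on the same data.
* Smoothing-parameter uncertainty is ignored (V is conditional on λ̂, θ̂),
  so credible intervals are mildly anti-conservative.
* The spatial term is a smooth surface, not a spatial-error model; residual
  autocorrelation at sub-smooth scales leaks into the trap random effects.
* Phenophases are resolved to whole weeks; a 1-week configured lag is at
  the resolution limit and recovered lags of 0–2 weeks are expected.
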