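# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `camshield`.

## Detection records and the independence filter

Input records are (station, species, timestamp) rows; a survey design
table gives each station's grid cell, deployment start date and number of
daily occasions. Stations and grid cells are one-to-one in the default
design; when a station carries two cameras, their records are pooled —
the grid cell, not the camera, is the sampling unit.

Repeated triggers of the same animal are collapsed with a greedy
independence filter: within each (station, species) group, scanned in
time order, an event is retained iff it falls at least `window_minutes`
(default 15) after the last *retained* event of that group. Anchoring at
retained events makes the rule deterministic, order-independent and
idempotent; an all-pairs sliding rule would not be. The filter can
optionally pool a species across stations (`scope="survey"`), since
survey-wide application is a defensible alternative reading of the
independence convention; per-station is the default because the rule
exists to remove repeated triggers of one animal at one camera.

Occasions are local calendar days starting at midnight. Clock time, not
sun time, defines both occasions and the diel circle: the surveys this
targets are short (weeks) and within one time zone, so sunrise drift is
negligible relative to the 24-h structure. Stations may have unequal
deployment lengths; occasions outside a station's window are *missing*
(not zero) in detection histories.

## Co-occurrence occupancy model

Latent presence of the S detection units at a site is z ∈ {0,1}^S with

    P(z) = exp( Σ_s f_s z_s + Σ_{j<k} f_jk z_j z_k ) / Z,

the multinomial-logit natural parameterisation; the all-absent state has
weight 1. First-order f_s is the log-odds of unit s occurring alone;
second-order f_jk > 0 means units j and k co-occur more than expected
under independence. Third-order terms are never estimated (S ≤ 3, and
pairwise terms are the scientific quantity of interest). No covariates
are modelled on ψ or p; the survey designs this targets are single-season
and covariate-free.

Detection is occasion-wise Bernoulli per guild with constant p_s, and the
likelihood is kept history-exact (Bernoulli product, no binomial
coefficient), so the site likelihood is

    L_i = Σ_z P(z) Π_s g(y_is | z_s),   g = p_s^{y_is} (1-p_s)^{K_is - y_is}

for z_s = 1 and the indicator of an all-zero history otherwise. With
constant p the likelihood depends on histories only through per-guild
detection counts, so sites are compressed to unique count patterns before
optimisation.

**Fitting.** Parameters (f's plus logit p's, ≤ 9 in total) are estimated
by L-BFGS-B with finite-difference gradients from three starts: f = 0 and
logit p at the naive detection rate, plus seeded uniform(-0.5, 0.5)
jitters. All parameters are box-bounded at ±15 on the estimation scale,
which keeps degenerate data (e.g. a guild with zero detections, which is
warned about) on a finite boundary instead of diverging. The covariance
is the inverse of a central-difference observed information matrix; if
that matrix is numerically singular the fit is returned with interval
methods disabled and a warning. AIC = 2k − 2ℓ ranks models; ties below
1e−9 go to the smaller model.

**Derived quantities.** Marginal ψ_s, pairwise P(z_s = z_t = 1) and
conditional P(z_s = 1 | z_t) are sums or ratios over the fitted state
distribution. Default intervals are delta-method (numerically
differentiated on the natural-parameter scale, truncated to [0, 1]); a
seeded parametric bootstrap (simulate from the fit, refit, percentile) is
available where the Wald approximation is doubtful, e.g. estimates near
the boundary.

## Diel activity overlap

Clock times map to angles 2π·(seconds since midnight)/86400. Activity
densities are von Mises kernel estimates; the kernel concentration comes
from the standard plug-in rule for circular data — the maximum-likelihood
von Mises concentration κ̂ (solving I₁(κ)/I₀(κ) = R̄) inserted into the
asymptotic MISE-optimal formula

    κ* = ( 3 n κ̂² I₂(2κ̂) / (4 √π I₀(κ̂)²) )^{2/5},

times an estimator-specific adjustment (0.8 for the grid estimator Δ̂₁,
1.0 for Δ̂₄/Δ̂₅). Bessel ratios use exponentially scaled functions, so the
rule is overflow-safe; kernels are capped at κ = 2000 (with a warning),
beyond which the default 512-point grid cannot resolve them anyway.

The coefficient of overlapping Δ = ∫ min(f, g) ∈ [0, 1] is estimated by:

- **Δ̂₁** — Riemann sum of min(f̂, ĝ) on the angular grid (T = 512 by
  default, finer than typical reference grids; Riemann error is
  negligible at that resolution);
- **Δ̂₄** — ½[ n₁⁻¹ Σ min{1, ĝ(xᵢ)/f̂(xᵢ)} + n₂⁻¹ Σ min{1, f̂(yⱼ)/ĝ(yⱼ)} ];
- **Δ̂₅** — P̂_f(f̂ ≤ ĝ) + P̂_g(ĝ < f̂), the empirical-probability form of
  ∫min; it is exactly symmetric only up to ties, and is clamped to [0, 1].

Estimator choice follows the sample-size recommendation: Δ̂₄ when the
smaller sample exceeds 75, Δ̂₅ between 50 and 75, otherwise Δ̂₁ with a
warning (below the range for which the point estimators were validated).
Classification: Δ < 0.5 low, 0.5–0.75 moderate (boundaries inclusive),
> 0.75 high.

**Uncertainty.** Bootstrap with B resamples (default 1000, minimum 100):
the default smoothed scheme draws each resample from the fitted kernel
density (resampled data point plus von Mises kernel noise), re-estimating
bandwidths per resample; a plain nonparametric resample is available.
Intervals default to the *recentered* basic form 2Δ̂ − q_{1−α/2}, 2Δ̂ −
q_{α/2}: kernel smoothing biases Δ̂ upward in small samples and the raw
percentile interval inherits that shift twice over, which measured well
below nominal coverage in simulation (≈ 45% vs 95% at n = 100), while the
recentered interval was at nominal level. Raw percentile bounds remain
available (`interval="percentile"`) for comparability with conventions
that report them.

## Spatiotemporal overlap

Independent records aggregate into per-guild grids × 24 count matrices
(floor of local clock hour; counts summed over the whole survey). Counts
are stored un-binarised; binarisation to *active cells* — (grid, hour)
pairs with count > 0 — happens only when statistics are computed, keeping
rate-based extensions possible.

Denominators are explicit because several conventions circulate:

- exclusive proportion of guild g: |cells(g) \ ∪ others| / |cells(g)| —
  the share of g's own activity cells where it was alone;
- pairwise and triple overlap: Jaccard, intersection over union of the
  sets involved.

Per-guild exclusive denominators are the only internally consistent
choice when the three exclusive proportions exceed 1 in sum, as reported
values in this literature do; every output row carries its numerator and
denominator so alternative conventions can be recomputed. Venn region
counts of the 3-set partition are emitted for external diagram rendering.

Uncertainty comes from resampling grids (the independent spatial units of
the design) with replacement, each draw carrying the grid's full record
set as a distinct pseudo-grid, with all statistics recomputed per
resample; 95% percentile intervals and bootstrap SEs are reported. The
resampling unit is the grid rather than records or grid-hours because
records within a grid share one camera placement and are not
exchangeable. Resamples where a statistic is undefined (empty focal set)
are dropped from its percentiles.

## Synthetic surveys

The generator draws grid-level guild presence from the same
multinomial-logit state distribution the model fits, then produces
timestamped records through a Poisson encounter process: each occupied
(grid, species, day) yields Poisson(λ_species) events whose clock times
follow the species' von Mises diel mixture. One mechanism therefore
drives day-level histories and event times alike, and the implied
per-occasion guild detection probability p = 1 − exp(−Σ member λ) is
exact, so recovery tests have closed-form truth. Unoccupied sites never
produce records (no false positives). Species within a guild share the
guild's latent presence but have independent encounter rates. All
randomness flows from one root seed through named substreams (presence,
counts, times).

The survey-scale preset emulates a gridded corridor survey: 88 one-km²
grids, 20 concurrent days; guild marginal occupancies (0.78 prey, 0.42
predator, 0.38 human) obtained by deterministic inversion of the state
distribution with fixed second-order truth (prey–human +1.25,
prey–predator 0, predator–human 0); encounter rates chosen so expected
independent captures approximate a heavily human-used corridor (humans
≈ 1.6 events per occupied site-day, spotted deer 0.35, the other
ungulates 0.10, tiger 0.11, leopard 0.07); and diel mixtures that make
humans, spotted deer and wild boar diurnal, tiger and sambar nocturnal,
and leopard and barking deer crepuscular (bimodal). The prey–human
interaction of +1.25 puts conditional prey occupancy near 0.90 given
human presence versus 0.71 given absence, the magnitude of contrast the
human-shield literature reports.

What the generator does **not** emulate: camera failures and unequal
effort, landscape covariates and spatial autocorrelation of presence,
animal movement (records are independent given presence, so
within-guild temporal clustering beyond the Poisson day structure is
absent), false positives and misidentification, and seasonal turnover.
Passing recovery tests therefore show the estimators are correct under
the stated model, not that the model captures every feature of field
data.

## Problem sizes in tests

The test suite exercises the estimators at sizes chosen to make the
statistical properties sharp but cheap to verify: parameter recovery uses
300 sites × 20 occasions × 40 replicates (Wald coverage ≥ 85% per
parameter); model-selection power uses 20 replicates at 300 sites;
the qualitative human-shield pattern uses 20 replicates of the preset
scaled to 300 grids; bootstrap coverage for Δ uses 30 sample pairs of
n = 100. Exhaustive-enumeration oracles (site likelihood, spatiotemporal
set statistics) run at full combinatorial coverage for S ≤ 3, K ≤ 3 and
≤ 10 grids respectively.

## Known limitations

- Wald/delta-method intervals can degrade near parameter boundaries; the
  parametric bootstrap is the fallback, at real computational cost.
- Δ̂ point estimators retain positive small-sample bias (order +0.05 at
  n = 100 for moderately overlapping densities); the recentered bootstrap
  interval corrects the interval, not the point estimate.
- The Jaccard convention for pairwise spatiotemporal overlap is a
  documented reconstruction of a convention the field reports
  inconsistently; outputs carry denominators precisely so results can be
  re-expressed under other conventions.
- Occupancy fitting supports 2 or 3 detection units with at most pairwise
  interactions; larger assemblages need a different parameterisation.
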