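# Methods

## Scope and model

`fishamr` estimates the activity component of field metabolic rate in
fishes.  The chain is: (1) intermittent-closed respirometry trials →
per-fish SMR and MMR; (2) stereo-video tracks → distance-corrected lengths
and mean field swimming speeds; (3) flume maximum-speed records → a
size/aspect-ratio model of v_max; (4) three hierarchical Bayesian
regressions tie each quantity to body size; (5) log-linear interpolation
between SMR (speed 0) and MMR (speed v_max) at the average field speed
gives AMRfield per species and 1-cm length class, with FAS = MMR/SMR and
the time-weighted FSA; (6) visual-census counts scale individuals to areal
assemblage demand.

Assumptions worth stating explicitly:

* metabolic rate is an exponential (log-linear) function of swimming speed
  between the SMR and MMR anchors; no plateau near v_max is modeled;
* MMR is reached exactly at v_max, and the first post-chase respirometry
  cycle measures MMR;
* fish rest `rest_hours` per day (default 12) at exactly SMR; digestion
  (SDA) and reproduction costs are outside scope;
* all rates are whole-animal g O₂ d⁻¹ at a single temperature; masses g,
  lengths cm, speeds cm s⁻¹.

## Respirometry extraction

ṀO₂ per closed cycle is `slope × (chamber volume − fish volume) × 1440 /
1000` with fish volume from mass at 1 g ml⁻¹.  SMR is the mean of the
⌈10%⌉ lowest cycle rates after outlier removal, excluding the first
(MMR) cycle; the ceiling keeps at least one value in small trials.
Outliers are removed on log10(rate) outside median ± 5·scaled-MAD.  The
log scale is used because cycle rates vary multiplicatively around the
resting baseline, and the 5-MAD threshold removes only order-of-magnitude
departures (probe/flush faults) while never trimming the genuine resting
tail — a 3-MAD rule on either scale cannot do both.  Both the fraction and
the threshold are arguments.  Trials whose extracted SMR exceeds MMR are
excluded with a logged reason rather than clamped.

## Hierarchical regressions

All three models share one engine: y = (a + a_j) + (b + b_j)·x (+ c·z),
with Normal (metabolic rates) or Student-t (speeds) likelihood.  Priors:
global slope Normal(0.75, 0.1) for the MR model (the metabolic-scaling
prior) and Normal(0, 5) elsewhere; intercepts Normal(0, 5); group offsets
Normal(0, τ) with τ ~ half-Normal(1); σ ~ half-Normal(1); ν = 2 + g with
g ~ Gamma(2, 0.1)-shaped tail (ν > 2 keeps the variance finite).  All are
overridable per fit.

### Sampling

The sampler is an affine-invariant ensemble (emcee) over an unconstrained
parametrization (log transforms for σ, τ, ν−2; offsets non-centered as
τ·u), with covariates centered internally and draws mapped back, and
differential-evolution moves (80% DEMove, 20% DESnookerMove).  Ensemble
samplers alone mix poorly across hierarchical funnels, in both directions:
with centered offsets the walker population collapses into the small-τ
spike and its differential proposals can never re-expand; with
non-centered offsets a well-identified τ moves only through coordinated
(τ, u) proposals.  We therefore interleave, every `gibbs_interval` (10)
ensemble steps, an ancillarity–sufficiency sweep on each τ: several 1-D
Metropolis updates of log τ holding u (efficient when τ is weakly
identified), followed by an exact inverse-CDF Gibbs draw of τ from
p(τ | offsets) with u rescaled so the offsets are unchanged (efficient
when the offsets are pinned by data).  On a fixture where the slope-offset
SD is weakly identified, this reproduces a JAGS gold-standard fit of the
identical model (posterior of the global slope and of τ_b agreeing to well
within Monte-Carlo error), where the plain ensemble under-covered.

Defaults: 4 independent ensembles (chains) × 4000 steps, walkers =
max(2·dim + 2, 48), first half discarded, thinned by 4.  Walkers start
from a jittered MAP point (L-BFGS).  Convergence is gated on split R-hat ≤
1.01 computed across ensembles (arviz); fits that fail raise with the
draws attached.  Within an ensemble the retained (step, walker) samples
are flattened into the draw dimension, which is exact for posterior
summaries but makes the reported ESS an approximation (walker correlation
is not resolved by the flattening); R-hat across independent ensembles is
the binding diagnostic.

Exact zero-noise data make the posterior degenerate and stall any MCMC;
recovery tests therefore use small-but-finite noise where a "zero-noise"
limit is meant.

### Prediction and R²

`predict_expected` returns the posterior of the expected value 10^μ — no
residual noise — because the field speed enters the pipeline as an
*average* speed and SMR/MMR/v_max enter as medians; posterior-predictive
draws (with Normal or Student-t residuals) are available behind
`include_residual=True`.  The posterior median commutes with the monotone
back-transform.  For the max-speed model an unseen family × body-shape
group is allowed: its offsets are drawn fresh from N(0, τ) per posterior
draw, widening the interval.  The Bayesian R² is per-draw
Var(μ)/(Var(μ) + σ²·ν/(ν−2)).

## The estimate grid

Per species, integer lengths from the configured minimum to maximum:
mass = lw_a·L^lw_b; SMR/MMR/v_max as posterior medians; `n_iter` (1000)
draws of expected field speed → `n_iter` AMRfield and FSA values; FAS from
the joint SMR/MMR draws at matching posterior indices.  The asymmetry —
medians for the AMRfield inputs, full draws for FAS — is deliberate and
mirrors the two-stage design of the estimation procedure.  Summaries are
mean, SD and the equal-tailed 95% interval.  AMRfield is never capped at
MMR: field-speed draws above v_max extrapolate the log-linear relation and
are counted in `n_extrapolated`.  A consequence worth knowing: with the
heavy-tailed speed model, large size classes of fast-swimming species can
show mean AMRfield above the MMR median.

## Assemblage scale-up

Census lengths are nearest-cm (half-up rounding into the grid).  Transect
density is Σ(count × rate)/area; a site is the mean ± SD of its transect
densities rather than a pooled sum, because transect areas differ and the
mean-of-densities is the design-consistent summary.  Per-individual rates
are the grid's SMR median and AMRfield mean (point summaries).

## Synthetic data

The generator emulates the full study design with known truth: six reef
species spanning grouper-like piscivores to small grazing herbivores, with
Table-like intercepts/exponents (SMR at 1 g around 0.003–0.004 g O₂ d⁻¹,
exponents 0.68–0.78), length–weight coefficients near W = 0.02·L³, masses
log-uniform over 5–500 g (spreads leverage evenly in log space for slope
estimation), speed residual σ = 0.37 log10 units with Student-t (ν = 5)
tails, and within-fish SMR/MMR residual correlation ρ = 0.5 (a free knob,
not an estimated quantity).  Respirometry trials default to 150 cycles of
8 min (~24 h): the first carries true MMR, 15% of the rest sit exactly on
the SMR floor, the others are elevated by 10^Exponential(0.15), with
log-normal cycle noise (σ = 0.02) and optional gross low outliers
(multiplicative factors 0.02–0.1).  Census transects hold a fixed number
of fish allocated multinomially over configured relative abundances.
Every generator is a pure function of (config, seed), with independent
seed streams per table.

What the generator does **not** emulate — and hence what green tests do
not certify about real data: temperature effects, background (microbial)
respiration drift within trials, diel activity cycles in the filmed
speeds, size-selective detectability in the census, and correlated
measurement error between cameras.

## Design choices and limitations

* A recovery-study helper centers the drawn species slope offsets so the
  realized mean slope equals the nominal global exponent exactly; the
  recovery experiment then measures estimation error, not the finite-
  species sampling of offsets.
* The group-SD grid for the exact Gibbs draw spans 10⁻⁴–30 (500 log-spaced
  points); SDs below 10⁻⁴ log10 units are indistinguishable from no group
  effect.
* Robustness of the Student-t likelihood is demonstrated on a fixture
  where outliers dominate the error budget (σ_v = 0.1, ν = 30 base noise,
  5% gross outliers); under the default σ_v = 0.37 the comparison is
  diluted by ordinary residual noise.
* Sample sizes in the test suite (e.g. 6 species × 10 fish for recovery,
  20 replicates at 4 species × 8 fish for coverage) are the package's
  reference study sizes; they match the scale of a realistic single-reef
  campaign.
* Model comparison (LOO/WAIC), phylogenetic covariance, temperature terms
  and nocturnal activity are out of scope.
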