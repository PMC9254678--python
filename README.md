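# fishamr

Estimating the metabolic rate of free-swimming fishes — the *field active
metabolic rate* (AMRfield) — by combining three things a reef ecologist can
actually measure: laboratory respirometry (standard and maximum metabolic
rates), swimming speeds of unrestrained fish filmed with stereo-video, and
maximum swimming speeds from flume experiments.  Individual estimates scale
up to assemblage-level metabolic demand from standard visual-census data.

The package is aimed at fish ecophysiologists and reef ecologists who want
field metabolic estimates without telemetry tags or destructive sampling.

## The model

Whole-animal metabolic rate is assumed to rise log-linearly with swimming
speed between two anchors: SMR at speed zero and MMR at the maximum
sustainable speed v<sub>max</sub>:

    log10 AMRfield = log10 SMR + (log10 MMR − log10 SMR) · v_field / v_max

Two derived scopes summarize the result: the factorial aerobic scope
FAS = MMR/SMR, and the factorial scope for activity over a day with *t*
resting hours,

    FSA = ((24 − t)·AMRfield + t·SMR) / (24·SMR).

The four ingredients come from three hierarchical Bayesian regressions on
log10-transformed data:

* **Metabolic rates** — log10 MR ~ Normal(μ, σ) with
  μ = (a + a<sub>jk</sub>) + (b + b<sub>jk</sub>)·log10 mass, grouped by
  species *j* × rate type *k* ∈ {SMR, MMR}.  The global slope *b* (the
  mass-scaling exponent) carries an informative Normal(0.75, 0.1) prior.
* **Field swimming speed** — log10 v ~ Student-t(ν, μ, σ) with species
  varying intercepts/slopes on log10 length; the heavy-tailed likelihood is
  robust to video-tracking outliers.
* **Maximum swimming speed** — as above plus a linear caudal aspect-ratio
  term, grouped by family × body shape.

Per species and 1-cm length class, SMR, MMR and v<sub>max</sub> enter as
posterior medians while 1000 posterior draws of the expected field speed
propagate uncertainty into AMRfield and FSA; FAS is computed draw-wise from
the joint SMR/MMR posterior.  Census records (species × length × count per
transect) then give areal totals in g O₂ m⁻² d⁻¹.

Sampling uses an affine-invariant ensemble (emcee) with differential-
evolution moves, interleaved with ancillarity–sufficiency Metropolis/Gibbs
sweeps on the group-SD parameters; convergence is gated on split R-hat ≤
1.01 (arviz).  A synthetic-data module generates all five input tables from
known ground truth, so every stage is testable end to end.

## Worked example

```sh
python examples/03_hierarchical_allometry.py
```

fits the metabolic-rate model to a synthetic six-species study whose true
global scaling exponent is 0.75 and prints:

```
             mean  median      sd  ci_2.5  ci_97.5    rhat          ess
parameter
a         -2.2089 -2.2108  0.0723 -2.3486  -2.0632  1.0042   95473.2860
b          0.7550  0.7550  0.0109  0.7338   0.7766  1.0033  118030.6869
sigma      0.0461  0.0459  0.0026  0.0413   0.0516  1.0022  120062.3686
tau_a      0.3066  0.2941  0.0727  0.2013   0.4784  1.0001  118499.9621
tau_b      0.0339  0.0323  0.0127  0.0136   0.0629  1.0020  109598.5013

global scaling exponent: 0.755 (truth 0.75, 95% CI 0.734-0.777)
max split R-hat: 1.0047 (converged at <= 1.01)
Bayesian R2: 0.991 (0.988-0.992)
```

`b` is the recovered mass-scaling exponent (truth 0.75); `tau_a`/`tau_b`
are the between-group SDs of intercepts and slopes; the Bayesian R² is the
posterior variance-explained of the regression.  The other examples walk
through respirometry extraction (`01`), stereo-video corrections (`02`),
the full AMRfield/FAS/FSA grid (`04`) and the assemblage scale-up (`05`).

A thin CLI wraps the same functions for shell use:

```sh
fishamr simulate --seed 1 --outdir synthetic
fishamr run --config run.yaml        # respirometry -> fits -> grid -> sites
```

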