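"""Hierarchical Bayesian regressions for metabolic and swimming allometry.

Three models share one engine, a varying-intercept/varying-slope regression
on log10-transformed data:

* metabolic rates: log10 MR ~ Normal(mu, sigma) with
  mu = (a + a_jk) + (b + b_jk) * log10 mass, grouped by species x rate type
  (SMR or MMR).  The global slope b carries the informative metabolic
  scaling prior Normal(0.75, 0.1).
* field swimming speed: log10 v ~ Student-t(nu, mu, sigma) with
  mu = (a + a_j) + (b + b_j) * log10 length, grouped by species.  The
  Student-t likelihood makes the fit robust to tracking outliers.
* maximum swimming speed: as above plus a linear caudal aspect-ratio term
  c * AR, grouped by family x body shape.

Group offsets are non-centered (offset = tau * u, u ~ N(0, 1)) with
half-Normal priors on the group SDs tau.  Per-group coefficients are the
sums of global and offset draws, taken jointly from the posterior.

Sampling uses an affine-invariant ensemble sampler (emcee) with a
vectorized log-posterior, interleaved with ancillarity-sufficiency sweeps
on the group SDs (Metropolis on log tau plus an offset-preserving exact
Gibbs redraw) so the hierarchical funnel is traversed in both its
weakly- and strongly-identified regimes.  Independent ensembles act as
chains for split R-hat; within an ensemble the retained (step, walker)
samples are flattened into the draw dimension.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln

from ._exceptions import ConvergenceError, InputError

__all__ = [
    "Priors",
    "SamplerSettings",
    "ModelFit",
    "fit_mr_model",
    "fit_speed_model",
    "fit_maxspeed_model",
    "predict_expected",
    "bayes_r2",
    "mr_group",
]

log = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)

# grid for the exact draw of a group SD from its conditional p(tau | offsets);
# the 1e-4 floor only bounds the numerical range (group SDs that small are
# indistinguishable from no group effect on log10 data)
_TAU_GRID = np.geomspace(1e-4, 30.0, 500)
_LOG_DTAU = np.log(np.gradient(_TAU_GRID))


def _sample_tau(s2, n_groups, scale, rng):
    """Draw tau ~ p(tau | offsets) per row of ``s2`` (sum of squared
    offsets): tau^-G exp(-s2 / 2 tau^2) x half-Normal(scale), sampled by
    inverse-CDF on the grid."""
    tau = _TAU_GRID[None, :]
    lw = (
        -n_groups * np.log(tau)
        - 0.5 * (tau / scale) ** 2
        - 0.5 * np.atleast_1d(s2)[:, None] / tau**2
        + _LOG_DTAU[None, :]
    )
    lw -= lw.max(axis=1, keepdims=True)
    cdf = np.cumsum(np.exp(lw), axis=1)
    cdf /= cdf[:, -1:]
    idx = np.argmax(cdf >= rng.random(len(cdf))[:, None], axis=1)
    return _TAU_GRID[idx]

@dataclass(frozen=True)
class Priors:
    """Prior hyperparameters (weakly informative defaults; the MR fit
    overrides the slope prior with the metabolic-scaling Normal(0.75, 0.1))."""

    slope_mean: float = 0.0
    slope_sd: float = 5.0
    intercept_mean: float = 0.0
    intercept_sd: float = 5.0
    coef_sd: float = 5.0
    group_sd_scale: float = 1.0
    sigma_scale: float = 1.0
    nu_shape: float = 2.0
    nu_rate: float = 0.1


@dataclass(frozen=True)
class SamplerSettings:
    """Ensemble-sampler budget and convergence contract.

    ``n_chains`` independent ensembles of ``n_walkers`` walkers run for
    ``n_steps`` steps; the first ``burn_frac`` of steps is discarded and the
    rest thinned by ``thin``.  A fit whose worst split R-hat exceeds
    ``rhat_threshold`` raises :class:`ConvergenceError` (draws attached)
    unless ``check_convergence`` is off.
    """

    n_chains: int = 4
    n_steps: int = 4000
    burn_frac: float = 0.5
    thin: int = 4
    n_walkers: int | None = None
    gibbs_interval: int = 10
    rhat_threshold: float = 1.01
    check_convergence: bool = True


class _ModelDef:
    """Internal: data + parameter layout + vectorized log-posterior."""

    def __init__(self, y, x, group_idx, n_groups, *, z=None,
                 student_t=False, known_sigma=None, priors=Priors()):
        self.y = np.asarray(y, float)
        # center covariates: decorrelates intercepts from slopes, which the
        # ensemble sampler needs; draws are mapped back afterwards
        self.x_center = float(np.mean(x))
        self.z_center = None if z is None else float(np.mean(z))
        self.x = np.asarray(x, float) - self.x_center
        self.z = None if z is None else np.asarray(z, float) - self.z_center
        self.group_idx = np.asarray(group_idx, int)
        self.n_groups = int(n_groups)
        self.student_t = bool(student_t)
        self.known_sigma = known_sigma
        self.priors = priors
        self.hierarchical = self.n_groups > 1
        # unconstrained layout: a, b, [c], [log_sigma], then group block,
        # then [eta] (nu = 2 + exp(eta))
        names = ["a", "b"]
        if self.z is not None:
            names.append("c")
        if known_sigma is None:
            names.append("log_sigma")
        if self.hierarchical:
            # non-centered offsets (offset = tau * u, u ~ N(0, 1)): the
            # unit-scale prior keeps the walker population from collapsing
            # in the funnel neck; dedicated Metropolis sweeps on the taus
            # (interleaved between ensemble segments) move along the funnel
            names += ["log_tau_a", "log_tau_b"]
            names += [f"ua_{g}" for g in range(self.n_groups)]
            names += [f"ub_{g}" for g in range(self.n_groups)]
        if self.student_t:
            names.append("eta")
        self.param_names = names
        self.slices = {n: i for i, n in enumerate(names)}
        self.ndim = len(names)
        if self.hierarchical:
            base = self.slices["ua_0"]
            self.ua_sl = slice(base, base + self.n_groups)
            self.ub_sl = slice(base + self.n_groups, base + 2 * self.n_groups)
            self.tau_sl = [self.slices["log_tau_a"], self.slices["log_tau_b"]]

    # -- posterior ---------------------------------------------------------

    def log_prob(self, theta):
        theta = np.atleast_2d(np.asarray(theta, float))
        W = theta.shape[0]
        p, s = self.priors, self.slices
        a = theta[:, s["a"]]
        b = theta[:, s["b"]]
        lp = (
            -0.5 * ((a - p.intercept_mean) / p.intercept_sd) ** 2
            - 0.5 * ((b - p.slope_mean) / p.slope_sd) ** 2
        )
        mu = a[:, None] + b[:, None] * self.x[None, :]
        if self.z is not None:
            c = theta[:, s["c"]]
            lp += -0.5 * (c / p.coef_sd) ** 2
            mu = mu + c[:, None] * self.z[None, :]
        if self.known_sigma is not None:
            sigma = np.full(W, float(self.known_sigma))
        else:
            log_sigma = theta[:, s["log_sigma"]]
            bad = np.abs(log_sigma) > 12.0
            log_sigma = np.clip(log_sigma, -12.0, 12.0)
            sigma = np.exp(log_sigma)
            # half-Normal(0, sigma_scale) prior + log-Jacobian of exp
            lp += -0.5 * (sigma / p.sigma_scale) ** 2 + log_sigma
            lp = np.where(bad, -np.inf, lp)
        if self.hierarchical:
            log_tau = np.clip(theta[:, self.tau_sl], -9.0, 3.0)
            bad = np.any(np.abs(theta[:, self.tau_sl]) > 9.5, axis=1)
            tau = np.exp(log_tau)
            # half-Normal(scale) prior on tau + log-Jacobian of exp
            lp += np.sum(-0.5 * (tau / p.group_sd_scale) ** 2 + log_tau, axis=1)
            lp = np.where(bad, -np.inf, lp)
            ua = theta[:, self.ua_sl]
            ub = theta[:, self.ub_sl]
            lp += -0.5 * np.sum(ua**2, axis=1) - 0.5 * np.sum(ub**2, axis=1)
            oa = tau[:, 0:1] * ua
            ob = tau[:, 1:2] * ub
            mu = (
                mu
                + oa[:, self.group_idx]
                + ob[:, self.group_idx] * self.x[None, :]
            )
        resid = self.y[None, :] - mu
        n = self.y.size
        if self.student_t:
            eta = np.clip(theta[:, s["eta"]], -12.0, 8.0)
            nu = 2.0 + np.exp(eta)
            # Gamma(nu_shape, nu_rate) on nu truncated to nu > 2, + Jacobian
            lp += (
                (p.nu_shape - 1.0) * np.log(nu)
                - p.nu_rate * nu
                + np.log(nu - 2.0)
            )
            ll = n * (
                gammaln((nu + 1.0) / 2.0)
                - gammaln(nu / 2.0)
                - 0.5 * np.log(nu * math.pi)
                - np.log(sigma)
            ) - 0.5 * (nu + 1.0) * np.sum(
                np.log1p(resid**2 / (nu[:, None] * sigma[:, None] ** 2)), axis=1
            )
        else:
            ll = (
                -n * np.log(sigma)
                - 0.5 * n * _LOG_2PI
                - 0.5 * np.sum(resid**2, axis=1) / sigma**2
            )
        out = lp + ll
        return np.where(np.isfinite(out), out, -np.inf)

    # -- initialization ----------------------------------------------------

    def initial_point(self):
        X = [np.ones_like(self.x), self.x]
        if self.z is not None:
            X.append(self.z)
        X = np.column_stack(X)
        beta, *_ = np.linalg.lstsq(X, self.y, rcond=None)
        resid = self.y - X @ beta
        sd = max(float(resid.std()), 1e-3)
        theta0 = np.zeros(self.ndim)
        s = self.slices
        theta0[s["a"]], theta0[s["b"]] = beta[0], beta[1]
        if self.z is not None:
            theta0[s["c"]] = beta[2]
        if self.known_sigma is None:
            theta0[s["log_sigma"]] = math.log(sd)
        if self.hierarchical:
            # start intercept offsets at the per-group mean residuals
            oa0 = np.zeros(self.n_groups)
            for g in range(self.n_groups):
                m = self.group_idx == g
                if m.any():
                    oa0[g] = float(resid[m].mean())
            tau_a0 = max(float(oa0.std()), 0.05)
            theta0[self.tau_sl[0]] = math.log(tau_a0)
            theta0[self.tau_sl[1]] = math.log(0.05)
            theta0[self.ua_sl] = oa0 / tau_a0
        if self.student_t:
            theta0[s["eta"]] = math.log(8.0)  # nu ~ 10
        with np.errstate(all="ignore"):
            res = optimize.minimize(
                lambda t: -float(self.log_prob(t[None, :])[0]),
                theta0,
                method="L-BFGS-B",
            )
        return res.x if res.success and np.isfinite(res.fun) else theta0

    def init_scales(self):
        scales = np.full(self.ndim, 0.02)
        for name, i in self.slices.items():
            if name in ("eta", "log_tau_a", "log_tau_b"):
                scales[i] = 0.25
            elif name.startswith(("ua_", "ub_")):
                scales[i] = 0.3
        return scales

    def mh_tau(self, coords, rng, n_sweeps: int = 5, step: float = 0.4):
        """Interwoven group-SD updates, vectorized across walkers.

        Two complementary moves per sweep (ancillarity-sufficiency
        interweaving): (i) random-walk Metropolis on log tau holding the
        unit-scale offsets u — efficient when the data barely identify tau;
        (ii) an exact Gibbs redraw of tau from p(tau | offsets) with u
        rescaled so the offsets tau * u stay fixed — efficient when the
        offsets are pinned by the likelihood."""
        if not self.hierarchical:
            return coords
        coords = coords.copy()
        logp = self.log_prob(coords)
        for k in range(n_sweeps):
            prop = coords.copy()
            # alternate small and large proposal scales for local moves and
            # funnel-length jumps
            prop[:, self.tau_sl] += (step if k % 2 else 2.5 * step) * (
                rng.standard_normal((coords.shape[0], 2))
            )
            logp_prop = self.log_prob(prop)
            accept = np.log(rng.random(coords.shape[0])) < logp_prop - logp
            coords[accept] = prop[accept]
            logp = np.where(accept, logp_prop, logp)
        # offset-preserving redraw (likelihood invariant, no accept step)
        for u_sl, tau_col in ((self.ua_sl, self.tau_sl[0]),
                              (self.ub_sl, self.tau_sl[1])):
            tau = np.exp(np.clip(coords[:, tau_col], -9.0, 3.0))
            offsets = tau[:, None] * coords[:, u_sl]
            new_tau = _sample_tau(
                np.sum(offsets**2, axis=1), self.n_groups,
                self.priors.group_sd_scale, rng,
            )
            coords[:, tau_col] = np.log(new_tau)
            coords[:, u_sl] = offsets / new_tau[:, None]
        return coords


@dataclass
class ModelFit:
    """Posterior draws and diagnostics of one hierarchical regression.

    ``draws`` maps parameter names to arrays shaped (chain, draw) or
    (chain, draw, group): ``a``, ``b``, optional ``c``, ``sigma``, optional
    ``nu``, and for hierarchical fits ``tau_a``, ``tau_b``, ``a_offset``,
    ``b_offset``.  Per-group coefficients are ``a + a_offset[..., g]`` and
    ``b + b_offset[..., g]``, summed draw-wise.
    """

    kind: str
    draws: dict
    group_labels: list
    likelihood: str
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray | None
    group_idx: np.ndarray
    diagnostics: pd.DataFrame
    seed: int
    known_sigma: float | None = None
    warnings: list = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.draws["a"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws["a"].shape[1]

    def flat(self, name: str) -> np.ndarray:
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def group_index(self, label: str) -> int:
        try:
            return self.group_labels.index(label)
        except ValueError:
            raise InputError(
                f"group {label!r} unknown to the {self.kind} model"
            ) from None

    def coef_draws(self, label: str):
        """Joint (intercept, slope) draws for one group, flattened."""
        a, b = self.flat("a"), self.flat("b")
        if len(self.group_labels) > 1:
            g = self.group_index(label)
            a = a + self.flat("a_offset")[:, g]
            b = b + self.flat("b_offset")[:, g]
        return a, b

    @property
    def max_rhat(self) -> float:
        return float(self.diagnostics["rhat"].max())

    def summary(self) -> pd.DataFrame:
        """Posterior summary (mean, median, SD, 95% CI, R-hat, ESS) for all
        parameters plus per-group summed intercepts and slopes."""
        rows = []

        def add(name, flat_draws, diag_key=None):
            q = np.percentile(flat_draws, [2.5, 50.0, 97.5])
            diag = (
                self.diagnostics.loc[diag_key]
                if diag_key is not None and diag_key in self.diagnostics.index
                else None
            )
            rows.append(
                {
                    "parameter": name,
                    "mean": float(np.mean(flat_draws)),
                    "median": float(q[1]),
                    "sd": float(np.std(flat_draws)),
                    "ci_2.5": float(q[0]),
                    "ci_97.5": float(q[2]),
                    "rhat": float(diag["rhat"]) if diag is not None else np.nan,
                    "ess": float(diag["ess"]) if diag is not None else np.nan,
                }
            )

        for name in ("a", "b", "c", "sigma", "nu", "tau_a", "tau_b"):
            if name in self.draws:
                add(name, self.flat(name), name)
        if len(self.group_labels) > 1:
            for g, label in enumerate(self.group_labels):
                add(f"intercept[{label}]", self.coef_draws(label)[0])
                add(f"slope[{label}]", self.coef_draws(label)[1])
        return pd.DataFrame(rows).set_index("parameter")

    def to_draws_frame(self) -> pd.DataFrame:
        """Long-format draws table (chain, draw, parameter, value)."""
        frames = []
        for name, arr in self.draws.items():
            if arr.ndim == 2:
                cols = {name: arr}
            else:
                cols = {
                    f"{name}[{self.group_labels[g]}]": arr[:, :, g]
                    for g in range(arr.shape[2])
                }
            for col, a2 in cols.items():
                c, d = np.meshgrid(
                    np.arange(a2.shape[0]), np.arange(a2.shape[1]), indexing="ij"
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "chain": c.ravel(),
                            "draw": d.ravel(),
                            "parameter": col,
                            "value": a2.ravel(),
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)


def _run_sampler(model: _ModelDef, settings: SamplerSettings, seed: int):
    n_walkers = settings.n_walkers or max(2 * model.ndim + 2, 48)
    if n_walkers < 2 * model.ndim:
        n_walkers = 2 * model.ndim + 2
    if n_walkers % 2:
        n_walkers += 1
    center = model.initial_point()
    scales = model.init_scales()
    burn = int(settings.burn_frac * settings.n_steps)
    segment = max(settings.gibbs_interval, 1)
    chains = []
    for c in range(settings.n_chains):
        rng = np.random.default_rng([int(seed) % (2**31), 101 + c])
        p0 = center[None, :] + scales[None, :] * rng.standard_normal(
            (n_walkers, model.ndim)
        )
        p0 = model.mh_tau(p0, rng)
        sampler = emcee.EnsembleSampler(
            n_walkers, model.ndim, model.log_prob, vectorize=True,
            moves=[
                (emcee.moves.DEMove(), 0.8),
                (emcee.moves.DESnookerMove(), 0.2),
            ],
        )
        state = emcee.State(
            p0,
            random_state=np.random.RandomState(
                (int(seed) * 7919 + c) % (2**32)
            ).get_state(),
        )
        # alternate ensemble segments with Metropolis sweeps on the group
        # SDs: the ensemble moves the regression surface and the unit-scale
        # offsets, the sweeps walk the (tau, offsets) funnel
        done = 0
        while done < settings.n_steps:
            n_seg = min(segment, settings.n_steps - done)
            state = sampler.run_mcmc(state, n_seg, progress=False)
            done += n_seg
            if model.hierarchical and done < settings.n_steps:
                state = emcee.State(
                    model.mh_tau(state.coords, rng),
                    random_state=state.random_state,
                )
        chain = sampler.get_chain(discard=burn, thin=settings.thin)
        # flatten (step, walker) -> draw
        chains.append(chain.reshape(-1, model.ndim))
    return np.stack(chains)  # (chain, draw, ndim)


def _natural_draws(model: _ModelDef, raw: np.ndarray) -> dict:
    s = model.slices
    a_c = raw[:, :, s["a"]]
    b = raw[:, :, s["b"]]
    out = {"b": b}
    # undo the covariate centering: a = a_c - b * xbar (- c * zbar)
    a = a_c - b * model.x_center
    if model.z is not None:
        c = raw[:, :, s["c"]]
        out["c"] = c
        a = a - c * model.z_center
    out["a"] = a
    if model.known_sigma is None:
        out["sigma"] = np.exp(raw[:, :, s["log_sigma"]])
    else:
        out["sigma"] = np.full_like(out["a"], float(model.known_sigma))
    if model.hierarchical:
        tau_a = np.exp(raw[:, :, model.tau_sl[0]])
        tau_b = np.exp(raw[:, :, model.tau_sl[1]])
        oa = tau_a[:, :, None] * raw[:, :, model.ua_sl]
        ob = tau_b[:, :, None] * raw[:, :, model.ub_sl]
        out["a_offset"] = oa - ob * model.x_center
        out["b_offset"] = ob
        out["tau_a"], out["tau_b"] = tau_a, tau_b
    if model.student_t:
        out["nu"] = 2.0 + np.exp(raw[:, :, s["eta"]])
    return out


def _diagnostics(draws: dict, group_labels) -> pd.DataFrame:
    data = {}
    for name, arr in draws.items():
        if name == "sigma" and np.ptp(arr) == 0:
            continue  # fixed sigma
        data[name] = arr
    ds = az.convert_to_dataset(data)
    rhat = az.rhat(ds)
    ess = az.ess(ds)
    rows = []
    for name in data:
        r = np.atleast_1d(np.asarray(rhat[name]))
        e = np.atleast_1d(np.asarray(ess[name]))
        if r.size == 1:
            rows.append({"parameter": name, "rhat": float(r[0]), "ess": float(e[0])})
        else:
            for g in range(r.size):
                rows.append(
                    {
                        "parameter": f"{name}[{group_labels[g]}]",
                        "rhat": float(r[g]),
                        "ess": float(e[g]),
                    }
                )
            rows.append(
                {"parameter": name, "rhat": float(r.max()), "ess": float(e.min())}
            )
    return pd.DataFrame(rows).set_index("parameter")


def _fit(kind, y, x, group_labels_per_obs, *, z=None, student_t=False,
         priors=Priors(), settings=None, seed=0, known_sigma=None,
         warnings_list=None):
    settings = settings or SamplerSettings()
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    labels_obs = np.asarray(group_labels_per_obs)
    # canonical ordering makes fits invariant to input row permutations
    order = np.lexsort((y, x, labels_obs))
    y, x, labels_obs = y[order], x[order], labels_obs[order]
    if z is not None:
        z = np.asarray(z, float)[order]
    group_labels = sorted(set(labels_obs.tolist()))
    gidx = np.array([group_labels.index(g) for g in labels_obs])
    model = _ModelDef(
        y, x, gidx, len(group_labels), z=z, student_t=student_t,
        known_sigma=known_sigma, priors=priors,
    )
    raw = _run_sampler(model, settings, seed)
    draws = _natural_draws(model, raw)
    diagnostics = _diagnostics(draws, group_labels)
    fit = ModelFit(
        kind=kind,
        draws=draws,
        group_labels=group_labels,
        likelihood="student_t" if student_t else "normal",
        x=x,
        y=y,
        z=z,
        group_idx=gidx,
        diagnostics=diagnostics,
        seed=seed,
        known_sigma=known_sigma,
        warnings=warnings_list or [],
    )
    if settings.check_convergence and fit.max_rhat > settings.rhat_threshold:
        raise ConvergenceError(
            f"{kind} fit failed convergence: max R-hat "
            f"{fit.max_rhat:.4f} > {settings.rhat_threshold}",
            fit=fit,
        )
    return fit


def mr_group(species_id: str, rate_type: str) -> str:
    """Group label of the MR model: one cell per species x rate type."""
    return f"{species_id}|{rate_type}"


def fit_mr_model(
    obs: pd.DataFrame,
    settings: SamplerSettings | None = None,
    seed: int = 0,
    rate_types: tuple[str, ...] = ("smr", "mmr"),
    priors: Priors | None = None,
    known_sigma: float | None = None,
) -> ModelFit:
    """Fit log10 MR on log10 mass with species x rate-type varying
    intercepts and slopes (Normal likelihood, metabolic-scaling slope prior
    Normal(0.75, 0.1) unless overridden).

    ``obs`` needs columns ``species_id``, ``mass_g`` and one column per
    entry of ``rate_types`` (``smr``/``mmr``, g O2 d-1).
    """
    for col in ("species_id", "mass_g", *rate_types):
        if col not in obs.columns:
            raise InputError(f"MR observations missing column {col!r}")
        if col in rate_types and obs[col].isna().any():
            bad = obs.loc[obs[col].isna(), "species_id"].unique()
            raise InputError(f"missing {col} values for species {list(bad)}")
    if (obs[list(rate_types)].to_numpy() <= 0).any() or (obs["mass_g"] <= 0).any():
        raise InputError("masses and metabolic rates must be positive")
    ys, xs, labels = [], [], []
    for k in rate_types:
        ys.append(np.log10(obs[k].to_numpy(float)))
        xs.append(np.log10(obs["mass_g"].to_numpy(float)))
        labels.append([mr_group(s, k) for s in obs["species_id"]])
    priors = priors or Priors(slope_mean=0.75, slope_sd=0.1)
    return _fit(
        "mr",
        np.concatenate(ys),
        np.concatenate(xs),
        np.concatenate(labels),
        priors=priors,
        settings=settings,
        seed=seed,
        known_sigma=known_sigma,
    )


def fit_speed_model(
    obs: pd.DataFrame,
    settings: SamplerSettings | None = None,
    seed: int = 0,
    priors: Priors | None = None,
    likelihood: str = "student_t",
) -> ModelFit:
    """Fit log10 field speed on log10 length with species varying
    intercepts/slopes and a Student-t likelihood (robust to outliers).

    ``likelihood="normal"`` fits the non-robust counterpart (used for
    robustness comparisons).
    """
    for col in ("species_id", "length_cm", "v_field"):
        if col not in obs.columns:
            raise InputError(f"speed observations missing column {col!r}")
    if (obs["v_field"] <= 0).any() or (obs["length_cm"] <= 0).any():
        raise InputError("lengths and speeds must be positive")
    warnings_list = []
    counts = obs.groupby("species_id").size()
    low = counts[counts < 10]
    if not low.empty:
        msg = f"species with < 10 speed observations: {dict(low)}"
        warnings_list.append(msg)
        log.warning(msg)
    return _fit(
        "speed",
        np.log10(obs["v_field"].to_numpy(float)),
        np.log10(obs["length_cm"].to_numpy(float)),
        obs["species_id"].to_numpy(),
        student_t=(likelihood == "student_t"),
        priors=priors or Priors(),
        settings=settings,
        seed=seed,
        warnings_list=warnings_list,
    )


def fit_maxspeed_model(
    records: pd.DataFrame,
    settings: SamplerSettings | None = None,
    seed: int = 0,
    priors: Priors | None = None,
) -> ModelFit:
    """Fit log10 maximum speed on log10 length + aspect ratio, with family x
    body-shape varying intercepts/slopes and a Student-t likelihood."""
    for col in ("family", "body_shape", "length_cm", "aspect_ratio", "v_max"):
        if col not in records.columns:
            raise InputError(f"max-speed records missing column {col!r}")
    groups = records["family"].astype(str) + "|" + records["body_shape"].astype(str)
    if groups.nunique() < 2:
        raise InputError(
            "need >= 2 family x body-shape groups to identify group effects"
        )
    return _fit(
        "maxspeed",
        np.log10(records["v_max"].to_numpy(float)),
        np.log10(records["length_cm"].to_numpy(float)),
        groups.to_numpy(),
        z=records["aspect_ratio"].to_numpy(float),
        student_t=True,
        priors=priors or Priors(),
        settings=settings,
        seed=seed,
    )


def predict_expected(
    fit: ModelFit,
    covariate: float,
    group: str | None = None,
    aspect_ratio: float | None = None,
    median: bool = False,
    include_residual: bool = False,
    n_draws: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Posterior draws of the expected response (natural scale) at one
    covariate value.

    ``covariate`` is the natural-scale mass (g) or length (cm); the model's
    log10 transform is applied internally.  By default the posterior of
    10**mu is returned (no residual noise): field speed enters the pipeline
    as an average and SMR/MMR/vmax as medians.  ``include_residual=True``
    instead samples the posterior predictive.  ``median=True`` returns the
    scalar posterior median (10**x is monotone, so it commutes with the
    median of mu).

    For the max-speed model an unknown group is allowed: its offsets are
    marginalized by drawing fresh N(0, tau) offsets per posterior draw
    (requires ``rng``).
    """
    if covariate <= 0:
        raise InputError("covariate must be positive")
    lx = math.log10(covariate)
    a, b = fit.flat("a"), fit.flat("b")
    hier = len(fit.group_labels) > 1
    if hier:
        if group is None:
            raise InputError(f"{fit.kind} model prediction needs a group label")
        if group in fit.group_labels:
            g = fit.group_index(group)
            a = a + fit.flat("a_offset")[:, g]
            b = b + fit.flat("b_offset")[:, g]
        elif fit.kind == "maxspeed":
            if rng is None:
                rng = np.random.default_rng(fit.seed)
            tau_a, tau_b = fit.flat("tau_a"), fit.flat("tau_b")
            a = a + tau_a * rng.standard_normal(tau_a.size)
            b = b + tau_b * rng.standard_normal(tau_b.size)
        else:
            raise InputError(
                f"species/group {group!r} unknown to the {fit.kind} model"
            )
    mu = a + b * lx
    if fit.z is not None:
        if aspect_ratio is None:
            raise InputError("max-speed prediction needs an aspect ratio")
        mu = mu + fit.flat("c") * aspect_ratio
    if include_residual:
        if rng is None:
            rng = np.random.default_rng(fit.seed)
        sigma = fit.flat("sigma")
        if fit.likelihood == "student_t":
            eps = rng.standard_t(fit.flat("nu"))
        else:
            eps = rng.standard_normal(mu.size)
        mu = mu + sigma * eps
    if median:
        return float(10.0 ** np.median(mu))
    if n_draws is not None and n_draws < mu.size:
        if rng is None:
            rng = np.random.default_rng(fit.seed)
        mu = mu[rng.choice(mu.size, size=n_draws, replace=False)]
    return 10.0 ** mu


def bayes_r2(fit: ModelFit, max_draws: int = 4000) -> dict:
    """Per-draw Bayesian R2: Var(fitted mu) / (Var(fitted mu) + residual
    variance implied by sigma (scaled by nu/(nu-2) for Student-t fits)).

    Returns median, mean and the equal-tailed 95% interval plus the draws.
    """
    a, b = fit.flat("a"), fit.flat("b")
    n_total = a.size
    idx = (
        np.linspace(0, n_total - 1, max_draws).astype(int)
        if n_total > max_draws
        else np.arange(n_total)
    )
    a, b = a[idx], b[idx]
    mu = a[:, None] + b[:, None] * fit.x[None, :]
    if fit.z is not None:
        mu = mu + fit.flat("c")[idx, None] * fit.z[None, :]
    if len(fit.group_labels) > 1:
        a_off = fit.flat("a_offset")[idx][:, fit.group_idx]
        b_off = fit.flat("b_offset")[idx][:, fit.group_idx]
        mu = mu + a_off + b_off * fit.x[None, :]
    var_mu = mu.var(axis=1)
    sigma2 = fit.flat("sigma")[idx] ** 2
    if fit.likelihood == "student_t":
        nu = fit.flat("nu")[idx]
        sigma2 = sigma2 * nu / (nu - 2.0)
    r2 = var_mu / (var_mu + sigma2)
    q = np.percentile(r2, [2.5, 50.0, 97.5])
    return {
        "median": float(q[1]),
        "mean": float(r2.mean()),
        "ci_2.5": float(q[0]),
        "ci_97.5": float(q[2]),
        "draws": r2,
    }
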