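import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from fishamr.hier_models import (
    ModelFit,
    SamplerSettings,
    fit_maxspeed_model,
    fit_mr_model,
    fit_speed_model,
)
from fishamr.synthetic_data import (
    default_config,
    generate_maxspeed_records,
    generate_mr_observations,
    generate_speed_observations,
    recovery_config,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fast_settings():
    """Reduced sampler budget for fits whose convergence is not the point."""
    return SamplerSettings(n_chains=3, n_steps=2000, check_convergence=False)


@pytest.fixture(scope="session")
def tiny_settings():
    """Minimal budget for tests of plumbing (determinism, serialization)."""
    return SamplerSettings(n_chains=2, n_steps=400, thin=2, check_convergence=False)


@pytest.fixture(scope="session")
def recovery_data():
    """Synthetic MR table whose true global scaling exponent is 0.75
    (6 species x 10 fish x 2 rate types, masses log-uniform 5-500 g,
    species slope-offset SD 0.03, residual SD 0.05)."""
    cfg = recovery_config(seed=1)
    obs, truth = generate_mr_observations(cfg)
    return cfg, obs, truth


@pytest.fixture(scope="session")
def recovery_fit(recovery_data):
    _, obs, _ = recovery_data
    return fit_mr_model(obs, seed=1)


@pytest.fixture(scope="session")
def speed_fit_data():
    cfg = default_config(seed=5, n_per_species=40)
    obs = generate_speed_observations(cfg)
    return cfg, obs, fit_speed_model(obs, seed=2)


@pytest.fixture(scope="session")
def maxspeed_fit_data():
    cfg = default_config(seed=11)
    records = generate_maxspeed_records(cfg)
    return cfg, records, fit_maxspeed_model(records, seed=11)


def make_degenerate_fit(
    kind,
    group_labels,
    a,
    b,
    a_offsets=None,
    b_offsets=None,
    c=None,
    sigma=1e-12,
    nu=None,
    x=None,
    y=None,
    z=None,
    group_idx=None,
):
    """A ModelFit whose posterior is a point mass: every draw equals the
    supplied coefficients.  Used to test the estimation pipeline's algebra
    separately from the sampler."""
    G = len(group_labels)
    shape = (1, 4)  # a few identical draws so CI code paths run
    draws = {
        "a": np.full(shape, float(a)),
        "b": np.full(shape, float(b)),
        "sigma": np.full(shape, float(sigma)),
    }
    if G > 1:
        draws["a_offset"] = np.tile(
            np.asarray(a_offsets if a_offsets is not None else np.zeros(G)),
            (*shape, 1),
        ).reshape(*shape, G)
        draws["b_offset"] = np.tile(
            np.asarray(b_offsets if b_offsets is not None else np.zeros(G)),
            (*shape, 1),
        ).reshape(*shape, G)
        draws["tau_a"] = np.full(shape, 0.1)
        draws["tau_b"] = np.full(shape, 0.1)
    if c is not None:
        draws["c"] = np.full(shape, float(c))
    if nu is not None:
        draws["nu"] = np.full(shape, float(nu))
    diag = pd.DataFrame({"rhat": [1.0], "ess": [1e6]}, index=["a"])
    return ModelFit(
        kind=kind,
        draws=draws,
        group_labels=list(group_labels),
        likelihood="student_t" if nu is not None else "normal",
        x=np.empty(0) if x is None else np.asarray(x, float),
        y=np.empty(0) if y is None else np.asarray(y, float),
        z=(np.asarray(z, float) if z is not None else (np.empty(0) if c is not None else None)),
        group_idx=(
            np.asarray(group_idx, int) if group_idx is not None else np.empty(0, int)
        ),
        diagnostics=diag,
        seed=0,
    )
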