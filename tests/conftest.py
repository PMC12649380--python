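"""Shared fixtures: small hydraulic fields and canonical models."""

import numpy as np
import pandas as pd
import pytest

from flumefish.endurance import AFTModel
from flumefish.hydraulics import FIELD_QUANTITIES, HydraulicField
from flumefish.synth import AFTTruth, gen_flow_field


@pytest.fixture
def rng():
    return np.random.default_rng(20250923)


@pytest.fixture(scope="session")
def flow_field():
    """Deterministic synthetic field at the highest nominal velocity."""
    return gen_flow_field(2.50, seed=11)


def make_uniform_field(u=-2.0, v=0.0, tke=0.1, tau=(1.0, 0.5, 0.2),
                       x=None, y=None):
    """Spatially constant field for geometry-only tests."""
    x = np.linspace(-2.0, 2.0, 9) if x is None else np.asarray(x, float)
    y = np.linspace(-2.0, 2.0, 9) if y is None else np.asarray(y, float)
    shape = (x.size, y.size)
    vals = {"u_bar": u, "v_bar": v, "w_bar": 0.0,
            "speed": float(np.hypot(u, v)), "tke": tke,
            "tau_uv": tau[0], "tau_uw": tau[1], "tau_vw": tau[2]}
    data = {q: np.full(shape, vals[q]) for q in FIELD_QUANTITIES}
    return HydraulicField(x=x, y=y, data=data)


@pytest.fixture
def uniform_field():
    return make_uniform_field()


#: Fitted endurance coefficients of the study species (prolonged / sprint),
#: used as generating truth and for prediction examples.
REFERENCE_COEFFS = {
    "prolonged": {"Intercept": 6.29, "Vs": -0.94, "BL": 6.98,
                  "Log(scale)": -0.86, "n": 47},
    "sprint": {"Intercept": 9.87, "Vs": -0.48, "BL": -7.81,
               "Log(scale)": -0.50, "n": 138},
}


@pytest.fixture(scope="session")
def reference_model() -> AFTModel:
    return AFTModel.from_coefficients(
        6.13, ("Vs", "BL"),
        REFERENCE_COEFFS["prolonged"], REFERENCE_COEFFS["sprint"])


@pytest.fixture(scope="session")
def reference_truth() -> AFTTruth:
    return AFTTruth()


def simulate_fatigue_dataset(rng, truth=None, n_prolonged=47, n_sprint=138,
                             censor_fraction=0.10):
    """Record table drawn from the two-regime truth (47/138 split default)."""
    from flumefish.synth import gen_fatigue

    truth = truth or AFTTruth()
    vs = np.concatenate([
        rng.uniform(3.83, truth.breakpoint, n_prolonged),
        rng.uniform(truth.breakpoint, 9.0, n_sprint)])
    bl = np.clip(rng.normal(0.3916, 0.045, n_prolonged + n_sprint), 0.25, None)
    fish = pd.DataFrame({
        "fish_id": [f"f{i}" for i in range(vs.size)],
        "mean_Vs_bls": vs, "BL_m": bl})
    return gen_fatigue(fish, truth, rng=rng, censor_fraction=censor_fraction)
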