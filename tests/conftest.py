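"""Shared fixtures and independent closed-form oracles.

The oracles here are written directly from textbook solutions (Bateman
function, separable-ODE stretched exponential) and never call the package's
integrators, so solver/oracle agreement is a genuine cross-check.
"""

import numpy as np
import pytest

from fractalpk import (
    DoseEvent,
    ModelSpec,
    PKParameters,
    PopulationDesign,
    PopulationModel,
    generate_population,
)


# ---------------------------------------------------------------------------
# closed-form oracles
# ---------------------------------------------------------------------------


def bateman(t, dose, ka, ke, v1):
    """First-order absorption, 1-compartment concentration; limit-safe at
    ka == ke."""
    t = np.asarray(t, dtype=float)
    if abs(ka - ke) < 1e-10 * max(ka, ke):
        return dose * ka * t * np.exp(-ka * t) / v1
    return dose * ka / (v1 * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))


def stretched_exp_decay(t, a0, theta, h, t0):
    """Amount in a single compartment draining through a fractal rate
    theta/t**h from amount ``a0`` at time ``t0`` (fractal clock at 0):
    A(t) = a0 * exp(-theta * (t^(1-h) - t0^(1-h)) / (1-h))."""
    t = np.asarray(t, dtype=float)
    return a0 * np.exp(-theta * (t ** (1 - h) - t0 ** (1 - h)) / (1 - h))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def one_comp_spec():
    return ModelSpec(n_compartments=1, absorption="first_order")


@pytest.fixture(scope="session")
def one_comp_params():
    return PKParameters(Ka=0.3, CL=0.033, V1=10.0)


@pytest.fixture(scope="session")
def two_comp_params():
    return PKParameters(Ka=0.3, CL=0.033, V1=10.0, Q=3.0, V2=100.0)


@pytest.fixture(scope="session")
def single_dose():
    return [DoseEvent(time=0.0, amount=100.0)]


@pytest.fixture(scope="session")
def grid_times():
    return np.arange(0.0, 400.5, 0.5)


@pytest.fixture(scope="session")
def fractal_abs_truth():
    """True population model of the recovery study: 2-compartment,
    fractal first-order absorption (h = 0.3), 30% CV IIV on Ka and CL,
    15% proportional error."""
    spec = ModelSpec(n_compartments=2, absorption="first_order", fractal_on={"Ka": 0.3})
    return PopulationModel(
        spec=spec,
        theta={"Ka": 0.3, "CL": 0.5, "V1": 10.0, "Q": 1.0, "V2": 20.0, "h_Ka": 0.3},
        omega={"Ka": 0.09, "CL": 0.09},
        sigma_prop=0.15,
    )


@pytest.fixture(scope="session")
def rich_times():
    return (0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 36.0, 48.0, 72.0)


@pytest.fixture(scope="session")
def small_population(fractal_abs_truth, rich_times):
    """A 10-subject dataset simulated from the fractal-absorption truth."""
    design = PopulationDesign(
        model=fractal_abs_truth,
        n_subjects=10,
        doses=[DoseEvent(time=0.0, amount=100.0)],
        sampling_times=rich_times,
        seed=20260101,
    )
    return generate_population(design)
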