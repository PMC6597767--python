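"""Shared fixtures: published per-patient parameter sets and visit series.

The three reference parameter sets are reconstructed from the grouped
products of their published closed-form FT4 formulas (a*ic50, c,
a*ic50*c1, ic50) — the form that reproduces the published prediction
tables — together with the visit series they were fitted to.
"""

import numpy as np
import pytest

import thyrodose as td


@pytest.fixture(scope="session")
def patient2_params() -> td.ModelParams:
    """Patient 2: a*ic50=3.024, c=0.003, a*ic50*c1=-0.154, ic50=58.151."""
    return td.ModelParams.from_products(3.024, 0.003, -0.154, 58.151)


@pytest.fixture(scope="session")
def patient16_params() -> td.ModelParams:
    """Patient 16: a*ic50=378.648, c=0.371, a*ic50*c1=-0.379, ic50=72.901."""
    return td.ModelParams.from_products(378.648, 0.371, -0.379, 72.901)


@pytest.fixture(scope="session")
def patient23_params() -> td.ModelParams:
    """Patient 23: a*ic50=148.558, c=0.246, a*ic50*c1=-4.902, ic50=35.062."""
    return td.ModelParams.from_products(148.558, 0.246, -4.902, 35.062)


@pytest.fixture(scope="session")
def patient16_series() -> td.PatientSeries:
    """Patient 16's three visits: doses 0/15/17.5 mg, intervals 0/90/78 d."""
    return td.PatientSeries.from_arrays(
        "16", doses_prev=[0, 15, 17.5], intervals=[0, 90, 78], ft4=[14, 13, 10]
    )


@pytest.fixture(scope="session")
def patient23_series() -> td.PatientSeries:
    """Patient 23's four visits: doses 0/15/15/7.5 mg, intervals 0/35/84/84 d."""
    return td.PatientSeries.from_arrays(
        "23", doses_prev=[0, 15, 15, 7.5], intervals=[0, 35, 84, 84],
        ft4=[40, 16, 10, 13]
    )


def draw_valid_params(rng: np.random.Generator) -> tuple[td.ModelParams, float]:
    """One random parameter set honouring every validity condition.

    The untreated steady state a/c is placed strictly below the initial FT4
    y1 and c1 is pinned by the initial-condition identity, so c1 < 0 always.
    """
    y1 = rng.uniform(20.0, 90.0)
    a = np.exp(rng.uniform(np.log(0.01), np.log(10.0)))
    steady0 = y1 * rng.uniform(0.2, 0.95)
    c = a / steady0
    ic50 = rng.uniform(5.0, 150.0)
    c1 = 1.0 / y1 - c / a
    return td.ModelParams(a=a, c=c, ic50=ic50, c1=c1), float(y1)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """20 model-true virtual patients, >=4 visits, stepped-down doses."""
    spec = td.SyntheticSpec(n_patients=20, noise_sd=0.0, visits_range=(4, 8), seed=7)
    cohort, truths = td.simulate_cohort(spec)
    return cohort, truths
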