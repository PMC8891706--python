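"""Shared fixtures.

The expensive differential-evolution fits are session-scoped and reused
by the recovery, admissibility and acceptance tests so each one is run
exactly once per session.
"""

from __future__ import annotations

import pytest

from mosskinetics.fitting import default_bounds, fit
from mosskinetics.synthetic_data import (
    NoiseModel,
    generate,
    get_fixture,
)

PRODUCT_FREE = ["r_x_max", "k_n", "y_x_n", "r_p_max", "k_p", "k_pd"]
GROWTH_FREE = ["r_x_max", "k_n", "y_x_n"]


@pytest.fixture(scope="session")
def line_b_batch_fixture():
    return get_fixture("lineB-batch")


@pytest.fixture(scope="session")
def parental_fixture():
    return get_fixture("parental-batch")


@pytest.fixture(scope="session")
def batch_recovery_fits(line_b_batch_fixture):
    """Producer-line batch refits on three 5%-CV noise realizations.

    Returns a list of (dataset, FitResult) with all product and growth
    parameters free and the optics fixed at the generating truth.
    """
    fx = line_b_batch_fixture
    bounds = default_bounds(fx.params, PRODUCT_FREE)
    out = []
    for seed in (101, 102, 103):
        ds = generate(fx, NoiseModel(cv=0.05, replicates=2, seed=seed))
        out.append((ds, fit(ds, bounds, fixed_params=fx.params, seed=seed)))
    return out


@pytest.fixture(scope="session")
def noiseless_batch_fit(line_b_batch_fixture):
    """Self-consistency fit: refit noiseless data generated at the truth."""
    fx = line_b_batch_fixture
    ds = generate(fx, NoiseModel(cv=0.0, replicates=1, seed=0))
    bounds = default_bounds(fx.params, PRODUCT_FREE)
    return ds, fit(ds, bounds, fixed_params=fx.params, seed=5)


@pytest.fixture(scope="session")
def semi_recovery_fit():
    """Semi-continuous (D = 0.4/d) refit on one noise realization."""
    fx = get_fixture("lineB-semicontinuous-D0.4")
    ds = generate(fx, NoiseModel(cv=0.05, replicates=2, seed=211))
    bounds = default_bounds(fx.params, PRODUCT_FREE)
    return ds, fit(ds, bounds, fixed_params=fx.params, seed=211)


@pytest.fixture(scope="session")
def parental_recovery_fit(parental_fixture):
    """Parental-line (biomass/nitrate only) refit on one realization."""
    fx = parental_fixture
    ds = generate(fx, NoiseModel(cv=0.05, replicates=2, seed=307))
    bounds = default_bounds(fx.params, GROWTH_FREE)
    return ds, fit(ds, bounds, fixed_params=fx.params, seed=307)
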