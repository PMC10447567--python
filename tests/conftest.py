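"""Shared fixtures.

The expensive simulations (steady-state case runs, the long-horizon dosed
run) are session-scoped so the acceptance tests and the physics tests
share one integration each.
"""

from __future__ import annotations

import numpy as np
import pytest

import biofilmhp as bh


@pytest.fixture(scope="session")
def params() -> bh.ModelParameters:
    return bh.ModelParameters()


@pytest.fixture(scope="session")
def case_a(params):
    """Untreated base case run to the steady-state criterion."""
    return bh.integrate_to_steady_state(params, bh.DoseSchedule())


@pytest.fixture(scope="session")
def case_a_live(case_a):
    """Untreated steady-state areal live biomass (reference for log reductions)."""
    return bh.areal_biomass(case_a.final_state)[0]


@pytest.fixture(scope="session")
def case_b(params):
    """Continuously dosed base case (500 g/m^3 from day 2), 100-day horizon,
    densely sampled over the first treatment day."""
    samples = np.unique(np.concatenate([np.linspace(0.0, 100.0, 401),
                                        np.linspace(2.0, 3.0, 201)]))
    return bh.integrate(params, bh.continuous_schedule(500.0), sample_times=samples)


@pytest.fixture(scope="session")
def case_a_fine_grid(params):
    """Untreated base case at four-fold grid refinement (Nz = 200)."""
    return bh.integrate(params.replace(Nz=200), bh.DoseSchedule(), n_samples=51)


@pytest.fixture(scope="session")
def case_b_long(params):
    """Continuously dosed base case on the extended 2000-day horizon (the
    interior of the film equilibrates slowly)."""
    return bh.integrate(params, bh.continuous_schedule(500.0), t_final=2000.0)
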