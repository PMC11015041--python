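"""Shared fixtures.

The heavy coupled 50-hour simulations are session-scoped and shared between
the property tests and the acceptance tests, so each sweep is integrated only
once per test run.
"""

from __future__ import annotations

import numpy as np
import pytest

from psmasim import (
    AdministrationProtocol,
    BatchMember,
    Phantom,
    SweepSpec,
    make_spherical_phantom,
    run_batch,
    run_sweep,
    solve_ifp,
)
from psmasim.params import load_parameters


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def params_tumor2():
    return load_parameters(scenario="tumor2")


@pytest.fixture(scope="session")
def sweep_phantom():
    """The 0.5 cm spherical surrogate used by all sweep experiments."""
    return make_spherical_phantom(0.5, 1.0, 0.1)


@pytest.fixture(scope="session")
def sweep_flow(sweep_phantom, params):
    return solve_ifp(sweep_phantom, params)


@pytest.fixture(scope="session")
def micro_phantom():
    """Tiny hand-built phantom (7^3 grid, 3^3 tumor core) for fast engine tests."""
    labels = np.ones((7, 7, 7), dtype=np.int8)
    labels[2:5, 2:5, 2:5] = 2
    return Phantom(
        labels=labels,
        spacing=(0.1, 0.1, 0.1),
        origin=(-0.3, -0.3, -0.3),
        provenance="micro test phantom",
    )


@pytest.fixture(scope="session")
def micro_flow(micro_phantom, params):
    return solve_ifp(micro_phantom, params)


def default_protocol(params, **kw):
    kw.setdefault("amount_total", 100.0)
    kw.setdefault("labeled_fraction", 0.10)
    kw.setdefault("plasma_volume", params.plasma_volume)
    kw.setdefault("alpha", params.alpha * 3600.0)
    return AdministrationProtocol(**kw)


# --- heavy shared simulations (50 h horizon, 0.1 min step) -----------------

@pytest.fixture(scope="session")
def krec_sweep_density50(sweep_phantom, params, sweep_flow):
    """Recycling-rate sweep {1e-4..1e-1}/min on the density-50 surrogate."""
    spec = SweepSpec("k_rec", (1e-4, 1e-3, 1e-2, 1e-1))
    return run_sweep(spec, phantom=sweep_phantom, params=params, flow=sweep_flow)


@pytest.fixture(scope="session")
def krec_sweep_density500(sweep_phantom, params_tumor2, sweep_flow):
    spec = SweepSpec("k_rec", (1e-4, 1e-1), scenario="tumor2")
    return run_sweep(spec, phantom=sweep_phantom, params=params_tumor2, flow=sweep_flow)


@pytest.fixture(scope="session")
def labeled_fraction_sweep(sweep_phantom, params, sweep_flow):
    spec = SweepSpec("labeled_fraction", (0.01, 0.10))
    return run_sweep(spec, phantom=sweep_phantom, params=params, flow=sweep_flow)


@pytest.fixture(scope="session")
def amount_sweep(sweep_phantom, params, sweep_flow):
    spec = SweepSpec("amount_total", tuple(float(a) for a in range(100, 1001, 100)))
    return run_sweep(spec, phantom=sweep_phantom, params=params, flow=sweep_flow)


@pytest.fixture(scope="session")
def density_sweep(sweep_phantom, params, sweep_flow):
    spec = SweepSpec("receptor_density", (10.0, 50.0, 100.0, 200.0, 500.0))
    return run_sweep(spec, phantom=sweep_phantom, params=params, flow=sweep_flow)


@pytest.fixture(scope="session")
def bolus_infusion_pair(sweep_phantom, params, sweep_flow):
    """Bolus and 60-min infusion of 100 nmol (10% labeled), same phantom."""
    members = [
        BatchMember(default_protocol(params, mode="bolus"), label="bolus"),
        BatchMember(
            default_protocol(params, mode="infusion", infusion_duration=60.0),
            label="infusion",
        ),
    ]
    return run_batch(sweep_phantom, params, members, flow=sweep_flow)


@pytest.fixture(scope="session")
def reference_run(bolus_infusion_pair):
    """The standard bolus run (member 0 of the bolus/infusion batch)."""
    return bolus_infusion_pair
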