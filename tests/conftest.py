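"""Shared fixtures: study-condition twin objects at full and reduced size.

Heavy simulations are session-scoped so the acceptance checks and the
property tests share one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from grainfield import (ForcingScenario, MaterialParams, TruthField,
                        clean_readings, generate_synthetic_campaign)
from grainfield.field_reconstruction import PlanarGrid
from grainfield.pde_core import (CoupledSimulator, FieldState, Mesh,
                                 SolverConfig)


@pytest.fixture(scope="session")
def params() -> MaterialParams:
    return MaterialParams()

@pytest.fixture(scope="session")
def forcing() -> ForcingScenario:
    return ForcingScenario()


@pytest.fixture(scope="session")
def twin_mesh() -> Mesh:
    return Mesh(plane="XOZ", width=24.0, height=6.0, spacing=0.1)


@pytest.fixture(scope="session")
def truth_field() -> TruthField:
    return TruthField()


@pytest.fixture(scope="session")
def twin_campaign(truth_field):
    """30-day synthetic campaign (9360 records), cleaned."""
    raw = generate_synthetic_campaign(truth=truth_field, days=30,
                                      noise_sd=0.1, seed=42)
    return clean_readings(raw.readings, layout=raw.layout)


def grid_of(mesh: Mesh, values: np.ndarray) -> PlanarGrid:
    return PlanarGrid(axes=("x", "z"), axis1_coords=mesh.x,
                      axis2_coords=mesh.z, values=values)


@pytest.fixture(scope="session")
def twin_truth_run(twin_mesh, truth_field, params, forcing):
    """31-day reference trajectory from the exact analytic initial field."""
    X, Z = twin_mesh.meshgrid()
    state = FieldState.from_temperature(twin_mesh, truth_field(X, Z, 0.0),
                                        0.1628, params)
    sim = CoupledSimulator(twin_mesh, params, forcing, SolverConfig(dt=600.0))
    return list(sim.advance(state, horizon_s=31 * 86400.0))


@pytest.fixture(scope="session")
def twin_init_report(twin_campaign, twin_mesh, params, forcing):
    """Sensor-initialized field on the campaign's first day."""
    from grainfield.initialization import initialize_fields
    return initialize_fields(twin_campaign, "2020-08-01", twin_mesh,
                             params, forcing, plane_offset=7.5)


@pytest.fixture(scope="session")
def twin_model_run(twin_init_report, twin_mesh, params, forcing):
    """31-day trajectory from the sensor-initialized field."""
    sim = CoupledSimulator(twin_mesh, params, forcing, SolverConfig(dt=600.0))
    return list(sim.advance(twin_init_report.state.copy(),
                            horizon_s=31 * 86400.0))
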