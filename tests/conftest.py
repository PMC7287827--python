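import warnings

import numpy as np
import pytest

import protoacoustic as pa


@pytest.fixture(scope="session")
def beam_100mev():
    return pa.BeamConfig(
        energy=100.0,
        n_protons=5e6,
        sigma_lateral=1.0,
        entry_point=(0.0, 0.0, 0.0),
        direction=(0.0, 0.0, 1.0),
    )


@pytest.fixture(scope="session")
def dose_100mev(beam_100mev):
    """Reference 100 MeV dose grid, 1 mm voxels."""
    return pa.deposit_3d(beam_100mev, spacing=1.0)


@pytest.fixture(scope="session")
def dose_100mev_fine(beam_100mev):
    """Reference 100 MeV dose grid, 0.5 mm voxels (chain resolution)."""
    return pa.deposit_3d(beam_100mev, spacing=0.5)


@pytest.fixture(scope="session")
def default_scene():
    return pa.build_default_scene()


@pytest.fixture(scope="session")
def chain_corrected(default_scene):
    return pa.run_full_chain(default_scene, correction="per-sensor")


@pytest.fixture(scope="session")
def chain_uncorrected(default_scene):
    return pa.run_full_chain(default_scene, correction="none")


@pytest.fixture(scope="session")
def table1_array():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pa.SensorArray(positions=pa.TABLE1_SENSORS.copy())


def point_source_grid(value=1e3, spacing=1.0, position=(0.0, 0.0, 0.0)):
    """Single-voxel dose grid centred at ``position`` (helper)."""
    origin = np.asarray(position, dtype=float) - spacing / 2.0
    values = np.full((1, 1, 1), value)
    return pa.DoseGrid(origin=origin, spacing=spacing, values=values)
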