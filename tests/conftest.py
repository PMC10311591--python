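import numpy as np
import pytest

from edchiro.synthetic import (
    PlantedLandscapeSpec,
    PlantedShellSpec,
    make_planted_trajectory,
    make_solvated_frame,
)


@pytest.fixture(scope="session")
def two_basin_setup():
    """One planted two-basin trajectory (4:1 occupancy) with ground truth."""
    spec = PlantedLandscapeSpec(
        n_atoms=30, n_frames=5000, n_modes=2,
        basin_centres=np.array([[0.0, 0.0], [0.5, 0.0]]),
        occupancies=(0.8, 0.2), widths=(0.06, 0.06), noise=1e-6, seed=0)
    return make_planted_trajectory(spec)


@pytest.fixture(scope="session")
def shell_setup():
    """200 synthetic waters at known ellipsoidal distances around a solute."""
    rng = np.random.default_rng(7)
    d2 = rng.uniform(0.5, 9.0, 200)
    spec = PlantedShellSpec(semi_axes=(1.2, 1.0, 0.8), n_solute_atoms=120,
                            sq_distances=d2, seed=11)
    frame, topology, ellipsoid, ranking = make_solvated_frame(spec)
    return frame, topology, ellipsoid, ranking, d2


@pytest.fixture
def rng():
    return np.random.default_rng(42)
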