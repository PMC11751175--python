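import numpy as np
import pytest

from mvstim.geometry import LabyrinthConfig, build_labyrinth
from mvstim.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def left_geom():
    """Default-resolution left labyrinth, shared across the suite."""
    return build_labyrinth(LabyrinthConfig())


@pytest.fixture(scope="session")
def supine_run():
    """Full supine 7 T pipeline result (both labyrinths), shared."""
    return run_pipeline(RunConfig())


@pytest.fixture(scope="session")
def mini_config():
    """Coarse, fast labyrinth configuration for topology-only tests."""
    return LabyrinthConfig(
        canal_major_radius_mm=1.6,
        duct_radius_mm=0.3,
        ampulla_radius_mm=0.5,
        cupula_thickness_mm=0.3,
        voxel_mm=0.14,
        min_cells=100,
    )
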