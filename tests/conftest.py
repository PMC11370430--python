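import numpy as np
import pytest

from ctcflow.membrane import ElasticParams
from ctcflow.meshes import build_biconcave_mesh, build_sphere_mesh


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240819)


@pytest.fixture(scope="session")
def sphere_cell():
    return build_sphere_mesh(8e-6, refinement=1, params=ElasticParams())


@pytest.fixture(scope="session")
def biconcave_cell():
    return build_biconcave_mesh(8e-6, refinement=2, params=ElasticParams())


@pytest.fixture()
def perturbed_sphere(sphere_cell, rng):
    cell = sphere_cell.copy()
    cell.vertices = cell.vertices * (
        1.0 + 0.01 * rng.standard_normal(cell.vertices.shape))
    return cell
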