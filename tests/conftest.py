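import numpy as np
import pytest

import fibrilgeom as fg


@pytest.fixture(scope="session")
def simple_spec():
    """Small noise-free single-stack beta fibril."""
    return fg.GeneratorSpec(sequence="AEAKAAEK", phi_deg=-120.0, psi_deg=132.0,
                            twist_deg_per_layer=-1.66, rise_A=4.8,
                            n_layers=6, residue_start=1)


@pytest.fixture(scope="session")
def simple_fibril(simple_spec):
    return fg.build_fibril(simple_spec)


@pytest.fixture(scope="session")
def vascular_like():
    """Two non-equal stacks, C1, left twist (vascular AA geometry)."""
    return fg.vascular_like_model()


@pytest.fixture(scope="session")
def glomerular_like():
    """Two equal stacks, pseudo-2_1, right twist (glomerular AA geometry)."""
    return fg.glomerular_like_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def rotation_matrix(axis, deg):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    from scipy.spatial.transform import Rotation
    return Rotation.from_rotvec(np.radians(deg) * axis).as_matrix()
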