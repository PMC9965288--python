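import numpy as np
import pytest

from tmdkit import helix_geometry as hg
from tmdkit import synthetic_data as syn


@pytest.fixture
def straight_helix():
    """Noise-free 28-residue poly-Ala helix along +z."""
    return syn.make_helix(syn.HelixSpec("A" * 28, first_residue=1))


@pytest.fixture
def kinked_helix():
    """Noise-free helix with a 70-degree hinge at residue 14."""
    return syn.make_helix(
        syn.HelixSpec("A" * 28, 1, kink_position=14, kink_angle=70.0)
    )


@pytest.fixture
def irr_standin():
    """Synthetic stand-in two-state ensemble for the IRR TMD."""
    return syn.standin_ensemble("IRR", seed=1)


def random_rigid_transform(rng):
    """Random rotation matrix + translation vector."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    trans = rng.normal(scale=20.0, size=3)
    return rot, trans


def transform_model(model, rot, trans):
    return model.with_coordinates(model.coordinates @ rot.T + trans)
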