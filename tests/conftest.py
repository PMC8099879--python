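import numpy as np
import pytest

from g4smlm.fields import ROI, LocalizationField
from g4smlm.synthetic import SceneSpec, generate_point_field, generate_triplet_scene


@pytest.fixture(scope="session")
def csr_field():
    """A moderately dense CSR field on the standard 6 µm ROI."""
    return generate_point_field(200.0, 6000.0, channel=1, seed=11)


@pytest.fixture(scope="session")
def planted_scene():
    """Equilateral 100 nm triplet scene with CSR background (ground truth kept)."""
    spec = SceneSpec(
        n_triplets=50,
        triplet_geometry=(100.0, 100.0, 100.0),
        background_density=(20.0, 20.0, 20.0),
        seed=7,
    )
    return generate_triplet_scene(spec)


def make_field(xy, side=6000.0, channel=0):
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    return LocalizationField(xy=xy, roi=ROI.square(side), channel=channel)
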