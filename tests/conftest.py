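import numpy as np
import pytest

from virtpol.dataprep import TilePair
from virtpol.phantoms import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One 128-px phantom reused by read-only tests."""
    return generate_phantom(PhantomSpec(image_size=128, n_amyloid_blobs=3, n_nuclei=6, seed=42))


@pytest.fixture(scope="session")
def phantom_tiles():
    """Aligned phantom tile pairs for all three modalities (8 stacks).

    The generous amyloid fraction keeps desk-scale training budgets small:
    colour-mapping gradients scale with the fraction of signal pixels.
    """
    tiles = []
    for i in range(8):
        s = generate_phantom(
            PhantomSpec(image_size=128, n_amyloid_blobs=3, n_nuclei=8, amyloid_area_fraction=0.25, seed=100 + i)
        )
        for modality, target in (
            ("brightfield", s.brightfield_gt),
            ("crosspol", s.crosspol_gt),
            ("angleshift", s.angleshift_gt),
        ):
            tiles.append(TilePair(stack=s.stack, target=target, modality=modality, tile_origin=(0, 0)))
    return tiles


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
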