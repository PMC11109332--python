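import numpy as np
import pytest

from segpatch import (
    ClassifierSpec,
    SmallConvNet,
    gen_blobs3d,
    gen_cells,
    gen_oriented_textures,
)


@pytest.fixture(scope="session")
def cells_scene():
    """Small gray-level cells scene: two classes split by mean intensity."""
    return gen_cells(n_cells=25, canvas=(128, 128), seed=7)


@pytest.fixture(scope="session")
def texture_scene():
    """Small oriented-texture scene: matched moments, 0 vs 90 degrees."""
    return gen_oriented_textures(n_tiles=16, tile=(16, 16), seed=3)


@pytest.fixture(scope="session")
def blob_scene():
    """Small 3D blob scene with the intensity class rule."""
    return gen_blobs3d(n_blobs=6, canvas=(28, 48, 48), seed=5)


@pytest.fixture()
def tiny_model():
    """Untrained 2-channel, 2-class model on 16x16 patches (zero head:
    constant logits, argmax ties)."""
    spec = ClassifierSpec(
        dim=2, depth=2, width=8, in_channels=2, n_classes=2, patch_size=(16, 16)
    )
    return SmallConvNet(spec, seed=11)
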