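import numpy as np
import pytest

from tilecurator.autoencoder import EncoderConfig, build_autoencoder
from tilecurator.synthetic_slide import (
    Region,
    SlideSpec,
    TextureSpec,
    default_texture_palette,
    generate_slide,
    generate_texture_tiles,
    quadrant_slide_spec,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quadrant_slide():
    """1536x1536 slide with four grid-aligned texture regions on white."""
    return generate_slide(quadrant_slide_spec(side=1536, region_side=512, margin=256, seed=7))


@pytest.fixture(scope="session")
def texture_tiles():
    """Forty single-texture 256x256 tiles cycling through the palette."""
    return generate_texture_tiles(40, seed=11)


@pytest.fixture(scope="session")
def reduced_model():
    """Untrained reduced-width autoencoder (seeded init) for shape/embedding tests."""
    return build_autoencoder(EncoderConfig().reduced(8), seed=3)


@pytest.fixture
def single_rect_spec():
    tex = TextureSpec(1, "blob", (160, 60, 150), scale=10.0, contrast=0.5)
    return SlideSpec(
        width=1024, height=1024, textures=[tex],
        regions=[Region(texture_id=1, rect=(0, 0, 512, 512))], seed=3, slide_id="rect",
    )
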