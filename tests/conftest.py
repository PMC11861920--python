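import numpy as np
import pytest

from chromadens.imaging_io import IntensityImage, Stain
from chromadens.phantom import PhantomSpec, generate_phantom


def rasterize_ellipse(a: float, b: float, pad: int = 3) -> np.ndarray:
    """Axis-aligned ellipse mask with half-axes (a rows, b cols)."""
    ha = int(np.ceil(a)) + pad
    hb = int(np.ceil(b)) + pad
    rr, cc = np.mgrid[-ha : ha + 1, -hb : hb + 1].astype(float)
    return (rr / a) ** 2 + (cc / b) ** 2 <= 1.0


@pytest.fixture
def clean_tb_phantom():
    """Noise-free TB phantom with five normal heads."""
    spec = PhantomSpec(
        image_size=(420, 420), n_heads=5, assignments=["N"] * 5,
        noise_sigma=0.0, seed=5,
    )
    return generate_phantom(spec)


@pytest.fixture
def tb_intensity(clean_tb_phantom):
    micro, _ = clean_tb_phantom
    return IntensityImage(values=micro.pixels / 255.0, stain=Stain.TB)
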