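import numpy as np
import pytest

from nucfish.images import ImageStack
from nucfish.synthetic import OpticsParams, generate_cell_scene, render_image


@pytest.fixture(scope="session")
def default_counts():
    return {
        ("intact", "cytoplasm"): 2,
        ("five_prime_part", "periphery"): 2,
        ("intact", "nucleus"): 1,
        ("three_prime_part", "cytoplasm"): 1,
    }


@pytest.fixture(scope="session")
def clean_scene(default_counts):
    return generate_cell_scene(default_counts, orientation_fraction=0.81, seed=11)


@pytest.fixture(scope="session")
def clean_stack(clean_scene):
    return render_image(clean_scene, OpticsParams(noise_model="none"), seed=0)


@pytest.fixture(scope="session")
def probe_map():
    return {
        "red": ("geneA", "five_prime"),
        "ir": ("geneA", "internal"),
        "green": ("geneA", "three_prime"),
    }


@pytest.fixture()
def ramp_stack():
    """A 1-channel stack whose DAPI rises linearly 0 -> 100 along x."""
    nx = 101
    img = np.tile(np.arange(nx, dtype=float), (3, 5, 1))
    return ImageStack(img[None], (0.1, 0.1, 0.1), ["dapi"])
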