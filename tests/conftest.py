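import numpy as np
import pytest

from lensfree_detect import GrayImage
from lensfree_detect.synth_scene import ObjectSpec, SceneSpec, render_scene


@pytest.fixture
def flat_image():
    """A constant frame: no contrast anywhere."""
    return GrayImage(np.full((60, 60), 128, dtype=np.uint8))


@pytest.fixture
def single_bead_scene():
    """One noise-free 10 µm object centred in a 300×300 frame."""
    spec = SceneSpec(height=300, width=300, noise_sigma=0.0,
                     objects=(ObjectSpec(center=(150, 150), size_um=10.0),))
    return render_scene(spec)


def add_streak(pixels: np.ndarray, center: tuple[int, int],
               length: int = 30, width: int = 3, depth: int = 35) -> None:
    """Paint a dark elongated streak (non-circular noise) in place."""
    r, c = center
    half_l, half_w = length // 2, width // 2
    pixels[r - half_w:r + half_w + 1, c - half_l:c + half_l + 1] = \
        np.maximum(0, int(pixels[r, c]) - depth)
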