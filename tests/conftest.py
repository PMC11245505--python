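import numpy as np
import pytest

from ulcerquant import EyeRegionSet, EyeSpec, LesionRequest, generate_eye


@pytest.fixture
def rng():
    return np.random.default_rng(20240712)


def make_disc(size, center, radius):
    rows, cols = np.indices((size, size))
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2


@pytest.fixture
def simple_eye():
    """A centered cornea/pupil pair with a small scar in the top-left quadrant."""
    size = 64
    c = ((size - 1) / 2, (size - 1) / 2)
    cornea = make_disc(size, c, 26)
    pupil = make_disc(size, c, 8)
    scar = make_disc(size, (16, 16), 5) & cornea & ~pupil
    return EyeRegionSet(cornea, pupil, {"scar": scar}, eye_id="simple")


@pytest.fixture
def grade2_eye():
    """Synthetic eye with a ~30% scar over two quadrants, away from the pupil."""
    spec = EyeSpec(
        size=96,
        lesions={"scar": LesionRequest(0.30, quadrants=(0, 1), pupil_overlap=False)},
        seed=7,
        eye_id="g2",
    )
    return generate_eye(spec)
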