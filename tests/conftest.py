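import numpy as np
import pytest

from shelladc import BinaryMask, ImageVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def make_volume(data, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(data, dtype=float), spacing)


def make_mask(data, spacing=(1.0, 1.0, 1.0), role="tumor"):
    return BinaryMask(np.asarray(data), spacing, role=role)


def ball_mask(shape, center, radius, spacing=(1.0, 1.0, 1.0), role="tumor"):
    grids = np.meshgrid(*(np.arange(n) * s for n, s in zip(shape, spacing)),
                        indexing="ij")
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return BinaryMask(r2 <= radius**2, spacing, role=role)


@pytest.fixture
def sphere_tumor():
    """Digital sphere of radius 5 mm centered in a 30^3 1 mm grid."""
    return ball_mask((30, 30, 30), (14.5, 14.5, 14.5), 5.0)
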