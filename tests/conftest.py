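"""Shared fixtures: small deterministic phantoms and helper constructors."""

from __future__ import annotations

import numpy as np
import pytest

from simscorr.phantom import PhantomSpec, make_em_phantom
from simscorr.rois import ROISet


def disk_mask(shape, center, radius):
    rr, cc = np.ogrid[:shape[0], :shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def square_mask(shape, r0, c0, side):
    m = np.zeros(shape, dtype=bool)
    m[r0:r0 + side, c0:c0 + side] = True
    return m


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic 384x384 phantom with a few instances per class."""
    spec = PhantomSpec(
        image_shape=(384, 384),
        counts={"nucleolus": 1, "mitochondria": 3, "ER": 2, "Golgi": 2,
                "vacuoles": 2, "vesicles": 4},
        seed=11)
    image, truth = make_em_phantom(spec)
    return spec, image, truth


@pytest.fixture()
def empty_roiset():
    return ROISet(image_shape=(64, 64))
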