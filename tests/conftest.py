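import numpy as np
import pytest

from growcutvol.core import ImageGeometry, LabelMap, ScalarVolume, ScribbleSet
from growcutvol.phantom import PhantomParams, make_phantom, make_scribbles


@pytest.fixture
def unit_geom():
    """64³ grid at 1 mm isotropic spacing."""
    return ImageGeometry(shape=(64, 64, 64))


@pytest.fixture
def small_phantom():
    """A clean 40³ phantom (image, ground truth, scribbles)."""
    params = PhantomParams(
        shape=(40, 40, 40), radii=(8.0, 7.0, 7.5), noise_sigma=0.0, rng_seed=0
    )
    volume, truth = make_phantom(params)
    scribbles = make_scribbles(truth)
    return volume, truth, scribbles


def random_instance(rng, shape=(12, 12, 12), n_fg=(1, 6), n_bg=(1, 6)):
    """Random intensity volume + random 2-class scribbles on it."""
    geom = ImageGeometry(shape=shape)
    values = rng.normal(0.0, 1.0, shape)
    labels = np.zeros(shape, dtype=np.int16)
    for _ in range(int(rng.integers(*n_fg))):
        labels[tuple(rng.integers(0, s) for s in shape)] = 1
    placed = 0
    target = int(rng.integers(*n_bg))
    while placed < target:
        idx = tuple(rng.integers(0, s) for s in shape)
        if labels[idx] == 0:
            labels[idx] = 2
            placed += 1
    return ScalarVolume(geom, values), ScribbleSet(geom, labels)


def binary_map(arr, spacing=(1.0, 1.0, 1.0)) -> LabelMap:
    """Wrap a boolean/0-1 array as a binary LabelMap."""
    arr = np.asarray(arr)
    geom = ImageGeometry(shape=arr.shape, spacing=spacing)
    return LabelMap(
        geometry=geom, labels=arr.astype(np.int16), label_meaning={1: "tumor"}
    )
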