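"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from ratpet.atlas import smooth_gaussian
from ratpet.extraction import apply_mask
from ratpet.phantom import PhantomSpec, make_ground_truth
from ratpet.template import TemplateSet
from ratpet.volume import Volume


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Reduced phantom grid used by registration-heavy tests."""
    return PhantomSpec(dims=(48, 36, 30))


@pytest.fixture(scope="session")
def ground_truth(small_spec):
    return make_ground_truth(small_spec)


@pytest.fixture(scope="session")
def default_ground_truth():
    return make_ground_truth(PhantomSpec())


@pytest.fixture(scope="session")
def template_set(default_ground_truth) -> TemplateSet:
    """Phantom-derived template set: blurred truth, canonical brain, mask."""
    gt = default_ground_truth
    tpl = smooth_gaussian(gt.pet, (2.0, 2.0, 4.0))
    return TemplateSet(
        template=tpl,
        canonical=apply_mask(tpl, gt.brain_mask),
        mask=gt.brain_mask,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy_volume() -> Volume:
    data = np.zeros((8, 8, 8))
    data[2:6, 2:6, 2:6] = 1.0
    return Volume(data, voxel_size=(1.0, 1.0, 1.0), origin=(4, 4, 4), space="template")
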