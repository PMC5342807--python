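import numpy as np
import pytest

from collalign import AffineTransform, FiberFieldSpec, make_fiber_image


@pytest.fixture(scope="session")
def shg_scene():
    """A moderately aligned fiber field reused by the registration tests."""
    spec = FiberFieldSpec(
        n_fibers=220, mean_angle=130.0, kappa=3.0, image_size_px=(256, 256), seed=7
    )
    img, fibers = make_fiber_image(spec)
    return img, fibers


@pytest.fixture(scope="session")
def dense_field():
    """A dense stationary field for ROI sampling-variability checks."""
    spec = FiberFieldSpec(
        n_fibers=900, mean_angle=40.0, kappa=2.0, image_size_px=(512, 512), seed=11
    )
    return make_fiber_image(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def identity():
    return AffineTransform.identity()
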