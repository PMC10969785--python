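import numpy as np
import pytest

from pulpscan import GrayImage, PhantomSpec, SegmentationConfig


@pytest.fixture
def default_config() -> SegmentationConfig:
    return SegmentationConfig()


@pytest.fixture
def small_spec() -> PhantomSpec:
    """A 256-px phantom that segments in a few hundredths of a second."""
    return PhantomSpec(
        image_size=256,
        fruit_radius=100.0,
        peel_thickness=10.0,
        cavity_radius=(30.0, 24.0),
        n_segments=8,
        seed=11,
    )


def as_gray(arr, value_range=(0.0, 255.0), section_kind="cross") -> GrayImage:
    return GrayImage(np.asarray(arr, dtype=np.float32), value_range, section_kind)


@pytest.fixture
def gray_factory():
    return as_gray
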