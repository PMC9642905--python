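import numpy as np
import pytest

from endodomain.roi import PixelImage
from endodomain.synthetic import EndosomeSpec, SceneSpec


@pytest.fixture
def make_endosome():
    """Factory for a one- or two-channel endosome spec with overridable fields."""

    def _make(**kwargs):
        defaults = dict(
            center=(100.0, 60.0),
            radius_um=2.0,
            ring_width_um=0.6,
            ring_intensity=100.0,
            arc_center_deg=30.0,
            arc_coverage=0.25,
            arc_intensity=300.0,
        )
        defaults.update(kwargs)
        return EndosomeSpec(**defaults)

    return _make


@pytest.fixture
def make_scene(make_endosome):
    """Factory for a valid 200x200 scene with one endosome by default."""

    def _make(endosomes=None, **kwargs):
        if endosomes is None:
            endosomes = (make_endosome(),)
        defaults = dict(
            cell_center=(100.0, 100.0),
            cell_radius_um=8.0,
            nucleus_radius_um=2.5,
            cytoplasm_intensity=50.0,
            background_intensity=5.0,
            endosomes=tuple(endosomes),
            noise_sd=0.0,
            pixel_size_um=0.1,
            image_shape=(200, 200),
            seed=1,
        )
        defaults.update(kwargs)
        return SceneSpec(**defaults)

    return _make


@pytest.fixture
def constant_image():
    def _make(value=50.0, shape=(64, 64), pixel_size_um=0.1):
        return PixelImage(values=np.full(shape, value), pixel_size_um=pixel_size_um)

    return _make
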