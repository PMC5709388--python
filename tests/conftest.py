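import numpy as np
import pytest

from vitalseg import ImageSet, LabelMap, SegmentationParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_params():
    """Segmentation parameters scaled for tiny hand-built rasters."""
    return SegmentationParams(neighborhood_size=5, min_object_area=0.0)


def make_label_map(shape, blobs, pixel_area=1.0):
    """Build a LabelMap from (slice_rows, slice_cols) blob specs."""
    labels = np.zeros(shape, dtype=np.int32)
    for i, (rs, cs) in enumerate(blobs, start=1):
        labels[rs, cs] = i
    return LabelMap(labels, pixel_area, list(range(1, len(blobs) + 1)))


def make_image_set(shape=(32, 32), fill=(100.0, 50.0, 25.0), **kwargs):
    defaults = dict(pixel_area=1.0, well_id="w1", group="no_treatment")
    defaults.update(kwargs)
    return ImageSet(
        brightfield=np.full(shape, fill[0]),
        live=np.full(shape, fill[1]),
        dead=np.full(shape, fill[2]),
        **defaults,
    )
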