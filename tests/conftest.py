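import numpy as np
import pytest

from pniscreen.postprocess import label_components
from pniscreen.synthgen import PNIEvent, TileSpec, generate_tile


@pytest.fixture(scope="session")
def small_tile_spec():
    """A quick-to-generate 128 px tile for unit tests."""
    return TileSpec(
        height=128,
        width=128,
        n_nerves=1,
        n_malignant_glands=1,
        n_benign_glands=1,
        nerve_thickness_range=(14.0, 20.0),
        gland_radius_range=(30.0, 40.0),
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_tile(small_tile_spec):
    return generate_tile(small_tile_spec)


@pytest.fixture(scope="session")
def event_tile():
    """A full-size tile with one planted contact/encirclement event."""
    spec = TileSpec(rng_seed=42)
    rgb, gt = generate_tile(spec, [PNIEvent(target_distance=0.0, target_encirclement=0.5)])
    return spec, rgb, gt


@pytest.fixture()
def regions_from():
    """Helper: boolean raster -> LabeledRegions."""

    def _make(mask, connectivity=8):
        return label_components(np.asarray(mask, dtype=bool), connectivity=connectivity)

    return _make
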