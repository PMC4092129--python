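import numpy as np
import pytest

from gyrospec.spectral_scene import (Scene, default_library, generate_dtm,
                                     generate_patch_map, DEFAULT_BACKGROUND)


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def small_scene():
    """10 m x 10 m scene at g=0.05 with one disc and background mosaic."""
    shape = (200, 200)
    dtm = generate_dtm(shape, "flat", 0.0)
    base = Scene(dtm=dtm, class_map=np.zeros(shape, np.int16),
                 class_names=["carpobrotus"] + DEFAULT_BACKGROUND,
                 g_fine=0.05, origin=(0.0, 0.0))
    return generate_patch_map(base, n_disc_patches=1,
                              disc_radius_range=(2.0, 2.0), n_tendrils=0,
                              tendril_width=0.2,
                              background_classes=DEFAULT_BACKGROUND, seed=3)


@pytest.fixture()
def flat_scene_factory():
    """Flat single-class Scene of arbitrary size/grid for geometry tests."""

    def make(width_m=100.0, height_m=100.0, g=0.5, origin=None, z=0.0):
        shape = (int(round(height_m / g)), int(round(width_m / g)))
        if origin is None:
            origin = (-width_m / 2.0, height_m / 2.0)
        return Scene(dtm=np.full(shape, float(z)),
                     class_map=np.zeros(shape, np.int16),
                     class_names=["target"], g_fine=g, origin=origin)

    return make
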