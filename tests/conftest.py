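import numpy as np
import pytest

from gbseg import phantom


@pytest.fixture(scope="session")
def easy_params():
    """High-contrast, large-lesion, low-speckle 64x64 phantom family: a task
    separable by intensity thresholding, used wherever learnability matters."""
    return phantom.PhantomParams(
        image_height=64, image_width=64,
        lumen_axes_range=(16, 23), wall_thickness_range=(3, 5),
        lesion_count_range=(1, 2), lesion_radius_range=(7, 11),
        stone_probability=0.0, speckle_shape=15.0,
    )


def make_arrays(params, n, master_seed=7):
    samples = [phantom.generate_phantom(params, phantom.derive_seed(master_seed, i))
               for i in range(n)]
    images = np.stack([s.image for s in samples])
    masks = np.stack([s.mask for s in samples])
    return images, masks


@pytest.fixture(scope="session")
def small_arrays(easy_params):
    """8 easy phantoms as in-memory arrays (shared across training tests)."""
    return make_arrays(easy_params, 8)


@pytest.fixture()
def small_dataset(tmp_path, easy_params):
    """6-sample phantom dataset on disk with its manifest."""
    out = tmp_path / "data"
    manifest = phantom.generate_dataset(easy_params, 6, seed=11, out_dir=out)
    return out, manifest
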