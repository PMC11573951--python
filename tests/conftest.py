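import warnings

import numpy as np
import pytest

from gliotme import pcl, synthetic

warnings.filterwarnings("ignore", message="element .* constant for pair")


@pytest.fixture(scope="session")
def small_cohort():
    """5 grades x 3 images at 128 px, study-default specs."""
    return synthetic.generate_cohort(
        synthetic.small_test_config(3, image_size=128), seed=11
    )


@pytest.fixture(scope="session")
def easy_cohort():
    """Three well-separated planted phenotypes in pure neighborhoods."""
    return synthetic.generate_cohort(synthetic.easy_phenotype_config(), seed=11)


@pytest.fixture(scope="session")
def easy_patches(easy_cohort):
    patches = []
    for img, truth, iid in zip(
        easy_cohort.images, easy_cohort.truths, easy_cohort.image_ids
    ):
        patches.extend(pcl.tile_image(img, truth.tissue_mask, 16, 16, iid))
    return patches


@pytest.fixture(scope="session")
def trained_encoder(easy_patches):
    return pcl.train_encoder(easy_patches, pcl.PCLConfig(epochs=4, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
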