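import logging

import numpy as np
import pytest

from strokemri.geometry import AcquisitionGeometry, DEFAULT_GEOMETRY
from strokemri.phantom import build_template, make_lesion, make_tissue_field

logging.getLogger("strokemri.pipeline").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def geo_small():
    """Scaled-down protocol: same voxel size, smaller brain, fewer slices."""
    return AcquisitionGeometry(matrix_size=(32, 32), fov_mm=(12.5, 12.5), n_slices=9)


@pytest.fixture(scope="session")
def template_small(geo_small):
    return build_template(geo_small)


@pytest.fixture(scope="session")
def template_default():
    return build_template(DEFAULT_GEOMETRY)


@pytest.fixture(scope="session")
def lesion_small(template_small):
    return make_lesion(template_small, cortical_fraction_2h=0.6,
                       cortical_fraction_24h=0.95, rng_seed=4)


@pytest.fixture(scope="session")
def tissue_small(template_small, lesion_small):
    return make_tissue_field(template_small, lesion_small.lesion_mask_24h)


@pytest.fixture(scope="session")
def healthy_tissue_default(template_default):
    return make_tissue_field(template_default, np.zeros(template_default.shape, bool))
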