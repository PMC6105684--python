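import warnings

import numpy as np
import pytest

from finpigment import synth
from finpigment.preprocess import normalise, to_grey
from finpigment.registration import extract_contour
from finpigment.subdivision import contour_subdivide, estimate_base, grid_subdivide


@pytest.fixture(scope="session")
def identity():
    return synth.make_identity("FIX1", seed=42)


@pytest.fixture(scope="session")
def clean_photo(identity):
    """Noise-free canonical-pose render: (pixels, mask, ground truth)."""
    return synth.render_photo(identity, synth.NuisanceDraw(), photo_seed=7)


@pytest.fixture(scope="session")
def fin_mask(clean_photo):
    return clean_photo[1]


@pytest.fixture(scope="session")
def normalised_fin(clean_photo):
    pixels, mask, _ = clean_photo
    return normalise(to_grey(pixels), mask)


@pytest.fixture(scope="session")
def fin_contour(fin_mask):
    return extract_contour(fin_mask)


@pytest.fixture(scope="session")
def base_line(fin_contour):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return estimate_base(fin_contour)


@pytest.fixture(scope="session")
def grid_partition(fin_mask, base_line):
    return grid_subdivide(fin_mask, base_line)


@pytest.fixture(scope="session")
def contour_partition(fin_mask, fin_contour, base_line):
    return contour_subdivide(fin_mask, fin_contour, base_line)


@pytest.fixture(scope="session")
def small_catalogue():
    """8 identities x 3 photos with mild nuisance."""
    nuisance = synth.PhotoNuisance(
        homography_jitter=5.0,
        rotation_jitter=4.0,
        scale_jitter=0.03,
        translation_jitter=2.0,
        gain_jitter=0.1,
        offset_jitter=8.0,
        noise_sd=3.0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synth.generate_catalogue(8, 3, nuisance, master_seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
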