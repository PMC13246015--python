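"""Shared fixtures.

Heavy simulation/registration fixtures are session-scoped so the default
study is computed once and shared by every test that needs it.
"""

from __future__ import annotations

import numpy as np
import pytest

from regresponse import StudyConfig, generate_cohort, run_study
from regresponse.synthetic import make_interval_deformation, make_phantom


@pytest.fixture(scope="session")
def default_config() -> StudyConfig:
    return StudyConfig(seed=1)


@pytest.fixture(scope="session")
def phantom(default_config):
    """One baseline phantom (image, pancreas mask, tumor mask)."""
    return make_phantom(default_config, (1, 0, 1))


@pytest.fixture(scope="session")
def deformed_pair(default_config, phantom):
    """Phantom pair with a known interval deformation (rho = 0.6)."""
    img, panc, tum = phantom
    field, post, panc_post, tum_post = make_interval_deformation(
        img, panc, tum, 0.6, default_config, (1, 0, 3)
    )
    return {
        "pre_image": img,
        "pancreas_pre": panc,
        "tumor_pre": tum,
        "field": field,
        "post_image": post,
        "pancreas_post": panc_post,
        "tumor_post": tum_post,
    }


@pytest.fixture(scope="session")
def small_cohort():
    """Four-patient cohort with default readers (no registration run)."""
    return generate_cohort(StudyConfig(seed=7, n_patients=4))


@pytest.fixture(scope="session")
def headline_studies():
    """Full default studies (n = 30, 4 readers) for five seeds."""
    return {seed: run_study(StudyConfig(seed=seed), plots=False) for seed in (1, 2, 3, 4, 5)}


def random_blob_mask(rng: np.random.Generator, shape=(20, 20, 6)) -> np.ndarray:
    """A connected-ish random binary mask for statistic fixtures."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    mask = field > np.percentile(field, 70)
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    return mask
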