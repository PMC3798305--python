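import numpy as np
import pytest

from vastex.cohort import CohortConfig, features_table, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but two-class cohort used across module tests (fast)."""
    cfg = CohortConfig(
        n_normal_subjects=4, n_abnormal_subjects=4, rois_per_subject=2,
        frames_per_roi=5, roi_height=48, roi_width=64,
        abnormal_total_rois=None, seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return features_table(small_cohort)


def random_gray(rng, shape, levels):
    """Random test image at a given gray-level count."""
    from vastex.image import GrayImage
    return GrayImage(rng.integers(0, levels, size=shape), levels=levels)
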