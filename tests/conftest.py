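"""Shared fixtures: small deterministic images and synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from octascreen import AngiogramImage, PhantomSpec, generate_phantom
from octascreen.features import FEATURE_COLUMNS


@pytest.fixture(scope="session")
def ridge_image():
    """Single bright width-3 horizontal ridge on a dark background."""
    im = np.zeros((304, 304))
    im[150:153, :] = 1.0
    return AngiogramImage(im)


@pytest.fixture(scope="session")
def disk_faz_scene():
    """Speckled vessel field with a vessel-free central disk of radius 25 px.

    Returns (image, vessel_mask, ground-truth disk mask).
    """
    rng = np.random.default_rng(0)
    mask = rng.random((304, 304)) < 0.25
    mask |= np.roll(mask, 1, axis=0)  # slight clumping
    rr, cc = np.mgrid[0:304, 0:304]
    disk = (rr - 152) ** 2 + (cc - 152) ** 2 <= 25**2
    mask[disk] = False
    img = AngiogramImage(np.where(mask, 1.0, 0.0))
    return img, mask, disk


@pytest.fixture(scope="session")
def default_phantom():
    """One disease-free phantom pair with ground truth (fixed seed)."""
    return generate_phantom(PhantomSpec(seed=7))


def synthetic_cohort(seed, n_per_class=60, effect=2.0,
                     informative=("BVT_S", "FAZ_A_S"),
                     labels=("control", "mild_scr"), permute=False):
    """Gaussian feature cohort: chosen features shift by ``effect`` SD per
    class index, everything else is pure noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for cls, label in enumerate(labels):
        X = rng.standard_normal((n_per_class, len(FEATURE_COLUMNS)))
        if not permute:
            for f in informative:
                X[:, FEATURE_COLUMNS.index(f)] += effect * cls
        for i in range(n_per_class):
            row = {"subject_id": f"{label}_{i}", "eye": "OD", "label": label}
            row.update(dict(zip(FEATURE_COLUMNS, X[i])))
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def two_class_cohort():
    return synthetic_cohort(seed=12345)
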