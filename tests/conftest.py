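import numpy as np
import pytest

from polarlr import ml, synthetic
from polarlr.optics import PolStateSequence, random_physical_mueller


@pytest.fixture(scope="session")
def default_seq() -> PolStateSequence:
    return PolStateSequence.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def physical_matrices():
    """100 random physical Mueller matrices (fixed seed)."""
    rng = np.random.default_rng(42)
    return [random_physical_mueller(rng) for _ in range(100)]


@pytest.fixture(scope="session")
def separable_cohort():
    """Well-separated two-class cohort: 14 no-LR / 7 LR patients."""
    cfg = synthetic.CohortConfig(n_patients=(14, 7), pixels_per_roi=300, seed=11)
    feats, pats, truth = synthetic.generate_cohort(cfg, synthetic.separable_class_params())
    return feats, pats, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Identical class distributions: no real signal."""
    cfg = synthetic.CohortConfig(n_patients=(20, 10), pixels_per_roi=200, seed=0)
    feats, pats, truth = synthetic.generate_cohort(cfg, synthetic.null_class_params())
    return feats, pats, truth


@pytest.fixture(scope="session")
def default_cohort():
    """Study-shaped cohort with default class contrast and exact ROI totals."""
    cfg = synthetic.CohortConfig(
        roi_counts=synthetic.study_roi_counts(), pixels_per_roi=300, seed=5
    )
    feats, pats, truth = synthetic.generate_cohort(cfg)
    return feats, pats, truth
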