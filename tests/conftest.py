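import numpy as np
import pytest

from rectomics.synthetic import CohortSpec, generate_cohort, generate_study_cohort


def random_roi_slice(rng: np.random.Generator, size_range=(4, 12), level_range=(2, 8)):
    """A random discretized ROI slice with an irregular (non-rectangular) mask."""
    rows = rng.integers(*size_range, endpoint=True)
    cols = rng.integers(*size_range, endpoint=True)
    n_levels = int(rng.integers(*level_range, endpoint=True))
    grid = rng.integers(1, n_levels, size=(rows, cols), endpoint=True).astype(np.int32)
    # carve out background while keeping at least 4 ROI pixels
    hole = rng.random((rows, cols)) < 0.25
    grid[hole] = 0
    if (grid > 0).sum() < 4:
        grid[:2, :2] = rng.integers(1, n_levels, size=(2, 2), endpoint=True)
    return grid, n_levels


@pytest.fixture(scope="session")
def tiny_cohort():
    """6 construction + 4 validation cases; shared across read-only tests."""
    return generate_study_cohort((3, 3), (2, 2), seed=7)


@pytest.fixture(scope="session")
def one_case():
    spec = CohortSpec(n_responders=1, n_nonresponders=1, centres=("A",), rng_seed=11)
    return generate_cohort(spec)[0]
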