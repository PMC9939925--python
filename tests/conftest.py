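import numpy as np
import pytest

from stabkrig.geometry import voronoi_region
from stabkrig.laa_data import from_counts
from stabkrig.semivariogram import CovarianceModel, SphericalVariogram


@pytest.fixture(scope="session")
def small_region():
    """A fixed 26-LAA Voronoi county reused across tests."""
    return voronoi_region(seed=7, n_laas=26, bounds=(0.0, 0.5, 0.0, 0.42))


@pytest.fixture()
def four_area_table():
    """Four areas, one of them with zero cases (infinite variance)."""
    return from_counts(
        [
            ("a", (0.0, 0.0), 10, 1000.0),
            ("b", (1.0, 0.0), 0, 500.0),
            ("c", (0.0, 1.0), 20, 2000.0),
            ("d", (1.0, 1.0), 5, 800.0),
        ]
    )


@pytest.fixture()
def simple_model():
    return CovarianceModel(SphericalVariogram(nugget=0.05, partial_sill=0.3, range_=1.5))


def random_table(rng, n=8, zero_case_prob=0.0, spread=1.0):
    """Random count-derived table on uniform points (test helper)."""
    pts = rng.uniform(0, spread, size=(n, 2))
    pops = rng.uniform(500, 5000, size=n)
    lam = pops * 1e-2 * rng.lognormal(0.0, 0.3, size=n)
    cases = np.maximum(rng.poisson(lam), 1)
    if zero_case_prob > 0:
        cases[rng.random(n) < zero_case_prob] = 0
    return from_counts(
        (f"r{i}", tuple(pts[i]), int(cases[i]), float(pops[i])) for i in range(n)
    )
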