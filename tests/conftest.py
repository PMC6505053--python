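import pandas as pd
import pytest

import saeprev as sp
from saeprev import fixtures


@pytest.fixture(scope="session")
def small_census():
    return sp.generate_census(n_areas=6, mean_area_pop=20_000,
                              area_pop_sigma=0.0, seed=3)


@pytest.fixture(scope="session")
def small_truth(small_census):
    return sp.generate_truth(small_census, sigma_v=0.3, seed=3)


@pytest.fixture(scope="session")
def small_survey(small_census, small_truth):
    return sp.draw_survey(small_census, small_truth, 300, seed=3)


@pytest.fixture(scope="session")
def census31():
    return sp.generate_census(n_areas=31, mean_area_pop=30_000,
                              area_pop_sigma=0.0, seed=31)


@pytest.fixture(scope="session")
def sizes31(census31):
    sizes = fixtures.table4_sample_sizes().sort_values().to_list()
    return dict(zip(sorted(census31["area_id"].unique()), sizes))


@pytest.fixture(scope="session")
def survey31(census31, sizes31):
    truth = sp.generate_truth(census31, sigma_v=0.3, seed=31)
    return sp.draw_survey(census31, truth, sizes31, seed=31), truth


@pytest.fixture()
def two_area_toy():
    """Two single-cell areas with known binomial data; used against the
    deterministic quadrature oracle."""
    census = pd.DataFrame({"area_id": ["area_a", "area_b"],
                           "cell_id": ["all", "all"], "count": [500, 400]})
    rows, uid = [], 0
    for area, (n, k) in {"area_a": (40, 12), "area_b": (35, 18)}.items():
        for j in range(n):
            rows.append((uid, area, "all", int(j < k), 1.0))
            uid += 1
    survey = pd.DataFrame(rows, columns=["unit_id", "area_id", "cell_id",
                                         "y", "w"])
    return census, survey
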