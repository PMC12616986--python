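"""Shared fixtures.

The expensive objects (herd simulations, the baseline estimation context,
breeding-scheme runs) are session-scoped and shared across test modules;
scheme runs for different breeding goals are served from a factory with a
cache so the goal-ranking and method-comparison tests reuse the same runs.
"""

import warnings

import numpy as np
import pytest

from lactsel import breedsim, envgen, founders, herd_model, mmlink, quantgen

warnings.filterwarnings("ignore", message="negative sire variance")


@pytest.fixture(scope="session")
def ref_params():
    return quantgen.load_default_parameters()


@pytest.fixture(scope="session")
def goals():
    return quantgen.load_default_goals()


@pytest.fixture(scope="session")
def hs_calendar():
    return envgen.make_feed_calendar("HS", 13)


@pytest.fixture(scope="session")
def ms_calendar():
    return envgen.make_feed_calendar("MS", 13)


@pytest.fixture(scope="session")
def small_population():
    """10 x 20 founder population used by the herd-model tests."""
    return founders.sample_founders(10, 20, rng_seed=3)


@pytest.fixture(scope="session")
def herd_results(small_population, hs_calendar, ms_calendar):
    """Full-channel lifetime simulations of the same cows in HS and MS,
    with common random numbers (same seed)."""
    pop, _ = small_population
    return {
        sc: herd_model.simulate_herd(pop, cal, None, rng_seed=5)
        for sc, cal in (("HS", hs_calendar), ("MS", ms_calendar))
    }


@pytest.fixture(scope="session")
def baseline_ctx():
    """Desk-scale baseline (50 sires x 40 daughters) with estimated
    genetic parameters for both environments."""
    return mmlink.estimate_baseline(50, 40, rng_seed=3)


SCHEME_TEST_CONFIG = breedsim.SchemeConfig(
    n_cows=600, n_herds=6, n_sires_per_year=8, n_genotyped_per_sex=120,
    n_moet_heifers=12, horizon_years=16, burn_in_years=8, replicates=3)


@pytest.fixture(scope="session")
def scheme_run(ref_params, goals):
    """Factory returning (and caching) reduced-size scheme runs per goal."""
    cache = {}

    def run(goal_name, seed=5):
        key = (goal_name, seed)
        if key not in cache:
            cache[key] = breedsim.run_scheme(SCHEME_TEST_CONFIG, ref_params,
                                             goals[goal_name], rng_seed=seed)
        return cache[key]

    return run
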