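import numpy as np
import pytest

from trunkct import (CohortSpec, PhantomSpec, RaterNoiseSpec, generate_cohort,
                     generate_phantom, simulate_raters)


@pytest.fixture(scope="session")
def default_phantom():
    """One default phantom shared across tests (read-only)."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def calibrated_raters():
    """533 cases x 4 raters calibrated to the study's reliability summary:
    true angles N(38.6, 13.5^2), rating error SD 3.69."""
    rng = np.random.default_rng(123)
    true = rng.normal(38.6, 13.5, size=533)
    return simulate_raters(true, RaterNoiseSpec(k_raters=4,
                                                per_rating_error_sd=3.69,
                                                seed=456))


@pytest.fixture()
def loaded_cohort_spec():
    """Cohort with a planted paraspinal correlation and confounders."""
    return CohortSpec(
        n_cases=433,
        per_muscle_loading={"paraspinal": 0.42, "psoas": 0.23},
        per_muscle_fat_mean={"paraspinal": 15.0, "psoas": 5.0},
        per_muscle_fat_sd={"paraspinal": 9.0, "psoas": 2.5},
        n_surgery=7, n_atrophy=5, n_fracture=20, n_transitional=10,
        seed=99,
    )


@pytest.fixture()
def clean_cohort():
    """Confounder-free cohort with moderate loadings."""
    spec = CohortSpec(
        n_cases=500,
        per_muscle_loading={g: 0.4 for g in
                            ("paraspinal", "psoas", "quadratus_lumborum")},
        seed=5,
    )
    return generate_cohort(spec)
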