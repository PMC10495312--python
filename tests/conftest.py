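import numpy as np
import pytest

from aize import build_24_2, make_study_cohort, run_experiment, study_plan

#: Seed fixing the synthetic study cohort and experiments used across tests.
COHORT_SEED = 20230911


@pytest.fixture(scope="session")
def grid():
    return build_24_2()


@pytest.fixture(scope="session")
def cohort(grid):
    return make_study_cohort(np.random.default_rng(COHORT_SEED), grid=grid)


@pytest.fixture(scope="session")
def normal_cohort(cohort):
    return [f for f in cohort if f.label == "normal"]


@pytest.fixture(scope="session")
def glaucoma_cohort(cohort):
    return [f for f in cohort if f.label == "glaucoma"]


@pytest.fixture(scope="session")
def ordering_table(cohort):
    """Three-arm experiment over the full cohort for ordering comparisons.

    40 repetitions per (field, condition) cell keep the run desk-scale; the
    paired Wilcoxon comparisons operate on per-cell medians (100 pairs per
    cohort), for which this replication is ample.
    """
    plan = study_plan(cohort, base_seed=99, repetitions=40)
    return run_experiment(plan)


@pytest.fixture(scope="session")
def aize_table(cohort):
    """AIZE-only experiment at 100 repetitions per cell (both cohorts)."""
    plan = study_plan(cohort, base_seed=7, repetitions=100, strategies=("aize",))
    return run_experiment(plan)
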