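import numpy as np
import pandas as pd
import pytest

from methclock.synthetic_cohort import CohortSpec, simulate_cohort
from methclock.workflow import run_clock_pipeline, selection_truth_scores

# Scaled-down clock-recovery study: 30 individuals, 20,000 sites of which
# ~300 carry a logit-linear age trend (slopes 0.03-0.08/yr, residual SD 0.3)
# at mean read coverage 30.  One fixed cohort seed; the alpha grid is
# coarsened to steps of 0.1 to keep the tuning affordable at desk scale.
CLOCK_RECOVERY_SPEC = CohortSpec(
    n_individuals=30,
    n_sites=20_000,
    p_age=300 / 20_000,
    slope_range=(0.03, 0.08),
    sigma_site=0.3,
    coverage_mean=30.0,
    seed=11,
)
CLOCK_RECOVERY_ALPHA_GRID = np.round(np.arange(0.0, 1.01, 0.1), 2)


@pytest.fixture(scope="session")
def clock_recovery():
    """Full pipeline run on the clock-recovery cohort (shared; expensive)."""
    dataset, truth = simulate_cohort(CLOCK_RECOVERY_SPEC)
    result = run_clock_pipeline(
        dataset, alpha_grid=CLOCK_RECOVERY_ALPHA_GRID,
        seed=CLOCK_RECOVERY_SPEC.seed,
    )
    scores = selection_truth_scores(
        result.selected, truth, result.filtered.sites,
        result.filtered.samples["age_years"].to_numpy(float),
        CLOCK_RECOVERY_SPEC.coverage_mean,
    )
    return {
        "spec": CLOCK_RECOVERY_SPEC,
        "dataset": dataset,
        "truth": truth,
        "result": result,
        "selection_scores": scores,
    }


@pytest.fixture(scope="session")
def small_cohort():
    """A cheap cohort for I/O, preprocessing and evaluation tests."""
    spec = CohortSpec(n_individuals=12, n_sites=800, seed=7,
                      female_fraction=0.6)
    dataset, truth = simulate_cohort(spec)
    return {"spec": spec, "dataset": dataset, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
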