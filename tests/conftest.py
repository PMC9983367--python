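import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cuedyn.paradigm import build_schedule, canonical_hrf

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from cuedyn.simulate import SimConfig, simulate_cohort
from cuedyn.windowed_glm import make_windows, window_betas

# The LME stage logs expected notices (dropped covariates, exact fits) that
# would otherwise clutter test output.
logging.getLogger("cuedyn").setLevel(logging.ERROR)


def deterministic_beta_table(
    n_subjects: int = 4,
    food=(1.0, 0.7, 0.4),
    neutral=(0.2, 0.2, 0.2),
    motion: float | None = 0.0,
    roi: str = "roi_1",
) -> pd.DataFrame:
    """Exactly linear beta pattern, identical for every subject.

    The food response declines by 0.3 per window while neutral is flat, so
    the condition-by-time interaction is exactly -0.3 with zero residual.
    """
    rows = []
    for s in range(n_subjects):
        enorm = motion if motion is not None else 0.05 * (s + 1)
        for w, (f, n) in enumerate(zip(food, neutral)):
            rows.append((f"sub-{s + 1:02d}", roi, w, "food", f, enorm))
            rows.append((f"sub-{s + 1:02d}", roi, w, "neutral", n, enorm))
    return pd.DataFrame(
        rows, columns=["subject", "roi", "window", "condition", "beta", "mean_enorm"]
    )


@pytest.fixture(scope="session")
def default_schedule():
    return build_schedule(seed=0)


@pytest.fixture(scope="session")
def hrf_kernel():
    return canonical_hrf(0.1)


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Tiny cohort with no noise and no subject variability (habituating food)."""
    cfg = SimConfig(
        n_subjects=2, noise_sd=0.0, between_subject_sd=0.0, slope_diff_sd=0.0,
        slope_common_sd=0.0, motion_sd=0.0, seed=0,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_noisy_cohort():
    return simulate_cohort(SimConfig(n_subjects=8, seed=42))


@pytest.fixture(scope="session")
def small_noisy_betas(small_noisy_cohort):
    ds = small_noisy_cohort
    windows = make_windows(ds.schedule.run_duration_s)
    return window_betas(
        ds.ts, ds.schedule, ds.kernel, windows, motion_by_subject=ds.motion
    )


def cohort_betas(ds, **kwargs):
    windows = make_windows(ds.schedule.run_duration_s)
    return window_betas(
        ds.ts, ds.schedule, ds.kernel, windows, motion_by_subject=ds.motion, **kwargs
    )


def rng_cov_t(t_values, df):
    """Two-sided rejection rate of |t| at alpha=0.05 for the given df."""
    from scipy import stats

    crit = stats.t.ppf(0.975, df)
    t_values = np.asarray(t_values)
    return float(np.mean(np.abs(t_values) > crit))
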