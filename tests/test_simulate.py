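"""Generative-model contracts: determinism, ground truth, behavior coupling."""

import numpy as np
import pandas as pd
import pytest

from cuedyn.simulate import (
    BehaviorMeasure,
    SimConfig,
    SimConfigError,
    attach_behavior,
    simulate_cohort,
    simulate_null_cohort,
)
from cuedyn.windowed_glm import make_windows, window_betas

from conftest import cohort_betas


def test_same_seed_is_bit_identical():
    a = simulate_cohort(SimConfig(n_subjects=3, seed=5))
    b = simulate_cohort(SimConfig(n_subjects=3, seed=5))
    for s in a.subjects:
        pd.testing.assert_frame_equal(a.ts[s], b.ts[s])
        np.testing.assert_array_equal(a.motion[s], b.motion[s])
    pd.testing.assert_frame_equal(a.behavior, b.behavior)
    pd.testing.assert_frame_equal(a.truth, b.truth)


def test_different_seed_changes_noise():
    a = simulate_cohort(SimConfig(n_subjects=2, seed=5))
    b = simulate_cohort(SimConfig(n_subjects=2, seed=6))
    assert not np.allclose(a.ts["sub-01"], b.ts["sub-01"])


def test_roi_streams_are_isolated():
    """Adding a second ROI leaves the first ROI's series untouched."""
    one = simulate_cohort(SimConfig(n_subjects=2, roi_names=("a",), seed=7))
    two = simulate_cohort(SimConfig(n_subjects=2, roi_names=("a", "b"), seed=7))
    for s in one.subjects:
        np.testing.assert_array_equal(one.ts[s]["a"], two.ts[s]["a"])
        assert not np.allclose(two.ts[s]["a"], two.ts[s]["b"])


def test_behavior_field_does_not_touch_timeseries():
    base = SimConfig(n_subjects=2, seed=7)
    other = SimConfig(
        n_subjects=2, seed=7,
        behavior_measures=(BehaviorMeasure("fcq_state", -10.0, 5.0, 32.0, 15.0, 75.0),),
    )
    a, b = simulate_cohort(base), simulate_cohort(other)
    for s in a.subjects:
        pd.testing.assert_frame_equal(a.ts[s], b.ts[s])


def test_truth_dimensions_match_data():
    cfg = SimConfig(n_subjects=4, roi_names=("x", "y", "z"), seed=1)
    ds = simulate_cohort(cfg)
    assert len(ds.truth) == 4 * 3
    assert len(ds.ts) == 4
    assert all(ts.shape == (ds.schedule.n_scans, 3) for ts in ds.ts.values())
    assert len(ds.behavior) == 4


def test_empty_roi_list_rejected():
    with pytest.raises(SimConfigError):
        SimConfig(roi_names=())


def test_time_invariant_signal_gives_equal_window_betas():
    """No habituation, no noise: every window's beta equals the amplitude.

    The analysis block model is matched to the generative stimulus duration
    (24 s) so the window GLM is exactly specified and betas are constant
    across windows at machine precision.
    """
    cfg = SimConfig(
        n_subjects=1, noise_sd=0.0, between_subject_sd=0.0, slope_diff_sd=0.0,
        slope_common_sd=0.0, motion_sd=0.0,
        hab_slope_food=0.0, hab_slope_neutral=0.0, seed=0,
    )
    ds = simulate_cohort(cfg)
    betas = cohort_betas(ds, block_model_duration_s=24.0)
    piv = betas.pivot_table(index="window", columns="condition", values="beta")
    assert np.ptp(piv["food"]) < 1e-8
    assert np.ptp(piv["neutral"]) < 1e-8
    assert piv["food"].iloc[0] == pytest.approx(1.0, abs=1e-6)
    assert piv["neutral"].iloc[0] == pytest.approx(0.6, abs=1e-6)


def test_noise_free_pipeline_recovers_generative_slope():
    """hab_slope_food −0.3, no noise → fitted interaction −0.3 ± 0.02.

    The tolerance absorbs the window/block time-grid mismatch: windows weight
    blocks unevenly (overlap, truncation) and the 25-s analysis block model
    slightly exceeds the 24 s of stimulation.
    """
    cfg = SimConfig(
        n_subjects=2, noise_sd=0.0, between_subject_sd=0.0, slope_diff_sd=0.0,
        slope_common_sd=0.0, motion_sd=0.0, seed=0,
    )
    ds = simulate_cohort(cfg)
    betas = cohort_betas(ds)
    piv = betas.pivot_table(index="window", columns="condition", values="beta")
    contrast = piv["food"] - piv["neutral"]
    mean_consecutive_diff = (contrast.iloc[-1] - contrast.iloc[0]) / (len(contrast) - 1)
    assert mean_consecutive_diff == pytest.approx(-0.3, abs=0.02)


def test_null_cohort_noise_free_interaction_exactly_zero():
    """Generative null, exactly specified window model: zero contrast everywhere."""
    cfg = SimConfig(
        n_subjects=2, noise_sd=0.0, between_subject_sd=0.0, slope_diff_sd=0.0,
        slope_common_sd=0.0, motion_sd=0.0, seed=0,
    )
    ds = simulate_null_cohort(cfg)
    betas = cohort_betas(ds, block_model_duration_s=24.0)
    piv = betas.pivot_table(index="window", columns="condition", values="beta")
    np.testing.assert_allclose(piv["food"], piv["neutral"], atol=1e-10)


def test_null_cohort_group_contrast_near_zero():
    """Full-run food-minus-neutral contrast is centred on zero under the null."""
    from cuedyn.paradigm import build_design_matrix
    from cuedyn.windowed_glm import fit_glm, group_onesample

    ds = simulate_null_cohort(SimConfig(n_subjects=20, seed=31))
    design = build_design_matrix(ds.schedule, ds.kernel)
    contrasts = []
    for s in ds.subjects:
        fit = fit_glm(ds.ts[s].iloc[:, 0].to_numpy(), design)
        contrasts.append(fit["food"] - fit["neutral"])
    res = group_onesample(np.array(contrasts))
    se = np.std(contrasts, ddof=1) / np.sqrt(len(contrasts))
    assert abs(res.mean) < 3 * se


def test_fullrun_contrast_t_is_central_under_null():
    """Across null cohorts the group t follows the central t distribution."""
    from scipy import stats

    from cuedyn.paradigm import build_design_matrix, canonical_hrf
    from cuedyn.windowed_glm import fit_glm, group_onesample

    n_subj, reps = 12, 150
    tvals = []
    design = None
    for i in range(reps):
        ds = simulate_null_cohort(SimConfig(n_subjects=n_subj, seed=7000 + i))
        if design is None:
            design = build_design_matrix(ds.schedule, ds.kernel)
        contrasts = [
            fit_glm(ds.ts[s].iloc[:, 0].to_numpy(), design)["food"]
            - fit_glm(ds.ts[s].iloc[:, 0].to_numpy(), design)["neutral"]
            for s in ds.subjects
        ]
        tvals.append(group_onesample(np.array(contrasts)).t)
    ks = stats.kstest(tvals, stats.t(df=n_subj - 1).cdf)
    assert ks.pvalue > 0.01


class TestAttachBehavior:
    slopes = pd.Series(
        np.linspace(-0.5, 0.1, 20), index=[f"sub-{i:02d}" for i in range(20)]
    )

    def test_perfect_positive_coupling(self):
        m = BehaviorMeasure("fcq_state", coupling=20.0, noise_sd=0.0,
                            intercept=40.0, lo=0.0, hi=100.0)
        beh = attach_behavior(self.slopes, [m], seed=0)
        r = np.corrcoef(self.slopes, beh["fcq_state"])[0, 1]
        assert r == pytest.approx(1.0)

    def test_perfect_negative_coupling(self):
        m = BehaviorMeasure("fcq_state", coupling=-20.0, noise_sd=0.0,
                            intercept=40.0, lo=0.0, hi=100.0)
        beh = attach_behavior(self.slopes, [m], seed=0)
        r = np.corrcoef(self.slopes, beh["fcq_state"])[0, 1]
        assert r == pytest.approx(-1.0)

    def test_zero_coupling_mean_r_near_zero(self):
        m = BehaviorMeasure("dass", coupling=0.0, noise_sd=8.0)
        rs = []
        for rep in range(200):
            beh = attach_behavior(self.slopes, [m], seed=rep)
            rs.append(np.corrcoef(self.slopes, beh["dass"])[0, 1])
        assert abs(np.mean(rs)) < 0.05

    def test_unknown_measure_rejected(self):
        m = BehaviorMeasure("mystery_scale", coupling=1.0, noise_sd=1.0)
        with pytest.raises(SimConfigError, match="unknown"):
            attach_behavior(self.slopes, [m], seed=0)

    def test_duplicate_slopes_rejected(self):
        bad = pd.Series([0.1, 0.2], index=["sub-01", "sub-01"])
        with pytest.raises(SimConfigError):
            attach_behavior(bad, [BehaviorMeasure("dass", 1.0, 1.0)], seed=0)


def test_recovery_improves_with_less_noise_and_more_subjects():
    """Estimator consistency: error shrinks as noise drops and n grows."""
    from cuedyn.dynamics_lme import fit_dynamics_lme

    def mean_abs_err(n_subjects, noise_sd, reps=8):
        errs = []
        for i in range(reps):
            cfg = SimConfig(
                n_subjects=n_subjects, noise_sd=noise_sd, slope_diff_sd=0.0,
                slope_common_sd=0.0, seed=3000 + i,
            )
            ds = simulate_cohort(cfg)
            est = fit_dynamics_lme(cohort_betas(ds)).interaction.estimate
            errs.append(abs(est + 0.3))
        return float(np.mean(errs))

    noisy = mean_abs_err(8, 1.28)
    quiet = mean_abs_err(8, 0.16)
    bigger = mean_abs_err(32, 1.28)
    assert quiet < noisy
    assert bigger < noisy
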