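"""Mixed-effects dynamics model: exact fits, coding invariance, REML oracle."""

import numpy as np
import pandas as pd
import pytest

from cuedyn.dynamics_lme import (
    LmeError,
    condition_trends,
    fit_dynamics_lme,
    scan_rois,
)
from cuedyn.simulate import SimConfig, simulate_cohort, simulate_null_cohort

from conftest import cohort_betas, deterministic_beta_table


class TestExactFit:
    def test_saturated_pattern_gives_exact_interaction(self):
        """food (1.0,.7,.4) vs neutral (.2,.2,.2): Condition:Time = -0.3 exactly."""
        table = deterministic_beta_table()
        fit = fit_dynamics_lme(table)
        assert fit.interaction.estimate == pytest.approx(-0.3, abs=1e-10)
        assert fit.degenerate and fit.boundary
        # food declines by .3/window starting above neutral: main effects follow
        assert fit.terms["time"].estimate == pytest.approx(0.0, abs=1e-10)

    def test_condition_trend_decomposition(self):
        table = deterministic_beta_table()
        trends = condition_trends(table)
        assert trends["food"].estimate == pytest.approx(-0.3, abs=1e-10)
        assert trends["neutral"].estimate == pytest.approx(0.0, abs=1e-10)

    def test_residual_df_convention(self):
        """Complete 49 x 3 x 2 table: denominator df = 294 - 5 = 289."""
        table = deterministic_beta_table(n_subjects=49, motion=None)
        fit = fit_dynamics_lme(table)
        assert fit.n_obs == 294
        assert fit.df_residual == 289
        assert fit.interaction.df == 289

    def test_reversed_condition_coding_flips_sign(self):
        table = deterministic_beta_table()
        fit = fit_dynamics_lme(table, condition_reference="food")
        assert fit.interaction.estimate == pytest.approx(+0.3, abs=1e-10)


class TestInvariances:
    def test_time_recoding_leaves_interaction_unchanged(self, small_noisy_betas):
        """Windows (1,2,3) vs (0,1,2): interaction estimate/SE/t/p identical."""
        a = fit_dynamics_lme(small_noisy_betas, time_origin=1.0)
        b = fit_dynamics_lme(small_noisy_betas, time_origin=0.0)
        assert b.interaction.estimate == pytest.approx(a.interaction.estimate, rel=1e-6)
        assert b.interaction.se == pytest.approx(a.interaction.se, rel=1e-6)
        assert b.interaction.t == pytest.approx(a.interaction.t, rel=1e-6)
        assert b.interaction.p == pytest.approx(a.interaction.p, rel=1e-6)
        # condition main effect (evaluated at time 0) must differ
        assert b.terms["condition"].estimate != pytest.approx(
            a.terms["condition"].estimate, abs=1e-12
        )

    def test_ols_limit_at_zero_random_intercept(self):
        """With the subject variance on the boundary, estimates equal pooled OLS."""
        rng = np.random.default_rng(4)
        rows = []
        for s in range(15):
            for w in range(3):
                for c in ("food", "neutral"):
                    rows.append((f"s{s}", "r", w, c, rng.normal(), 0.1 + 0.01 * s))
        table = pd.DataFrame(
            rows, columns=["subject", "roi", "window", "condition", "beta", "mean_enorm"]
        )
        fit = fit_dynamics_lme(table)
        assert fit.boundary
        time = table["window"].to_numpy(float) + 1.0
        cond = (table["condition"] == "food").astype(float).to_numpy()
        X = np.column_stack(
            [np.ones(len(table)), table["mean_enorm"], time, cond, cond * time]
        )
        ols = np.linalg.lstsq(X, table["beta"].to_numpy(), rcond=None)[0]
        got = [fit.terms[k].estimate for k in
               ("intercept", "motion", "time", "condition", "condition:time")]
        np.testing.assert_allclose(got, ols, atol=1e-6)


def _profile_reml(y, X, groups, lams):
    """Independent REML oracle: profile the variance ratio on a dense grid.

    For each lambda = var_subject / var_resid, V = I + lambda Z Z' blockwise;
    GLS estimates, the profiled sigma^2 and the restricted log-likelihood are
    evaluated in closed form.
    """
    n, p = X.shape
    best = None
    codes = pd.factorize(groups)[0]
    for lam in lams:
        Vi_blocks = []
        logdetV = 0.0
        for g in np.unique(codes):
            m = int(np.sum(codes == g))
            # (I + lam J)^-1 = I - lam/(1+lam m) J ; |I + lam J| = 1 + lam m
            Vi = np.eye(m) - (lam / (1 + lam * m)) * np.ones((m, m))
            Vi_blocks.append(Vi)
            logdetV += np.log(1 + lam * m)
        XtViX = np.zeros((p, p))
        XtViy = np.zeros(p)
        rows_by_g = [np.where(codes == g)[0] for g in np.unique(codes)]
        for Vi, idx in zip(Vi_blocks, rows_by_g):
            Xg, yg = X[idx], y[idx]
            XtViX += Xg.T @ Vi @ Xg
            XtViy += Xg.T @ Vi @ yg
        beta = np.linalg.solve(XtViX, XtViy)
        quad = 0.0
        for Vi, idx in zip(Vi_blocks, rows_by_g):
            rg = y[idx] - X[idx] @ beta
            quad += rg @ Vi @ rg
        sigma2 = quad / (n - p)
        ll = -0.5 * (
            (n - p) * np.log(sigma2) + logdetV + np.linalg.slogdet(XtViX)[1]
        )
        if best is None or ll > best[0]:
            best = (ll, lam, sigma2)
    return best  # (loglik, lambda, sigma2)


def test_reml_matches_profiled_likelihood_grid():
    """MixedLM's REML optimum agrees with a dense profiled-likelihood grid."""
    cfg = SimConfig(n_subjects=6, between_subject_sd=0.4, seed=21)
    betas = cohort_betas(simulate_cohort(cfg))
    fit = fit_dynamics_lme(betas)
    from cuedyn.dynamics_lme import _encode

    y, X, groups, _ = _encode(betas)
    lams = np.concatenate([[0.0], np.logspace(-3, 2, 400)])
    ll, lam_star, sigma2_star = _profile_reml(y, X.to_numpy(float), groups, lams)
    lam_fit = (fit.random_intercept_sd**2) / (fit.residual_sd**2)
    assert lam_fit == pytest.approx(lam_star, rel=0.1, abs=0.02)
    assert fit.residual_sd**2 == pytest.approx(sigma2_star, rel=0.05)


class TestScanRois:
    def test_habituating_rois_rank_first(self):
        """ROIs with injected habituation outrank null ROIs by interaction p."""
        hits = 0
        reps = 25
        for i in range(reps):
            cfg = SimConfig(
                n_subjects=10,
                roi_names=tuple(f"r{k}" for k in range(6)),
                hab_slope_food={f"r{k}": (-0.3 if k < 2 else 0.0) for k in range(6)},
                noise_sd=0.3, slope_diff_sd=0.0, slope_common_sd=0.0,
                seed=500 + i,
            )
            betas = cohort_betas(simulate_cohort(cfg))
            scan = scan_rois(betas)
            hits += set(scan["roi"].iloc[:2]) == {"r0", "r1"}
        assert hits >= int(0.9 * reps)

    def test_null_scan_does_not_inflate_false_positives(self):
        """Flags per all-null multi-ROI cohort stay at or below the nominal rate.

        The windowed-beta errors are positively correlated between conditions
        within a window, which makes the pooled-LME interaction test
        conservative; the defensible guarantee is an upper bound.
        """
        flags = []
        reps = 15
        for i in range(reps):
            cfg = SimConfig(n_subjects=10, roi_names=tuple(f"r{k}" for k in range(8)),
                            seed=800 + i)
            betas = cohort_betas(simulate_null_cohort(cfg))
            flags.append(scan_rois(betas, alpha=0.05)["flagged"].sum())
        n_tests = reps * 8
        upper = 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_tests)
        assert np.sum(flags) / n_tests <= upper

    def test_empty_table_gives_empty_result(self):
        out = scan_rois(pd.DataFrame(columns=["subject", "roi", "window",
                                              "condition", "beta", "mean_enorm"]))
        assert out.empty

    def test_failures_recorded_not_raised(self):
        # one ROI has a single window: unfittable, but the scan continues
        good = deterministic_beta_table(roi="ok")
        bad = deterministic_beta_table(roi="bad").query("window == 0")
        out = scan_rois(pd.concat([good, bad]))
        assert set(out["roi"]) == {"ok", "bad"}
        bad_row = out[out["roi"] == "bad"].iloc[0]
        assert bad_row["error"] != ""
        assert not bad_row["flagged"]


class TestConditionTrends:
    def test_opposite_trends_recovered(self):
        """Declining food with rising neutral: both signs recovered at good SNR."""
        correct = 0
        reps = 20
        for i in range(reps):
            cfg = SimConfig(
                n_subjects=10, hab_slope_food=-0.3, hab_slope_neutral=0.15,
                noise_sd=0.3, slope_diff_sd=0.0, slope_common_sd=0.0, seed=1500 + i,
            )
            betas = cohort_betas(simulate_cohort(cfg))
            trends = condition_trends(betas)
            correct += (trends["food"].estimate < 0) and (trends["neutral"].estimate > 0)
        assert correct >= int(0.9 * reps)

    def test_single_window_rejected(self):
        table = deterministic_beta_table().query("window == 1")
        with pytest.raises(LmeError):
            condition_trends(table)


class TestPreconditions:
    def test_single_subject_rejected(self):
        table = deterministic_beta_table(n_subjects=1)
        with pytest.raises(LmeError):
            fit_dynamics_lme(table)

    def test_single_condition_rejected(self):
        table = deterministic_beta_table().query("condition == 'food'")
        with pytest.raises(LmeError):
            fit_dynamics_lme(table)

    def test_missing_betas_dropped_not_fatal(self):
        table = deterministic_beta_table(n_subjects=6, motion=None)
        table.loc[table.index[:4], "beta"] = np.nan
        fit = fit_dynamics_lme(table)
        assert fit.n_obs == len(table) - 4
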