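"""Mixed-effects temporal-dynamics models on windowed betas.

For each ROI the model is

    beta ~ Condition * Time + Motion + (1 | Subject)

with Time the numeric window index, Condition an indicator (food = 1 by
default, so a *negative* Condition:Time coefficient means the food response
declines relative to neutral — habituation), and Motion the subject's mean
frame-to-frame displacement.  Fitting is REML via statsmodels MixedLM;
fixed-effect tests use the residual degrees-of-freedom convention
(n observations minus number of fixed coefficients).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

INTERACTION = "condition:time"
FIXED_TERMS = ("intercept", "motion", "time", "condition", INTERACTION)


class LmeError(ValueError):
    """Mixed-model input or estimation failure."""


@dataclass(frozen=True)
class TermStats:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class LmeFit:
    """Fixed-effect table plus variance components for one ROI's model."""

    terms: dict[str, TermStats]
    random_intercept_sd: float
    residual_sd: float
    n_obs: int
    df_residual: int
    coding: dict = field(default_factory=dict)
    boundary: bool = False
    degenerate: bool = False
    converged: bool = True

    @property
    def interaction(self) -> TermStats:
        return self.terms[INTERACTION]


def _encode(
    table: pd.DataFrame,
    condition_reference: str = "neutral",
    time_origin: float = 1.0,
    include_motion: bool = True,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray, dict]:
    """Design columns for the dynamics model from a long beta table.

    Windows are coded numerically as ``window + time_origin`` (index 0 maps
    to time 1 by default); the condition indicator is 1 for the non-reference
    level (reference "neutral" means food = 1).
    """
    required = {"subject", "window", "condition", "beta"}
    missing = required - set(table.columns)
    if missing:
        raise LmeError(f"beta table missing columns: {sorted(missing)}")
    data = table.dropna(subset=["beta"]).copy()
    n_dropped = len(table) - len(data)
    if n_dropped:
        logger.info("dropped %d rows with missing betas", n_dropped)
    if data.empty:
        raise LmeError("no usable rows in beta table")
    if data["subject"].nunique() < 2:
        raise LmeError("need at least 2 subjects")
    if data["window"].nunique() < 2:
        raise LmeError("need at least 2 windows (time points)")
    conds = set(data["condition"].unique())
    if len(conds) < 2:
        raise LmeError("need both conditions")
    if condition_reference not in conds:
        raise LmeError(f"condition reference {condition_reference!r} not present")

    time = data["window"].to_numpy(dtype=float) + time_origin
    cond = (data["condition"] != condition_reference).astype(float).to_numpy()
    X = pd.DataFrame({"intercept": np.ones(len(data))})
    if include_motion and "mean_enorm" in data.columns:
        motion = data["mean_enorm"].to_numpy(dtype=float)
        if np.ptp(motion) > 0:
            X["motion"] = motion
        else:
            logger.info("motion covariate is constant; dropped as collinear with intercept")
    X["time"] = time
    X["condition"] = cond
    X[INTERACTION] = cond * time
    y = data["beta"].to_numpy(dtype=float)
    coding = {
        "condition_reference": condition_reference,
        "condition_level_1": sorted(conds - {condition_reference})[0],
        "time_origin": time_origin,
        "motion_included": "motion" in X.columns,
    }
    return y, X, data["subject"].to_numpy(), coding


def _term_table(
    names: list[str], est: np.ndarray, se: np.ndarray, df: float
) -> dict[str, TermStats]:
    terms = {}
    tcrit = stats.t.ppf(0.975, df) if df > 0 else np.nan
    for name, b, s in zip(names, est, se):
        if s > 0:
            t = b / s
            p = 2 * stats.t.sf(abs(t), df)
            ci = (b - tcrit * s, b + tcrit * s)
        else:
            t, p, ci = np.nan, np.nan, (b, b)
        terms[name] = TermStats(
            estimate=float(b), se=float(s), ci_low=float(ci[0]), ci_high=float(ci[1]),
            t=float(t), df=float(df), p=float(p),
        )
    return terms


def fit_dynamics_lme(
    table: pd.DataFrame,
    condition_reference: str = "neutral",
    time_origin: float = 1.0,
    include_motion: bool = True,
) -> LmeFit:
    """REML fit of beta ~ Condition*Time + Motion with a subject random intercept.

    Degenerate inputs (zero residual variation, as in exactly linear synthetic
    tables) short-circuit to the pooled OLS solution with ``degenerate=True``;
    a random-intercept variance estimated at the zero boundary sets
    ``boundary=True`` (a flag, not a failure).
    """
    y, X, groups, coding = _encode(table, condition_reference, time_origin, include_motion)
    n, p = X.shape
    df_resid = n - p
    Xv = X.to_numpy(dtype=float)

    # Exact-fit guard: with zero residual variance REML is on the boundary and
    # the optimiser has nothing to estimate; the OLS solution is exact.
    coef, rss_arr, rank, _ = np.linalg.lstsq(Xv, y, rcond=None)
    rss = float(rss_arr[0]) if rss_arr.size else float(np.sum((y - Xv @ coef) ** 2))
    scale_y = float(np.var(y)) + 1.0
    if rss <= 1e-12 * n * scale_y:
        logger.info("zero residual variance; returning exact OLS solution")
        terms = _term_table(list(X.columns), coef, np.zeros(p), df_resid)
        return LmeFit(
            terms=terms, random_intercept_sd=0.0, residual_sd=0.0,
            n_obs=n, df_residual=df_resid, coding=coding,
            boundary=True, degenerate=True,
        )

    model = sm.MixedLM(y, Xv, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        result = model.fit(reml=True)
    converged = bool(getattr(result, "converged", True))
    var_re = float(np.asarray(result.cov_re)[0, 0])
    scale = float(result.scale)
    # A variance ratio this small is the zero boundary: truncate it to exactly
    # 0, where GLS reduces to pooled OLS.
    boundary = var_re <= 1e-4 * (var_re + scale)
    if boundary:
        est = coef
        sigma2 = rss / df_resid
        se = np.sqrt(sigma2 * np.diag(np.linalg.inv(Xv.T @ Xv)))
        var_re = 0.0
        scale = sigma2
    else:
        est = np.asarray(result.fe_params, dtype=float)
        se = np.asarray(result.bse_fe, dtype=float)
    terms = _term_table(list(X.columns), est, se, df_resid)
    return LmeFit(
        terms=terms,
        random_intercept_sd=float(np.sqrt(max(var_re, 0.0))),
        residual_sd=float(np.sqrt(scale)),
        n_obs=n,
        df_residual=df_resid,
        coding=coding,
        boundary=boundary,
        converged=converged,
    )


def scan_rois(
    table: pd.DataFrame,
    alpha: float = 0.05,
    condition_reference: str = "neutral",
    time_origin: float = 1.0,
    include_motion: bool = True,
) -> pd.DataFrame:
    """Fit the dynamics model independently per ROI and flag interactions.

    No multiplicity correction is applied (the regional scan is exploratory
    by design); rows are sorted by interaction p-value.  Per-ROI failures
    are recorded in the ``error`` column and the scan continues.
    """
    if table.empty:
        return pd.DataFrame(
            columns=["roi", "estimate", "se", "t", "df", "p", "flagged", "boundary", "error"]
        )
    rows = []
    for roi, sub in table.groupby("roi", sort=True):
        row: dict = {"roi": roi}
        try:
            fit = fit_dynamics_lme(
                sub, condition_reference=condition_reference,
                time_origin=time_origin, include_motion=include_motion,
            )
            ix = fit.interaction
            row.update(
                estimate=ix.estimate, se=ix.se, t=ix.t, df=ix.df, p=ix.p,
                flagged=bool(np.isfinite(ix.p) and ix.p < alpha),
                boundary=fit.boundary, error="",
            )
        except Exception as exc:  # scan continues past per-ROI failures
            logger.warning("ROI %s: %s", roi, exc)
            row.update(
                estimate=np.nan, se=np.nan, t=np.nan, df=np.nan, p=np.nan,
                flagged=False, boundary=False, error=str(exc),
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values("p", na_position="last").reset_index(drop=True)


def condition_trends(
    table: pd.DataFrame,
    time_origin: float = 1.0,
) -> dict[str, TermStats]:
    """Per-condition time slope (beta on window index), random intercept kept.

    Decomposes a condition-by-time interaction: each condition's rows are fit
    with beta ~ Time + (1 | Subject) separately.
    """
    data = table.dropna(subset=["beta"])
    if data["window"].nunique() < 2:
        raise LmeError("need at least 2 windows to estimate a time slope")
    out: dict[str, TermStats] = {}
    for cond, sub in data.groupby("condition", sort=True):
        if sub["window"].nunique() < 2:
            raise LmeError(f"condition {cond!r} has a single window")
        y = sub["beta"].to_numpy(dtype=float)
        time = sub["window"].to_numpy(dtype=float) + time_origin
        X = np.column_stack([np.ones(len(sub)), time])
        df_resid = len(sub) - 2
        coef, rss_arr, _, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(rss_arr[0]) if rss_arr.size else float(np.sum((y - X @ coef) ** 2))
        if rss <= 1e-12 * len(sub) * (float(np.var(y)) + 1.0):
            out[str(cond)] = _term_table(["intercept", "time"], coef, np.zeros(2), df_resid)["time"]
            continue
        model = sm.MixedLM(y, X, groups=sub["subject"].to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            result = model.fit(reml=True)
        est = np.asarray(result.fe_params, dtype=float)
        se = np.asarray(result.bse_fe, dtype=float)
        out[str(cond)] = _term_table(["intercept", "time"], est, se, df_resid)["time"]
    return out


def lme_results_table(fits: dict[str, LmeFit], alpha: float = 0.05) -> pd.DataFrame:
    """Long-format results (one row per ROI x term) for TSV export."""
    rows = []
    for roi, fit in fits.items():
        for term, ts in fit.terms.items():
            rows.append(
                {
                    "roi": roi, "term": term, "estimate": ts.estimate, "se": ts.se,
                    "ci_low": ts.ci_low, "ci_high": ts.ci_high, "t": ts.t,
                    "df": ts.df, "p": ts.p,
                    "flagged": bool(
                        term == INTERACTION and np.isfinite(ts.p) and ts.p < alpha
                    ),
                }
            )
        rows.append(
            {
                "roi": roi, "term": "random_intercept_sd", "estimate": fit.random_intercept_sd,
                "se": np.nan, "ci_low": np.nan, "ci_high": np.nan, "t": np.nan,
                "df": np.nan, "p": np.nan, "flagged": False,
            }
        )
    return pd.DataFrame(rows)
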