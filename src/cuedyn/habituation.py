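"""Per-subject habituation slopes and their behavioral correlates.

A subject's habituation slope is the Condition:Time coefficient of an
ordinary least-squares fit of that subject's windowed betas on

    beta ~ Condition + Time + Condition:Time

with the same coding as the group dynamics model (food = 1 by default).
Negative slopes mean the food response declines across windows relative to
the neutral response.  Slopes are related to questionnaire and visual-analog
ratings with Pearson correlations, and pre/post rating changes are tested
with Welch's t-test (fractional Welch-Satterthwaite df); a paired mode is
also provided and is the statistically preferable choice for within-subject
pre/post designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class BehaviorError(ValueError):
    """Invalid input to the habituation/behavior stage."""


@dataclass(frozen=True)
class SlopeRecord:
    subject: str
    roi: str
    slope: float
    condition_effect: float
    time_effect: float
    intercept: float


def subject_habituation_slope(
    records: pd.DataFrame,
    condition_reference: str = "neutral",
    time_origin: float = 1.0,
) -> SlopeRecord | None:
    """OLS habituation slope for one subject's betas in one ROI.

    Returns None (with a log line) when fewer than two windows or only one
    condition survive missing-beta removal.
    """
    data = records.dropna(subset=["beta"])
    subject = str(records["subject"].iloc[0]) if len(records) else "?"
    roi = str(records["roi"].iloc[0]) if "roi" in records.columns and len(records) else ""
    if data.empty or data["window"].nunique() < 2 or data["condition"].nunique() < 2:
        logger.info("subject %s roi %s: insufficient rows for a slope; skipped", subject, roi)
        return None
    time = data["window"].to_numpy(dtype=float) + time_origin
    cond = (data["condition"] != condition_reference).astype(float).to_numpy()
    X = np.column_stack([np.ones(len(data)), cond, time, cond * time])
    y = data["beta"].to_numpy(dtype=float)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 4:
        logger.info("subject %s roi %s: rank-deficient slope fit; skipped", subject, roi)
        return None
    return SlopeRecord(
        subject=subject, roi=roi, slope=float(coef[3]),
        condition_effect=float(coef[1]), time_effect=float(coef[2]),
        intercept=float(coef[0]),
    )


def habituation_slopes(
    table: pd.DataFrame,
    condition_reference: str = "neutral",
    time_origin: float = 1.0,
) -> pd.DataFrame:
    """Habituation slopes for every subject x ROI in a beta table."""
    rows = []
    for (subject, roi), sub in table.groupby(["subject", "roi"], sort=True):
        rec = subject_habituation_slope(sub, condition_reference, time_origin)
        if rec is not None:
            rows.append({"subject": subject, "roi": roi, "slope": rec.slope})
    return pd.DataFrame(rows, columns=["subject", "roi", "slope"])


@dataclass(frozen=True)
class CorrelationResult:
    roi: str
    measure: str
    r: float
    p: float
    n: int
    degenerate: bool = False


def slope_behavior_correlation(
    slopes: pd.DataFrame,
    behavior: pd.DataFrame,
    measures: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlations between per-subject slopes and behavioral measures.

    Pairwise-complete: each ROI x measure correlation uses subjects with both
    values present.  Raw two-sided p-values; no multiplicity correction (the
    screen is exploratory), though ``bh_adjust`` can be applied downstream.
    """
    if measures is None:
        measures = [c for c in behavior.columns if c != "subject"]
    unknown = [m for m in measures if m not in behavior.columns]
    if unknown:
        raise BehaviorError(f"measures not in behavior table: {unknown}")
    beh = behavior.set_index("subject")
    rows = []
    for roi, sub in slopes.groupby("roi", sort=True):
        s = sub.set_index("subject")["slope"]
        for measure in measures:
            joined = pd.concat([s, beh[measure]], axis=1, join="inner").dropna()
            n = len(joined)
            if n < 3:
                raise BehaviorError(
                    f"fewer than 3 complete pairs for roi={roi!r}, measure={measure!r}"
                )
            x = joined.iloc[:, 0].to_numpy(dtype=float)
            yv = joined.iloc[:, 1].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(yv) == 0:
                logger.warning("zero variance in %s/%s; correlation undefined", roi, measure)
                rows.append(
                    {"roi": roi, "measure": measure, "r": np.nan, "p": np.nan,
                     "n": n, "degenerate": True}
                )
                continue
            res = stats.pearsonr(x, yv)
            rows.append(
                {"roi": roi, "measure": measure, "r": float(res.statistic),
                 "p": float(res.pvalue), "n": n, "degenerate": False}
            )
    return pd.DataFrame(rows, columns=["roi", "measure", "r", "p", "n", "degenerate"])


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional, off by default upstream)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@dataclass(frozen=True)
class PrePostResult:
    t: float
    df: float
    p: float
    direction: int  # sign of mean(post) - mean(pre)
    mean_pre: float
    mean_post: float
    paired: bool = False
    degenerate: bool = False


def pre_post_test(
    pre: np.ndarray | pd.Series,
    post: np.ndarray | pd.Series,
    paired: bool = False,
) -> PrePostResult:
    """Pre- vs post-task comparison of a rating.

    Default is Welch's unpaired t-test on (pre, post) — an increase therefore
    yields a *negative* t — with fractional Welch-Satterthwaite df.  For a
    within-subject design the paired mode is the better-powered, better-
    calibrated test and should normally be preferred; the unpaired default
    exists for comparability with analyses that treated the two rating
    occasions as independent samples.
    """
    x = np.asarray(pre, dtype=float)
    y = np.asarray(post, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise BehaviorError("need at least 2 observations per sample")
    direction = int(np.sign(y.mean() - x.mean()))
    if paired:
        if x.size != y.size:
            raise BehaviorError("paired test requires equal-length samples")
        d = x - y
        if np.std(d, ddof=1) == 0:
            return PrePostResult(
                t=0.0 if d.mean() == 0 else np.inf * np.sign(-d.mean()),
                df=float(x.size - 1), p=1.0 if d.mean() == 0 else 0.0,
                direction=direction, mean_pre=float(x.mean()),
                mean_post=float(y.mean()), paired=True, degenerate=True,
            )
        res = stats.ttest_rel(x, y)
        return PrePostResult(
            t=float(res.statistic), df=float(x.size - 1), p=float(res.pvalue),
            direction=direction, mean_pre=float(x.mean()), mean_post=float(y.mean()),
            paired=True,
        )
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx == 0 and vy == 0:
        return PrePostResult(
            t=0.0 if direction == 0 else np.inf * -direction,
            df=float(x.size + y.size - 2), p=1.0 if direction == 0 else 0.0,
            direction=direction, mean_pre=float(x.mean()), mean_post=float(y.mean()),
            degenerate=True,
        )
    res = stats.ttest_ind(x, y, equal_var=False)
    # Welch-Satterthwaite df, kept fractional
    a, b = vx / x.size, vy / y.size
    df = (a + b) ** 2 / (a**2 / (x.size - 1) + b**2 / (y.size - 1))
    return PrePostResult(
        t=float(res.statistic), df=float(df), p=float(res.pvalue),
        direction=direction, mean_pre=float(x.mean()), mean_post=float(y.mean()),
    )


def behavior_pre_post_tests(
    behavior: pd.DataFrame,
    pre_suffix: str = "_pre",
    post_suffix: str = "_post",
    paired: bool = False,
) -> pd.DataFrame:
    """Run pre/post tests for every measure pair sharing a stem."""
    stems = sorted(
        c[: -len(pre_suffix)]
        for c in behavior.columns
        if c.endswith(pre_suffix) and (c[: -len(pre_suffix)] + post_suffix) in behavior.columns
    )
    rows = []
    for stem in stems:
        res = pre_post_test(
            behavior[stem + pre_suffix], behavior[stem + post_suffix], paired=paired
        )
        rows.append(
            {"measure": stem, "t": res.t, "df": res.df, "p": res.p,
             "direction": res.direction, "mean_pre": res.mean_pre,
             "mean_post": res.mean_post}
        )
    return pd.DataFrame(rows, columns=["measure", "t", "df", "p", "direction", "mean_pre", "mean_post"])
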