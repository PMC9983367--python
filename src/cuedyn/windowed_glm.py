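"""Sliding-window GLM: window geometry, per-window OLS betas, contrasts.

The run is divided into overlapping temporal windows (default 198 s long,
103 s apart, the spacing that yields three windows over a ~6 min run).
Within each window the condition regressors are the full-run HRF-convolved
regressors *sliced* to the window — so hemodynamic spill-over from a block
just before the window boundary is kept — while intercept and drift are
re-estimated inside the window.  The per-window food and neutral betas form
the long-format table consumed by the mixed-effects dynamics stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .paradigm import (
    CONDITIONS,
    DesignMatrix,
    EventSchedule,
    HrfKernel,
    ParadigmError,
    censor_scans,
    condition_regressor,
    motion_enorm,
)

logger = logging.getLogger(__name__)

BETA_COLUMNS = ["subject", "roi", "window", "condition", "beta", "mean_enorm"]


class GlmError(ValueError):
    """Estimation failure in the windowed GLM stage."""


@dataclass(frozen=True)
class WindowSpec:
    length_s: float = 198.0
    step_s: float = 103.0
    min_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.length_s <= 0 or self.step_s <= 0:
            raise ParadigmError("window length and step must be positive")
        if not (0 < self.min_fraction <= 1):
            raise ParadigmError("min_fraction must be in (0, 1]")


@dataclass(frozen=True)
class Window:
    index: int
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def make_windows(run_duration_s: float, spec: WindowSpec | None = None) -> list[Window]:
    """Enumerate windows starting at 0, step, 2*step, ... truncated at run end.

    A candidate window that retains less than ``min_fraction`` of the nominal
    length after truncation is dropped; indices are consecutive from 0.
    """
    if run_duration_s <= 0:
        raise ParadigmError("run_duration_s must be positive")
    spec = spec or WindowSpec()
    windows: list[Window] = []
    k = 0
    while True:
        start = k * spec.step_s
        if start >= run_duration_s:
            break
        end = min(start + spec.length_s, run_duration_s)
        if end - start >= spec.min_fraction * spec.length_s:
            windows.append(Window(index=len(windows), start_s=start, end_s=end))
        k += 1
    return windows


@dataclass(frozen=True)
class GlmFit:
    """OLS fit of one ROI series against a named design."""

    coefficients: dict[str, float]
    residual_variance: float
    df: int
    n_scans_used: int
    rank: int

    def __getitem__(self, name: str) -> float:
        return self.coefficients[name]


def fit_glm(ts: np.ndarray, design: DesignMatrix) -> GlmFit:
    """Ordinary least squares of one time series on a design matrix.

    Censored scans (mask False) are dropped from both sides.  Rank-deficient
    designs fall back to the minimum-norm solution with a logged warning.
    """
    y = np.asarray(ts, dtype=float)
    if y.shape[0] != design.n_scans:
        raise GlmError(f"series has {y.shape[0]} scans, design has {design.n_scans}")
    keep = design.censor_mask
    y = y[keep]
    X = design.values()[keep]
    if y.size == 0:
        raise GlmError("all scans censored; nothing to fit")
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        logger.warning(
            "rank-deficient design (rank %d < %d columns); minimum-norm solution used",
            rank, X.shape[1],
        )
    resid = y - X @ coef
    df = int(y.size - rank)
    resid_var = float(resid @ resid / df) if df > 0 else 0.0
    return GlmFit(
        coefficients=dict(zip(design.columns, coef.tolist())),
        residual_variance=resid_var,
        df=df,
        n_scans_used=int(y.size),
        rank=int(rank),
    )


def _window_design(
    full_design: DesignMatrix,
    window: Window,
    tr_s: float,
) -> tuple[np.ndarray, DesignMatrix]:
    """Scan indices for a window plus the window design with refit nuisance.

    A scan at start time t belongs to the window iff start <= t < end
    (half-open, so boundary scans are not double-counted).  Condition and
    motion columns are sliced from the full-run design; intercept and drift
    are rebuilt inside the window so slow trends are removed per-window.
    """
    scan_times = np.arange(full_design.n_scans) * tr_s
    idx = np.where((scan_times >= window.start_s) & (scan_times < window.end_s))[0]
    sub = full_design.frame.iloc[idx].reset_index(drop=True)
    n = len(sub)
    drift_cols = [c for c in sub.columns if c.startswith("drift_")]
    sub["intercept"] = np.ones(n)
    if drift_cols:
        u = np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n)
        for c in drift_cols:
            k = int(c.split("_")[1])
            sub[c] = u**k
    wdesign = DesignMatrix(
        frame=sub, tr_s=tr_s, censor_mask=full_design.censor_mask[idx]
    )
    return idx, wdesign


def window_betas(
    ts_by_subject: dict[str, pd.DataFrame],
    schedule: EventSchedule,
    kernel: HrfKernel,
    windows: list[Window],
    motion_by_subject: dict[str, np.ndarray] | None = None,
    psc: bool = False,
    drift_order: int = 1,
    block_model_duration_s: float = 25.0,
    censor_threshold_mm: float | None = 3.0,
) -> pd.DataFrame:
    """Per-subject, per-ROI, per-window condition betas (the beta table).

    ``ts_by_subject`` maps subject id -> DataFrame (rows scans, columns ROI
    names).  All subjects share the stimulus schedule (the task used one
    fixed pseudo-random order for everyone).  Returns a long-format frame
    with columns subject, roi, window, condition, beta, mean_enorm.

    With ``psc`` the betas are rescaled to percent of the window's intercept
    estimate; a window whose regressor carries no block of a condition yields
    a missing (NaN) beta with a logged warning.
    """
    from .paradigm import build_design_matrix

    records: list[tuple] = []
    for subject in sorted(ts_by_subject):
        ts = ts_by_subject[subject]
        motion = None if motion_by_subject is None else motion_by_subject.get(subject)
        n_scans = len(ts)
        design = build_design_matrix(
            schedule,
            kernel,
            motion=motion,
            drift_order=drift_order,
            n_scans=n_scans,
            block_model_duration_s=block_model_duration_s,
        )
        if motion is not None:
            enorm = motion_enorm(motion).mean_enorm
            if censor_threshold_mm is not None:
                design.censor_mask = censor_scans(motion, censor_threshold_mm)
        else:
            enorm = 0.0
        for window in windows:
            idx, wdesign = _window_design(design, window, schedule.tr_s)
            # A beta is meaningful only if a block of that condition actually
            # overlaps the window (HRF tail alone does not count).
            active = {
                cond: any(
                    b.onset_s < window.end_s and b.end_s > window.start_s
                    for b in schedule.condition_blocks(cond)
                )
                for cond in CONDITIONS
            }
            for roi in ts.columns:
                fit = fit_glm(ts[roi].to_numpy()[idx], wdesign)
                baseline = fit.coefficients.get("intercept", np.nan)
                for cond in CONDITIONS:
                    if not active[cond]:
                        logger.warning(
                            "subject %s window %d has no %s signal; beta recorded as missing",
                            subject, window.index, cond,
                        )
                        beta = np.nan
                    else:
                        beta = fit.coefficients[cond]
                        if psc:
                            beta = beta / baseline * 100.0
                    records.append((subject, str(roi), window.index, cond, beta, enorm))
    return pd.DataFrame(records, columns=BETA_COLUMNS)


def food_minus_neutral(table: pd.DataFrame, per_window: bool = True) -> pd.DataFrame:
    """Food-minus-neutral contrast per subject (and per window, or averaged).

    Missing betas propagate to missing contrasts.
    """
    wide = table.pivot_table(
        index=["subject", "roi", "window"], columns="condition", values="beta",
        dropna=False,
    )
    for cond in CONDITIONS:
        if cond not in wide.columns:
            raise GlmError(f"condition {cond!r} missing from beta table")
    wide["contrast"] = wide["food"] - wide["neutral"]
    out = wide.reset_index()[["subject", "roi", "window", "contrast"]]
    if per_window:
        return out
    return (
        out.groupby(["subject", "roi"], as_index=False)["contrast"].mean()
    )


@dataclass(frozen=True)
class OneSampleResult:
    t: float
    df: int
    p: float
    mean: float
    degenerate: bool = False


def group_onesample(contrasts: np.ndarray | pd.Series) -> OneSampleResult:
    """One-sample t-test of per-subject contrasts against zero.

    A simplification of precision-weighted group mixed-effects modelling:
    at ROI level each subject contributes one contrast value.
    """
    x = np.asarray(contrasts, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise GlmError("need at least 2 subjects for a group test")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        # all values identical: direction is the only information left
        return OneSampleResult(
            t=np.inf * np.sign(mean) if mean != 0 else 0.0,
            df=n - 1,
            p=0.0 if mean != 0 else 1.0,
            mean=mean,
            degenerate=True,
        )
    res = stats.ttest_1samp(x, 0.0)
    return OneSampleResult(
        t=float(res.statistic), df=n - 1, p=float(res.pvalue), mean=mean
    )
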