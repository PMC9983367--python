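"""Block-design paradigm: stimulus schedules, HRF kernels, design matrices.

The cue-reactivity task alternates short blocks of reward-associated (food)
and neutral pictures.  Everything downstream — the simulator, the windowed
GLM and the mixed-effects dynamics models — shares the schedule and the
HRF-convolved regressors built here.

Conventions: onsets are seconds from run start, scan indices are 0-based,
and the scan grid is anchored at scan *start* times (scan i sits at
``i * tr_s``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FOOD = "food"
NEUTRAL = "neutral"
CONDITIONS = (FOOD, NEUTRAL)


class ParadigmError(ValueError):
    """Invalid schedule or design-matrix construction."""


@dataclass(frozen=True)
class Block:
    onset_s: float
    duration_s: float
    condition: str

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s

    @property
    def center_s(self) -> float:
        return self.onset_s + 0.5 * self.duration_s


@dataclass(frozen=True)
class EventSchedule:
    """Ordered, non-overlapping stimulus blocks for one run.

    ``run_duration_s`` ends at the last block offset; there is no trailing
    rest period unless the caller extends it explicitly.
    """

    blocks: tuple[Block, ...]
    run_duration_s: float
    tr_s: float = 2.5
    stimuli_per_block: int = 6
    stimulus_duration_s: float = 4.0

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ParadigmError(f"tr_s must be positive, got {self.tr_s}")
        prev_end = 0.0
        for i, b in enumerate(self.blocks):
            if b.condition not in CONDITIONS:
                raise ParadigmError(f"block {i}: unknown condition {b.condition!r}")
            if b.onset_s < 0 or b.duration_s < 0:
                raise ParadigmError(f"block {i}: negative onset or duration")
            if b.onset_s < prev_end - 1e-9:
                raise ParadigmError(
                    f"block {i} at {b.onset_s:g}s overlaps previous block ending {prev_end:g}s"
                )
            if b.end_s > self.run_duration_s + 1e-9:
                raise ParadigmError(f"block {i} extends past run end {self.run_duration_s:g}s")
            prev_end = b.end_s

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_stimuli(self) -> int:
        return self.n_blocks * self.stimuli_per_block

    @property
    def n_scans(self) -> int:
        return int(math.floor(self.run_duration_s / self.tr_s))

    def condition_blocks(self, condition: str) -> tuple[Block, ...]:
        return tuple(b for b in self.blocks if b.condition == condition)

    def condition_counts(self) -> dict[str, int]:
        return {c: len(self.condition_blocks(c)) for c in CONDITIONS}

    def with_tr(self, tr_s: float) -> "EventSchedule":
        return replace(self, tr_s=tr_s)

    def to_frame(self) -> pd.DataFrame:
        """BIDS-style events table (one row per block)."""
        return pd.DataFrame(
            {
                "onset": [b.onset_s for b in self.blocks],
                "duration": [b.duration_s for b in self.blocks],
                "trial_type": [b.condition for b in self.blocks],
            }
        )


def build_schedule(
    n_blocks_per_condition: int = 6,
    stimuli_per_block: int = 6,
    stimulus_duration_s: float = 4.0,
    ibi_range_s: tuple[float, float] = (8.0, 12.0),
    order: str | list[str] = "alternating",
    seed: int = 0,
    tr_s: float = 2.5,
) -> EventSchedule:
    """Build a block schedule with inter-block intervals drawn uniformly.

    With the defaults this reproduces the task structure: 12 blocks of six
    4-s pictures (6 food, 6 neutral, strictly alternating starting with
    food), separated by 8-12 s rest intervals.  The run ends at the offset
    of the final block, so its exact length depends on the sampled gaps.
    """
    if n_blocks_per_condition < 0 or stimuli_per_block < 0:
        raise ParadigmError("block and stimulus counts must be non-negative")
    if stimulus_duration_s < 0:
        raise ParadigmError("stimulus_duration_s must be non-negative")
    low, high = ibi_range_s
    if low > high or low < 0:
        raise ParadigmError(f"invalid inter-block interval range {ibi_range_s}")

    n_total = 2 * n_blocks_per_condition
    if isinstance(order, str):
        if order != "alternating":
            raise ParadigmError(f"unknown order {order!r}")
        conditions = [CONDITIONS[i % 2] for i in range(n_total)]
    else:
        conditions = list(order)
        if len(conditions) != n_total:
            raise ParadigmError(
                f"custom order has {len(conditions)} entries, schedule needs {n_total}"
            )
        for c in conditions:
            if c not in CONDITIONS:
                raise ParadigmError(f"unknown condition {c!r} in custom order")

    block_dur = stimuli_per_block * stimulus_duration_s
    rng = np.random.default_rng(seed)
    gaps = rng.uniform(low, high, size=max(n_total - 1, 0))

    blocks = []
    t = 0.0
    for i, cond in enumerate(conditions):
        blocks.append(Block(onset_s=t, duration_s=block_dur, condition=cond))
        t += block_dur
        if i < n_total - 1:
            t += float(gaps[i])
    return EventSchedule(
        blocks=tuple(blocks),
        run_duration_s=t,
        tr_s=tr_s,
        stimuli_per_block=stimuli_per_block,
        stimulus_duration_s=stimulus_duration_s,
    )


# ---------------------------------------------------------------------------
# Hemodynamic response function
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HrfParams:
    """Double-gamma HRF parameters.

    Each lobe is ``t**(delay/dispersion) * exp(-t/dispersion)`` peak-normalised,
    so its mode falls exactly at the delay parameter (in seconds); the
    undershoot lobe is subtracted scaled by ``undershoot_ratio``.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length_s: float = 32.0


@dataclass(frozen=True)
class HrfKernel:
    dt_s: float
    values: np.ndarray
    params: HrfParams

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ParadigmError(f"dt_s must be positive, got {self.dt_s}")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt_s


def _gamma_lobe(t: np.ndarray, delay: float, dispersion: float) -> np.ndarray:
    # t**a * exp(-t/b) with a*b = delay has its mode at t = delay.
    a = delay / dispersion
    with np.errstate(divide="ignore", invalid="ignore"):
        logv = a * np.log(np.where(t > 0, t, np.nan)) - t / dispersion
    peak_log = a * np.log(delay) - delay / dispersion
    v = np.exp(logv - peak_log)
    return np.nan_to_num(v, nan=0.0)


def canonical_hrf(dt_s: float = 0.1, params: HrfParams | None = None) -> HrfKernel:
    """Sample the canonical double-gamma HRF, scaled to peak amplitude 1."""
    if dt_s <= 0:
        raise ParadigmError(f"dt_s must be positive, got {dt_s}")
    p = params or HrfParams()
    t = np.arange(0.0, p.length_s + dt_s / 2, dt_s)
    v = _gamma_lobe(t, p.peak_delay_s, p.peak_dispersion_s)
    v = v - p.undershoot_ratio * _gamma_lobe(t, p.undershoot_delay_s, p.undershoot_dispersion_s)
    v = v / np.max(v)
    return HrfKernel(dt_s=dt_s, values=v, params=p)


# ---------------------------------------------------------------------------
# Regressors and design matrices
# ---------------------------------------------------------------------------

def _fine_grid_signal(
    onsets: np.ndarray,
    duration_s: float,
    amplitudes: np.ndarray,
    run_duration_s: float,
    kernel: HrfKernel,
) -> tuple[np.ndarray, np.ndarray]:
    """Convolve per-onset boxcars (with per-onset amplitudes) on the kernel grid."""
    dt = kernel.dt_s
    n_fine = int(np.ceil(run_duration_s / dt)) + len(kernel.values) + 1
    box = np.zeros(n_fine)
    for onset, amp in zip(onsets, amplitudes):
        i0 = int(round(onset / dt))
        i1 = int(round((onset + duration_s) / dt))
        box[i0:i1] += amp
    conv = np.convolve(box, kernel.values)[:n_fine] * dt
    t_fine = np.arange(n_fine) * dt
    return t_fine, conv


def sample_at_scans(t_fine: np.ndarray, values: np.ndarray, tr_s: float, n_scans: int) -> np.ndarray:
    scan_times = np.arange(n_scans) * tr_s
    return np.interp(scan_times, t_fine, values)


def condition_regressor(
    schedule: EventSchedule,
    condition: str,
    kernel: HrfKernel,
    n_scans: int | None = None,
    block_model_duration_s: float = 25.0,
    amplitudes: np.ndarray | None = None,
) -> np.ndarray:
    """HRF-convolved block regressor for one condition, sampled at the TR grid.

    Each block is modelled as a ``block_model_duration_s`` boxcar at its onset
    (the conventional sustained-response block model; the default 25 s slightly
    exceeds the 24 s of actual stimulation).  ``amplitudes`` lets the simulator
    reuse this machinery with per-block response amplitudes; analysis always
    uses unit amplitude.
    """
    if block_model_duration_s <= 0:
        raise ParadigmError("block_model_duration_s must be positive")
    if n_scans is None:
        n_scans = schedule.n_scans
    blocks = schedule.condition_blocks(condition)
    if not blocks:
        logger.warning("condition %r has no blocks in schedule; returning zero regressor", condition)
        return np.zeros(n_scans)
    onsets = np.array([b.onset_s for b in blocks])
    if amplitudes is None:
        amplitudes = np.ones(len(blocks))
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.shape != (len(blocks),):
        raise ParadigmError("amplitudes must have one entry per block of the condition")
    t_fine, conv = _fine_grid_signal(
        onsets, block_model_duration_s, amplitudes, schedule.run_duration_s, kernel
    )
    return sample_at_scans(t_fine, conv, schedule.tr_s, n_scans)


@dataclass
class DesignMatrix:
    """Named-column design matrix on the scan grid, plus a censor mask."""

    frame: pd.DataFrame
    tr_s: float
    censor_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.censor_mask is None:
            self.censor_mask = np.ones(len(self.frame), dtype=bool)
        self.censor_mask = np.asarray(self.censor_mask, dtype=bool)
        if len(self.censor_mask) != len(self.frame):
            raise ParadigmError("censor mask length does not match design rows")
        if self.frame.columns.duplicated().any():
            raise ParadigmError("design matrix column names must be unique")

    @property
    def n_scans(self) -> int:
        return len(self.frame)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)


MOTION_COLUMNS = ["mot_tx", "mot_ty", "mot_tz", "mot_rx", "mot_ry", "mot_rz"]


def build_design_matrix(
    schedule: EventSchedule,
    kernel: HrfKernel,
    motion: np.ndarray | pd.DataFrame | None = None,
    drift_order: int = 1,
    tr_s: float | None = None,
    n_scans: int | None = None,
    block_model_duration_s: float = 25.0,
) -> DesignMatrix:
    """Full-run design: condition regressors, intercept, polynomial drift, motion.

    Drift columns are Legendre-like centred polynomials of scan time up to
    ``drift_order`` (0 disables drift regressors; the intercept is always
    present).
    """
    if tr_s is not None and tr_s != schedule.tr_s:
        schedule = schedule.with_tr(tr_s)
    if n_scans is None:
        n_scans = schedule.n_scans
    cols: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        cols[cond] = condition_regressor(
            schedule, cond, kernel, n_scans=n_scans, block_model_duration_s=block_model_duration_s
        )
    cols["intercept"] = np.ones(n_scans)
    if drift_order > 0:
        u = np.linspace(-1.0, 1.0, n_scans) if n_scans > 1 else np.zeros(n_scans)
        for k in range(1, drift_order + 1):
            cols[f"drift_{k}"] = u**k
    if motion is not None:
        mot = np.asarray(motion, dtype=float) if not isinstance(motion, pd.DataFrame) else motion.to_numpy(dtype=float)
        if mot.ndim != 2 or mot.shape[1] != 6:
            raise ParadigmError(f"motion table must have 6 columns, got shape {mot.shape}")
        if mot.shape[0] != n_scans:
            raise ParadigmError(
                f"motion table has {mot.shape[0]} rows but design has {n_scans} scans"
            )
        for j, name in enumerate(MOTION_COLUMNS):
            cols[name] = mot[:, j]
    return DesignMatrix(frame=pd.DataFrame(cols), tr_s=schedule.tr_s)


# ---------------------------------------------------------------------------
# Motion summaries and censoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotionSummary:
    """Frame-to-frame Euclidean-norm motion (AFNI-style enorm, mm-ish units)."""

    per_scan_enorm: np.ndarray
    mean_enorm: float


def motion_enorm(motion: np.ndarray | pd.DataFrame) -> MotionSummary:
    """Euclidean norm of the backward difference of the 6 motion parameters.

    The first scan has no predecessor and gets enorm 0; the mean is taken over
    all scans.  Rotations are treated on the same numeric footing as
    translations, as in common practice.
    """
    mot = np.asarray(motion, dtype=float) if not isinstance(motion, pd.DataFrame) else motion.to_numpy(dtype=float)
    if mot.ndim != 2 or mot.shape[1] != 6:
        raise ParadigmError(f"motion table must have 6 columns, got shape {mot.shape}")
    if mot.shape[0] < 2:
        raise ParadigmError("motion table needs at least 2 scans")
    if not np.all(np.isfinite(mot)):
        raise ParadigmError("motion parameters contain non-finite values")
    diffs = np.diff(mot, axis=0)
    enorm = np.concatenate([[0.0], np.linalg.norm(diffs, axis=1)])
    return MotionSummary(per_scan_enorm=enorm, mean_enorm=float(enorm.mean()))


def censor_scans(motion: np.ndarray | pd.DataFrame, threshold_mm: float = 3.0) -> np.ndarray:
    """Boolean keep-mask: False where per-scan enorm exceeds the threshold."""
    if threshold_mm <= 0:
        raise ParadigmError("censor threshold must be positive")
    summary = motion_enorm(motion)
    mask = summary.per_scan_enorm <= threshold_mm
    n_censored = int((~mask).sum())
    if n_censored:
        logger.info("censoring %d scans exceeding %.3g mm enorm", n_censored, threshold_mm)
    return mask
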