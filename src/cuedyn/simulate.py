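"""Synthetic ROI-BOLD cohorts with known habituation dynamics.

Generates everything the analysis pipeline ingests — per-subject ROI time
series, motion traces, behavioral scores — from an explicit generative model
whose ground truth (per-subject response amplitudes and habituation slopes)
is stored alongside the data.  The generative model mirrors the models the
pipeline fits: each block's latent response amplitude is linear in time, per
condition, with subject-level random offsets; noise is AR(1); behavior is
linearly coupled to the subject's true food-vs-neutral slope difference.

Time units of the habituation slopes: "per window step", i.e. the latent
amplitude changes by ``hab_slope`` when block time advances by one window
step (103 s by default).  This makes the generative slope directly
commensurable with the Condition:Time coefficient fitted on window indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .paradigm import (
    CONDITIONS,
    FOOD,
    NEUTRAL,
    EventSchedule,
    HrfKernel,
    build_schedule,
    canonical_hrf,
    _fine_grid_signal,
    sample_at_scans,
)

logger = logging.getLogger(__name__)


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class BehaviorMeasure:
    """One simulated behavioral measure, linearly coupled to the true slope.

    value = intercept + coupling * slope_diff(subject) + N(0, noise_sd),
    clipped to [lo, hi] (clipping is logged; it attenuates correlations).
    """

    name: str
    coupling: float
    noise_sd: float
    intercept: float = 50.0
    lo: float = 0.0
    hi: float = 100.0


# Natural scales for the measures the default cohort carries (VAS ratings are
# 0-100; questionnaire totals use their instrument ranges).
MEASURE_RANGES: dict[str, tuple[float, float, float]] = {
    # name: (default intercept, lo, hi)
    "craving_vas_pre": (65.0, 0.0, 100.0),
    "craving_vas_post": (75.0, 0.0, 100.0),
    "hunger_vas_pre": (55.0, 0.0, 100.0),
    "hunger_vas_post": (62.0, 0.0, 100.0),
    "food_control_vas_pre": (60.0, 0.0, 100.0),
    "food_control_vas_post": (53.0, 0.0, 100.0),
    "fcq_state": (32.0, 15.0, 75.0),
    "fcq_trait": (90.0, 0.0, 195.0),
    "dass": (21.0, 0.0, 63.0),
    "ces": (11.0, 0.0, 40.0),
}


def default_behavior_measures() -> list[BehaviorMeasure]:
    """Cohort defaults: craving-type VAS measures coupled to habituation.

    Negative coupling means subjects whose food response habituates more
    steeply (more negative slope) report *higher* craving — the direction of
    the strongest reported brain-behavior associations.
    """
    specs = [
        ("craving_vas_pre", -40.0, 10.0),
        ("craving_vas_post", -40.0, 10.0),
        ("hunger_vas_pre", 0.0, 15.0),
        ("hunger_vas_post", 0.0, 15.0),
        ("fcq_state", -25.0, 12.0),
        ("dass", 0.0, 12.0),
    ]
    out = []
    for name, coupling, noise in specs:
        intercept, lo, hi = MEASURE_RANGES[name]
        out.append(BehaviorMeasure(name, coupling, noise, intercept, lo, hi))
    return out


RoiValue = float | dict[str, float]


def _roi_value(x: RoiValue, roi: str) -> float:
    if isinstance(x, dict):
        return float(x[roi])
    return float(x)


@dataclass(frozen=True)
class SimConfig:
    """Full generative specification for one simulated cohort.

    Defaults emulate the study conditions: 49 subjects, TR 2.5 s, 12
    alternating 24-s blocks separated by 8-12 s, a clear food response with
    a habituating (negative) food slope and a flat neutral slope, moderate
    AR(1) scanner noise, and behavioral scores coupled to the true slope.
    """

    n_subjects: int = 49
    roi_names: tuple[str, ...] = ("roi_1",)
    tr_s: float = 2.5
    # schedule
    n_blocks_per_condition: int = 6
    stimuli_per_block: int = 6
    stimulus_duration_s: float = 4.0
    ibi_range_s: tuple[float, float] = (8.0, 12.0)
    # response model (arbitrary BOLD units on top of a baseline level)
    amp_food: RoiValue = 1.0
    amp_neutral: RoiValue = 0.6
    hab_slope_food: RoiValue = -0.3
    hab_slope_neutral: RoiValue = 0.0
    between_subject_sd: float = 0.2
    slope_diff_sd: float = 0.1
    slope_common_sd: float = 0.05
    # noise: the default innovation SD is calibrated so the sampling SE of a
    # single window beta is ~0.1 BOLD units under the default design
    baseline_level: float = 100.0
    noise_sd: float = 1.28
    ar1_coef: float = 0.3
    motion_sd: float = 0.02
    motion_bound_mm: float = 1.0
    # window step that defines the slope's time unit
    window_step_s: float = 103.0
    behavior_measures: tuple[BehaviorMeasure, ...] = field(
        default_factory=lambda: tuple(default_behavior_measures())
    )
    behavior_roi: str | None = None  # ROI whose slope drives behavior (default: first)
    hrf_dt_s: float = 0.1
    # The task layout is part of the study design: one fixed pseudo-random
    # order shared by all subjects and all simulated cohorts.  Only the noise,
    # subject effects and behavior vary with `seed`.
    schedule_seed: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise SimConfigError("n_subjects must be >= 1")
        if not self.roi_names:
            raise SimConfigError("roi_names must not be empty")
        if not abs(self.ar1_coef) < 1:
            raise SimConfigError("|ar1_coef| must be < 1")
        if self.noise_sd < 0:
            raise SimConfigError("noise_sd must be >= 0")
        names = [m.name for m in self.behavior_measures]
        if len(set(names)) != len(names):
            raise SimConfigError("duplicate behavior measure names")


@dataclass
class SimDataset:
    """One simulated cohort plus its generative ground truth."""

    config: SimConfig
    schedule: EventSchedule
    kernel: HrfKernel
    ts: dict[str, pd.DataFrame]          # subject -> (scans x ROIs)
    motion: dict[str, np.ndarray]        # subject -> (scans x 6)
    behavior: pd.DataFrame               # one row per subject
    truth: pd.DataFrame                  # subject x roi ground truth

    @property
    def subjects(self) -> list[str]:
        return sorted(self.ts)


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _block_response_basis(
    schedule: EventSchedule, kernel: HrfKernel, condition: str, duration_s: float
) -> np.ndarray:
    """(n_blocks, n_scans) matrix: row b is the response to block b alone."""
    blocks = schedule.condition_blocks(condition)
    n_scans = schedule.n_scans
    basis = np.empty((len(blocks), n_scans))
    for i, b in enumerate(blocks):
        t_fine, conv = _fine_grid_signal(
            np.array([b.onset_s]), duration_s, np.array([1.0]),
            schedule.run_duration_s, kernel,
        )
        basis[i] = sample_at_scans(t_fine, conv, schedule.tr_s, n_scans)
    return basis


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    e = rng.normal(0.0, sd, size=n)
    x = np.empty(n)
    x[0] = e[0] / np.sqrt(1 - phi**2)  # stationary start
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t]
    return x


def simulate_cohort(config: SimConfig) -> SimDataset:
    """Simulate a full cohort; identical config + seed gives identical data.

    Noise streams are keyed by (subject index, ROI index) so different ROIs
    and subjects receive independent noise regardless of how many of either
    are requested.
    """
    schedule = build_schedule(
        n_blocks_per_condition=config.n_blocks_per_condition,
        stimuli_per_block=config.stimuli_per_block,
        stimulus_duration_s=config.stimulus_duration_s,
        ibi_range_s=config.ibi_range_s,
        order="alternating",
        seed=config.schedule_seed,
        tr_s=config.tr_s,
    )
    kernel = canonical_hrf(config.hrf_dt_s)
    n_scans = schedule.n_scans
    # Neural events last as long as the actual stimulation (6 x 4 s), not the
    # 25-s analysis convention.
    neural_dur = config.stimuli_per_block * config.stimulus_duration_s
    basis = {
        c: _block_response_basis(schedule, kernel, c, neural_dur) for c in CONDITIONS
    }
    # Block centers in window-step units: the latent amplitude moves by
    # hab_slope per one window step of elapsed time.
    u = {
        c: np.array([b.center_s for b in schedule.condition_blocks(c)])
        / config.window_step_s
        for c in CONDITIONS
    }

    subjects = [f"sub-{i + 1:02d}" for i in range(config.n_subjects)]
    ts: dict[str, pd.DataFrame] = {}
    motion: dict[str, np.ndarray] = {}
    truth_rows = []
    for si, subject in enumerate(subjects):
        dev = _stream(config.seed, 3, si)
        slope_common = dev.normal(0.0, config.slope_common_sd)
        slope_diff_dev = dev.normal(0.0, config.slope_diff_sd)
        series = {}
        for ri, roi in enumerate(config.roi_names):
            amp_offset = _stream(config.seed, 2, si, ri).normal(0.0, config.between_subject_sd)
            slopes = {
                FOOD: _roi_value(config.hab_slope_food, roi) + slope_common + slope_diff_dev,
                NEUTRAL: _roi_value(config.hab_slope_neutral, roi) + slope_common,
            }
            amps = {
                FOOD: _roi_value(config.amp_food, roi) + amp_offset,
                NEUTRAL: _roi_value(config.amp_neutral, roi) + amp_offset,
            }
            signal = np.full(n_scans, config.baseline_level)
            for cond in CONDITIONS:
                a_blocks = amps[cond] + slopes[cond] * u[cond]
                signal = signal + a_blocks @ basis[cond]
            noise = _ar1_noise(
                _stream(config.seed, 1, si, ri), n_scans, config.noise_sd, config.ar1_coef
            )
            series[roi] = signal + noise
            truth_rows.append(
                {
                    "subject": subject,
                    "roi": roi,
                    "amp_food": amps[FOOD],
                    "amp_neutral": amps[NEUTRAL],
                    "slope_food": slopes[FOOD],
                    "slope_neutral": slopes[NEUTRAL],
                    "slope_diff": slopes[FOOD] - slopes[NEUTRAL],
                }
            )
        ts[subject] = pd.DataFrame(series)
        steps = _stream(config.seed, 4, si).normal(0.0, config.motion_sd, size=(n_scans, 6))
        steps[0] = 0.0
        motion[subject] = np.clip(
            np.cumsum(steps, axis=0), -config.motion_bound_mm, config.motion_bound_mm
        )

    truth = pd.DataFrame(truth_rows)
    behavior_roi = config.behavior_roi or config.roi_names[0]
    slope_by_subject = (
        truth[truth["roi"] == behavior_roi].set_index("subject")["slope_diff"]
    )
    behavior = attach_behavior(slope_by_subject, config.behavior_measures, seed=config.seed)
    return SimDataset(
        config=config, schedule=schedule, kernel=kernel,
        ts=ts, motion=motion, behavior=behavior, truth=truth,
    )


def simulate_null_cohort(config: SimConfig) -> SimDataset:
    """Cohort with no condition effect: food parameters mirror neutral.

    Amplitudes, slopes and subject-level slope differences are equalised so
    the Condition and Condition:Time effects are exactly null; shared time
    trends and amplitude offsets are retained.
    """
    null_config = replace(
        config,
        amp_food=config.amp_neutral,
        hab_slope_food=config.hab_slope_neutral,
        slope_diff_sd=0.0,
    )
    return simulate_cohort(null_config)


def attach_behavior(
    slopes: pd.Series,
    measures: tuple[BehaviorMeasure, ...] | list[BehaviorMeasure],
    seed: int = 0,
) -> pd.DataFrame:
    """Behavioral table linearly coupled to per-subject true slopes.

    For measure m: value = intercept + coupling * slope + N(0, noise_sd),
    clipped to the measure's natural range.  The population correlation with
    the slope is coupling / sqrt(coupling^2 + noise_sd^2 / var(slope)).
    """
    if slopes.index.duplicated().any():
        raise SimConfigError("one slope per subject required")
    names = [m.name for m in measures]
    if len(set(names)) != len(names):
        raise SimConfigError("duplicate behavior measure names")
    for m in measures:
        if m.name not in MEASURE_RANGES and (m.lo, m.hi) == (0.0, 100.0) and m.intercept == 50.0:
            raise SimConfigError(
                f"unknown behavior measure {m.name!r}: not in the measure registry and "
                "no explicit intercept/range given"
            )
    out = pd.DataFrame({"subject": slopes.index})
    s = slopes.to_numpy(dtype=float)
    for mi, m in enumerate(measures):
        rng = _stream(seed, 5, mi)
        raw = m.intercept + m.coupling * s + rng.normal(0.0, m.noise_sd, size=s.size)
        clipped = np.clip(raw, m.lo, m.hi)
        n_clip = int((clipped != raw).sum())
        if n_clip:
            logger.info("measure %s: clipped %d/%d values to [%g, %g]",
                        m.name, n_clip, s.size, m.lo, m.hi)
        out[m.name] = clipped
    return out.set_index("subject").reset_index()
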