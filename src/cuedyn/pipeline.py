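"""End-to-end pipeline: events + ROI series -> betas -> LME -> slopes -> correlations.

Configuration is a plain dataclass round-trippable through YAML; a JSON run
manifest records package versions, a hash of the resolved configuration and
per-stage record counts, so no subject can be dropped silently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import statsmodels

from . import __version__
from .dynamics_lme import fit_dynamics_lme, lme_results_table, scan_rois
from .habituation import behavior_pre_post_tests, habituation_slopes, slope_behavior_correlation
from .io import DataError, read_behavior, read_dataset_dir, write_beta_table
from .paradigm import canonical_hrf
from .windowed_glm import WindowSpec, make_windows, window_betas

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


@dataclass
class PipelineConfig:
    """All knobs for one pipeline run; serialises losslessly to YAML."""

    data_dir: str = "."
    out_dir: str = "out"
    tr_s: float = 2.5
    n_discard_scans: int = 0
    block_model_duration_s: float = 25.0
    drift_order: int = 1
    censor_threshold_mm: float = 3.0
    window_length_s: float = 198.0
    window_step_s: float = 103.0
    window_min_fraction: float = 0.5
    alpha: float = 0.05
    psc: bool = False
    condition_reference: str = "neutral"
    time_origin: float = 1.0
    correlate: bool = True
    behavior_file: str | None = None  # default: <data_dir>/behavior.csv when present
    pre_post: bool = True
    seed: int = 0
    log_level: str = "INFO"
    hrf: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> Path:
        import yaml

        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write betas, LME results, slopes and correlations.

    Deterministic for a fixed config: rerunning into a fresh directory gives
    byte-identical CSV/TSV outputs.  Configuration problems (e.g. the
    correlation stage enabled without a behavior table) abort before any
    computation.
    """
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    data_dir = Path(config.data_dir)
    out = Path(config.out_dir)

    behavior_path: Path | None = None
    if config.correlate or config.pre_post:
        behavior_path = (
            Path(config.behavior_file)
            if config.behavior_file
            else data_dir / "behavior.csv"
        )
        if not behavior_path.is_file():
            if config.behavior_file or config.correlate:
                raise ConfigError(
                    f"behavior stage enabled but behavior table not found: {behavior_path}"
                )
            behavior_path = None

    logger.info("stage load: reading dataset from %s", data_dir)
    schedule, ts, motion = read_dataset_dir(
        data_dir, tr_s=config.tr_s, n_discard=config.n_discard_scans
    )
    if motion and set(motion) != set(ts):
        raise DataError(
            f"subjects mismatch between roi_ts ({len(ts)}) and motion ({len(motion)})"
        )
    manifest_counts = {"subjects_in": len(ts), "blocks": schedule.n_blocks}

    kernel = canonical_hrf(**config.hrf) if config.hrf else canonical_hrf()
    spec = WindowSpec(
        length_s=config.window_length_s,
        step_s=config.window_step_s,
        min_fraction=config.window_min_fraction,
    )
    windows = make_windows(schedule.run_duration_s, spec)
    logger.info("stage windows: %d windows over %.1f s", len(windows), schedule.run_duration_s)
    manifest_counts["windows"] = len(windows)

    logger.info("stage betas: fitting per-window GLMs")
    betas = window_betas(
        ts, schedule, kernel, windows,
        motion_by_subject=motion or None,
        psc=config.psc,
        drift_order=config.drift_order,
        block_model_duration_s=config.block_model_duration_s,
        censor_threshold_mm=config.censor_threshold_mm if motion else None,
    )
    out.mkdir(parents=True, exist_ok=True)
    write_beta_table(betas, out / "betas.csv")
    manifest_counts["beta_records"] = len(betas)
    manifest_counts["beta_missing"] = int(betas["beta"].isna().sum())

    logger.info("stage lme: scanning %d ROIs", betas["roi"].nunique())
    scan = scan_rois(
        betas, alpha=config.alpha,
        condition_reference=config.condition_reference,
        time_origin=config.time_origin,
    )
    scan.to_csv(out / "lme_scan.tsv", sep="\t", index=False)
    fits = {}
    for roi, sub in betas.groupby("roi", sort=True):
        try:
            fits[str(roi)] = fit_dynamics_lme(
                sub, condition_reference=config.condition_reference,
                time_origin=config.time_origin,
            )
        except Exception as exc:
            logger.warning("stage lme: ROI %s failed: %s", roi, exc)
    lme_results_table(fits, alpha=config.alpha).to_csv(
        out / "lme.tsv", sep="\t", index=False
    )
    manifest_counts["rois_fit"] = len(fits)
    manifest_counts["rois_flagged"] = int(scan["flagged"].sum()) if len(scan) else 0

    logger.info("stage slopes: per-subject habituation slopes")
    slopes = habituation_slopes(
        betas, condition_reference=config.condition_reference,
        time_origin=config.time_origin,
    )
    slopes.to_csv(out / "slopes.csv", index=False)
    manifest_counts["slope_records"] = len(slopes)

    behavior = None
    if behavior_path is not None:
        behavior = read_behavior(behavior_path)
        missing_subjects = sorted(set(ts) - set(behavior["subject"]))
        if missing_subjects:
            logger.warning("subjects without behavior: %s", missing_subjects)
    if config.correlate and behavior is not None:
        logger.info("stage correlate: slope-behavior Pearson correlations")
        corr = slope_behavior_correlation(slopes, behavior)
        corr.to_csv(out / "correlations.tsv", sep="\t", index=False)
        manifest_counts["correlations"] = len(corr)
    if config.pre_post and behavior is not None:
        tests = behavior_pre_post_tests(behavior)
        if len(tests):
            tests.to_csv(out / "behavior_tests.tsv", sep="\t", index=False)
            manifest_counts["pre_post_tests"] = len(tests)

    # truth-vs-estimate report when the generative ground truth is available
    truth_path = data_dir / "truth.csv"
    if truth_path.is_file():
        truth = pd.read_csv(truth_path)
        merged = slopes.merge(truth, on=["subject", "roi"], how="inner")
        if len(merged):
            report = (
                merged.assign(error=merged["slope"] - merged["slope_diff"])
                .groupby("roi")
                .agg(
                    mean_estimated=("slope", "mean"),
                    mean_true=("slope_diff", "mean"),
                    rmse=("error", lambda e: float(np.sqrt(np.mean(e**2)))),
                    n=("subject", "count"),
                )
                .reset_index()
            )
            report.to_csv(out / "recovery_report.tsv", sep="\t", index=False)
            manifest_counts["recovery_rois"] = len(report)

    manifest = {
        "package": {"cuedyn": __version__},
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "counts": manifest_counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return out
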