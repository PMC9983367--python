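"""Readers and writers for the interchange formats.

Plain-text formats throughout: BIDS-style events TSV, whitespace-delimited
6-column motion text (AFNI/FSL dialect), CSV for ROI time series, betas,
slopes and behavior, TSV for statistical results.  Every writer produces a
file its paired reader accepts.  NIfTI ROI extraction is available when an
integer parcellation is supplied; the imaging dependency is only imported
there.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .paradigm import CONDITIONS, Block, EventSchedule, ParadigmError
from .windowed_glm import BETA_COLUMNS

logger = logging.getLogger(__name__)


class DataError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

def write_events(schedule: EventSchedule, path: str | Path) -> Path:
    """One row per block: onset, duration, trial_type (BIDS events dialect)."""
    path = Path(path)
    schedule.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_events(
    path: str | Path,
    tr_s: float = 2.5,
    stimuli_per_block: int = 6,
    stimulus_duration_s: float = 4.0,
    run_duration_s: float | None = None,
) -> EventSchedule:
    """Parse an events TSV into a validated schedule.

    Accepts either one row per block or one row per picture; contiguous
    same-condition picture rows (next onset == previous offset) are merged
    into blocks, and when every merged run has the same length the per-block
    stimulus count and duration are inferred from the file.  Overlapping
    rows, unknown condition labels and non-numeric fields raise a parse
    error naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"onset", "duration", "trial_type"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: events file needs columns {sorted(required)}")
    for col in ("onset", "duration"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise DataError(f"{path}: non-numeric {col} in row {int(bad[0])}")
        df[col] = vals
    df = df.sort_values("onset", kind="stable").reset_index(drop=True)
    for i, cond in enumerate(df["trial_type"]):
        if cond not in CONDITIONS:
            raise DataError(f"{path}: unknown condition {cond!r} in row {i}")
    # overlap check on raw rows
    ends = (df["onset"] + df["duration"]).to_numpy()
    onsets = df["onset"].to_numpy()
    for i in range(1, len(df)):
        if onsets[i] < ends[i - 1] - 1e-9:
            raise DataError(f"{path}: row {i} overlaps previous row")

    # merge contiguous same-condition runs into blocks
    blocks: list[Block] = []
    run_lengths: list[int] = []
    row_durations: list[float] = []
    i = 0
    while i < len(df):
        j = i
        while (
            j + 1 < len(df)
            and df["trial_type"][j + 1] == df["trial_type"][i]
            and abs(onsets[j + 1] - ends[j]) < 1e-6
        ):
            j += 1
        # sum of row durations, not end-minus-onset: keeps written values
        # bit-exact through the text round-trip
        blocks.append(
            Block(
                onset_s=float(onsets[i]),
                duration_s=float(df["duration"][i : j + 1].sum()),
                condition=str(df["trial_type"][i]),
            )
        )
        run_lengths.append(j - i + 1)
        row_durations.append(float(df["duration"][i]))
        i = j + 1
    if run_lengths and all(n > 1 for n in run_lengths) and len(set(run_lengths)) == 1:
        stimuli_per_block = run_lengths[0]
        stimulus_duration_s = row_durations[0]
    if run_duration_s is None:
        run_duration_s = blocks[-1].end_s if blocks else 0.0
    try:
        return EventSchedule(
            blocks=tuple(blocks),
            run_duration_s=run_duration_s,
            tr_s=tr_s,
            stimuli_per_block=stimuli_per_block,
            stimulus_duration_s=stimulus_duration_s,
        )
    except ParadigmError as exc:
        raise DataError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Motion
# ---------------------------------------------------------------------------

def write_motion(motion: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    mot = np.asarray(motion, dtype=float)
    if mot.ndim != 2 or mot.shape[1] != 6:
        raise DataError(f"motion array must be (n_scans, 6), got {mot.shape}")
    np.savetxt(path, mot, fmt="%.17g")
    return path


def read_motion(path: str | Path) -> np.ndarray:
    path = Path(path)
    try:
        mot = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise DataError(f"{path}: {exc}") from exc
    if mot.shape[1] != 6:
        raise DataError(f"{path}: expected 6 motion columns, found {mot.shape[1]}")
    if not np.all(np.isfinite(mot)):
        raise DataError(f"{path}: non-finite motion parameters")
    return mot


# ---------------------------------------------------------------------------
# ROI time series / tables
# ---------------------------------------------------------------------------

def write_roi_timeseries(ts: pd.DataFrame, path: str | Path) -> Path:
    """Rows = scans, columns = ROI names."""
    path = Path(path)
    ts.to_csv(path, index=False)
    return path


def read_roi_timeseries(
    path: str | Path, n_discard: int = 0
) -> pd.DataFrame:
    """Read a scans-by-ROIs CSV, dropping the first ``n_discard`` scans.

    Scanner exports carry dummy volumes before steady-state magnetisation
    (conventionally 3 at this TR); synthetic data has none, so the default
    is 0 and the discard is the caller's explicit choice.
    """
    path = Path(path)
    ts = pd.read_csv(path, float_precision="round_trip")
    if ts.isna().any().any():
        raise DataError(f"{path}: missing values in ROI time series")
    if n_discard < 0:
        raise DataError("n_discard must be >= 0")
    if n_discard >= len(ts):
        raise DataError(f"{path}: n_discard={n_discard} leaves no scans")
    ts = ts.iloc[n_discard:].reset_index(drop=True)
    flat = [c for c in ts.columns if ts[c].nunique() <= 1]
    if flat:
        logger.warning("%s: flat (constant) ROI series: %s", path, flat)
    return ts


def write_beta_table(table: pd.DataFrame, path: str | Path) -> Path:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return Path(path)


def read_beta_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, float_precision="round_trip")
    missing = set(BETA_COLUMNS) - set(table.columns)
    if missing:
        raise DataError(f"{path}: beta table missing columns {sorted(missing)}")
    return table


def write_behavior(behavior: pd.DataFrame, path: str | Path) -> Path:
    behavior.to_csv(path, index=False)
    return Path(path)


def read_behavior(path: str | Path) -> pd.DataFrame:
    beh = pd.read_csv(path, float_precision="round_trip")
    if "subject" not in beh.columns:
        raise DataError(f"{path}: behavior table needs a 'subject' column")
    if beh["subject"].duplicated().any():
        raise DataError(f"{path}: duplicate subjects in behavior table")
    return beh


# ---------------------------------------------------------------------------
# NIfTI ROI extraction
# ---------------------------------------------------------------------------

def extract_roi_means(
    image_4d: str | Path,
    labels: str | Path,
    label_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Mean time series per parcel of an integer-labelled parcellation.

    ``label_names`` maps label values to ROI names (defaults to ``roi_<k>``);
    labels present in the table but empty in the image are skipped with a log
    line.  The functional image and the parcellation must share grid
    dimensions.
    """
    import nibabel as nib

    img = nib.load(str(image_4d))
    lab = nib.load(str(labels))
    data = np.asarray(img.dataobj, dtype=float)
    labvol = np.asarray(lab.dataobj)
    labvol = np.rint(labvol).astype(int)
    if data.ndim != 4:
        raise DataError(f"{image_4d}: expected a 4-D image, got shape {data.shape}")
    if labvol.shape != data.shape[:3]:
        raise DataError(
            f"grid mismatch: image {data.shape[:3]} vs labels {labvol.shape}"
        )
    values = sorted(int(v) for v in np.unique(labvol) if v != 0)
    if label_names is None:
        label_names = {v: f"roi_{v}" for v in values}
    out = {}
    for v, name in sorted(label_names.items()):
        mask = labvol == v
        if not mask.any():
            logger.warning("label %d (%s) has no voxels; column skipped", v, name)
            continue
        out[name] = data[mask].mean(axis=0)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Simulated-dataset directory layout
# ---------------------------------------------------------------------------

def write_dataset(dataset, out_dir: str | Path) -> Path:
    """Write a simulated cohort in the same layout the pipeline ingests.

    out/
      events.tsv            shared stimulus schedule
      roi_ts/sub-XX.csv     scans x ROIs per subject
      motion/sub-XX_motion.txt
      behavior.csv
      truth.csv             generative ground truth (amplitudes, slopes)
    """
    out = Path(out_dir)
    (out / "roi_ts").mkdir(parents=True, exist_ok=True)
    (out / "motion").mkdir(exist_ok=True)
    write_events(dataset.schedule, out / "events.tsv")
    for subject in dataset.subjects:
        write_roi_timeseries(dataset.ts[subject], out / "roi_ts" / f"{subject}.csv")
        write_motion(dataset.motion[subject], out / "motion" / f"{subject}_motion.txt")
    write_behavior(dataset.behavior, out / "behavior.csv")
    dataset.truth.to_csv(out / "truth.csv", index=False)
    return out


def read_dataset_dir(
    root: str | Path, tr_s: float = 2.5, n_discard: int = 0
) -> tuple[EventSchedule, dict[str, pd.DataFrame], dict[str, np.ndarray]]:
    """Load events, ROI series and motion from a dataset directory."""
    root = Path(root)
    schedule = read_events(root / "events.tsv", tr_s=tr_s)
    ts: dict[str, pd.DataFrame] = {}
    for f in sorted((root / "roi_ts").glob("*.csv")):
        ts[f.stem] = read_roi_timeseries(f, n_discard=n_discard)
    if not ts:
        raise DataError(f"{root}: no ROI time-series files in roi_ts/")
    motion: dict[str, np.ndarray] = {}
    mot_dir = root / "motion"
    if mot_dir.is_dir():
        for f in sorted(mot_dir.glob("*_motion.txt")):
            motion[f.stem.replace("_motion", "")] = read_motion(f)
    return schedule, ts, motion
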