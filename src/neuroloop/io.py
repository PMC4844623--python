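"""File formats and study configuration.

All tabular artifacts are TSV with a header row; times are in seconds and
volume indices 1-based in logs.  Waveforms are single-column text files with
a one-line ``fs=<Hz>`` header.  Multi-echo volume series and masks use NIfTI
(one file per echo).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .design import (
    BLOCK_TRS,
    AcquisitionParams,
    BlockSchedule,
    Condition,
    DirectionMapping,
    FeedbackType,
)
from .simulate import MultiEchoSeries

SCHEDULE_COLUMNS = ["onset_s", "duration_s", "condition", "regulation"]
FRAMELOG_COLUMNS = ["volume_index", "roi_value", "scaled", "displayed", "visible"]


class FormatError(ValueError):
    """Raised for malformed files, naming the offending part."""


# ---------------------------------------------------------------- TSV helpers

def tsv_write(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def tsv_read(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    if required:
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
    return frame


# ------------------------------------------------------------------ schedules

def schedule_write(
    schedule: BlockSchedule, path: str | Path, tr_seconds: float = 2.54
) -> None:
    tsv_write(schedule.to_frame(tr_seconds), path)


def schedule_read(
    path: str | Path,
    tr_seconds: float = 2.54,
    feedback_type: FeedbackType | str | None = None,
    mapping: DirectionMapping | None = None,
) -> BlockSchedule:
    """Reconstruct a BlockSchedule from its TSV (regulation column).

    Display rows mark the run as EoBF; otherwise the feedback type defaults
    to CF unless given.  Onsets are validated against the reconstructed
    block boundaries.
    """
    frame = tsv_read(path, required=SCHEDULE_COLUMNS)
    blocks: list[tuple[Condition, int]] = []
    has_display = False
    expected_onset = 0.0
    for i, row in frame.iterrows():
        if abs(row["onset_s"] - expected_onset) > 1e-6:
            raise FormatError(
                f"{path}: row {i} onset {row['onset_s']} != expected {expected_onset}"
            )
        n_trs = row["duration_s"] / tr_seconds
        if abs(n_trs - round(n_trs)) > 1e-6:
            raise FormatError(f"{path}: row {i} duration is not a whole number of TRs")
        expected_onset += row["duration_s"]
        if row["regulation"] == "DISPLAY":
            has_display = True
            continue
        blocks.append((Condition(row["regulation"]), int(round(n_trs))))
    if feedback_type is None:
        feedback_type = FeedbackType.EOBF if has_display else FeedbackType.CF
    if mapping is None:
        left = frame.loc[frame["condition"] == "LEFT", "regulation"]
        mapping = (
            DirectionMapping(Condition(left.iloc[0]))
            if len(left)
            else DirectionMapping()
        )
    return BlockSchedule(
        blocks=tuple(blocks), feedback_type=FeedbackType(feedback_type), mapping=mapping
    )


# ------------------------------------------------------------------ waveforms

def waveform_write(samples: np.ndarray, fs: float, path: str | Path) -> None:
    """Single-column text trace with an ``fs=<Hz>`` header line."""
    with open(path, "w") as fh:
        fh.write(f"fs={fs:g}\n")
        np.savetxt(fh, np.asarray(samples, dtype=float), fmt="%.6g")


def waveform_read(path: str | Path) -> tuple[np.ndarray, float]:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("fs="):
            raise FormatError(f"{path}: first line must be 'fs=<Hz>', got {header!r}")
        try:
            fs = float(header[3:])
        except ValueError as exc:
            raise FormatError(f"{path}: bad sampling rate in header {header!r}") from exc
        samples = np.loadtxt(fh, ndmin=1)
    return samples, fs


# ------------------------------------------------------------------ frame logs

def framelog_write(frame: pd.DataFrame, path: str | Path) -> None:
    tsv_write(frame[FRAMELOG_COLUMNS], path)


def framelog_read(path: str | Path) -> pd.DataFrame:
    """Read a frame log, validating contiguous 1-based volume indices."""
    frame = tsv_read(path, required=FRAMELOG_COLUMNS)
    idx = frame["volume_index"].to_numpy()
    expected = np.arange(1, len(frame) + 1)
    bad = np.flatnonzero(idx != expected)
    if bad.size:
        row = int(bad[0])
        raise FormatError(
            f"{path}: volume_index gap at row {row}: got {idx[row]}, expected {expected[row]}"
        )
    return frame


# --------------------------------------------------------------------- motion

def motion_write(motion: np.ndarray, path: str | Path) -> None:
    cols = [f"mot_{i + 1}" for i in range(6)]
    tsv_write(pd.DataFrame(np.asarray(motion, dtype=float), columns=cols), path)


def motion_read(path: str | Path) -> np.ndarray:
    frame = tsv_read(path)
    if frame.shape[1] != 6:
        raise FormatError(f"{path}: motion table must have 6 columns, has {frame.shape[1]}")
    return frame.to_numpy(dtype=float)


# ---------------------------------------------------------------------- NIfTI

def nifti_write(data: np.ndarray, path: str | Path, voxel_size_mm: float = 4.0) -> None:
    affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def nifti_read(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def multiecho_write(series: MultiEchoSeries, directory: str | Path, stem: str = "echo") -> list[Path]:
    """Write a volume-mode series as one 4D NIfTI per echo plus the mask."""
    if not series.is_volume_mode:
        raise ValueError("multiecho_write expects a volume-mode series")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for e in range(series.data.shape[0]):
        p = directory / f"{stem}_{e + 1}.nii.gz"
        nifti_write(series.data[e], p)
        paths.append(p)
    if series.mask is not None:
        nifti_write(series.mask.astype(np.uint8), directory / "mask.nii.gz")
    return paths


def multiecho_read(
    echo_paths: list[str | Path], acq: AcquisitionParams, mask_path: str | Path | None = None
) -> MultiEchoSeries:
    data = np.stack([nifti_read(p) for p in echo_paths], axis=0)
    mask = nifti_read(mask_path).astype(bool) if mask_path else None
    return MultiEchoSeries(data=data, acq=acq, mask=mask)


# --------------------------------------------------------------------- config

@dataclass
class StudyConfig:
    """Desk-scale study configuration; round-trips through YAML unchanged."""

    n_subjects: int = 32
    n_per_condition: int = 8
    feedback_type: str = "NONE"  # transfer run
    effect_mean_psc: float = 0.43
    effect_sd_psc: float = 1.0
    tr_seconds: float = 2.54
    echo_times_ms: tuple[float, ...] = (8.6, 18.3, 28.0, 38.0, 48.0, 57.0)
    t2star_ms: float = 30.0
    noise_sd: float = 4.0
    drift_slope: float = 0.02
    seed: int = 0
    n_boot: int = 1000
    simulate_physio: bool = False
    physio_fs: float = 50.0
    outdir: str | None = None

    def acquisition(self) -> AcquisitionParams:
        return AcquisitionParams(
            tr_seconds=self.tr_seconds,
            echo_times_ms=tuple(self.echo_times_ms),
            t2star_ms=self.t2star_ms,
        )


def config_write(config: StudyConfig, path: str | Path) -> None:
    payload = asdict(config)
    payload["echo_times_ms"] = list(payload["echo_times_ms"])
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def config_read(path: str | Path) -> StudyConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise FormatError(f"{path}: config must be a mapping")
    known = set(StudyConfig.__dataclass_fields__)
    unknown = set(payload) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    if "echo_times_ms" in payload:
        payload["echo_times_ms"] = tuple(payload["echo_times_ms"])
    return StudyConfig(**payload)
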