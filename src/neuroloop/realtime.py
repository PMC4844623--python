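"""Real-time feedback signal chain: echo combination, baseline scaling, display.

Per acquired volume the engine (1) combines the six echo images with fixed
TE-dependent weights chosen for the ROI's T2*, (2) averages the combined
signal over the target ROI, (3) once volumes 6-15 of the run have arrived,
freezes their mean and standard deviation as the run baseline, (4) maps each
subsequent ROI value to a display coordinate where the baseline mean sits at
screen center and +/-4 SD at the edges, (5) applies the counterbalanced
direction-mapping sign, and (6) keeps the 12 most recent displayed values as
the moving-dot history.  Scaling state is reset at every run boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    AcquisitionParams,
    BlockSchedule,
    DirectionMapping,
    FeedbackType,
)

#: baseline window in 1-based inclusive volume indices
BASELINE_WINDOW = (6, 15)

#: baseline offset (in baseline SDs) that maps to the display edge
DISPLAY_EDGE_SD = 4.0

#: number of dot-history samples shown on screen
HISTORY_LENGTH = 12


class DegenerateBaselineError(ValueError):
    """Raised when the baseline window has zero variance (scaling undefined)."""


@dataclass(frozen=True)
class EchoWeights:
    """Fixed TE-dependent echo-combination weights, normalized to max 1."""

    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.size == 0:
            raise ValueError("weights must be non-empty")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if not np.isclose(w.max(), 1.0):
            raise ValueError("weights must be normalized so the maximum is 1")


def te_weights(
    echo_times_ms: tuple[float, ...] | np.ndarray, t2star_ms: float
) -> EchoWeights:
    """BOLD-sensitivity weights w_n = TE_n * exp(-TE_n/T2*), max-normalized.

    The unnormalized weight peaks at TE = T2*, so echoes read out near the
    tissue T2* dominate the combination.
    """
    tes = np.asarray(echo_times_ms, dtype=float)
    if tes.size == 0:
        raise ValueError("echo_times_ms must be non-empty")
    if t2star_ms <= 0:
        raise ValueError("t2star_ms must be positive")
    w = tes * np.exp(-tes / t2star_ms)
    w = w / w.max()
    return EchoWeights(weights=tuple(float(v) for v in w))


def combine_echoes(
    values_per_echo: np.ndarray | list[float], weights: EchoWeights
) -> np.ndarray | float:
    """Weighted average of per-echo values: sum(w*v) / sum(w).

    Accepts one scalar per echo or an (n_echoes, n_volumes) array; dividing
    by the weight sum makes the output scale-free (all-equal echoes combine
    to that same value).
    """
    v = np.asarray(values_per_echo, dtype=float)
    w = np.asarray(weights.weights)
    if v.shape[0] != w.size:
        raise ValueError(
            f"got {v.shape[0]} echo values for {w.size} weights"
        )
    combined = np.tensordot(w, v, axes=(0, 0)) / w.sum()
    return float(combined) if np.ndim(combined) == 0 else combined


def roi_mean(volume: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of a volume over the in-mask voxels."""
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    if not mask.any():
        raise ValueError("empty ROI mask")
    return float(volume[mask].mean())


@dataclass(frozen=True)
class BaselineStats:
    """Mean/SD of the combined ROI signal over the rest baseline window."""

    mean: float
    sd: float
    window: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def estimate_baseline(
    series: np.ndarray | list[float], window: tuple[int, int] = BASELINE_WINDOW
) -> BaselineStats:
    """Mean and sample SD over a 1-based inclusive volume window.

    The default window, volumes 6-15, skips the initial signal transient and
    uses ten early-rest volumes.  A constant window is rejected because
    display scaling would be undefined.
    """
    series = np.asarray(series, dtype=float)
    lo, hi = window
    if lo < 1 or hi < lo:
        raise ValueError("window must be 1-based with lo <= hi")
    if series.size < hi:
        raise ValueError(
            f"series has {series.size} volumes; baseline window needs {hi}"
        )
    vals = series[lo - 1 : hi]
    sd = float(vals.std(ddof=1))
    if sd == 0.0:
        raise DegenerateBaselineError("baseline window is constant; scaling undefined")
    return BaselineStats(mean=float(vals.mean()), sd=sd, window=tuple(range(lo, hi + 1)))


def scale_to_display(value: float, baseline: BaselineStats) -> float:
    """Map a raw ROI value to display units: 0 = center, +/-1 = screen edge.

    An offset of +/- DISPLAY_EDGE_SD baseline SDs reaches the edge; values
    beyond that are clipped so the dots stay on screen.
    """
    if baseline.sd <= 0:
        raise DegenerateBaselineError("baseline SD must be positive")
    scaled = (value - baseline.mean) / (DISPLAY_EDGE_SD * baseline.sd)
    return float(np.clip(scaled, -1.0, 1.0))


@dataclass(frozen=True)
class FeedbackFrame:
    """Per-TR display state written to the frame log."""

    volume_index: int  # 1-based
    roi_value: float
    scaled: float  # NaN before the baseline is available
    displayed: float  # scaled * mapping sign; NaN pre-baseline
    visible: bool
    pre_baseline: bool
    history: tuple[float, ...]  # up to 12 displayed values, oldest -> newest


class FeedbackEngine:
    """Streaming per-volume feedback computation for one run.

    Feed volumes in order with :meth:`step`; state (baseline, history) never
    leaks across runs -- build a new engine or call :meth:`reset` per run.
    """

    def __init__(
        self,
        acq: AcquisitionParams,
        mapping: DirectionMapping | None = None,
        feedback_type: FeedbackType | str = FeedbackType.CF,
        schedule: BlockSchedule | None = None,
        weights: EchoWeights | None = None,
        baseline_window: tuple[int, int] = BASELINE_WINDOW,
    ) -> None:
        self.acq = acq
        self.schedule = schedule
        if schedule is not None:
            self.feedback_type = schedule.feedback_type
            self.mapping = schedule.mapping if mapping is None else mapping
        else:
            self.feedback_type = FeedbackType(feedback_type)
            self.mapping = mapping if mapping is not None else DirectionMapping()
        self.weights = weights if weights is not None else te_weights(
            acq.echo_times_ms, acq.t2star_ms
        )
        self.baseline_window = baseline_window
        self._visible_volumes = self._visibility_table()
        self.reset()

    def reset(self) -> None:
        """Clear all per-run state (called automatically at construction)."""
        self.baseline: BaselineStats | None = None
        self._raw: list[float] = []
        self._history: list[float] = []
        self.frames: list[FeedbackFrame] = []

    def _visibility_table(self) -> set[int] | None:
        """1-based volume indices at which feedback is shown (None = every TR)."""
        if self.feedback_type is FeedbackType.NONE:
            return set()
        if self.feedback_type is FeedbackType.CF:
            return None
        if self.schedule is None:
            raise ValueError("EoBF visibility requires a schedule")
        visible = set()
        vol = 0
        for _, trs in self.schedule.blocks:
            vol += trs
            for k in range(self.schedule.display_trs_per_block):
                visible.add(vol + k + 1)
            vol += self.schedule.display_trs_per_block
        return visible

    def step(
        self,
        values_per_echo: np.ndarray | list[float],
        volume_index: int | None = None,
    ) -> FeedbackFrame:
        """Ingest one multi-echo volume (one ROI value per echo); emit a frame.

        ``volume_index`` (1-based) may be passed for validation; it must be
        exactly the next expected index.
        """
        expected = len(self._raw) + 1
        if volume_index is not None and volume_index != expected:
            raise ValueError(
                f"out-of-order volume index {volume_index}; expected {expected}"
            )
        volume_index = expected
        roi_value = float(combine_echoes(np.asarray(values_per_echo, float), self.weights))
        self._raw.append(roi_value)

        if self.baseline is None and volume_index >= self.baseline_window[1]:
            self.baseline = estimate_baseline(self._raw, self.baseline_window)

        pre_baseline = self.baseline is None
        if pre_baseline:
            scaled = float("nan")
            displayed = float("nan")
        else:
            scaled = scale_to_display(roi_value, self.baseline)
            displayed = scaled * self.mapping.sign
            self._history.append(displayed)
            if len(self._history) > HISTORY_LENGTH:
                self._history = self._history[-HISTORY_LENGTH:]

        if pre_baseline:
            visible = False
        elif self._visible_volumes is None:
            visible = True
        else:
            visible = volume_index in self._visible_volumes

        frame = FeedbackFrame(
            volume_index=volume_index,
            roi_value=roi_value,
            scaled=scaled,
            displayed=displayed,
            visible=visible,
            pre_baseline=pre_baseline,
            history=tuple(self._history),
        )
        self.frames.append(frame)
        return frame

    def run(self, roi_values_per_echo: np.ndarray) -> pd.DataFrame:
        """Process a whole (n_echoes, n_volumes) ROI series and return the log."""
        arr = np.asarray(roi_values_per_echo, dtype=float)
        if arr.ndim != 2:
            raise ValueError("expected (n_echoes, n_volumes) ROI series")
        for v in range(arr.shape[1]):
            self.step(arr[:, v])
        return self.frame_log()

    def frame_log(self) -> pd.DataFrame:
        """Frame log as a table (volume_index, roi_value, scaled, displayed, visible)."""
        return pd.DataFrame(
            {
                "volume_index": [f.volume_index for f in self.frames],
                "roi_value": [f.roi_value for f in self.frames],
                "scaled": [f.scaled for f in self.frames],
                "displayed": [f.displayed for f in self.frames],
                "visible": [int(f.visible) for f in self.frames],
            }
        )
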