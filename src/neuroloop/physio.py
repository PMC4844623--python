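"""Heart-rate and respiration-volume-per-time extraction and condition summaries.

Pulse and respiration-belt waveforms are reduced to per-TR time courses:

* HR: 60 / inter-beat interval (bpm), placed at beat midpoints and linearly
  interpolated onto the TR grid.
* RVT: per breath, (inspiration peak - following trough) divided by the
  breath-to-breath period, interpolated onto the TR grid.  For a pure
  sinusoid of amplitude A and period T this equals 2A/T.

Quality control flags traces with signal loss or excessive flat plateaus;
condition summaries average the derived series within UP/DOWN/REST blocks and
report the UP-DOWN difference relative to the REST mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .design import BlockSchedule, Condition

#: peak prominence threshold as a fraction of the waveform SD
PROMINENCE_FACTOR = 0.3
#: minimum inter-peak distance as a fraction of the median period
MIN_DISTANCE_FACTOR = 0.5

#: QC: identical consecutive samples longer than this count as a plateau run
PLATEAU_RUN_S = 2.0
#: QC: flag when plateau runs cover more than this fraction of the trace
PLATEAU_FRACTION = 0.10
#: QC: |signal| below this fraction of the range counts as lost signal ...
LOSS_LEVEL_FRACTION = 0.01
#: ... when sustained longer than this
LOSS_RUN_S = 5.0


@dataclass
class QCResult:
    usable: bool
    reasons: list[str]


@dataclass
class PhysioDerived:
    """Per-TR derived series for one run."""

    hr: np.ndarray
    rvt: np.ndarray
    qc: QCResult


@dataclass(frozen=True)
class ConditionSummary:
    """Condition means of a per-TR series and the relative UP-DOWN difference.

    ``relative_up_down`` is (mean_up - mean_down) / mean_rest, defined only
    for a nonzero REST mean.
    """

    mean_up: float
    mean_down: float
    mean_rest: float

    @property
    def relative_up_down(self) -> float:
        if self.mean_rest == 0:
            raise ZeroDivisionError("REST mean is zero; relative difference undefined")
        return (self.mean_up - self.mean_down) / self.mean_rest


def detect_peaks(
    waveform: np.ndarray,
    fs: float,
    prominence_factor: float = PROMINENCE_FACTOR,
    min_distance_factor: float = MIN_DISTANCE_FACTOR,
) -> np.ndarray:
    """Peak times (s) of a quasi-periodic waveform.

    The trace is lightly smoothed (0.1 s moving average, which preserves the
    location of symmetric peaks) before a two-pass detection: an initial pass
    thresholded at ``prominence_factor * SD`` estimates the median period, a
    second pass additionally enforces a minimum spacing of
    ``min_distance_factor`` median periods.  A flat waveform yields no peaks.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    w = np.asarray(waveform, dtype=float)
    if w.size < 3 or w.max() == w.min():
        return np.empty(0)
    width = max(1, int(round(0.1 * fs)))
    if w.size >= width > 1:
        from scipy.ndimage import uniform_filter1d

        w = uniform_filter1d(w, width, mode="nearest")
    sd = w.std()
    if sd == 0:
        return np.empty(0)
    # normalize so detection is exactly invariant to amplitude scaling
    w = w / sd
    prominence = prominence_factor
    peaks, _ = find_peaks(w, prominence=prominence)
    if peaks.size >= 3:
        median_period = float(np.median(np.diff(peaks)))
        distance = max(1, int(round(min_distance_factor * median_period)))
        peaks, _ = find_peaks(w, prominence=prominence, distance=distance)
    return peaks / fs


def heart_rate(peak_times: np.ndarray, tr_grid: np.ndarray) -> np.ndarray:
    """Beats-per-minute series on the TR grid from pulse peak times.

    Instantaneous HR (60 / inter-beat interval) is placed at each beat-pair
    midpoint and linearly interpolated; the grid edges take the nearest value.
    Fewer than two peaks make HR undefined.
    """
    peak_times = np.asarray(peak_times, dtype=float)
    if peak_times.size < 2:
        raise ValueError("need at least 2 pulse peaks to compute heart rate")
    ibi = np.diff(peak_times)
    if np.any(ibi <= 0):
        raise ValueError("peak times must be strictly increasing")
    hr = 60.0 / ibi
    mid = (peak_times[:-1] + peak_times[1:]) / 2.0
    return np.interp(np.asarray(tr_grid, dtype=float), mid, hr)


def rvt(
    respiration: np.ndarray,
    fs: float,
    tr_grid: np.ndarray,
    prominence_factor: float = PROMINENCE_FACTOR,
    min_distance_factor: float = MIN_DISTANCE_FACTOR,
) -> np.ndarray:
    """Respiration volume per time on the TR grid.

    For each consecutive pair of inspiration peaks, the breath depth is the
    peak value minus the deepest trough between the peaks, and the breath
    period is the peak-to-peak interval; their ratio is placed at the
    interval midpoint and interpolated onto the grid.
    """
    w = np.asarray(respiration, dtype=float)
    peak_t = detect_peaks(w, fs, prominence_factor, min_distance_factor)
    if peak_t.size < 2:
        raise ValueError("need at least 2 breaths to compute RVT")
    peak_idx = np.round(peak_t * fs).astype(int)
    values = []
    times = []
    for i in range(peak_idx.size - 1):
        a, b = peak_idx[i], peak_idx[i + 1]
        trough = float(w[a : b + 1].min())
        depth = float(w[a]) - trough
        period = (b - a) / fs
        values.append(depth / period)
        times.append((peak_t[i] + peak_t[i + 1]) / 2.0)
    return np.interp(np.asarray(tr_grid, dtype=float), np.asarray(times), np.asarray(values))


def _flat_run_samples(w: np.ndarray, min_run: int) -> int:
    """Total samples inside runs of >= min_run identical consecutive values."""
    if w.size == 0:
        return 0
    change = np.flatnonzero(np.diff(w) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [w.size]))
    lengths = ends - starts
    return int(lengths[lengths >= min_run].sum())


def qc_waveform(waveform: np.ndarray, fs: float) -> QCResult:
    """Flag signal loss and excessive plateaus in a raw waveform.

    * "loss of signal": |signal| stays below 1% of the trace range for more
      than 5 s (an all-flat trace is degenerate loss).
    * "excessive signal plateaus": runs of identical consecutive samples
      longer than 2 s covering more than 10% of the trace.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    w = np.asarray(waveform, dtype=float)
    reasons: list[str] = []
    rng = float(w.max() - w.min()) if w.size else 0.0

    if w.size == 0 or rng == 0.0:
        reasons.append("loss of signal")
        return QCResult(usable=False, reasons=reasons)

    near_zero = (np.abs(w) < LOSS_LEVEL_FRACTION * rng).astype(float)
    min_loss_run = int(np.ceil(LOSS_RUN_S * fs))
    # longest run of near-zero samples
    padded = np.concatenate(([0.0], near_zero, [0.0]))
    edges = np.flatnonzero(np.diff(padded) != 0)
    if edges.size:
        run_lengths = edges[1::2] - edges[::2]
        if run_lengths.size and run_lengths.max() > min_loss_run:
            reasons.append("loss of signal")

    min_plateau_run = int(np.ceil(PLATEAU_RUN_S * fs))
    flat = _flat_run_samples(w, min_plateau_run)
    if flat / w.size > PLATEAU_FRACTION:
        reasons.append("excessive signal plateaus")

    return QCResult(usable=not reasons, reasons=reasons)


def derive_physio(
    respiration: np.ndarray,
    pulse: np.ndarray,
    fs: float,
    n_volumes: int,
    tr_seconds: float,
) -> PhysioDerived:
    """QC both waveforms and extract per-TR HR and RVT series.

    TR bins are centered (grid point at the middle of each TR).  If either
    waveform fails QC or has too few peaks, the run is marked unusable and
    the series are NaN.
    """
    tr_grid = (np.arange(n_volumes) + 0.5) * tr_seconds
    reasons = []
    for name, w in (("respiration", respiration), ("pulse", pulse)):
        qc = qc_waveform(w, fs)
        reasons.extend(f"{name}: {r}" for r in qc.reasons)
    hr_series = np.full(n_volumes, np.nan)
    rvt_series = np.full(n_volumes, np.nan)
    if not reasons:
        try:
            hr_series = heart_rate(detect_peaks(pulse, fs), tr_grid)
            rvt_series = rvt(respiration, fs, tr_grid)
        except ValueError as exc:
            reasons.append(str(exc))
    return PhysioDerived(hr=hr_series, rvt=rvt_series, qc=QCResult(not reasons, reasons))


def condition_summary(
    series: np.ndarray,
    schedule: BlockSchedule,
    lag_trs: int = 0,
) -> ConditionSummary:
    """Condition means of a per-TR series.

    ``lag_trs`` shifts condition labels later by that many TRs to allow for
    response latency (default 0 for physiological series).  EoBF display TRs
    belong to no condition.  An empty condition is an error.
    """
    x = np.asarray(series, dtype=float)
    labels = schedule.volume_labels()
    if x.size != len(labels):
        raise ValueError(
            f"series has {x.size} bins but schedule implies {len(labels)} volumes"
        )
    if lag_trs:
        labels = [None] * lag_trs + labels[: len(labels) - lag_trs]
    means = {}
    for cond in (Condition.UP, Condition.DOWN, Condition.REST):
        sel = np.array([lab == cond.value for lab in labels])
        sel &= ~np.isnan(x)
        if not sel.any():
            raise ValueError(f"no usable {cond.value} bins in this run")
        means[cond] = float(x[sel].mean())
    return ConditionSummary(
        mean_up=means[Condition.UP],
        mean_down=means[Condition.DOWN],
        mean_rest=means[Condition.REST],
    )
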