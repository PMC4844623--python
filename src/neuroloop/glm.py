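"""Offline per-run GLM analysis: HRF, design matrix, OLS fit, percent signal change.

The per-run model regresses the ROI (or voxel) time series on canonical-HRF
convolved boxcars for the UP and DOWN regulation conditions (REST is the
implicit baseline), an optional feedback-display regressor for EoBF runs, six
motion parameters if supplied, a discrete-cosine high-pass basis below
1/128 Hz, and a constant.  Condition coefficients are converted to percent
signal change with

    PSC = beta * max(single event (x) HRF) * 100 / beta_constant

where the "single event" is a one-TR boxcar convolved with the HRF on the
microtime grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .design import (
    DISPLAY_LABEL,
    AcquisitionParams,
    BlockSchedule,
    Condition,
    FeedbackType,
)

#: microtime bins per TR used for boxcar convolution
MICROTIME_RESOLUTION = 16

#: default high-pass cutoff (Hz); fluctuations slower than 128 s are nuisance
DEFAULT_HP_CUTOFF_HZ = 1.0 / 128.0

MOTION_COLUMNS = ("mot_1", "mot_2", "mot_3", "mot_4", "mot_5", "mot_6")


class RankDeficientDesignError(ValueError):
    """Raised when the design matrix has linearly dependent columns."""


@dataclass(frozen=True)
class HRFModel:
    """Canonical double-gamma hemodynamic response function.

    ``kernel`` is sampled every ``dt`` seconds over 32 s and normalized to
    unit peak.  ``single_event_peak`` is the maximum of a one-TR event
    convolved with the kernel (continuous-convolution approximation, i.e.
    discrete convolution times dt); it is the scale factor of the PSC formula.
    """

    kernel: np.ndarray
    dt: float
    single_event_peak: float

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.single_event_peak <= 0:
            raise ValueError("single_event_peak must be positive")

    def convolve(self, fine_series: np.ndarray) -> np.ndarray:
        """Causal convolution of a microtime series with the kernel (times dt)."""
        fine_series = np.asarray(fine_series, dtype=float)
        return np.convolve(fine_series, self.kernel)[: fine_series.size] * self.dt


def canonical_hrf(
    dt: float,
    tr_seconds: float = 2.54,
    *,
    duration_s: float = 32.0,
    response_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    response_dispersion: float = 1.0,
    undershoot_dispersion: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> HRFModel:
    """Sample the canonical double-gamma HRF on a microtime grid.

    The kernel is the difference of two gamma densities (response peak near
    5 s, undershoot near 15 s), truncated at 32 s and normalized to unit
    peak.  ``tr_seconds`` defines the one-TR "single event" whose convolution
    peak is stored for PSC conversion.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, duration_s + dt / 2, dt)
    kernel = (
        gamma_dist.pdf(t, response_delay / response_dispersion, scale=response_dispersion)
        - undershoot_ratio
        * gamma_dist.pdf(t, undershoot_delay / undershoot_dispersion, scale=undershoot_dispersion)
    )
    kernel = kernel / kernel.max()
    n_event = max(1, int(round(tr_seconds / dt)))
    event = np.ones(n_event)
    single_event_peak = float((np.convolve(event, kernel) * dt).max())
    return HRFModel(kernel=kernel, dt=dt, single_event_peak=single_event_peak)


def _fine_boxcars(
    schedule: BlockSchedule, oversample: int = MICROTIME_RESOLUTION
) -> dict[str, np.ndarray]:
    """Microtime indicator series for each condition label present in the run."""
    labels = schedule.volume_labels()
    out: dict[str, np.ndarray] = {}
    wanted = [Condition.UP.value, Condition.DOWN.value]
    if schedule.feedback_type is FeedbackType.EOBF:
        wanted.append(DISPLAY_LABEL)
    for name in wanted:
        per_vol = np.array([1.0 if lab == name else 0.0 for lab in labels])
        out[name] = np.repeat(per_vol, oversample)
    return out


def condition_regressors(
    schedule: BlockSchedule,
    acq: AcquisitionParams,
    hrf: HRFModel | None = None,
    oversample: int = MICROTIME_RESOLUTION,
) -> dict[str, np.ndarray]:
    """HRF-convolved condition regressors sampled once per volume.

    Boxcars are built on a microtime grid of ``oversample`` bins per TR,
    convolved with the kernel, and sampled at each volume onset.  The same
    routine serves the design matrix and the synthetic-data generator, so the
    two agree on the convolution convention by construction.
    """
    dt = acq.tr_seconds / oversample
    if hrf is None:
        hrf = canonical_hrf(dt, acq.tr_seconds)
    elif abs(hrf.dt - dt) > 1e-12:
        raise ValueError("hrf.dt does not match acq.tr_seconds / oversample")
    out = {}
    for name, box in _fine_boxcars(schedule, oversample).items():
        fine = hrf.convolve(box)
        out[name] = fine[::oversample].copy()
    return out


def dct_highpass_basis(
    n_volumes: int, tr_seconds: float, cutoff_hz: float = DEFAULT_HP_CUTOFF_HZ
) -> np.ndarray:
    """Discrete-cosine drift basis with frequencies below ``cutoff_hz``.

    The number of components is floor(2 * N * TR * cutoff), the standard
    count of DCT-II basis functions with period longer than the cutoff
    period.  Returns an (N, K) array; K may be zero for short runs.
    """
    n_basis = int(np.floor(2.0 * n_volumes * tr_seconds * cutoff_hz))
    t = np.arange(n_volumes)
    cols = [
        np.sqrt(2.0 / n_volumes) * np.cos(np.pi * (2 * t + 1) * k / (2.0 * n_volumes))
        for k in range(1, n_basis + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


@dataclass
class DesignMatrix:
    """Named per-volume regressors; the constant column is always last."""

    frame: pd.DataFrame
    hrf: HRFModel
    tr_seconds: float

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_volumes(self) -> int:
        return len(self.frame)

    @property
    def condition_columns(self) -> list[str]:
        return [c for c in (Condition.UP.value, Condition.DOWN.value) if c in self.frame]


def build_design(
    schedule: BlockSchedule,
    acq: AcquisitionParams,
    motion: pd.DataFrame | np.ndarray | None = None,
    hp_cutoff_hz: float | None = DEFAULT_HP_CUTOFF_HZ,
    hrf: HRFModel | None = None,
    n_volumes: int | None = None,
) -> DesignMatrix:
    """Assemble the per-run design matrix.

    Columns, in order: UP, DOWN, FEEDBACK_DISPLAY (EoBF runs only), six
    motion parameters (if given), the high-pass set (a centered linear trend
    plus the discrete-cosine basis below the cutoff), constant.
    """
    if n_volumes is None:
        n_volumes = schedule.n_volumes
    if n_volumes != schedule.n_volumes:
        raise ValueError(
            f"schedule implies {schedule.n_volumes} volumes but {n_volumes} requested"
        )
    dt = acq.tr_seconds / MICROTIME_RESOLUTION
    if hrf is None:
        hrf = canonical_hrf(dt, acq.tr_seconds)
    regs = condition_regressors(schedule, acq, hrf)

    data: dict[str, np.ndarray] = {}
    for cond in (Condition.UP.value, Condition.DOWN.value):
        if cond in regs:
            data[cond] = regs[cond]
    if DISPLAY_LABEL in regs:
        data["FEEDBACK_DISPLAY"] = regs[DISPLAY_LABEL]

    if motion is not None:
        mot = np.asarray(motion, dtype=float)
        if mot.ndim != 2 or mot.shape[1] != 6:
            raise ValueError("motion table must have exactly 6 columns")
        if mot.shape[0] != n_volumes:
            raise ValueError(
                f"motion table has {mot.shape[0]} rows, expected {n_volumes}"
            )
        for i, name in enumerate(MOTION_COLUMNS):
            data[name] = mot[:, i]

    if hp_cutoff_hz is not None:
        # centered linear term first: scanner drift is dominantly linear and a
        # finite cosine set only approximates it
        t = np.arange(n_volumes, dtype=float)
        lin = t - t.mean()
        data["hp_linear"] = lin / np.sqrt((lin**2).sum())
        basis = dct_highpass_basis(n_volumes, acq.tr_seconds, hp_cutoff_hz)
        for k in range(basis.shape[1]):
            data[f"hp_{k + 1}"] = basis[:, k]

    data["constant"] = np.ones(n_volumes)
    frame = pd.DataFrame(data)
    return DesignMatrix(frame=frame, hrf=hrf, tr_seconds=acq.tr_seconds)


@dataclass
class GLMFit:
    """Ordinary least-squares fit of one time series on a design matrix."""

    betas: pd.Series
    residual_variance: float
    df_resid: int
    design: DesignMatrix
    fitted: np.ndarray
    residuals: np.ndarray

    @property
    def beta_constant(self) -> float:
        return float(self.betas["constant"])


def _collinear_columns(matrix: np.ndarray, columns: list[str]) -> list[str]:
    """Name columns implicated in a rank deficiency via pivoted QR."""
    from scipy.linalg import qr

    _, r, piv = qr(matrix, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(matrix.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    return sorted(columns[i] for i in piv[rank:])


def fit(series: np.ndarray, design: DesignMatrix) -> GLMFit:
    """Fit a single time series by ordinary least squares.

    Raises :class:`RankDeficientDesignError` naming the dependent columns if
    the design is not full rank.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ValueError("series must be one-dimensional; use fit_voxels for volumes")
    x = design.matrix
    if y.size != x.shape[0]:
        raise ValueError(
            f"series has {y.size} volumes but design has {x.shape[0]} rows"
        )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = _collinear_columns(x, design.columns)
        raise RankDeficientDesignError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ coef
    resid = y - fitted
    df = y.size - x.shape[1]
    resid_var = float(resid @ resid / df) if df > 0 else 0.0
    return GLMFit(
        betas=pd.Series(coef, index=design.columns),
        residual_variance=resid_var,
        df_resid=df,
        design=design,
        fitted=fitted,
        residuals=resid,
    )


def fit_voxels(data: np.ndarray, design: DesignMatrix) -> pd.DataFrame:
    """OLS fit of many voxel time series at once.

    ``data`` is (n_voxels, n_volumes); returns a DataFrame of betas with one
    row per voxel and one column per regressor.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 2:
        raise ValueError("data must be (n_voxels, n_volumes)")
    x = design.matrix
    if y.shape[1] != x.shape[0]:
        raise ValueError("volume count mismatch between data and design")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = _collinear_columns(x, design.columns)
        raise RankDeficientDesignError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )
    coef, _, _, _ = np.linalg.lstsq(x, y.T, rcond=None)
    return pd.DataFrame(coef.T, columns=design.columns)


@dataclass(frozen=True)
class PSCResult:
    """Percent-signal-change values and the three run contrasts.

    With REST as the implicit baseline, UP-REST equals psc_up and REST-DOWN
    equals -psc_down by construction.
    """

    psc_up: float
    psc_down: float

    @property
    def up_down(self) -> float:
        return self.psc_up - self.psc_down

    @property
    def up_rest(self) -> float:
        return self.psc_up

    @property
    def rest_down(self) -> float:
        return -self.psc_down

    def as_dict(self) -> dict[str, float]:
        return {
            "psc_up": self.psc_up,
            "psc_down": self.psc_down,
            "up_down": self.up_down,
            "up_rest": self.up_rest,
            "rest_down": self.rest_down,
        }


def to_psc(glm_fit: GLMFit, hrf: HRFModel | None = None) -> PSCResult:
    """Convert condition betas to percent signal change.

    PSC = beta * single_event_peak * 100 / beta_constant.  Raises on a
    zero or near-zero constant term (the run mean), for which percent change
    is undefined.
    """
    if hrf is None:
        hrf = glm_fit.design.hrf
    bc = glm_fit.beta_constant
    scale = float(np.max(np.abs(glm_fit.betas.to_numpy()))) or 1.0
    if abs(bc) < 1e-10 * scale or bc == 0.0:
        raise ValueError("beta_constant is zero or near zero; PSC undefined")

    def one(cond: str) -> float:
        if cond not in glm_fit.betas.index:
            return 0.0
        return float(glm_fit.betas[cond] * hrf.single_event_peak * 100.0 / bc)

    return PSCResult(psc_up=one(Condition.UP.value), psc_down=one(Condition.DOWN.value))


def roi_psc(
    voxel_betas: pd.DataFrame,
    mask: np.ndarray,
    hrf: HRFModel,
) -> PSCResult:
    """Average voxelwise PSC contrasts over an ROI mask.

    ``voxel_betas`` must carry one row per voxel of the full grid (flattened
    C-order) or one row per in-mask voxel; ``mask`` is the boolean grid.
    """
    mask = np.asarray(mask, dtype=bool)
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ValueError("empty ROI mask")
    if len(voxel_betas) == mask.size:
        betas = voxel_betas.iloc[np.flatnonzero(mask.ravel())]
    elif len(voxel_betas) == n_mask:
        betas = voxel_betas
    else:
        raise ValueError("voxel_betas rows match neither grid size nor mask size")

    bc = betas["constant"].to_numpy()
    if np.any(np.abs(bc) < 1e-12):
        raise ValueError("near-zero constant beta inside mask; PSC undefined")

    def mean_psc(cond: str) -> float:
        if cond not in betas.columns:
            return 0.0
        vals = betas[cond].to_numpy() * hrf.single_event_peak * 100.0 / bc
        return float(vals.mean())

    return PSCResult(
        psc_up=mean_psc(Condition.UP.value), psc_down=mean_psc(Condition.DOWN.value)
    )
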