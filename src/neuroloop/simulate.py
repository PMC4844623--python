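"""Synthetic multi-echo fMRI, physiology, and cohort fixtures with known truth.

Every downstream stage (real-time feedback, GLM/PSC, physiology, group
statistics) is exercised against data from this module, whose ground truth is
recorded explicitly:

* ROI signal: mono-exponential multi-echo decay ``s0 * exp(-TE/T2*)``
  modulated by a block-design BOLD response common to all echoes, plus white
  noise and a linear drift per echo.
* The BOLD effect amplitude is expressed in *single-event-peak units*: an
  amplitude ``a`` means a single one-TR event would peak at a fractional
  signal change of ``a``, so the offline PSC estimate of a condition with
  amplitude ``a`` is ``100 * a`` percent at zero noise.  This is a deliberate
  simplification (a fractional modulation rather than a T2* perturbation).
* Physiology: an amplitude-modulated sinusoidal respiration trace and a
  periodic peaked pulse waveform, optionally with condition-locked breathing
  amplitude changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import (
    DISPLAY_LABEL,
    AcquisitionParams,
    BlockSchedule,
    Condition,
    DirectionMapping,
    FeedbackType,
    assign_direction_mapping,
    generate_schedule,
)
from .glm import MICROTIME_RESOLUTION, HRFModel, canonical_hrf, condition_regressors

#: default synthetic volume grid (x, y, z) and ROI radius in voxels
VOLUME_GRID = (12, 12, 8)
ROI_RADIUS_VOX = 2.0


@dataclass(frozen=True)
class SubjectParams:
    """Ground-truth generative parameters for one synthetic subject.

    ``effect_up``/``effect_down`` are fractional BOLD amplitudes in
    single-event-peak units (0.002 = 0.2% PSC).  ``noise_sd`` is per-echo
    white noise; ``drift_slope`` a linear trend per volume, both in the
    arbitrary units of ``s0``.
    """

    s0: float = 1000.0
    t2star_rest_ms: float = 30.0
    effect_up: float = 0.002
    effect_down: float = -0.002
    noise_sd: float = 4.0
    drift_slope: float = 0.02
    breath_period_s: float = 4.0
    breath_amp: float = 1.0
    pulse_rate_hz: float = 1.1

    def __post_init__(self) -> None:
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")
        if self.t2star_rest_ms <= 0:
            raise ValueError("t2star_rest_ms must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.breath_period_s <= 0:
            raise ValueError("breath_period_s must be positive")

    @property
    def true_up_down_psc(self) -> float:
        """Ground-truth UP-DOWN percent-signal-change contrast."""
        return 100.0 * (self.effect_up - self.effect_down)


@dataclass
class MultiEchoSeries:
    """Per-echo signal: (n_echoes, n_volumes) in ROI mode or
    (n_echoes, x, y, z, n_volumes) in volume mode (with a boolean mask)."""

    data: np.ndarray
    acq: AcquisitionParams
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.data.shape[0] != self.acq.n_echoes:
            raise ValueError("first axis of data must index echoes")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def is_volume_mode(self) -> bool:
        return self.data.ndim == 5

    def roi_series(self) -> np.ndarray:
        """(n_echoes, n_volumes) ROI-mean series (identity in ROI mode)."""
        if not self.is_volume_mode:
            return self.data
        if self.mask is None:
            raise ValueError("volume-mode series requires a mask for ROI extraction")
        m = np.asarray(self.mask, dtype=bool)
        return self.data[:, m, :].mean(axis=1)


@dataclass
class PhysioTraces:
    """Sampled respiration and pulse waveforms at a common rate ``fs``."""

    respiration: np.ndarray
    pulse: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.respiration.shape != self.pulse.shape:
            raise ValueError("respiration and pulse must have equal length")

    @property
    def duration_s(self) -> float:
        return self.respiration.size / self.fs


def ideal_bold(
    schedule: BlockSchedule,
    effects: dict[Condition | str, float],
    acq: AcquisitionParams,
    hrf: HRFModel | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Noise-free fractional BOLD time course for a run.

    Sum over conditions of amplitude x (12-TR boxcar convolved with the
    canonical HRF), sampled once per volume.  With ``normalize`` (default)
    the convolved response is divided by the HRF's single-event peak so that
    amplitudes are in single-event-peak units (see module docstring).
    """
    if hrf is None:
        hrf = canonical_hrf(acq.tr_seconds / MICROTIME_RESOLUTION, acq.tr_seconds)
    regs = condition_regressors(schedule, acq, hrf)
    out = np.zeros(schedule.n_volumes)
    for cond, amp in effects.items():
        name = cond.value if isinstance(cond, Condition) else str(cond)
        if name not in regs:
            if amp != 0.0 and name not in (Condition.REST.value,):
                raise ValueError(f"no regressor for condition {name!r} in this run")
            continue
        out = out + amp * regs[name]
    if normalize:
        out = out / hrf.single_event_peak
    return out


def _roi_mask(grid: tuple[int, int, int] = VOLUME_GRID, radius: float = ROI_RADIUS_VOX) -> np.ndarray:
    """Spherical stand-in ROI mask at the grid center."""
    zz = np.indices(grid, dtype=float)
    center = (np.asarray(grid, dtype=float) - 1.0) / 2.0
    dist2 = sum((zz[i] - center[i]) ** 2 for i in range(3))
    return dist2 <= radius**2


def simulate_multiecho(
    schedule: BlockSchedule,
    acq: AcquisitionParams,
    subject: SubjectParams,
    seed: int = 0,
    mode: str = "roi",
    hrf: HRFModel | None = None,
    grid: tuple[int, int, int] = VOLUME_GRID,
) -> MultiEchoSeries:
    """Generate a multi-echo run with the subject's ground-truth effects.

    Echo ``n`` fluctuates around ``s0 * exp(-TE_n / T2*)``; the BOLD effect
    multiplies the decayed baseline identically across echoes (so the
    fractional effect is TE-independent); white noise (sd ``noise_sd``) and a
    centered linear drift (slope ``drift_slope`` per volume) are added per
    echo.  In volume mode the BOLD effect is confined to a spherical ROI mask
    and each voxel receives independent noise.
    """
    if mode not in ("roi", "volume"):
        raise ValueError("mode must be 'roi' or 'volume'")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 11]))
    bold = ideal_bold(
        schedule,
        {Condition.UP: subject.effect_up, Condition.DOWN: subject.effect_down},
        acq,
        hrf,
    )
    n_vol = schedule.n_volumes
    tes = np.asarray(acq.echo_times_ms, dtype=float)
    decay = subject.s0 * np.exp(-tes / subject.t2star_rest_ms)  # (E,)
    drift = subject.drift_slope * (np.arange(n_vol) - (n_vol - 1) / 2.0)

    if mode == "roi":
        clean = decay[:, None] * (1.0 + bold)[None, :] + drift[None, :]
        noise = rng.normal(0.0, subject.noise_sd, size=clean.shape)
        return MultiEchoSeries(data=clean + noise, acq=acq)

    mask = _roi_mask(grid)
    shape = (acq.n_echoes, *grid, n_vol)
    data = np.empty(shape)
    base = decay[:, None] * (1.0 + 0.0 * bold)[None, :] + drift[None, :]  # (E, T)
    in_roi = decay[:, None] * (1.0 + bold)[None, :] + drift[None, :]
    data[:] = base[:, None, None, None, :]
    data[:, mask, :] = in_roi[:, None, :]
    data += rng.normal(0.0, subject.noise_sd, size=shape)
    return MultiEchoSeries(data=data, acq=acq, mask=mask)


def _condition_factor(
    t: np.ndarray,
    schedule: BlockSchedule | None,
    tr_seconds: float,
    modulation: dict[Condition | str, float] | None,
) -> np.ndarray:
    """Per-sample breathing amplitude factor from condition-locked modulation."""
    factor = np.ones_like(t)
    if not modulation or schedule is None:
        return factor
    mod = {
        (k.value if isinstance(k, Condition) else str(k)): float(v)
        for k, v in modulation.items()
    }
    labels = schedule.volume_labels()
    for i, lab in enumerate(labels):
        f = mod.get(lab)
        if f is None or f == 1.0:
            continue
        sel = (t >= i * tr_seconds) & (t < (i + 1) * tr_seconds)
        factor[sel] = f
    return factor


def simulate_physio(
    duration_s: float,
    subject: SubjectParams,
    condition_modulation: dict[Condition | str, float] | None = None,
    seed: int = 0,
    fs: float = 50.0,
    schedule: BlockSchedule | None = None,
    tr_seconds: float = 2.54,
    noise_sd: float = 0.02,
) -> PhysioTraces:
    """Respiration-belt and pulse-plethysmograph style waveforms.

    Respiration is a sinusoid of period ``breath_period_s`` whose amplitude
    is ``breath_amp`` times an optional condition-locked factor; pulse is a
    raised-cosine-power spike train at ``pulse_rate_hz``.  Both carry small
    additive white noise.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 23]))
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    factor = _condition_factor(t, schedule, tr_seconds, condition_modulation)
    resp = (
        subject.breath_amp * factor * np.sin(2.0 * np.pi * t / subject.breath_period_s)
        + rng.normal(0.0, noise_sd, size=n)
    )
    pulse = (
        0.5 * (1.0 - np.cos(2.0 * np.pi * subject.pulse_rate_hz * t))
    ) ** 4 + rng.normal(0.0, noise_sd, size=n)
    return PhysioTraces(respiration=resp, pulse=pulse, fs=fs)


@dataclass(frozen=True)
class SubjectSpec:
    """One cohort member: identity, mapping, seed, and generative truth."""

    subject_id: int
    seed: int
    mapping: DirectionMapping
    params: SubjectParams

    @property
    def true_up_down_psc(self) -> float:
        return self.params.true_up_down_psc


@dataclass
class Cohort:
    """A simulated study cohort with per-subject ground truth."""

    subjects: list[SubjectSpec]
    effect_mean_psc: float
    effect_sd_psc: float
    seed: int

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def true_cohens_d(self) -> float:
        return self.effect_mean_psc / self.effect_sd_psc

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "seed": [s.seed for s in self.subjects],
                "left_means": [s.mapping.left_means.value for s in self.subjects],
                "true_up_down_psc": [s.true_up_down_psc for s in self.subjects],
                "effect_up": [s.params.effect_up for s in self.subjects],
                "effect_down": [s.params.effect_down for s in self.subjects],
                "noise_sd": [s.params.noise_sd for s in self.subjects],
            }
        )


def make_cohort(
    n_subjects: int,
    effect_mean_psc: float = 0.43,
    effect_sd_psc: float = 1.0,
    seed: int = 0,
    base_params: SubjectParams | None = None,
) -> Cohort:
    """Draw a cohort whose per-subject UP-DOWN PSC effects are
    N(effect_mean_psc, effect_sd_psc), so the true Cohen's d is mean/SD.

    Each subject's effect is split symmetrically between up- and
    down-regulation; direction mappings alternate so even cohorts are
    exactly balanced.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if effect_sd_psc <= 0:
        raise ValueError("effect_sd_psc must be positive")
    if base_params is None:
        base_params = SubjectParams()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 5]))
    deltas = rng.normal(effect_mean_psc, effect_sd_psc, size=n_subjects)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    subjects = []
    for i in range(n_subjects):
        frac = deltas[i] / 100.0  # percent -> fractional amplitude
        params = replace(base_params, effect_up=frac / 2.0, effect_down=-frac / 2.0)
        subjects.append(
            SubjectSpec(
                subject_id=i,
                seed=int(sub_seeds[i]),
                mapping=assign_direction_mapping(i),
                params=params,
            )
        )
    return Cohort(
        subjects=subjects,
        effect_mean_psc=effect_mean_psc,
        effect_sd_psc=effect_sd_psc,
        seed=seed,
    )
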