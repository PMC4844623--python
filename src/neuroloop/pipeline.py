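"""End-to-end cohort pipeline: simulate, analyze per subject, test at group level.

``run_pipeline`` mirrors one transfer-style run per subject: a balanced block
schedule is sampled, multi-echo ROI data are generated with the subject's
ground-truth effect, echoes are combined with the fixed TE weights, the
combined series is fit with the UP/DOWN GLM, and the per-subject UP-DOWN PSC
contrasts enter a one-tailed group t-test and a bootstrap Cohen's d CI.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import glm as glm_mod
from . import io as io_mod
from . import physio as physio_mod
from . import realtime, stats
from .design import (
    AcquisitionParams,
    BlockSchedule,
    Condition,
    FeedbackType,
    generate_schedule,
)
from .simulate import (
    Cohort,
    MultiEchoSeries,
    SubjectParams,
    SubjectSpec,
    make_cohort,
    simulate_multiecho,
    simulate_physio,
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class SubjectResult:
    subject_id: int
    psc: glm_mod.PSCResult
    true_up_down_psc: float
    physio_summary: dict[str, float] | None = None


@dataclass
class CohortReport:
    """Group-level outcome of one simulated cohort."""

    per_subject: pd.DataFrame
    d: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p: float
    true_d: float
    seed: int

    def as_dict(self) -> dict[str, float]:
        return {
            "d": self.d,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "true_d": self.true_d,
            "n": len(self.per_subject),
        }


def analyze_subject_run(
    series: MultiEchoSeries,
    schedule: BlockSchedule,
    motion: np.ndarray | None = None,
    hrf: glm_mod.HRFModel | None = None,
) -> glm_mod.PSCResult:
    """Offline analysis of one run: combine echoes, fit the GLM, convert to PSC."""
    weights = realtime.te_weights(series.acq.echo_times_ms, series.acq.t2star_ms)
    combined = realtime.combine_echoes(series.roi_series(), weights)
    design = glm_mod.build_design(schedule, series.acq, motion=motion, hrf=hrf)
    fit = glm_mod.fit(np.asarray(combined), design)
    return glm_mod.to_psc(fit)


def simulate_and_analyze_subject(
    spec: SubjectSpec,
    acq: AcquisitionParams,
    n_per_condition: int = 8,
    feedback_type: FeedbackType | str = FeedbackType.NONE,
    hrf: glm_mod.HRFModel | None = None,
    with_physio: bool = False,
    physio_fs: float = 50.0,
) -> SubjectResult:
    """One subject through the full generate -> analyze chain."""
    schedule = generate_schedule(
        n_per_condition, feedback_type, seed=spec.seed, mapping=spec.mapping
    )
    series = simulate_multiecho(schedule, acq, spec.params, seed=spec.seed)
    psc = analyze_subject_run(series, schedule, hrf=hrf)
    physio_summary = None
    if with_physio:
        duration = schedule.n_volumes * acq.tr_seconds
        traces = simulate_physio(
            duration,
            spec.params,
            seed=spec.seed,
            fs=physio_fs,
            schedule=schedule,
            tr_seconds=acq.tr_seconds,
        )
        derived = physio_mod.derive_physio(
            traces.respiration, traces.pulse, traces.fs, schedule.n_volumes, acq.tr_seconds
        )
        physio_summary = {"usable": float(derived.qc.usable)}
        if derived.qc.usable:
            for name, series_tr in (("hr", derived.hr), ("rvt", derived.rvt)):
                summ = physio_mod.condition_summary(series_tr, schedule)
                physio_summary[f"{name}_up"] = summ.mean_up
                physio_summary[f"{name}_down"] = summ.mean_down
                physio_summary[f"{name}_rest"] = summ.mean_rest
                physio_summary[f"{name}_relative_up_down"] = summ.relative_up_down
    return SubjectResult(
        subject_id=spec.subject_id,
        psc=psc,
        true_up_down_psc=spec.true_up_down_psc,
        physio_summary=physio_summary,
    )


def evaluate_cohort(
    cohort: Cohort,
    acq: AcquisitionParams | None = None,
    n_per_condition: int = 8,
    feedback_type: FeedbackType | str = FeedbackType.NONE,
    n_boot: int = 1000,
    with_physio: bool = False,
    physio_fs: float = 50.0,
) -> CohortReport:
    """Run every cohort subject through the pipeline and test the group effect."""
    if acq is None:
        acq = AcquisitionParams()
    hrf = glm_mod.canonical_hrf(
        acq.tr_seconds / glm_mod.MICROTIME_RESOLUTION, acq.tr_seconds
    )
    rows = []
    for spec in cohort.subjects:
        try:
            res = simulate_and_analyze_subject(
                spec,
                acq,
                n_per_condition=n_per_condition,
                feedback_type=feedback_type,
                hrf=hrf,
                with_physio=with_physio,
                physio_fs=physio_fs,
            )
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(
                f"subject stage failed for subject {spec.subject_id}: {exc}"
            ) from exc
        row = {
            "subject_id": res.subject_id,
            "true_up_down_psc": res.true_up_down_psc,
            **res.psc.as_dict(),
        }
        if res.physio_summary:
            row.update(res.physio_summary)
        rows.append(row)
    per_subject = pd.DataFrame(rows)

    values = per_subject["up_down"].to_numpy()
    try:
        ttest = stats.t_one_sample(values, tail="one")
        effect = stats.cohens_d_ci(values, n_boot=n_boot, seed=cohort.seed)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"group stage failed: {exc}") from exc
    return CohortReport(
        per_subject=per_subject,
        d=effect.d,
        ci_low=effect.ci_low,
        ci_high=effect.ci_high,
        t=ttest.t,
        df=ttest.df,
        p=ttest.p,
        true_d=cohort.true_cohens_d,
        seed=cohort.seed,
    )


def cohort_monte_carlo(
    n_cohorts: int,
    n_subjects: int = 32,
    effect_mean_psc: float = 0.43,
    effect_sd_psc: float = 1.0,
    seed: int = 0,
    n_per_condition: int = 8,
    n_boot: int = 1000,
    base_params: SubjectParams | None = None,
) -> pd.DataFrame:
    """Replicate the cohort pipeline ``n_cohorts`` times.

    Returns one row per cohort with the estimated d, its bootstrap CI, the
    one-tailed p, and whether the CI covers the true d.  Cohort seeds are
    derived deterministically from ``seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 41]))
    cohort_seeds = rng.integers(0, 2**31 - 1, size=n_cohorts)
    true_d = effect_mean_psc / effect_sd_psc
    rows = []
    for k in range(n_cohorts):
        cohort = make_cohort(
            n_subjects,
            effect_mean_psc=effect_mean_psc,
            effect_sd_psc=effect_sd_psc,
            seed=int(cohort_seeds[k]),
            base_params=base_params,
        )
        rep = evaluate_cohort(
            cohort, n_per_condition=n_per_condition, n_boot=n_boot
        )
        rows.append(
            {
                "cohort": k,
                "d": rep.d,
                "ci_low": rep.ci_low,
                "ci_high": rep.ci_high,
                "p": rep.p,
                "covers_truth": rep.ci_low <= true_d <= rep.ci_high,
                "rejects_null": rep.p < 0.05,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: io_mod.StudyConfig) -> CohortReport:
    """Simulate and analyze a whole cohort from a study configuration.

    If ``config.outdir`` is set, the cohort manifest, per-subject PSC table
    and a group summary TSV are written there.
    """
    base = SubjectParams(noise_sd=config.noise_sd, drift_slope=config.drift_slope)
    cohort = make_cohort(
        config.n_subjects,
        effect_mean_psc=config.effect_mean_psc,
        effect_sd_psc=config.effect_sd_psc,
        seed=config.seed,
        base_params=base,
    )
    report = evaluate_cohort(
        cohort,
        acq=config.acquisition(),
        n_per_condition=config.n_per_condition,
        feedback_type=config.feedback_type,
        n_boot=config.n_boot,
        with_physio=config.simulate_physio,
        physio_fs=config.physio_fs,
    )
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io_mod.tsv_write(cohort.manifest(), outdir / "cohort_manifest.tsv")
        io_mod.tsv_write(report.per_subject, outdir / "per_subject_psc.tsv")
        io_mod.tsv_write(
            pd.DataFrame([report.as_dict()]), outdir / "group_summary.tsv"
        )
    return report
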