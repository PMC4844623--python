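"""GLM: HRF, design construction, OLS oracle equivalence, PSC conversion."""

import numpy as np
import pandas as pd
import pytest

from neuroloop import AcquisitionParams, Condition, generate_schedule
from neuroloop.glm import (
    MICROTIME_RESOLUTION,
    RankDeficientDesignError,
    build_design,
    canonical_hrf,
    dct_highpass_basis,
    fit,
    fit_voxels,
    roi_psc,
    to_psc,
)
from neuroloop.pipeline import analyze_subject_run
from neuroloop.simulate import SubjectParams, simulate_multiecho


class TestCanonicalHrf:
    def test_kernel_peaks_near_5s(self, hrf):
        t_peak = np.argmax(hrf.kernel) * hrf.dt
        assert t_peak == pytest.approx(5.0, abs=0.2)

    def test_kernel_zero_at_t0_and_unit_peak(self, hrf):
        assert hrf.kernel[0] == 0.0
        assert hrf.kernel.max() == 1.0

    def test_unit_impulse_convolution_returns_kernel(self, hrf):
        impulse = np.zeros(hrf.kernel.size)
        impulse[0] = 1.0
        out = hrf.convolve(impulse)
        assert np.allclose(out, hrf.kernel * hrf.dt)

    def test_undershoot_present(self, hrf):
        assert hrf.kernel.min() < 0.0


class TestBuildDesign:
    def test_cf_columns(self, cf_schedule, acq):
        motion = np.tile(np.sin(np.arange(cf_schedule.n_volumes))[:, None], (1, 6))
        motion *= np.arange(1, 7)
        design = build_design(cf_schedule, acq, motion=motion)
        cols = design.columns
        assert cols[:2] == ["UP", "DOWN"]
        assert "FEEDBACK_DISPLAY" not in cols
        assert [c for c in cols if c.startswith("mot_")] == [f"mot_{i}" for i in range(1, 7)]
        assert cols[-1] == "constant"

    def test_eobf_adds_feedback_display_column(self, eobf_schedule, acq):
        design = build_design(eobf_schedule, acq)
        assert "FEEDBACK_DISPLAY" in design.columns

    def test_dct_basis_count_formula(self):
        # floor(2 * 300 * 2.54 / 128) = 11, confirmed by brute-force counting
        # of DCT frequencies k/(2*N*TR) below the cutoff
        basis = dct_highpass_basis(300, 2.54, 1.0 / 128.0)
        assert basis.shape == (300, 11)
        freqs = np.arange(1, 50) / (2 * 300 * 2.54)
        assert (freqs < 1.0 / 128.0).sum() == 11

    def test_motion_shape_validated(self, cf_schedule, acq):
        with pytest.raises(ValueError, match="6 columns"):
            build_design(cf_schedule, acq, motion=np.zeros((cf_schedule.n_volumes, 5)))

    def test_volume_count_mismatch_rejected(self, cf_schedule, acq):
        with pytest.raises(ValueError, match="volumes"):
            build_design(cf_schedule, acq, n_volumes=100)


class TestFit:
    def test_exact_linear_combination_recovered(self, transfer_schedule, acq):
        design = build_design(transfer_schedule, acq)
        x = design.matrix
        truth = np.linspace(-2, 2, x.shape[1])
        y = x @ truth
        res = fit(y, design)
        assert np.allclose(res.betas.to_numpy(), truth, atol=1e-10)
        assert np.allclose(res.residuals, 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        # independent solve of X'X beta = X'y on random small instances
        acq = AcquisitionParams()
        schedule = generate_schedule(2, "CF", seed=8)
        design = build_design(schedule, acq)
        x = design.matrix
        for _ in range(20):
            y = rng.normal(size=x.shape[0])
            beta_oracle = np.linalg.solve(x.T @ x, x.T @ y)
            res = fit(y, design)
            assert np.allclose(res.betas.to_numpy(), beta_oracle, rtol=1e-8, atol=1e-12)

    def test_intercept_shift_moves_only_constant(self, transfer_schedule, acq, rng):
        design = build_design(transfer_schedule, acq)
        y = rng.normal(size=design.n_volumes)
        a = fit(y, design)
        b = fit(y + 17.0, design)
        assert b.beta_constant - a.beta_constant == pytest.approx(17.0)
        for col in design.columns[:-1]:
            assert b.betas[col] == pytest.approx(a.betas[col], abs=1e-9)

    def test_residuals_orthogonal_to_design(self, transfer_schedule, acq, rng):
        design = build_design(transfer_schedule, acq)
        y = rng.normal(size=design.n_volumes)
        res = fit(y, design)
        assert np.max(np.abs(design.matrix.T @ res.residuals)) < 1e-8

    def test_rank_deficiency_names_collinear_columns(self, transfer_schedule, acq, rng):
        design = build_design(transfer_schedule, acq)
        # duplicate UP into a motion column to force collinearity
        frame = design.frame.copy()
        frame.insert(2, "mot_1", frame["UP"] * 2.0)
        design.frame = frame
        with pytest.raises(RankDeficientDesignError) as err:
            fit(rng.normal(size=design.n_volumes), design)
        assert "UP" in str(err.value) or "mot_1" in str(err.value)


class TestPsc:
    def test_zero_beta_gives_zero_psc(self, transfer_schedule, acq):
        design = build_design(transfer_schedule, acq)
        y = np.full(design.n_volumes, 500.0)
        res = fit(y, design)
        psc = to_psc(res)
        assert psc.psc_up == pytest.approx(0.0, abs=1e-12)
        assert psc.psc_down == pytest.approx(0.0, abs=1e-12)

    def test_zero_noise_roundtrip_recovers_generator_effect(self, acq):
        schedule = generate_schedule(8, "NONE", seed=21)
        params = SubjectParams(effect_up=0.01, effect_down=0.0,
                               noise_sd=0.0, drift_slope=0.0)
        series = simulate_multiecho(schedule, acq, params, seed=0)
        psc = analyze_subject_run(series, schedule)
        assert psc.psc_up == pytest.approx(1.0, abs=1e-6)
        assert psc.psc_down == pytest.approx(0.0, abs=1e-6)

    def test_contrast_identities(self, acq, rng):
        schedule = generate_schedule(4, "NONE", seed=2)
        design = build_design(schedule, acq)
        y = 800.0 + rng.normal(size=design.n_volumes)
        psc = to_psc(fit(y, design))
        assert psc.up_down == psc.psc_up - psc.psc_down
        assert psc.up_rest == psc.psc_up
        assert psc.rest_down == -psc.psc_down

    def test_near_zero_constant_rejected(self, transfer_schedule, acq, rng):
        design = build_design(transfer_schedule, acq)
        # exact multiple of the UP regressor: the constant coefficient is 0
        y = design.frame["UP"].to_numpy() * 5.0
        with pytest.raises(ValueError, match="constant"):
            to_psc(fit(y, design))

    def test_highpass_absorbs_drift_in_nuisance_span(self, transfer_schedule, acq, rng):
        design = build_design(transfer_schedule, acq)
        y = 1000.0 + 5.0 * design.frame["UP"].to_numpy() + rng.normal(size=design.n_volumes)
        base = fit(y, design)
        t = np.arange(design.n_volumes, dtype=float)
        drift = 0.5 * t + 30.0 * design.frame["hp_3"].to_numpy() - 12.0 * design.frame["hp_7"].to_numpy()
        shifted = fit(y + drift, design)
        for col in ("UP", "DOWN"):
            rel = abs(shifted.betas[col] - base.betas[col]) / max(abs(base.betas[col]), 1e-12)
            assert rel < 1e-6


class TestParameterRecovery:
    def test_median_error_under_10pct_low_noise(self, acq):
        """Across zero-drift, low-noise synthetic runs the median |estimated -
        true| UP-DOWN PSC stays below 10% of the true effect."""
        true_delta = 0.5  # percent
        errors = []
        hrf = canonical_hrf(acq.tr_seconds / MICROTIME_RESOLUTION, acq.tr_seconds)
        for seed in range(100):
            schedule = generate_schedule(8, "NONE", seed=seed)
            params = SubjectParams(effect_up=true_delta / 200.0,
                                   effect_down=-true_delta / 200.0,
                                   noise_sd=1.0, drift_slope=0.0)
            series = simulate_multiecho(schedule, acq, params, seed=seed)
            psc = analyze_subject_run(series, schedule, hrf=hrf)
            errors.append(abs(psc.up_down - true_delta))
        assert np.median(errors) < 0.1 * true_delta


class TestVolumeMode:
    def test_uniform_phantom_roi_equals_voxel(self, acq):
        schedule = generate_schedule(2, "NONE", seed=6)
        params = SubjectParams(effect_up=0.01, effect_down=-0.01,
                               noise_sd=0.0, drift_slope=0.0)
        series = simulate_multiecho(schedule, acq, params, seed=0, mode="volume")
        design = build_design(schedule, acq)
        from neuroloop.realtime import combine_echoes, te_weights

        w = te_weights(acq.echo_times_ms, acq.t2star_ms)
        combined = combine_echoes(series.data, w)  # (x,y,z,T)
        flat = combined.reshape(-1, combined.shape[-1])
        betas = fit_voxels(flat, design)
        psc_vol = roi_psc(betas, series.mask, design.hrf)

        # single-voxel value inside the ROI
        idx = np.flatnonzero(series.mask.ravel())[0]
        single = fit(flat[idx], design)
        psc_single = to_psc(single)
        assert psc_vol.up_down == pytest.approx(psc_single.up_down, abs=1e-9)

    def test_half_effect_mask_averages(self, acq):
        schedule = generate_schedule(2, "NONE", seed=6)
        design = build_design(schedule, acq)
        x = design.frame
        up = x["UP"].to_numpy() / design.hrf.single_event_peak
        base = 1000.0
        active = base * (1.0 + 0.01 * up)
        silent = np.full_like(active, base)
        data = np.stack([active, active, silent, silent])
        betas = fit_voxels(data, design)
        mask = np.ones((4, 1, 1), dtype=bool)
        psc = roi_psc(betas, mask, design.hrf)
        assert psc.psc_up == pytest.approx(0.5, abs=1e-6)

    def test_cross_mode_consistency(self, acq):
        schedule = generate_schedule(4, "NONE", seed=9)
        params = SubjectParams(effect_up=0.005, effect_down=-0.005,
                               noise_sd=0.5, drift_slope=0.0)
        roi_run = simulate_multiecho(schedule, acq, params, seed=3, mode="roi")
        vol_run = simulate_multiecho(schedule, acq, params, seed=3, mode="volume")
        psc_roi = analyze_subject_run(roi_run, schedule)
        psc_vol = analyze_subject_run(vol_run, schedule)
        assert psc_vol.up_down == pytest.approx(psc_roi.up_down, abs=0.15)
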