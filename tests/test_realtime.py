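"""Real-time feedback chain: weights, combination, baseline, scaling, engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroloop import AcquisitionParams, Condition, DirectionMapping, generate_schedule
from neuroloop.realtime import (
    BaselineStats,
    DegenerateBaselineError,
    FeedbackEngine,
    combine_echoes,
    estimate_baseline,
    roi_mean,
    scale_to_display,
    te_weights,
)
from neuroloop.simulate import SubjectParams, simulate_multiecho


class TestTeWeights:
    def test_printed_study_weights(self):
        w = te_weights((8.6, 18.3, 28.0, 38.0, 48.0, 57.0), 30.0)
        assert [round(v, 2) for v in w.weights] == [0.59, 0.90, 1.00, 0.97, 0.88, 0.77]

    def test_single_echo_normalizes_to_one(self):
        assert te_weights((25.0,), 30.0).weights == (1.0,)

    def test_unnormalized_weight_peaks_at_t2star(self):
        # TE * exp(-TE/T2*) is maximized at TE = T2*; among the printed TEs
        # the nearest echo (28 ms) gets weight 1
        tes = np.array([8.6, 18.3, 28.0, 38.0, 48.0, 57.0])
        raw = tes * np.exp(-tes / 30.0)
        assert tes[np.argmax(raw)] == 28.0
        fine = np.linspace(1, 100, 100000)
        assert fine[np.argmax(fine * np.exp(-fine / 30.0))] == pytest.approx(30.0, abs=0.01)

    def test_rejects_empty_or_bad_t2star(self):
        with pytest.raises(ValueError):
            te_weights((), 30.0)
        with pytest.raises(ValueError):
            te_weights((10.0,), 0.0)


class TestCombineEchoes:
    def test_equal_echoes_pass_through(self):
        w = te_weights((8.6, 18.3, 28.0), 30.0)
        assert combine_echoes([7.0, 7.0, 7.0], w) == pytest.approx(7.0)

    def test_hand_arithmetic(self):
        w = te_weights((30.0, 90.0), 30.0)  # raw weights e^-1*30, e^-3*90 -> (1, ~0.9957)
        # use explicit weights instead for the hand oracle
        from neuroloop.realtime import EchoWeights

        w = EchoWeights((1.0, 0.5))
        assert combine_echoes([10.0, 20.0], w) == pytest.approx(40.0 / 3.0)

    def test_pure_decay_combines_to_constant(self, acq, transfer_schedule):
        params = SubjectParams(noise_sd=0.0, drift_slope=0.0, effect_up=0.0, effect_down=0.0)
        series = simulate_multiecho(transfer_schedule, acq, params, seed=0)
        w = te_weights(acq.echo_times_ms, acq.t2star_ms)
        combined = combine_echoes(series.data, w)
        assert np.ptp(combined) < 1e-9

    def test_length_mismatch_raises(self):
        w = te_weights((10.0, 20.0), 30.0)
        with pytest.raises(ValueError):
            combine_echoes([1.0, 2.0, 3.0], w)


class TestRoiMean:
    def test_uniform_volume(self):
        vol = np.full((4, 4, 2), 3.5)
        mask = np.zeros((4, 4, 2), dtype=bool)
        mask[1:3, 1:3, :] = True
        assert roi_mean(vol, mask) == pytest.approx(3.5)

    def test_two_voxel_mask(self):
        vol = np.zeros((2, 2, 1))
        vol[0, 0, 0], vol[0, 1, 0] = 1.0, 3.0
        mask = np.zeros_like(vol, dtype=bool)
        mask[0, 0, 0] = mask[0, 1, 0] = True
        assert roi_mean(vol, mask) == pytest.approx(2.0)

    def test_matches_bruteforce_loop(self, rng):
        vol = rng.normal(size=(5, 5, 3))
        mask = rng.random((5, 5, 3)) > 0.5
        acc, n = 0.0, 0
        for i in range(5):
            for j in range(5):
                for k in range(3):
                    if mask[i, j, k]:
                        acc += vol[i, j, k]
                        n += 1
        assert roi_mean(vol, mask) == pytest.approx(acc / n)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            roi_mean(np.ones((2, 2, 2)), np.zeros((2, 2, 2), dtype=bool))


class TestEstimateBaseline:
    def test_closed_form_mean_and_sd(self):
        stats = estimate_baseline(np.arange(1.0, 11.0), window=(1, 10))
        assert stats.mean == pytest.approx(5.5)
        assert stats.sd == pytest.approx(3.0276503540974917)

    def test_default_window_uses_volumes_6_to_15(self):
        series = np.zeros(20)
        series[5:15] = np.arange(1.0, 11.0)  # volumes 6..15 hold 1..10
        stats = estimate_baseline(series)
        assert stats.window == tuple(range(6, 16))
        assert stats.mean == pytest.approx(5.5)

    def test_constant_window_raises(self):
        with pytest.raises(DegenerateBaselineError):
            estimate_baseline(np.ones(20))

    def test_short_series_raises(self):
        with pytest.raises(ValueError, match="baseline window"):
            estimate_baseline(np.arange(10.0))


class TestScaleToDisplay:
    @pytest.mark.parametrize(
        "offset_sd,expected", [(0.0, 0.0), (4.0, 1.0), (-2.0, -0.5), (8.0, 1.0), (-5.0, -1.0)]
    )
    def test_linear_with_clipping(self, offset_sd, expected):
        baseline = BaselineStats(mean=100.0, sd=2.0, window=tuple(range(6, 16)))
        assert scale_to_display(100.0 + offset_sd * 2.0, baseline) == pytest.approx(expected)

    @given(gain=st.floats(0.1, 10.0), offset=st.floats(-100.0, 100.0))
    @settings(deadline=None, max_examples=50)
    def test_invariant_to_affine_rescaling(self, gain, offset):
        rng = np.random.default_rng(99)
        series = rng.normal(50.0, 5.0, size=40)
        b0 = estimate_baseline(series)
        b1 = estimate_baseline(gain * series + offset)
        v = series[20]
        assert scale_to_display(gain * v + offset, b1) == pytest.approx(
            scale_to_display(v, b0), abs=1e-9
        )


class TestFeedbackEngine:
    def _run_engine(self, acq, schedule, params=None, seed=0, mapping=None):
        params = params or SubjectParams()
        series = simulate_multiecho(schedule, acq, params, seed=seed)
        engine = FeedbackEngine(acq, schedule=schedule, mapping=mapping)
        log = engine.run(series.data)
        return engine, log

    def test_prebaseline_frames_emit_no_display(self, acq, cf_schedule):
        engine, log = self._run_engine(acq, cf_schedule)
        assert np.isnan(log["scaled"][:14]).all()
        assert not log["visible"][:14].any()
        assert np.isfinite(log["scaled"][15:]).all()

    def test_history_caps_at_12_dropping_oldest(self, acq, cf_schedule):
        engine, _ = self._run_engine(acq, cf_schedule)
        post = [f for f in engine.frames if not f.pre_baseline]
        f13 = post[12]  # 13th post-baseline frame
        assert len(f13.history) == 12
        assert f13.history[0] == post[1].displayed  # oldest (frame 1) dropped
        assert f13.history[-1] == f13.displayed

    def test_mapping_flip_negates_displayed_only(self, acq, cf_schedule):
        m = DirectionMapping(Condition.UP)
        _, log_a = self._run_engine(acq, cf_schedule, mapping=m)
        _, log_b = self._run_engine(acq, cf_schedule, mapping=m.flipped())
        assert np.array_equal(log_a["roi_value"], log_b["roi_value"])
        mask = np.isfinite(log_a["displayed"])
        assert np.array_equal(
            log_a.loc[mask, "displayed"].to_numpy(),
            -log_b.loc[mask, "displayed"].to_numpy(),
        )

    def test_replaying_frames_is_bit_stable(self, acq, cf_schedule):
        _, log_a = self._run_engine(acq, cf_schedule, seed=5)
        _, log_b = self._run_engine(acq, cf_schedule, seed=5)
        assert log_a.equals(log_b)

    def test_out_of_order_volume_rejected(self, acq, cf_schedule):
        engine = FeedbackEngine(acq, schedule=cf_schedule)
        engine.step(np.ones(acq.n_echoes), volume_index=1)
        with pytest.raises(ValueError, match="out-of-order"):
            engine.step(np.ones(acq.n_echoes), volume_index=5)

    def test_eobf_visibility_limited_to_display_windows(self, acq, eobf_schedule):
        _, log = self._run_engine(acq, eobf_schedule)
        visible = log.loc[log["visible"] == 1, "volume_index"].to_numpy()
        labels = eobf_schedule.volume_labels()
        assert len(visible) > 0
        assert all(labels[v - 1] == "DISPLAY" for v in visible)

    def test_transfer_run_shows_nothing(self, acq, transfer_schedule):
        _, log = self._run_engine(acq, transfer_schedule)
        assert not log["visible"].any()

    def test_run_reset_isolates_runs(self, acq, cf_schedule):
        params = SubjectParams()
        series_a = simulate_multiecho(cf_schedule, acq, params, seed=1)
        series_b = simulate_multiecho(cf_schedule, acq, params, seed=2)
        # run b alone
        engine = FeedbackEngine(acq, schedule=cf_schedule)
        log_alone = engine.run(series_b.data)
        # run a, reset, then run b
        engine2 = FeedbackEngine(acq, schedule=cf_schedule)
        engine2.run(series_a.data)
        engine2.reset()
        log_after = engine2.run(series_b.data)
        assert log_alone.equals(log_after)

    def test_zero_noise_up_plateaus_exceed_down_after_unmapping(self, acq):
        schedule = generate_schedule(4, "CF", seed=3)
        params = SubjectParams(noise_sd=0.0, drift_slope=0.0,
                               effect_up=0.01, effect_down=-0.01)
        # nonzero baseline SD requires some variation in volumes 6-15: tiny noise
        params = SubjectParams(noise_sd=0.01, drift_slope=0.0,
                               effect_up=0.01, effect_down=-0.01)
        for mapping in (DirectionMapping(Condition.UP), DirectionMapping(Condition.DOWN)):
            _, log = self._run_engine(acq, schedule, params=params, mapping=mapping)
            labels = schedule.volume_labels()
            displayed = log["displayed"].to_numpy()
            unmapped = displayed * mapping.sign
            # plateau = last 6 TRs of each block, past the hemodynamic rise
            ups, downs = [], []
            vol = 0
            for cond, trs in schedule.blocks:
                sel = range(vol + 6, vol + trs)
                vals = [unmapped[i] for i in sel if np.isfinite(unmapped[i])]
                if cond is Condition.UP:
                    ups.extend(vals)
                elif cond is Condition.DOWN:
                    downs.extend(vals)
                vol += trs
            assert np.mean(ups) > np.mean(downs)
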