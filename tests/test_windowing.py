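import numpy as np
import pytest

import beatwise as bw
from beatwise.synth import _render
from beatwise.windowing import (CpCandidate, InitializationError, _derived,
                                initialize)
from beatwise._util import round_half_up


class TestDetermineCp:
    def test_dominant_rule_picks_far_extremum(self):
        # median 0 is near the minimum; the spike is the event
        assert bw.determine_cp([0, 0, 10, 0, 0], wst=100).index == 102
        assert bw.determine_cp([0, 0, -10, 0, 0], wst=0).index == 2

    def test_literal_rule_picks_near_extremum(self):
        cand = bw.determine_cp([0, 0, 10, 0, 0], wst=0, rule="literal")
        assert cand.index == np.argmin([0, 0, 10, 0, 0])

    def test_constant_window_is_degenerate(self):
        cand = bw.determine_cp([3.0, 3.0, 3.0], wst=50)
        assert cand.degenerate and cand.index == 50

    def test_tie_breaks_toward_maximum(self):
        cand = bw.determine_cp([-5, 0, 5], wst=0)
        assert cand.index == 2


class TestUpdateMean:
    def test_constant_intervals(self):
        buf, cbar = bw.update_mean(tuple([300.0] * 15), 300.0, K=16)
        assert cbar == 300.0 and len(buf) == 16

    def test_bruteforce_mean(self):
        buf = ()
        for c in range(1, 17):
            buf, cbar = bw.update_mean(buf, float(c), K=16)
        assert cbar == 8.5

    def test_ring_buffer_drops_oldest(self):
        buf = tuple(float(c) for c in range(1, 17))
        buf, cbar = bw.update_mean(buf, 17.0, K=16)
        assert buf[0] == 2.0 and cbar == np.mean(np.arange(2, 18))

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            bw.update_mean((), 0.0, K=16)


class TestConstants:
    def test_published_defaults(self):
        c = bw.WindowConstants()
        assert c.eta_w == 0.9 and c.eta_of == 0.1
        assert c.eta_s == pytest.approx(3 * 0.9 / 11)
        assert c.eta_ar == pytest.approx(5 / 11)
        assert (c.eta_cmin, c.eta_cmax) == (0.45, 1.45)
        assert c.eta_delta == 0.9 and c.p_b == 0.9
        assert c.M == 512 and c.K == 16

    def test_validation(self):
        with pytest.raises(ValueError):
            bw.WindowConstants(eta_cmin=1.2)
        with pytest.raises(ValueError):
            bw.WindowConstants(p_b=1.5)
        with pytest.raises(ValueError):
            bw.WindowConstants(cp_rule="argmax")

    def test_tiny_step_defaults_to_third_of_step_ratio(self):
        c = bw.WindowConstants()
        assert c.tiny_step_ratio == pytest.approx(c.eta_s / 3)
        assert bw.WindowConstants(eta_sof=0.05).tiny_step_ratio == 0.05


def _state(cbar=360.0, last_cp=640, wst=676):
    cns = bw.WindowConstants()
    omega, step, _, cp_min, cp_max, delta = _derived(cbar, last_cp, cns)
    return bw.WindowState(j=3, omega=omega, step=step, wst=wst, cbar=cbar,
                          intervals=tuple([cbar] * 16), last_cp=last_cp,
                          cp_min=cp_min, cp_max=cp_max, delta=delta), cns


class TestDetectionUpdate:
    def test_parameter_scaling_from_mean_interval(self):
        state, cns = _state()
        new, beat = bw.update_on_detection(state, cp=1000, cns=cns)
        assert new.cbar == 360.0          # interval 360 keeps the mean at 360
        assert new.omega == 324 and new.step == 88
        assert new.wst == 1036
        assert (new.cp_min, new.cp_max) == (162, 522)
        assert (beat.bl, beat.br) == (853, 1177)

    def test_segment_length_is_rounded_eta_delta_cbar(self):
        state, cns = _state()
        _, beat = bw.update_on_detection(state, cp=1000, cns=cns)
        assert beat.br - beat.bl == round_half_up(cns.eta_delta * 360.0)

    def test_split_ratio_five_to_six(self):
        bl, br = bw.method1_boundaries(1000, 360.0, bw.WindowConstants())
        left, right = 1000 - bl, br - 1000
        assert abs(left / right - 5 / 6) * right <= 1.0

    def test_too_far_detection_keeps_mean(self):
        state, cns = _state()
        new, beat = bw.update_on_detection(state, cp=state.last_cp + 600,
                                           cns=cns, include_in_mean=False)
        assert new.cbar == state.cbar
        assert new.intervals == state.intervals
        assert new.last_cp == state.last_cp + 600
        assert beat.bl < beat.cp < beat.br

    def test_mean_updated_before_boundaries(self):
        state, cns = _state(cbar=300.0)
        new, beat = bw.update_on_detection(state, cp=state.last_cp + 460,
                                           cns=cns)
        assert new.cbar == pytest.approx(310.0)     # (15*300 + 460)/16
        assert beat.br - beat.bl == round_half_up(cns.eta_delta * 310.0)


class TestMethod2:
    def test_midpoints_with_half_ratios(self):
        cns = bw.WindowConstants()
        assert bw.method2_boundaries(650, 1000, 1370, cns) == (825, 1185)

    def test_left_limit_case(self):
        cns = bw.WindowConstants(eta_l=0.0)
        bl2, _ = bw.method2_boundaries(650, 1000, 1370, cns)
        assert bl2 == 1000

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            bw.method2_boundaries(1000, 650, 1370, bw.WindowConstants())


class TestMissUpdate:
    def test_low_probability_advances_one_step(self):
        state, cns = _state()
        new = bw.update_on_miss(state, P=0.3, cand=None, cns=cns)
        assert new.wst == state.wst + state.step
        assert new.cbar == state.cbar and new.intervals == state.intervals

    def test_too_close_relocates_with_tiny_steps(self):
        state, cns = _state()
        cand = CpCandidate(index=state.wst + 50)
        new = bw.update_on_miss(state, P=0.95, cand=cand, cns=cns)
        assert new.wst == cand.index + state.delta
        assert new.small_step
        assert new.step == round_half_up(cns.tiny_step_ratio * state.cbar)
        assert new.intervals == state.intervals   # rejected cp never enters


class TestInitialize:
    def test_initial_window_is_half_a_second(self):
        cns = bw.WindowConstants()
        assert round_half_up(cns.init_window_s * 360) == 180

    def test_acquires_rhythm_within_five_percent(self, synth_record, oracle):
        cns = bw.WindowConstants()
        state, cps = initialize(synth_record.record.signal, oracle, cns, 360.0)
        assert len(cps) == cns.K
        idx = synth_record.record.annotation_indices()
        true_rr = float(np.mean(np.diff(idx[:cns.K])))
        assert abs(state.cbar - true_rr) / true_rr < 0.05
        assert state.wst > state.last_cp

    def test_flat_signal_fails_initialization(self, oracle):
        with pytest.raises(InitializationError):
            initialize(np.zeros(360 * 40), oracle, bw.WindowConstants(), 360.0)

    def test_too_short_signal_rejected(self, oracle):
        with pytest.raises(InitializationError):
            initialize(np.zeros(100), oracle, bw.WindowConstants(), 360.0)


class TestSegmentRecord:
    def test_runs_without_annotations(self, synth_record, oracle):
        bare = bw.EcgRecord("bare", 360.0, synth_record.record.signal)
        res = bw.segment_record(bare, oracle)
        assert len(res.beats) > 250

    def test_window_start_strictly_increases(self, segmentation):
        wst = segmentation.log["wst"].to_numpy()
        assert np.all(np.diff(wst) > 0)

    def test_accepted_intervals_respect_thresholds_in_force(self, segmentation):
        cns = segmentation.constants
        log = segmentation.log
        acc = log[log.decision == "accept"]
        lo = np.floor(cns.eta_cmin * acc["cbar"] + 0.5)
        hi = np.floor(cns.eta_cmax * acc["cbar"] + 0.5)
        assert np.all(acc["interval"] >= lo) and np.all(acc["interval"] <= hi)

    def test_method2_margins_bracket_neighbouring_cps(self, segmentation):
        cps = segmentation.cps
        pos = {cp: k for k, cp in enumerate(cps)}
        for beat in segmentation.beats:
            if beat.bl2 is None:
                continue
            k = pos[beat.cp]
            assert cps[k - 1] < beat.bl2 <= beat.cp
            assert beat.cp <= beat.br2 < cps[k + 1]

    def test_final_beat_lacks_method2_margins(self, segmentation):
        assert segmentation.beats[-1].bl2 is None
        assert all(b.bl2 is not None for b in segmentation.beats[:-1])

    def test_window_tracks_linearly_ramping_rhythm(self, default_cfg):
        # RR ramps 0.6 s -> 1.0 s; omega must stay locked to eta_w * cbar
        fs = 360.0
        rrs = np.linspace(0.6, 1.0, 120)
        times = 0.4 + np.concatenate([[0], np.cumsum(rrs)])
        n = int((times[-1] + 0.5) * fs)
        sig = _render(times, ["N"] * len(times), bw.SynthConfig(), n)
        rec = bw.EcgRecord("ramp", fs, sig)
        det = bw.oracle_detector(bw.make_template(default_cfg))
        res = bw.segment_record(rec, det)
        cns = res.constants
        for _, row in res.log[res.log.decision == "accept"].iterrows():
            assert abs(row["omega"] - cns.eta_w * row["cbar"]) <= 1.0
        assert len(res.beats) >= 100

    def test_ectopic_intervals_stay_out_of_the_mean(self):
        from beatwise.experiments import ectopic_experiment

        out = ectopic_experiment(seed=5)
        assert out["n_ectopic"] > 0
        assert out["max_deviation_pct"] < 5.0


class TestSegmenterEstimator:
    def test_sklearn_style_params_and_predict(self, synth_record, oracle):
        seg = bw.AdaptiveWindowSegmenter(detector=oracle, eta_cmax=1.45, K=16)
        assert seg.get_params()["eta_cmax"] == 1.45
        seg.set_params(eta_cmax=1.4)
        seg.fit()
        assert seg.constants_.eta_cmax == 1.4
        cps = seg.predict(synth_record.record)
        assert cps.size > 250

    def test_detector_required(self):
        with pytest.raises(ValueError):
            bw.AdaptiveWindowSegmenter().fit()
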