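"""Flight/contact detection, phase segmentation and timing outcomes."""

import numpy as np
import pytest

from kinegen.errors import ParameterError, SegmentationError
from kinegen.events import (
    PhaseSegmentation,
    classify_ssc_speed,
    detect_contact_flight,
    jump_height,
    segment_jump_phases,
    sprint_time,
)
from kinegen.io_formats import ForcePlateSeries, MarkerTrajectories
from kinegen.kinematics import LinearSeries, linear_kinematics
from kinegen.synthetic import JumpSimConfig, simulate_jump_trial, simulate_sprint_trial, SprintSimConfig

G = 9.81


class TestDetectContactFlight:
    def test_single_flight_window(self):
        fs = 1000.0
        fz = np.full(2000, 686.7)
        fz[1000:1400] = 0.0
        flights = detect_contact_flight(ForcePlateSeries(fz, fs))
        assert len(flights) == 1
        t_off, t_on = flights[0]
        assert t_off == pytest.approx(1.0, abs=1.5 / fs)
        assert t_on == pytest.approx(1.4, abs=1.5 / fs)

    def test_no_flight_when_loaded(self):
        fp = ForcePlateSeries(np.full(500, 600.0), 1000.0)
        assert detect_contact_flight(fp) == []

    def test_short_dropouts_debounced(self):
        fz = np.full(1000, 600.0)
        fz[100:110] = 0.0  # 10 ms dropout, below the 50 ms minimum
        fp = ForcePlateSeries(fz, 1000.0)
        assert detect_contact_flight(fp) == []

    def test_dj_contact_time_within_one_frame(self, dj_trial):
        markers, fp, truth = dj_trial
        seg = segment_jump_phases(markers, fp, "DJ")
        assert abs(seg.contact_time - truth.contact_time) <= 1.0 / markers.frequency


class TestSegmentation:
    def test_sj_has_no_eccentric_phase(self, sj_trial):
        markers, fp, _ = sj_trial
        seg = segment_jump_phases(markers, fp, "SJ")
        assert "E" not in seg.phases
        assert "C" in seg.phases and "F2" in seg.phases

    def test_cmj_ec_boundary_matches_truth(self, cmj_trial):
        markers, fp, truth = cmj_trial
        seg = segment_jump_phases(markers, fp, "CMJ")
        true_frame = truth.phase_times["E"][1] * markers.frequency
        assert abs(seg.phases["E"][1] - true_frame) <= 2.0

    def test_dj_phase_order(self, dj_trial):
        markers, fp, _ = dj_trial
        seg = segment_jump_phases(markers, fp, "DJ")
        labels = [p for p in ("D", "F1", "L1", "E", "C", "F2", "L2") if p in seg.phases]
        assert labels == ["D", "F1", "L1", "E", "C", "F2", "L2"]
        ends = [seg.phases[p][1] for p in labels]
        starts = [seg.phases[p][0] for p in labels]
        assert all(e <= s for e, s in zip(ends, starts[1:]))

    def test_padding_shifts_indices_not_durations(self, cmj_trial):
        markers, fp, _ = cmj_trial
        seg0 = segment_jump_phases(markers, fp, "CMJ")
        pad_s = 0.4
        pad_m = int(pad_s * markers.frequency)
        pos = np.concatenate([np.repeat(markers.positions[:, :1], pad_m, axis=1),
                              markers.positions], axis=1)
        mt = MarkerTrajectories(list(markers.marker_ids), pos, markers.frequency)
        pad_f = int(pad_s * fp.frequency)
        fz = np.concatenate([np.full(pad_f, fp.fz[0]), fp.fz])
        fp2 = ForcePlateSeries(fz, fp.frequency)
        seg1 = segment_jump_phases(mt, fp2, "CMJ")
        for lab in ("E", "C", "F2"):
            d0 = seg0.phases[lab][1] - seg0.phases[lab][0]
            d1 = seg1.phases[lab][1] - seg1.phases[lab][0]
            assert abs(d1 - d0) <= 1

    def test_missing_flight_is_segmentation_error(self):
        n = 400
        mt = MarkerTrajectories(
            ["F_sacrum"], np.tile([0.0, 0.0, 0.9], (1, n, 1)), 200.0)
        fp = ForcePlateSeries(np.full(2 * n, 600.0), 400.0)
        with pytest.raises(SegmentationError, match="F2|flight"):
            segment_jump_phases(mt, fp, "CMJ")

    def test_out_of_order_phases_rejected(self):
        with pytest.raises(SegmentationError):
            PhaseSegmentation({"E": (100, 90)}, 200.0)
        with pytest.raises(SegmentationError):
            PhaseSegmentation({"E": (100, 120), "C": (110, 130)}, 200.0)


class TestJumpHeight:
    def test_flight_time_closed_form(self):
        seg = PhaseSegmentation({"F2": (0, 80)}, 200.0, flight_time=0.4)
        lin = LinearSeries("z", np.zeros(100), np.zeros(100), np.zeros(100), 200.0)
        assert jump_height(seg, lin, "flight_time") == pytest.approx(0.1962)

    def test_zero_flight_time_is_zero_height(self):
        seg = PhaseSegmentation({"F2": (0, 1)}, 200.0, flight_time=0.0)
        lin = LinearSeries("z", np.zeros(10), np.zeros(10), np.zeros(10), 200.0)
        assert jump_height(seg, lin, "flight_time") == 0.0

    @pytest.mark.parametrize("jt", ["SJ", "CMJ", "DJ"])
    def test_methods_agree_on_noise_free_trials(self, jt):
        cfg = JumpSimConfig(jump_type=jt)
        markers, fp, truth = simulate_jump_trial(cfg)
        seg = segment_jump_phases(markers, fp, jt)
        lin = linear_kinematics(markers)
        h_ft = jump_height(seg, lin, "flight_time")
        h_mk = jump_height(seg, lin, "marker",
                           box_height=cfg.box_height if jt == "DJ" else 0.0)
        assert abs(h_ft - h_mk) < 0.02 * truth.flight_height
        assert abs(h_ft - truth.flight_height) < 0.02 * truth.flight_height


class TestSSCClassification:
    def test_fast_below_quarter_second(self):
        assert classify_ssc_speed(0.200) == "fast"

    def test_slow_above_quarter_second(self):
        assert classify_ssc_speed(0.300) == "slow"

    def test_boundary_is_slow(self):
        assert classify_ssc_speed(0.250) == "slow"

    def test_non_positive_rejected(self):
        with pytest.raises(ParameterError):
            classify_ssc_speed(0.0)


class TestSprintTime:
    @staticmethod
    def _walk(x_of_t, fs=200.0, T=3.0):
        t = np.arange(int(T * fs)) / fs
        pos = np.zeros((1, len(t), 3))
        pos[0, :, 0] = x_of_t(t)
        pos[0, :, 2] = 0.9
        return MarkerTrajectories(["F_sacrum"], pos, fs)

    def test_interpolated_crossings(self):
        # crosses x=0 at t=0.5 s and x=5 at t=1.7 s
        mt = self._walk(lambda t: (t - 0.5) * (5.0 / 1.2))
        assert sprint_time(mt, (0.0, 5.0)) == pytest.approx(1.2, abs=1e-6)

    def test_constant_acceleration_closed_form(self):
        cfg = SprintSimConfig(v0=0.0, acceleration=2.0, noise_sd=0.001, seed=2)
        markers, truth = simulate_sprint_trial(cfg)
        est = sprint_time(markers, truth.gate_positions)
        assert abs(est - (truth.gate_times[1] - truth.gate_times[0])) \
            <= 1.0 / markers.frequency

    def test_identical_gates_rejected(self):
        mt = self._walk(lambda t: 3 * t)
        with pytest.raises(ParameterError):
            sprint_time(mt, (2.0, 2.0))

    def test_uncrossed_gate_rejected(self):
        mt = self._walk(lambda t: 0.5 * t, T=2.0)
        with pytest.raises(SegmentationError):
            sprint_time(mt, (0.0, 5.0))
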