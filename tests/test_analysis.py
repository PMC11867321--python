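"""Event detection, kinematic integration, phase segmentation and metrics."""

import numpy as np
import pytest

from jumpmetrics import JumpAnalyzer, JumpSpec, analyze, select_best_trial, simulate_jump
from jumpmetrics.analysis import BodyWeightEstimate, JumpMetrics
from jumpmetrics.errors import (
    InvalidJumpError,
    NoCountermovementError,
    NoFlightError,
    NoLandingError,
    NoMovementError,
    SpecificationError,
)
from jumpmetrics.io import ForceRecording

ANALYZER = JumpAnalyzer()


def _flat(weight=700.0, n=3000, rate=1000.0):
    return ForceRecording(force=np.full(n, weight), sampling_rate=rate)


class TestBodyWeight:
    def test_constant_trace(self):
        bw = ANALYZER.estimate_body_weight(_flat())
        assert bw.weight == 700.0
        assert bw.weight_sd == 0.0
        assert bw.mass == pytest.approx(71.36, abs=0.01)
        assert bw.window == (0, 500)

    def test_noisy_trace_equals_direct_window_mean(self):
        rng = np.random.default_rng(5)
        force = 700.0 + rng.normal(0, 3, size=4000)
        rec = ForceRecording(force=force, sampling_rate=1000.0)
        bw = ANALYZER.estimate_body_weight(rec)
        assert bw.weight == pytest.approx(force[:500].mean(), abs=1e-12)
        assert bw.weight_sd == pytest.approx(force[:500].std(ddof=1), abs=1e-12)
        assert abs(bw.weight - 700.0) < 3 * 3 / np.sqrt(500)

    def test_too_short_recording(self):
        with pytest.raises(ValueError, match="too short"):
            ANALYZER.estimate_body_weight(_flat(n=300))


class TestEventDetection:
    def test_onset_constructed_step(self):
        force = np.full(3000, 700.0)
        force[1200:] = 680.0
        rec = ForceRecording(force=force, sampling_rate=1000.0)
        bw = BodyWeightEstimate(weight=700.0, weight_sd=2.0, mass=700 / 9.81, window=(0, 500))
        assert ANALYZER.detect_onset(rec, bw) == 1170

    def test_flat_trace_no_movement(self):
        rec = _flat()
        bw = ANALYZER.estimate_body_weight(rec)
        with pytest.raises(NoMovementError):
            ANALYZER.detect_onset(rec, bw)

    def test_zero_sd_without_floor_is_a_configuration_error(self):
        rec = _flat()
        bw = ANALYZER.estimate_body_weight(rec)
        strict = JumpAnalyzer(sd_floor_n=0.0)
        with pytest.raises(SpecificationError, match="sd_floor"):
            strict.detect_onset(rec, bw)

    def test_takeoff_at_constructed_threshold_crossing(self):
        force = np.full(3000, 700.0)
        force[1500:] = 0.0
        rec = ForceRecording(force=force, sampling_rate=1000.0)
        assert ANALYZER.detect_takeoff(rec, onset=1000) == 1500

    def test_no_flight_detected(self):
        with pytest.raises(NoFlightError):
            ANALYZER.detect_takeoff(_flat(), onset=100)

    def test_landing_pulse_detected(self):
        force = np.full(3000, 0.0)
        force[:1000] = 700.0
        force[2000:] = 900.0
        rec = ForceRecording(force=force, sampling_rate=1000.0)
        assert ANALYZER.detect_landing(rec, takeoff=1000) == 2000

    def test_flight_to_end_of_file(self):
        force = np.concatenate([np.full(1000, 700.0), np.zeros(1000)])
        rec = ForceRecording(force=force, sampling_rate=1000.0)
        with pytest.raises(NoLandingError):
            ANALYZER.detect_landing(rec, takeoff=1000)

    def test_simulated_event_timing(self, noisy_cmj):
        rec, gt = noisy_cmj
        an = analyze(rec)
        assert abs(an.events.onset * rec.dt - gt.onset_time) < 0.050
        assert abs(an.events.takeoff * rec.dt - gt.takeoff_time) < 0.002
        flight = (an.events.landing - an.events.takeoff) * rec.dt
        assert flight == pytest.approx(gt.flight_time, abs=2 * rec.dt)


class TestKinematics:
    def test_static_interval_stays_at_rest(self):
        rec = _flat()
        bw = ANALYZER.estimate_body_weight(rec)
        kin = ANALYZER.integrate_kinematics(rec, bw, 600, 2000)
        assert np.allclose(kin.velocity, 0.0)
        assert np.allclose(kin.displacement, 0.0)
        assert np.allclose(kin.power, 0.0)

    def test_rectangular_net_force_closed_form(self):
        # +100 N for 0.200 s on 70 kg -> dv = 100 * 0.2 / 70
        weight = 70.0 * 9.81
        force = np.full(2000, weight)
        force[1000:1200] = weight + 100.0
        rec = ForceRecording(force=force, sampling_rate=1000.0)
        bw = BodyWeightEstimate(weight=weight, weight_sd=0.0, mass=70.0, window=(0, 500))
        kin = ANALYZER.integrate_kinematics(rec, bw, 900, 1300)
        assert kin.velocity[-1] == pytest.approx(100 * 0.2 / 70, rel=0.006)

    def test_velocity_starts_at_zero(self, noiseless_cmj):
        rec, _ = noiseless_cmj
        an = analyze(rec)
        assert an.kinematics.velocity[0] == 0.0
        assert an.kinematics.displacement[0] == 0.0
        np.testing.assert_allclose(
            an.kinematics.power,
            rec.force[an.events.onset:an.events.takeoff + 1] * an.kinematics.velocity,
        )


class TestSegmentation:
    def test_cmj_has_six_contiguous_phases(self, noiseless_cmj):
        rec, _ = noiseless_cmj
        an = analyze(rec)
        seg = an.segmentation
        assert seg.labels() == (
            "weighting", "unweighting", "braking", "propulsion", "flight", "landing"
        )
        bounds = list(seg.phases.values())
        for (_, end), (start, _) in zip(bounds, bounds[1:]):
            assert end == start
        assert bounds[0][0] == 0 and bounds[-1][1] == rec.n_samples
        # braking starts at the velocity minimum
        v = an.kinematics.velocity
        assert seg["braking"][0] == an.events.onset + int(np.argmin(v))

    def test_cmj_force_returns_to_weight_at_velocity_minimum(self, noiseless_cmj):
        """a = 0 at a velocity extremum, so F crosses BW where v is minimal."""
        rec, _ = noiseless_cmj
        an = analyze(rec)
        assert abs(an.events.bw_return - an.events.velocity_min) <= 2

    def test_sj_has_no_countermovement_phases(self, noiseless_sj):
        rec, _ = noiseless_sj
        an = analyze(rec)
        assert an.segmentation.labels() == ("weighting", "propulsion", "flight", "landing")

    def test_cmj_without_countermovement_is_rejected(self, noiseless_sj):
        rec, _ = noiseless_sj
        with pytest.raises(NoCountermovementError, match="SJ"):
            analyze(rec, jump_type="CMJ")


class TestMetrics:
    def test_closed_form_values(self, noiseless_cmj):
        rec, _ = noiseless_cmj
        m = analyze(rec).metrics
        mass = 70.0
        assert m.peak_kinetic_energy == pytest.approx(
            0.5 * mass * m.peak_velocity**2, rel=1e-6
        )
        assert m.jump_height == pytest.approx(m.takeoff_velocity**2 / 19.62, abs=1e-12)

    def test_pke_and_jh_spot_values(self):
        # m = 70 kg, v_peak = 3 -> PKE = 315 J; v_to = 2.8 -> JH = 0.3996 m
        assert 0.5 * 70 * 3.0**2 == pytest.approx(315.0)
        assert 2.8**2 / (2 * 9.81) == pytest.approx(0.3996, abs=5e-5)

    def test_negative_takeoff_velocity_is_invalid(self):
        # a sagging "jump": force never rises, v at the 20 N crossing is negative
        force = np.concatenate(
            [np.full(1000, 700.0), np.full(300, 300.0), np.full(200, 10.0)]
        )
        rec = ForceRecording(force=force, sampling_rate=1000.0)
        with pytest.raises(InvalidJumpError):
            analyze(rec, jump_type="SJ")

    def test_subsampling_stability(self):
        """Metrics at 1000 Hz and 500 Hz agree within 1% on the same waveform."""
        m = {}
        for rate in (1000.0, 500.0):
            rec, _ = simulate_jump(JumpSpec(noise_sd=0.0, sampling_rate=rate))
            m[rate] = analyze(rec).metrics
        for name in (
            "peak_power", "mean_power", "relative_net_impulse",
            "jump_height", "peak_kinetic_energy",
        ):
            a, b = getattr(m[1000.0], name), getattr(m[500.0], name)
            assert a == pytest.approx(b, rel=0.01), name


class TestBestTrial:
    @staticmethod
    def _metrics(jh):
        return JumpMetrics(
            peak_power=1.0, mean_power=1.0, relative_net_impulse=1.0,
            jump_height=jh, peak_kinetic_energy=1.0,
            takeoff_velocity=1.0, peak_velocity=1.0,
        )

    def test_highest_jump_selected(self):
        trials = [self._metrics(h) for h in (0.35, 0.40, 0.38)]
        assert select_best_trial(trials) == 1

    def test_single_trial_and_tie_break(self):
        assert select_best_trial([self._metrics(0.3)]) == 0
        assert select_best_trial([self._metrics(0.40), self._metrics(0.40)]) == 0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_best_trial([])


def test_analyzer_sklearn_params_round_trip():
    from sklearn.base import clone

    a = JumpAnalyzer(takeoff_threshold_n=25.0)
    b = clone(a)
    assert b.get_params()["takeoff_threshold_n"] == 25.0
    b.set_params(onset_sd_mult=6.0)
    assert b.onset_sd_mult == 6.0 and a.onset_sd_mult == 5.0
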