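"""Event detection, landmarking, classification and feature extraction."""

from __future__ import annotations

import math

import numpy as np
import pytest

from apdecomp.config import AnalysisConfig
from apdecomp.core import APKind, DegenerateInputError, DetectionError, Trace
from apdecomp.event_detection import (
    NoiseModel,
    assign_group,
    classify_ap,
    compute_features,
    detect_eof,
    detect_eofr,
    detect_eos,
    detect_onset,
    estimate_noise_sd,
    estimate_rmp,
    select_training_cells,
    slope_profile,
)
from apdecomp.synthetic import (
    GeneratorConfig,
    compose_ap,
    gen_sejp_shape,
    gen_typeb_shape,
)

RAW = AnalysisConfig(smoothing_window=1)  # no smoothing: analytic landmarks


def _trace(samples, dt=0.5):
    return Trace(samples=np.asarray(samples, dtype=float), dt=dt)


class TestNoiseModel:
    def test_threshold_is_max_sigma_rounded_up(self):
        nm = NoiseModel.from_sigmas([0.42, 0.91, 0.6])
        assert nm.sigma_n == 0.91
        assert nm.onset_threshold == 1.0

    def test_threshold_below_sigma_rejected(self):
        with pytest.raises(DetectionError):
            NoiseModel(sigma_n=0.9, onset_threshold=0.5)


class TestBaselineEstimators:
    def test_rmp_of_constant_window(self):
        tr = _trace(np.full(100, -43.0))
        assert estimate_rmp(tr, (0, 100)) == -43.0

    def test_rmp_two_sample_mean(self):
        tr = _trace([-44.0, -42.0, 0.0])
        assert estimate_rmp(tr, (0, 2)) == -43.0

    def test_rmp_empty_window_raises(self):
        with pytest.raises(DegenerateInputError):
            estimate_rmp(_trace(np.zeros(10)), (5, 5))

    def test_rmp_monte_carlo_bound(self):
        # RMP -45, noise SD 0.5, 500-sample window: |error| < 0.1 mV in
        # >= 99% of 1000 seeded trials (SE = 0.5/sqrt(500) = 0.022)
        rng = np.random.default_rng(7)
        hits = sum(
            abs(estimate_rmp(_trace(rng.normal(-45, 0.5, 500)), (0, 500))
                + 45.0) < 0.1
            for _ in range(1000))
        assert hits >= 990

    def test_noise_sd_constant_is_zero(self):
        assert estimate_noise_sd(_trace(np.full(60, -43.0)), (0, 60)) == 0.0

    def test_noise_sd_alternating_closed_form(self):
        # +/-1 mV alternation around the mean: sample SD = sqrt(n/(n-1))
        v = -43.0 + np.tile([1.0, -1.0], 50)
        expected = math.sqrt(100 / 99)
        assert estimate_noise_sd(_trace(v), (0, 100)) == pytest.approx(
            expected, abs=1e-12)

    def test_noise_sd_gaussian_bound(self):
        # chi-distribution concentration: SD 0.9 estimated within 0.15 at
        # n = 500
        rng = np.random.default_rng(11)
        for _ in range(20):
            est = estimate_noise_sd(_trace(rng.normal(-43, 0.9, 500)),
                                    (0, 500))
            assert abs(est - 0.9) < 0.15

    def test_noise_sd_short_window_raises(self):
        with pytest.raises(DegenerateInputError):
            estimate_noise_sd(_trace(np.zeros(60)), (0, 30))


class TestDetectOnset:
    def test_first_crossing_by_inspection(self):
        tr = _trace([-43.0, -42.5, -41.8, -40.0])
        assert detect_onset(tr, rmp=-43.0, threshold=1.0, peak_idx=3) == 2

    def test_flat_trace_raises(self):
        with pytest.raises(DetectionError):
            detect_onset(_trace(np.full(50, -43.0)), -43.0, 1.0, 49)

    def test_search_starts_after_last_rmp_touch(self):
        # an earlier excursion followed by a return to RMP must not capture
        # the onset of the later event
        v = np.full(60, -43.0)
        v[10:15] = -41.0   # early bump
        v[20] = -43.0      # back at RMP
        v[30:] = -40.0     # the event
        assert detect_onset(_trace(v), -43.0, 1.0, peak_idx=35) == 30

    def test_noise_free_sejp_onset_bounds(self):
        # detected onset is never early, and no later than the time the
        # shape needs to rise 1 mV above baseline
        cfg = GeneratorConfig()
        for amp in (5.0, 9.0, 15.0):
            shape = gen_sejp_shape(amp, cfg.sejp_rise_tau,
                                   cfg.sejp_decay_tau, cfg.dt)
            k = 200
            v = np.full(1000, -43.0)
            v[k:k + len(shape)] += shape
            tr = _trace(v, cfg.dt)
            onset = detect_onset(tr, -43.0, 1.0, peak_idx=k + len(shape) // 2)
            rise_to_1mv = k + int(np.argmax(shape > 1.0))
            assert k <= onset <= rise_to_1mv


class TestSlopeProfile:
    def test_ramp_constant_slope(self):
        tr = _trace(np.arange(20.0), dt=0.5)  # 1 mV/sample
        prof = slope_profile(tr, (0, 20))
        np.testing.assert_allclose(prof, 2.0)

    def test_constant_trace_zero_profile(self):
        prof = slope_profile(_trace(np.full(30, -43.0)), (0, 30))
        np.testing.assert_allclose(prof, 0.0)

    def test_two_slope_foot_is_step(self):
        v = np.concatenate([np.arange(10.0), 9 + 3 * np.arange(10.0)])
        prof = slope_profile(_trace(v, dt=1.0), (0, 20))
        np.testing.assert_allclose(prof[:9], 1.0)
        np.testing.assert_allclose(prof[10:], 3.0)

    def test_length_contract(self):
        prof = slope_profile(_trace(np.zeros(50)), (10, 25))
        assert len(prof) == 14


class TestDetectEoF:
    def test_piecewise_two_slope_valley_at_breakpoint(self):
        # slope 1, then a valley plateau of slope 0.2, then a steep spike:
        # EoF is the instant the slope reaches the valley
        v = np.concatenate([
            np.arange(0, 10, 1.0),              # slope 1 (samples 0-9)
            9 + 0.2 * np.arange(1, 11),         # slope 0.2 (10-19)
            11 + 5.0 * np.arange(1, 11),        # slope 5 (20-29)
        ])
        eof = detect_eof(_trace(v, dt=1.0), 0, 29, RAW)
        assert eof == 10

    def test_junction_of_sejp_plus_spike(self):
        # slow sEJP rise up to the junction, then a fast linear spike:
        # EoF within +/-2 samples of the junction
        cfg = GeneratorConfig()
        shape = gen_sejp_shape(12.0, cfg.sejp_rise_tau, cfg.sejp_decay_tau,
                               cfg.dt)
        j = 24  # junction sample (12 ms into the rise)
        spike = shape[j] + 5.0 * cfg.dt * np.arange(1, 41)
        v = np.concatenate([shape[:j + 1], spike]) - 43.0
        tr = _trace(v, cfg.dt)
        eof = detect_eof(tr, 0, len(v) - 1, RAW)
        assert abs(eof - j) <= 2

    def test_monotone_accelerating_upstroke_flagged(self):
        v = np.expm1(0.25 * np.arange(40.0)) - 43.0
        with pytest.raises(DetectionError):
            detect_eof(_trace(v, dt=0.5), 0, 39, RAW)


class TestDetectEofr:
    def test_linear_repolarization_to_rmp(self):
        rmp = -43.0
        v = np.concatenate([
            rmp + np.arange(0, 50, 5.0),        # rise to peak
            rmp + 45 - 5.0 * np.arange(1, 10),  # linear fall, crosses rmp
            np.full(120, rmp),                  # flat after
        ])
        peak = 9
        eofr, truncated = detect_eofr(_trace(v, dt=0.5), peak, rmp, RAW)
        crossing = peak + int(np.argmax(v[peak:] <= rmp))
        assert not truncated
        assert abs(eofr - crossing) <= 1

    def test_never_flattening_decay_is_truncated(self):
        v = np.concatenate([np.arange(0, 50, 5.0), 45 - 0.1 * np.arange(200)])
        eofr, truncated = detect_eofr(_trace(v, dt=0.5), 9, -43.0, RAW)
        assert truncated

    def test_generator_nap_fast_repolarization(self, true_tpl, gen_config):
        y, truth = compose_ap(true_tpl, a=0.0, b=50.0, c=0.0, d=0.0, nd=0,
                              rmp=-43.0, noise_sd=0.0,
                              rng=np.random.default_rng(0))
        tr = _trace(y, gen_config.dt)
        eofr, truncated = detect_eofr(tr, truth["peak_idx"], -43.0,
                                      AnalysisConfig())
        assert not truncated
        # fast repolarization ends where the trace first re-crosses RMP
        crossing = truth["peak_idx"] + int(
            np.argmax(y[truth["peak_idx"]:] <= -43.0))
        assert abs(eofr - crossing) <= 2


class TestDetectEos:
    def test_return_to_rmp_then_flat(self):
        rmp = -43.0
        k = 60
        v = np.concatenate([rmp + 10 * np.exp(-np.arange(k) / 10.0),
                            np.full(300, rmp)])
        eos, truncated = detect_eos(_trace(v, dt=0.5), 0, rmp, 1.0, RAW)
        assert not truncated
        first_in_band = int(np.argmax(np.abs(v - rmp) < 1.0))
        assert eos == first_in_band

    def test_sahp_duration_from_generator(self, true_tpl, gen_config):
        cfg = AnalysisConfig()
        y, truth = compose_ap(true_tpl, a=13.0, b=40.0, c=3.0, d=0.0, nd=6,
                              rmp=-43.0, noise_sd=0.0,
                              rng=np.random.default_rng(0))
        y = np.concatenate([np.full(100, -43.0), y, np.full(600, -43.0)])
        tr = _trace(y, gen_config.dt)
        peak = int(np.argmax(y))
        eofr, _ = detect_eofr(tr, peak, -43.0, cfg)
        eos, truncated = detect_eos(tr, eofr, -43.0, 1.0, cfg)
        assert not truncated
        # the slow AHP (200 ms course anchored at the peak) ends inside the
        # detected signal span
        assert (eos - peak) * gen_config.dt >= 150.0

    def test_truncated_when_never_quiet(self):
        v = -43.0 + np.linspace(10, 5, 200)
        eos, truncated = detect_eos(_trace(v, dt=0.5), 0, -43.0, 1.0, RAW)
        assert truncated


class TestClassifyAp:
    def test_composite_is_type_a(self, true_tpl, gen_config):
        cfg = AnalysisConfig()
        for nd in (0, 8, 16):
            y, truth = compose_ap(true_tpl, a=13.0, b=40.0, c=0.0, d=0.0,
                                  nd=nd, rmp=-43.0, noise_sd=0.0,
                                  rng=np.random.default_rng(0))
            tr = _trace(np.concatenate([np.full(50, -43.0), y]),
                        gen_config.dt)
            peak = int(np.argmax(tr.samples))
            onset = detect_onset(tr, -43.0, 1.0, peak)
            assert classify_ap(tr, onset, peak, cfg) is APKind.TYPE_A

    def test_ramp_foot_is_type_b(self, gen_config):
        cfg = AnalysisConfig()
        shape = gen_typeb_shape(50.0, 100.0, gen_config.dt)
        tr = _trace(np.concatenate([np.full(50, -43.0), shape - 43.0]),
                    gen_config.dt)
        peak = int(np.argmax(tr.samples))
        onset = detect_onset(tr, -43.0, 1.0, peak)
        assert classify_ap(tr, onset, peak, cfg) is APKind.TYPE_B

    def test_pure_nap_is_not_type_a(self, true_tpl, gen_config):
        cfg = AnalysisConfig()
        y, truth = compose_ap(true_tpl, a=0.0, b=50.0, c=0.0, d=0.0, nd=0,
                              rmp=-43.0, noise_sd=0.0,
                              rng=np.random.default_rng(0))
        tr = _trace(np.concatenate([np.full(50, -43.0), y]), gen_config.dt)
        peak = int(np.argmax(tr.samples))
        onset = detect_onset(tr, -43.0, 1.0, peak)
        assert classify_ap(tr, onset, peak, cfg) is APKind.TYPE_B


class TestAssignGroup:
    @pytest.mark.parametrize("ahp_ms, group", [
        (200.0, "G1"),   # typical slow-AHP course
        (0.0, "G0"),
        (100.0, "G1"),   # boundary: >= 100 ms is G1
        (99.5, "G0"),
    ])
    def test_duration_rule(self, ahp_ms, group, annotated):
        ap = annotated.type_a()[0]
        ap = type(ap)(**{**ap.__dict__, "group": "NA",
                         "ahp_duration": ahp_ms})
        assert assign_group(ap).value == group

    def test_type_b_rejected(self, annotated):
        ap = annotated.type_a()[0]
        bad = type(ap)(**{**ap.__dict__, "kind": "TypeB", "group": "NA"})
        with pytest.raises(DetectionError):
            assign_group(bad)


class TestComputeFeatures:
    def test_triangle_geometry(self):
        rmp = -43.0
        n = 21  # 10 ms up, 10 ms down at dt=1
        up = np.linspace(rmp, -3.0, 11)
        down = np.linspace(-3.0, rmp, 11)[1:]
        v = np.concatenate([np.full(30, rmp), up, down, np.full(80, rmp)])
        tr = _trace(v, dt=1.0)
        feats = compute_features(tr, onset_idx=30, peak_idx=40,
                                 eos_idx=30 + n, rmp=rmp)
        assert feats["amplitude"] == pytest.approx(40.0)
        assert feats["half_width"] == pytest.approx(10.0, abs=0.01)

    def test_sejp_rise_time_matches_closed_form(self, gen_config):
        shape = gen_sejp_shape(9.0, gen_config.sejp_rise_tau,
                               gen_config.sejp_decay_tau, gen_config.dt)
        v = np.concatenate([np.full(40, -43.0), shape - 43.0,
                            np.full(40, -43.0)])
        tr = _trace(v, gen_config.dt)
        peak = int(np.argmax(v))
        feats = compute_features(tr, 40, peak, len(v) - 1, -43.0)
        # independent numeric 10-90% time on the dense closed-form curve
        t = np.arange(0, len(shape)) * gen_config.dt / 10.0
        dense = np.interp(np.arange(0, len(shape) * gen_config.dt, 0.05),
                          np.arange(len(shape)) * gen_config.dt, shape)
        lo = np.argmax(dense >= 0.1 * 9.0) * 0.05
        hi = np.argmax(dense >= 0.9 * 9.0) * 0.05
        assert feats["rise_time"] == pytest.approx(hi - lo, abs=gen_config.dt)

    def test_flat_limb_yields_nan(self):
        rmp = -43.0
        # rises but never falls back below half amplitude before EoS
        v = np.concatenate([np.full(20, rmp), np.linspace(rmp, -3.0, 30)])
        tr = _trace(v, dt=1.0)
        feats = compute_features(tr, 20, 49, 49, rmp)
        assert math.isnan(feats["half_width"])


class TestSelectTrainingCells:
    class _Cell:
        def __init__(self, minutes, n_aps, sejp_amps):
            from apdecomp.core import APAnnotation, SejpAnnotation
            n = int(minutes * 60000 / 0.5)
            self.trace = Trace(samples=np.zeros(max(n, 2)), dt=0.5)
            self.aps = [APAnnotation(id=f"a{i}", kind="TypeA", onset_idx=1,
                                     eof_idx=2, peak_idx=3, eofr_idx=4,
                                     eos_idx=5, rmp=-43, amplitude=50)
                        for i in range(n_aps)]
            self.sejps = [SejpAnnotation(id=f"s{i}", onset_idx=1, peak_idx=2,
                                         end_idx=3, rmp=-43, amplitude=amp)
                          for i, amp in enumerate(sejp_amps)]

    def test_selection_rules(self):
        too_short = self._Cell(4.0, 10, [8.0] * 10)
        boundary_ok = self._Cell(6.0, 5, [5.1] * 5)
        weak_sejps = self._Cell(6.0, 5, [5.0] * 10)   # strict > 5 mV
        few_aps = self._Cell(6.0, 4, [8.0] * 10)
        cells = [too_short, boundary_ok, weak_sejps, few_aps]
        assert select_training_cells(cells) == [boundary_ok]


class TestDetectionOnRecording:
    def test_landmark_ordering_invariant(self, annotated):
        assert annotated.aps, "recording should contain APs"
        for ap in annotated.aps:
            assert (ap.onset_idx <= ap.eof_idx <= ap.peak_idx
                    <= ap.eofr_idx <= ap.eos_idx)

    def test_event_counts_match_ground_truth(self, recording, annotated):
        truth_aps = [e for e in recording.truth if e.kind != "sejp"]
        truth_sejps = recording.events("sejp")
        assert len(annotated.aps) == len(truth_aps)
        assert len(annotated.sejps) == len(truth_sejps)

    def test_kind_agreement_with_generator(self, recording, annotated):
        got = 0
        total = 0
        for ev in recording.truth:
            if ev.kind == "sejp":
                continue
            hit = [ap for ap in annotated.aps
                   if abs(ap.peak_idx - ev.peak_idx) <= 40]
            if not hit:
                continue
            total += 1
            want = APKind.TYPE_A if ev.kind == "typea" else APKind.TYPE_B
            got += hit[0].kind is want
        assert total > 0
        assert got == total

    def test_feature_statistics_in_physiological_range(self, recording,
                                                       annotated):
        # cohort means within 1 SD of the target feature distributions
        sejp_amp = np.mean([s.amplitude for s in annotated.sejps])
        assert abs(sejp_amp - 9.23) < 3.56
        rises = [s.rise_time for s in annotated.sejps
                 if not math.isnan(s.rise_time)]
        assert abs(np.mean(rises) - 22.29) < 13.86
        aps = annotated.type_a()
        assert abs(np.mean([a.amplitude for a in aps]) - 52.49) < 7.60
        hws = [a.half_width for a in aps if not math.isnan(a.half_width)]
        assert abs(np.mean(hws) - 9.62) < 4.03
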