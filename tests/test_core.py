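"""Core types, I/O round trips, normalization and alignment primitives."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from apdecomp.config import AnalysisConfig
from apdecomp.core import (
    AlignmentError,
    APAnnotation,
    ConfigError,
    Decomposition,
    DegenerateInputError,
    LandmarkError,
    RmseThresholds,
    SejpAnnotation,
    TemplateSet,
    Trace,
    TraceFormatError,
    TraceParseError,
    align_by_index,
    anchored_mean,
    load_template,
    normalize_template,
    ragged_mean,
    read_annotations,
    read_trace,
    save_template,
    write_annotations,
    write_trace,
)


# ---------------------------------------------------------------------------
# Trace I/O
# ---------------------------------------------------------------------------

class TestTraceIO:
    def test_direct_parse(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("time_ms,voltage_mV\n0,-43\n1,-43\n2,-42\n")
        tr = read_trace(p)
        assert tr.dt == 1.0
        np.testing.assert_allclose(tr.samples, [-43, -43, -42])

    def test_non_uniform_sampling_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("time_ms,voltage_mV\n0,-43\n1,-43\n2,-42\n4,-41\n")
        with pytest.raises(TraceFormatError, match="non-uniform"):
            read_trace(p)

    def test_non_numeric_row_reports_line(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("time_ms,voltage_mV\n0,-43\n0.5,oops\n1,-42\n")
        with pytest.raises(TraceParseError, match="line 3"):
            read_trace(p)

    @pytest.mark.parametrize("seed", range(8))
    def test_round_trip(self, seed, tmp_path):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 200))
        dt = float(rng.choice([0.5, 0.25, 1.0, 0.1]))
        trace = Trace(samples=rng.normal(-43, 5, n), dt=dt,
                      t0=float(rng.normal(0, 10)))
        p = tmp_path / "t.csv"
        write_trace(p, trace)
        back = read_trace(p)
        np.testing.assert_allclose(back.samples, trace.samples, atol=1e-9)
        assert back.dt == pytest.approx(trace.dt, rel=1e-12)

    def test_trace_validation(self):
        with pytest.raises(TraceFormatError):
            Trace(samples=np.array([1.0, 2.0]), dt=0.0)
        with pytest.raises(TraceFormatError):
            Trace(samples=np.array([1.0]), dt=0.5)
        with pytest.raises(TraceFormatError):
            Trace(samples=np.array([1.0, np.nan]), dt=0.5)


# ---------------------------------------------------------------------------
# Template I/O
# ---------------------------------------------------------------------------

class TestTemplateIO:
    def test_save_load_with_metadata(self, tmp_path):
        v = np.linspace(0, 1, 37)
        p = tmp_path / "tpl.txt"
        save_template(p, v, dt_ms=0.5, mode="peak_positive")
        back, meta = load_template(p)
        np.testing.assert_allclose(back, v, atol=1e-15)
        assert meta["dt_ms"] == "0.5"
        assert meta["mode"] == "peak_positive"

    def test_template_set_round_trip(self, tmp_path, true_tpl):
        true_tpl.save(tmp_path)
        back = TemplateSet.load(tmp_path)
        for name in ("S", "A", "H1", "H2"):
            np.testing.assert_allclose(getattr(back, name),
                                       getattr(true_tpl, name), atol=1e-12)
        assert back.dt == true_tpl.dt
        assert back.h_offset == true_tpl.h_offset

    def test_missing_h_templates_load_as_none(self, tmp_path, true_tpl):
        true_tpl.save(tmp_path)
        (tmp_path / "sahp_template.txt").unlink()
        (tmp_path / "vsahp_template.txt").unlink()
        back = TemplateSet.load(tmp_path)
        assert back.H1 is None and back.H2 is None


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

class TestAnnotations:
    def test_json_round_trip(self, tmp_path):
        events = [
            APAnnotation(id="ap0", kind="TypeA", onset_idx=10, eof_idx=20,
                         peak_idx=40, eofr_idx=60, eos_idx=300, rmp=-43.0,
                         amplitude=50.0, group="G1", ahp_duration=200.0,
                         half_width=9.5, ap_duration=145.0),
            SejpAnnotation(id="s0", onset_idx=5, peak_idx=30, end_idx=100,
                           rmp=-43.0, amplitude=9.0, rise_time=10.0,
                           fall_time=50.0),
        ]
        p = tmp_path / "ev.json"
        write_annotations(p, events)
        back = read_annotations(p)
        assert back[0] == events[0]
        assert back[1] == events[1]

    def test_landmark_order_enforced(self):
        with pytest.raises(LandmarkError):
            APAnnotation(id="x", kind="TypeA", onset_idx=10, eof_idx=5,
                         peak_idx=40, eofr_idx=60, eos_idx=300, rmp=-43,
                         amplitude=50)
        with pytest.raises(LandmarkError):
            SejpAnnotation(id="x", onset_idx=10, peak_idx=10, end_idx=20,
                           rmp=-43, amplitude=9)

    def test_group_only_for_type_a(self):
        with pytest.raises(LandmarkError):
            APAnnotation(id="x", kind="TypeB", onset_idx=0, eof_idx=0,
                         peak_idx=10, eofr_idx=20, eos_idx=30, rmp=-43,
                         amplitude=50, group="G0")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

class TestNormalizeTemplate:
    @pytest.mark.parametrize("v, mode, expected", [
        ([0, 5, 10, 5], "peak_positive", [0, 0.5, 1, 0.5]),
        ([0, -2, -4, -1], "trough_negative", [0, -0.5, -1, -0.25]),
        ([2, 7, 12, 7], "peak_positive", [0, 0.5, 1, 0.5]),
    ])
    def test_linear_scaling(self, v, mode, expected):
        np.testing.assert_allclose(normalize_template(np.array(v, float),
                                                      mode), expected)

    @given(hnp.arrays(np.float64, st.integers(3, 50),
                      elements=st.floats(-50, 50, allow_nan=False)),
           st.floats(0.1, 100.0))
    def test_idempotent_and_scale_invariant(self, v, k):
        base = v - v[0]
        if np.max(base) <= 1e-6:
            return
        n1 = normalize_template(v, "peak_positive")
        np.testing.assert_allclose(normalize_template(n1, "peak_positive"),
                                   n1, atol=1e-12)
        np.testing.assert_allclose(normalize_template(k * v, "peak_positive"),
                                   n1, atol=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize_template(np.full(10, 3.0), "peak_positive")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

class TestAlignByIndex:
    def test_shift_arithmetic(self):
        fixed = np.zeros(30)
        moving = np.arange(10.0)
        aligned, shift = align_by_index(fixed, moving, 10, 3)
        assert shift == 7
        assert aligned[10] == 3.0
        assert np.isnan(aligned[:7]).all()
        assert np.isnan(aligned[17:]).all()

    def test_identical_anchors_zero_shift(self):
        v = np.arange(8.0)
        aligned, shift = align_by_index(v, v, 4, 4)
        assert shift == 0
        np.testing.assert_allclose(aligned, v)

    def test_overlap_length_exhaustive(self):
        fixed = np.zeros(20)
        moving = np.ones(20)
        for fa in range(0, 20, 3):
            for ma in range(0, 20, 3):
                aligned, shift = align_by_index(fixed, moving, fa, ma)
                assert shift == fa - ma
                expected = len(moving) - abs(shift)
                assert np.sum(~np.isnan(aligned)) == expected

    def test_swapped_roles_negate_shift(self):
        a, b = np.zeros(15), np.zeros(12)
        _, s1 = align_by_index(a, b, 9, 2)
        _, s2 = align_by_index(b, a, 2, 9)
        assert s1 == -s2

    def test_anchor_alignment_guarantees_anchor_sample(self):
        # in-bounds anchors always map at least the anchor sample itself
        aligned, shift = align_by_index(np.zeros(5), np.zeros(30), 0, 29)
        assert shift == -29
        assert np.sum(~np.isnan(aligned)) == 1

    def test_out_of_bounds_anchor_raises(self):
        with pytest.raises(AlignmentError):
            align_by_index(np.zeros(5), np.zeros(30), 7, 2)
        with pytest.raises(AlignmentError):
            align_by_index(np.zeros(5), np.zeros(30), 2, 30)


class TestRaggedMeans:
    def test_ragged_mean_uses_available_vectors(self):
        vecs = [np.ones(10), np.ones(20), 3 * np.ones(20)]
        out = ragged_mean(vecs, length_percentile=100)
        assert len(out) == 20
        np.testing.assert_allclose(out[:10], 5 / 3)
        np.testing.assert_allclose(out[10:], 2.0)

    def test_anchored_mean_aligns_peaks(self):
        a = np.array([0, 0, 1.0, 0])
        b = np.array([0, 1.0, 0, 0])
        mean, anchor = anchored_mean([a, b], [2, 1], length_percentile=100)
        assert mean[anchor] == 1.0


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

class TestResultTypes:
    def test_decomposition_delay_interval(self):
        with pytest.raises(Exception):
            Decomposition(ap_id="x", a=1, b=1, c=0, d=0, nd=50, rmse=0.1,
                          n1=0, n2=40)
        dec = Decomposition(ap_id="x", a=1, b=1, c=0, d=0, nd=20, rmse=0.1,
                            threshold_used=0.5, n1=0, n2=40)
        assert dec.good_fit

    def test_thresholds_mean_invariant(self):
        with pytest.raises(ConfigError):
            RmseThresholds(specific={"a": 2.0, "b": 4.0}, universal_T=5.0)
        t = RmseThresholds(specific={"a": 2.0, "b": 4.0}, universal_T=3.0)
        assert t.threshold_for("a") == 2.0
        assert t.threshold_for("unseen") == 3.0


class TestAnalysisConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = AnalysisConfig(onset_threshold_mV=1.5, eos_quiet_ms=40.0)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert AnalysisConfig.from_yaml(p) == cfg

    def test_unknown_key_named(self):
        with pytest.raises(ConfigError, match="bogus_key"):
            AnalysisConfig.from_dict({"bogus_key": 1})

    def test_invalid_values_rejected(self):
        with pytest.raises(ConfigError):
            AnalysisConfig(onset_threshold_mV=-1.0)
        with pytest.raises(ConfigError):
            AnalysisConfig(smoothing_window=4)
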