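"""PseudoECG interval detectors and derived biomarkers."""

import math

import numpy as np
import pytest

from cardiorisk import extract_biomarkers, iceb, qtc, emw
from cardiorisk.biomarkers import (
    delta,
    detect_qrs,
    detect_t_wave,
    qt_only_flag,
)


def _triangle(t, start, peak_t, end, amplitude):
    y = np.zeros_like(t)
    up = (t >= start) & (t <= peak_t)
    down = (t > peak_t) & (t <= end)
    y[up] = amplitude * (t[up] - start) / (peak_t - start)
    y[down] = amplitude * (end - t[down]) / (end - peak_t)
    return y


@pytest.fixture
def synthetic_beat():
    """Triangular QRS (100–140 ms) plus Gaussian T wave (center 300, σ 25)."""
    t = np.arange(0, 600, 0.5)
    qrs = _triangle(t, 100.0, 120.0, 140.0, 1.0)
    t_wave = 0.35 * np.exp(-((t - 300.0) ** 2) / (2 * 25.0**2))
    return t, qrs + t_wave


class TestDetectQrs:
    def test_triangular_deflection_duration(self, synthetic_beat):
        t, phi = synthetic_beat
        q, j = detect_qrs(phi, t)
        # 5% threshold: onset at 101, offset at 139 on each linear limb
        assert q == pytest.approx(101.0, abs=1.5)
        assert j == pytest.approx(139.0, abs=1.5)

    def test_all_zero_signal_unmeasurable(self):
        t = np.arange(0, 500, 0.5)
        q, j = detect_qrs(np.zeros_like(t), t)
        assert math.isnan(q) and math.isnan(j)

    def test_scale_invariance(self, synthetic_beat):
        t, phi = synthetic_beat
        q1, j1 = detect_qrs(phi, t)
        q10, j10 = detect_qrs(10.0 * phi, t)
        assert q1 == q10 and j1 == j10

    def test_negative_polarity_handled(self, synthetic_beat):
        t, phi = synthetic_beat
        q1, j1 = detect_qrs(phi, t)
        q2, j2 = detect_qrs(-phi, t)
        assert q1 == q2 and j1 == j2


class TestDetectTWave:
    def test_linear_limb_tangent_is_exact(self):
        # symmetric triangular T peaking at 300, returning to baseline at 400
        t = np.arange(0, 600, 0.5)
        phi = _triangle(t, 100, 120, 140, 1.0) + _triangle(t, 200, 300, 400, 0.3)
        _, j = detect_qrs(phi, t)
        t_peak, t_end = detect_t_wave(phi, t, j)
        assert t_peak == pytest.approx(300.0, abs=1.0)
        assert t_end == pytest.approx(400.0, abs=1.0)  # tangent of a line is the line

    def test_gaussian_t_end_matches_dense_tangent_oracle(self, synthetic_beat):
        t, phi = synthetic_beat
        _, j = detect_qrs(phi, t)
        t_peak, t_end = detect_t_wave(phi, t, j)
        assert t_peak == pytest.approx(300.0, abs=1.0)
        # independent brute-force tangent on a dense grid
        td = np.arange(250, 450, 0.001)
        yd = 0.35 * np.exp(-((td - 300.0) ** 2) / (2 * 25.0**2))
        sd = np.gradient(yd, td)
        k = int(np.argmin(sd))
        oracle = td[k] - yd[k] / sd[k]
        assert oracle == pytest.approx(350.0, abs=0.1)  # analytic: center + 2σ
        assert t_end == pytest.approx(oracle, abs=2.0)

    def test_flat_post_j_signal_unmeasurable(self):
        t = np.arange(0, 600, 0.5)
        phi = _triangle(t, 100, 120, 140, 1.0)
        _, j = detect_qrs(phi, t)
        t_peak, t_end = detect_t_wave(phi, t, j)
        assert math.isnan(t_peak) or math.isnan(t_end)

    def test_interval_identity(self, synthetic_beat):
        t, phi = synthetic_beat
        q, j = detect_qrs(phi, t)
        t_peak, t_end = detect_t_wave(phi, t, j)
        qt = t_end - q
        jtpeak = t_peak - j
        tpeak_tend = t_end - t_peak
        assert jtpeak + tpeak_tend == pytest.approx(qt - (j - q), abs=1e-9)


class TestScalarBiomarkers:
    @pytest.mark.parametrize("method", ["fridericia", "bazett"])
    def test_qtc_identity_at_unit_cycle_length(self, method):
        assert qtc(350.0, 1000.0, method) == pytest.approx(350.0)

    def test_qtc_fridericia_at_study_rr(self):
        assert qtc(350.0, 808.0, "fridericia") == pytest.approx(
            350.0 / 0.808 ** (1.0 / 3.0), rel=1e-9
        )
        assert qtc(350.0, 808.0, "fridericia") == pytest.approx(375.8, abs=0.1)

    def test_qtc_decreasing_in_rr(self):
        rrs = np.linspace(500, 1200, 20)
        vals = [qtc(350.0, r) for r in rrs]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("qt, qrs, expected", [(360, 90, 4.0), (400, 100, 4.0)])
    def test_iceb_quotient(self, qt, qrs, expected):
        assert iceb(qt, qrs) == expected

    def test_iceb_scale_invariance(self):
        assert iceb(360.0 * 3, 90.0 * 3) == iceb(360.0, 90.0)

    def test_iceb_unmeasurable_for_nonpositive_qrs(self):
        assert math.isnan(iceb(360.0, 0.0))

    def test_emw_sign_convention(self):
        assert emw(360.0, 380.0) == 20.0
        assert emw(380.0, 360.0) == -20.0
        assert math.isnan(emw(float("nan"), 360.0))

    def test_delta_antisymmetry(self):
        assert delta(375.0, 375.0) == 0.0
        assert delta(390.0, 375.0) == 15.0
        assert delta(375.0, 390.0) == -delta(390.0, 375.0)

    def test_qt_only_flag(self):
        assert not qt_only_flag({0.1: 0.0, 1.0: 0.0})
        assert qt_only_flag({0.1: 5.0, 1.0: 25.0}, threshold_ms=10.0)
        assert qt_only_flag({1.0: 10.0}, threshold_ms=10.0)  # >= convention


class TestExtractBiomarkers:
    def test_baseline_fiber_all_measurable(self, baseline_fiber):
        bm = extract_biomarkers(baseline_fiber)
        for name in ("qrs", "qt", "qtc", "jtpeak", "tpeak_tend", "emw", "iceb"):
            assert bm.is_measurable(name), name
        assert bm.qt > bm.qrs > 0
        assert 200 < bm.qt < 500

    def test_iceb_identity_machine_precision(self, baseline_fiber, ikr_blocked_fiber):
        for res in (baseline_fiber, ikr_blocked_fiber):
            bm = extract_biomarkers(res)
            assert bm.iceb == bm.qt / bm.qrs

    def test_subinterval_identity_within_tolerance(self, baseline_fiber):
        bm = extract_biomarkers(baseline_fiber)
        assert bm.jtpeak + bm.tpeak_tend == pytest.approx(bm.qt - bm.qrs, abs=2.0)

    def test_determinism(self, baseline_fiber):
        b1 = extract_biomarkers(baseline_fiber)
        b2 = extract_biomarkers(baseline_fiber)
        assert b1.to_dict() == b2.to_dict()

    def test_ikr_block_direction(self, baseline_fiber, ikr_blocked_fiber):
        base = extract_biomarkers(baseline_fiber)
        blocked = extract_biomarkers(ikr_blocked_fiber)
        assert blocked.qt > base.qt
        assert blocked.iceb > base.iceb
        assert blocked.emw < base.emw
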