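import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from albind.errors import DomainError, InsufficientDataError
from albind.quenching import (
    KQ_STATIC_THRESHOLD,
    Mechanism,
    analyze_titration,
    classify_mechanism,
    double_log_fit,
    ife_correct,
    stern_volmer_fit,
)
from albind.synthetic import QuenchingGroundTruth, generate_titration, titration_design


class TestIfeCorrect:
    def test_zero_absorbance_identity(self):
        assert ife_correct(123.4, 0.0, 0.0) == 123.4

    def test_direct_evaluation(self):
        assert ife_correct(100.0, 0.1, 0.1) == pytest.approx(100.0 * np.e**0.1)

    @given(
        a_ex=st.floats(0, 2), a_em=st.floats(0, 2), bump=st.floats(1e-6, 1.0)
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_absorbance(self, a_ex, a_em, bump):
        f = 50.0
        assert ife_correct(f, a_ex + bump, a_em) > ife_correct(f, a_ex, a_em)
        assert ife_correct(f, a_ex, a_em) >= f

    def test_negative_absorbance_rejected(self):
        with pytest.raises(DomainError):
            ife_correct(1.0, -0.1, 0.0)


class TestSternVolmer:
    def test_exact_line_recovered(self):
        q = np.array([0.0, 1e-5, 2e-5, 4e-5, 8e-5])
        res = stern_volmer_fit(q, 1.0 + 2.0e4 * q, temperature_K=296.0)
        assert res.Ksv_per_M == pytest.approx(2.0e4, rel=1e-12)
        assert res.r_squared == pytest.approx(1.0)
        assert res.intercept == pytest.approx(1.0)

    def test_no_quenching_zero_slope(self):
        res = stern_volmer_fit([0.0, 1e-5, 2e-5], [1.0, 1.0, 1.0])
        assert res.Ksv_per_M == pytest.approx(0.0, abs=1e-9)

    def test_kq_is_ksv_over_tau0_bitexact(self):
        q = np.array([0.0, 2e-5, 4e-5, 6e-5])
        res = stern_volmer_fit(q, 1.0 + 1.832e4 * q, tau0_s=1e-8)
        # a Ksv of 1.832e4 M⁻¹ with τ0 = 10⁻⁸ s gives Kq = 1.832e12 M⁻¹s⁻¹
        assert res.Kq_per_M_s == res.Ksv_per_M / res.tau0_s
        assert res.Kq_per_M_s == pytest.approx(1.832e12, rel=1e-9)

    def test_insufficient_points(self):
        with pytest.raises(InsufficientDataError):
            stern_volmer_fit([0.0, 1e-5], [1.0, 1.2])

    def test_negative_slope_warns_not_raises(self):
        q = np.array([0.0, 1e-5, 2e-5])
        with pytest.warns(UserWarning, match="negative_Ksv"):
            res = stern_volmer_fit(q, [1.0, 0.95, 0.9])
        assert "negative_Ksv" in res.warnings

    def test_duplicate_concentrations_averaged(self):
        q = [0.0, 1e-5, 1e-5, 2e-5]
        ratios = [1.0, 1.15, 1.25, 1.4]
        res = stern_volmer_fit(q, ratios)
        merged = stern_volmer_fit([0.0, 1e-5, 2e-5], [1.0, 1.2, 1.4])
        assert res.Ksv_per_M == pytest.approx(merged.Ksv_per_M)

    def test_noiseless_recovery_within_0p1_percent(self):
        gt = QuenchingGroundTruth(Ksv_dynamic_per_M=1.6e4)
        conc = np.concatenate([[0.0], np.linspace(1e-5, 1e-4, 8)])
        series = generate_titration(gt, conc, 296.0)
        qres, _ = analyze_titration(series)
        assert qres.Ksv_per_M == pytest.approx(1.6e4, rel=1e-3)


class TestClassifyMechanism:
    def _result(self, ksv, T, tau0=1e-8):
        q = np.array([0.0, 1e-5, 2e-5, 4e-5])
        return stern_volmer_fit(q, 1.0 + ksv * q, tau0_s=tau0, temperature_K=T)

    def test_high_kq_and_increasing_ksv_is_mixed(self):
        results = [
            self._result(k, T)
            for k, T in [(1.593e4, 296.0), (1.619e4, 303.0), (1.832e4, 310.0)]
        ]
        assert all(r.Kq_per_M_s > KQ_STATIC_THRESHOLD for r in results)
        assert classify_mechanism(results) is Mechanism.mixed

    def test_low_kq_increasing_ksv_is_dynamic(self):
        # τ0 chosen so Kq = Ksv/τ0 stays below the 2e10 threshold
        results = [self._result(k, T, tau0=1e-2) for k, T in [(1e4, 296.0), (2e4, 310.0)]]
        assert classify_mechanism(results) is Mechanism.dynamic

    def test_high_kq_decreasing_ksv_is_static(self):
        results = [self._result(k, T) for k, T in [(2e4, 296.0), (1e4, 310.0)]]
        assert classify_mechanism(results) is Mechanism.static

    def test_single_temperature_low_confidence(self):
        with pytest.warns(UserWarning, match="single temperature"):
            verdict = classify_mechanism([self._result(2e4, 310.0)])
        assert verdict is Mechanism.static


class TestDoubleLog:
    def test_identity_line(self):
        # (F0−F)/F = [Q] exactly → Ka = 1 M⁻¹, n = 1
        q = np.array([0.0, 1e-3, 1e-2, 1e-1])
        F0 = 100.0
        F = F0 / (1.0 + q)
        res = double_log_fit(q, F0, F)
        assert res.Ka_per_M == pytest.approx(1.0, rel=1e-9)
        assert res.n_sites == pytest.approx(1.0, rel=1e-9)

    def test_generator_round_trip_exact(self):
        gt = QuenchingGroundTruth(Ka_per_M=4923.0, n_sites=0.901)
        series = generate_titration(gt, titration_design(4923.0, 0.901), 296.0)
        _, bres = analyze_titration(series)
        assert bres.Ka_per_M == pytest.approx(4923.0, rel=1e-9)
        assert bres.n_sites == pytest.approx(0.901, rel=1e-9)

    def test_scale_invariance(self):
        q = np.array([0.0, 1e-5, 3e-5, 1e-4])
        F = np.array([100.0, 80.0, 60.0, 30.0])
        a = double_log_fit(q, 100.0, F)
        b = double_log_fit(q, 200.0, 2.0 * F)
        assert a.Ka_per_M == pytest.approx(b.Ka_per_M)
        assert a.n_sites == pytest.approx(b.n_sites)

    def test_unquenched_points_excluded_and_counted(self):
        q = np.array([0.0, 1e-6, 1e-5, 3e-5, 1e-4])
        F = np.array([100.0, 101.0, 80.0, 60.0, 30.0])  # F ≥ F0 at 1e-6
        res = double_log_fit(q, 100.0, F)
        assert res.n_excluded == 1
        assert res.n_used == 3
        assert res.n_used + res.n_excluded == np.count_nonzero(q)

    def test_insufficient_usable_points(self):
        q = np.array([0.0, 1e-5, 3e-5])
        F = np.array([100.0, 101.0, 60.0])
        with pytest.raises(InsufficientDataError):
            double_log_fit(q, 100.0, F)
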