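import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import trapezoid

from albind.errors import DomainError
from albind.fret import (
    analyze_fret,
    binding_distance,
    efficiency_from_intensities,
    forster_radius,
    overlap_integral,
    transfer_efficiency,
)
from albind.spectra import AxisKind, Spectrum

NM_TO_CM = 1e-7


def _gauss_pair(seed):
    """Random smooth donor/acceptor pair with guaranteed overlap."""
    rng = np.random.default_rng(seed)
    lam = np.arange(300.0, 540.0, 0.5)
    dc = rng.uniform(330, 400)
    F = rng.uniform(50, 2000) * np.exp(-((lam - dc) ** 2) / (2 * rng.uniform(15, 40) ** 2))
    conc = rng.uniform(1e-7, 1e-5)
    ac = dc + rng.uniform(-30, 30)
    A = conc * rng.uniform(5e3, 5e4) * np.exp(-((lam - ac) ** 2) / (2 * rng.uniform(10, 35) ** 2))
    donor = Spectrum(AxisKind.wavelength_nm, lam, F)
    acceptor = Spectrum(AxisKind.wavelength_nm, lam, A)
    return donor, acceptor, conc


class TestOverlapIntegral:
    def test_rectangular_closed_form(self):
        # donor flat on [400,500] nm, ε = 1e4 flat on [450,500] nm:
        # J = 1e4 · ∫_{450nm}^{500nm} λ⁴ dλ / ∫_{400nm}^{500nm} dλ  (λ in cm)
        lam = np.arange(400.0, 500.0 + 1e-9, 0.05)
        donor = Spectrum(AxisKind.wavelength_nm, lam, np.ones_like(lam))
        acc_lam = lam[lam >= 450.0]
        conc = 1e-6
        acceptor = Spectrum(
            AxisKind.wavelength_nm, acc_lam, np.full(acc_lam.size, 1e4 * conc)
        )
        lo, hi, full_lo = 450e-7, 500e-7, 400e-7
        expected = 1e4 * (hi**5 - lo**5) / 5.0 / (hi - full_lo)
        J = overlap_integral(donor, acceptor, conc, 1.0)
        assert J == pytest.approx(expected, rel=5e-3)

    def test_disjoint_supports_zero_with_warning(self):
        donor = Spectrum(AxisKind.wavelength_nm, [300.0, 310, 320], [1.0, 2, 1])
        acceptor = Spectrum(AxisKind.wavelength_nm, [400.0, 410, 420], [0.1, 0.2, 0.1])
        with pytest.warns(UserWarning, match="disjoint"):
            assert overlap_integral(donor, acceptor, 1e-6) == 0.0

    def test_donor_rescaling_invariance(self):
        donor, acceptor, conc = _gauss_pair(3)
        J1 = overlap_integral(donor, acceptor, conc)
        scaled = Spectrum(donor.axis_kind, donor.axis, 10.0 * donor.intensity)
        assert overlap_integral(scaled, acceptor, conc) == pytest.approx(J1, rel=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_trapezoid_oracle(self, seed):
        donor, acceptor, conc = _gauss_pair(seed)
        lam_cm = donor.axis * NM_TO_CM
        eps = acceptor.intensity / conc  # same grid by construction
        oracle = trapezoid(donor.intensity * eps * lam_cm**4, lam_cm) / trapezoid(
            donor.intensity, lam_cm
        )
        J = overlap_integral(donor, acceptor, conc)
        assert J == pytest.approx(oracle, rel=1e-3)

    def test_wavenumber_axis_rejected(self):
        s = Spectrum(AxisKind.wavenumber_cm1, [1600.0, 1650, 1700], [1.0, 2, 1])
        d = Spectrum(AxisKind.wavelength_nm, [300.0, 310, 320], [1.0, 2, 1])
        with pytest.raises(DomainError):
            overlap_integral(s, d, 1e-6)
        with pytest.raises(DomainError):
            overlap_integral(d, s, 1e-6)


class TestForsterRadius:
    def test_zero_overlap_zero_radius(self):
        assert forster_radius(0.0) == 0.0

    def test_sixth_root_scaling(self):
        r1 = forster_radius(1e-17)
        r2 = forster_radius(1e-11)
        assert r2 / r1 == pytest.approx(10.0, rel=1e-12)

    def test_direct_evaluation(self):
        # brute-force arithmetic: R0^6 = 8.8e-25 · (2/3) · 1.336^-4 · 0.118 · J
        J = 1.183e-17
        r0_cm6 = 8.8e-25 * (2.0 / 3.0) * 1.336**-4 * 0.118 * J
        expected_nm = r0_cm6 ** (1 / 6) * 1e7
        assert forster_radius(J, 2.0 / 3.0, 1.336, 0.118) == pytest.approx(
            expected_nm, rel=1e-12
        )


class TestEfficiencyDistance:
    def test_published_triplet_consistency(self):
        # critical distance 1.170 nm and donor–acceptor distance 2.017 nm
        assert transfer_efficiency(1.170, 2.017) == pytest.approx(0.0367, abs=5e-4)
        assert binding_distance(0.0367, 1.170) == pytest.approx(2.017, abs=5e-3)

    def test_half_transfer_at_r_equals_r0(self):
        assert transfer_efficiency(2.5, 2.5) == pytest.approx(0.5)
        assert binding_distance(0.5, 2.5) == pytest.approx(2.5, rel=1e-12)

    def test_monotone_decay_to_zero(self):
        rs = np.linspace(1.0, 50.0, 40)
        es = [transfer_efficiency(2.0, r) for r in rs]
        assert all(a > b for a, b in zip(es, es[1:]))
        assert es[-1] < 1e-6

    @given(
        E=st.floats(1e-6, 1.0 - 1e-6),
        R0=st.floats(0.1, 10.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_exact_inverse_pair(self, E, R0):
        r = binding_distance(E, R0)
        assert transfer_efficiency(R0, r) == pytest.approx(E, rel=1e-9)

    def test_efficiency_from_intensities(self):
        assert efficiency_from_intensities(10.0, 10.0) == 0.0
        assert efficiency_from_intensities(0.9633 * 80.0, 80.0) == pytest.approx(0.0367)
        assert efficiency_from_intensities(40.0, 80.0) == pytest.approx(0.5)
        with pytest.raises(DomainError):
            efficiency_from_intensities(90.0, 80.0)


class TestAnalyzeFret:
    def test_short_distance_flags_nonradiative(self):
        res = analyze_fret(F=0.9633, F0=1.0, R0_nm=1.170)
        assert res.nonradiative  # r ≈ 2 nm < 8 nm
        assert res.E == pytest.approx(0.0367)
        assert transfer_efficiency(res.R0_nm, res.r_nm) == pytest.approx(res.E, rel=1e-9)

    def test_supplied_r0_reported_alongside_j_derived(self):
        donor, acceptor, conc = _gauss_pair(5)
        res = analyze_fret(
            F=0.9,
            F0=1.0,
            donor_emission=donor,
            acceptor_absorption=acceptor,
            acceptor_conc_M=conc,
            R0_nm=1.170,
        )
        assert res.R0_nm == 1.170
        assert res.R0_from_J_nm is not None
        assert res.J_cm3_L_per_mol > 0
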