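import numpy as np
import pytest

from albind.errors import DomainError
from albind.secondary_structure import (
    STRUCTURE_CLASSES,
    AmideIDeconvolution,
    SecondaryStructure,
    assign_band,
    cd_helix_content,
    compare_structures,
    deconvolve_amide_i,
    helix_fraction,
    mre,
)
from albind.synthetic import AmideIGroundTruth, generate_amide_i
from conftest import amide_class_truth, amide_ground_truth


class TestAssignment:
    @pytest.mark.parametrize(
        "center,expected",
        [
            (1610.0, "beta_sheet"),
            (1639.99, "beta_sheet"),
            (1640.0, "random_coil"),  # left-closed boundary
            (1645.0, "random_coil"),
            (1650.0, "alpha_helix"),
            (1655.0, "alpha_helix"),
            (1658.0, "beta_turn"),  # 1658–1660 mapped to β-turn
            (1680.0, "beta_turn"),
            (1700.0, "beta_turn"),
        ],
    )
    def test_range_table(self, center, expected):
        assert assign_band(center) == expected


class TestDeconvolution:
    def test_single_band_pure_helix(self):
        grid = np.arange(1580.0, 1721.0, 1.0)
        spec = generate_amide_i(AmideIGroundTruth([(1655.0, 5.0, 1.0)]), grid)
        ss = deconvolve_amide_i(spec)
        assert ss.fractions["alpha_helix"] == pytest.approx(1.0, abs=1e-3)

    def test_single_band_random_coil(self):
        grid = np.arange(1580.0, 1721.0, 1.0)
        spec = generate_amide_i(AmideIGroundTruth([(1645.0, 4.0, 1.0)]), grid)
        ss = deconvolve_amide_i(spec)
        assert ss.fractions["random_coil"] == pytest.approx(1.0, abs=2e-2)

    def test_seven_band_recovery_noiseless(self, amide_spectrum):
        truth = amide_class_truth()
        ss = deconvolve_amide_i(amide_spectrum)
        assert len(ss.band_fits) == 7
        for k in STRUCTURE_CLASSES:
            assert ss.fractions[k] == pytest.approx(truth[k], abs=0.02)

    def test_seven_band_recovery_one_percent_noise(self):
        grid = np.arange(1580.0, 1721.0, 1.0)
        truth = amide_class_truth()
        spec = generate_amide_i(amide_ground_truth(noise_sd_rel=0.01, seed=5), grid)
        ss = deconvolve_amide_i(spec)
        for k in STRUCTURE_CLASSES:
            assert ss.fractions[k] == pytest.approx(truth[k], abs=0.05)

    def test_fractions_sum_to_one(self, amide_spectrum):
        ss = deconvolve_amide_i(amide_spectrum)
        assert sum(ss.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_estimator_transform_vector(self, amide_spectrum):
        est = AmideIDeconvolution().fit(amide_spectrum)
        vec = est.transform(None)
        assert vec.shape == (1, 4)
        assert vec.sum() == pytest.approx(1.0)

    def test_accepts_xy_arrays(self, amide_spectrum):
        est = AmideIDeconvolution().fit(
            amide_spectrum.axis.reshape(-1, 1), amide_spectrum.intensity
        )
        assert len(est.bands_) == 7

    def test_wavelength_axis_rejected(self):
        from albind.spectra import AxisKind, Spectrum

        s = Spectrum(AxisKind.wavelength_nm, [300.0, 301, 302], [1.0, 2, 1])
        with pytest.raises(DomainError):
            deconvolve_amide_i(s)


class TestMreHelix:
    def test_zero_cd_zero_mre(self):
        assert mre(0.0, 2e-6, 585, 1.0) == 0.0

    def test_linearity(self):
        assert mre(-20.0, 2e-6, 585, 1.0) == pytest.approx(
            2 * mre(-10.0, 2e-6, 585, 1.0)
        )

    def test_path_length_in_cm(self):
        # 1 mm path → denominator 10·Cp·n·0.1
        assert mre(-23.4, 2e-6, 585, 1.0) == pytest.approx(
            -23.4 / (10 * 2e-6 * 585 * 0.1)
        )

    @pytest.mark.parametrize(
        "mre_208,expected",
        [(-4000.0, 0.0), (-33000.0, 100.0), (-18500.0, 50.0)],
    )
    def test_helix_anchor_points(self, mre_208, expected):
        assert helix_fraction(mre_208) == pytest.approx(expected)

    def test_clamping(self):
        assert helix_fraction(-40000.0) == 100.0
        assert helix_fraction(0.0) == 0.0

    def test_affine_decreasing_on_unclamped_range(self):
        xs = np.linspace(-32000, -5000, 10)
        ys = [helix_fraction(x) for x in xs]
        assert all(a > b for a, b in zip(ys, ys[1:]))
        d = np.diff(ys) / np.diff(xs)
        np.testing.assert_allclose(d, d[0], rtol=1e-9)

    def test_cd_helix_content_record(self):
        res = cd_helix_content(-2.34, 2e-6, 585, 1.0)
        assert res.mre_208 == pytest.approx(-2000.0)
        assert res.helix_percent == 0.0


class TestCompareStructures:
    def test_identical_no_change(self):
        a = SecondaryStructure.from_percent(22.04, 33.63, 27.49, 16.84)
        change = compare_structures(a, a)
        assert all(v == 0 for v in change.deltas_percent.values())
        assert not change.loosening

    def test_published_free_vs_bound_composition(self):
        free = SecondaryStructure.from_percent(22.04, 33.63, 27.49, 16.84)
        bound = SecondaryStructure.from_percent(15.22, 39.35, 28.24, 17.19)
        change = compare_structures(free, bound)
        assert change.deltas_percent["alpha_helix"] == pytest.approx(-6.82, abs=0.01)
        assert change.loosening

    def test_helix_increase_not_flagged(self):
        a = SecondaryStructure.from_percent(20.0, 30.0, 30.0, 20.0)
        b = SecondaryStructure.from_percent(30.0, 25.0, 25.0, 20.0)
        assert not compare_structures(a, b).loosening


class TestValidation:
    def test_fraction_sum_enforced(self):
        with pytest.raises(DomainError):
            SecondaryStructure(
                {"alpha_helix": 0.5, "beta_sheet": 0.2, "beta_turn": 0.2, "random_coil": 0.2}
            )
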