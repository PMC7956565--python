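"""CD quantification: MRE conversion, helix fraction, state classification,
two-state titration fitting, isodichroic detection, thermal scans and basis
unmixing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from idpchar import constants as C
from idpchar.cdspec import (
    BasisDeconvolver,
    CDSpectrum,
    ThermalScan,
    TwoStateTitration,
    classify_double_wavelength,
    deconvolve_basis,
    default_basis,
    detect_isodichroic,
    fit_two_state_titration,
    from_mre,
    helix_fraction,
    helix_mre_reference,
    thermal_reversibility,
    to_mre,
    two_state_model,
)
from idpchar.synthgen import gen_cd_family, gen_titration, make_crossing_bases

WL = np.arange(190.0, 261.0, 1.0)


def raw_spectrum(signal, **meta):
    defaults = dict(pathlength_cm=0.1, conc_mg_ml=0.12, n_residues=83, mm_da=9200.0)
    defaults.update(meta)
    return CDSpectrum(wavelengths=WL, signal=np.asarray(signal, float), units="delta_a", **defaults)


class TestMRE:
    def test_null_signal(self):
        out = to_mre(raw_spectrum(np.zeros(WL.size)))
        assert np.all(out.signal == 0) and out.units == "mre"

    def test_known_conversion(self):
        # dA 1e-3, l 0.1 cm, c 0.12 mg/mL, n 83, M 9200 -> ~3.047e4
        out = to_mre(raw_spectrum(np.full(WL.size, 1e-3)))
        assert out.signal[0] == pytest.approx(30481.9, rel=1e-4)

    def test_inverse_linearity_in_concentration(self):
        a = to_mre(raw_spectrum(np.ones(WL.size), conc_mg_ml=0.12))
        b = to_mre(raw_spectrum(np.ones(WL.size), conc_mg_ml=0.24))
        assert np.allclose(a.signal, 2 * b.signal)

    @given(st.floats(-1e-2, 1e-2, allow_nan=False))
    def test_round_trip_identity(self, level):
        spec = raw_spectrum(np.full(WL.size, level))
        back = from_mre(to_mre(spec))
        assert np.allclose(back.signal, spec.signal, atol=1e-12)

    def test_double_conversion_rejected(self):
        spec = to_mre(raw_spectrum(np.ones(WL.size)))
        with pytest.raises(ValueError):
            to_mre(spec)

    def test_missing_metadata_rejected(self):
        with pytest.raises(ValueError):
            to_mre(CDSpectrum(wavelengths=WL, signal=np.ones(WL.size), units="delta_a"))


class TestHelixFraction:
    def test_zero_signal(self):
        assert helix_fraction(0.0, 83) == (0.0, False)

    def test_saturation(self):
        ref = helix_mre_reference(83)
        frac, clipped = helix_fraction(ref, 83)
        assert frac == pytest.approx(1.0) and not clipped

    def test_reference_at_83_residues(self):
        assert helix_mre_reference(83) == pytest.approx(-38276.9, abs=0.1)

    def test_reference_limit(self):
        assert helix_mre_reference(10**7) == pytest.approx(C.HELIX_MRE_INF, rel=1e-6)

    def test_monotone_in_mre(self):
        f1, _ = helix_fraction(-10000, 83)
        f2, _ = helix_fraction(-20000, 83)
        assert f2 > f1

    def test_clipping_flag(self):
        frac, clipped = helix_fraction(-50000, 83)
        assert frac == 1.0 and clipped

    def test_too_short(self):
        with pytest.raises(ValueError):
            helix_mre_reference(2)


class TestDoubleWavelength:
    @pytest.mark.parametrize(
        "mre200,mre222,label",
        [
            (-17000, -1500, "RC-like"),
            (-12000, -6000, "PMG-like"),
            (-5000, -12000, "folded/other"),
            (-19000, -1700, "RC-like"),
            (-10700, -3900, "PMG-like"),
        ],
    )
    def test_classification(self, mre200, mre222, label):
        assert classify_double_wavelength(mre200, mre222) == label


class TestTwoStateFit:
    def test_noise_free_self_consistency(self):
        grid = np.arange(0, 51, 10.0)
        rt = C.R_KCAL * 293.15
        clean = two_state_model(grid, 27.0, 0.049, 0.05, 0.40, rt)
        fit = fit_two_state_titration(np.column_stack([grid, clean]))
        assert fit.cm == pytest.approx(27.0, rel=1e-6)
        assert fit.m_value == pytest.approx(0.049, rel=1e-6)
        assert fit.f_min == pytest.approx(0.05, rel=1e-6)
        assert fit.f_max == pytest.approx(0.40, rel=1e-6)
        assert fit.dg0 == pytest.approx(27.0 * 0.049, rel=1e-6)

    def test_midpoint_is_half_transition(self):
        fit_rt = C.R_KCAL * 293.15
        val = two_state_model(33.0, 33.0, 0.08, 0.1, 0.5, fit_rt)
        assert val == pytest.approx((0.1 + 0.5) / 2, rel=1e-12)

    def test_requires_five_points(self):
        with pytest.raises(ValueError):
            fit_two_state_titration([(0, 0.1), (10, 0.2), (20, 0.3), (30, 0.4)])

    def test_extrapolation_flagged(self):
        grid = np.arange(0, 26, 5.0)
        rt = C.R_KCAL * 293.15
        clean = two_state_model(grid, 40.0, 0.1, 0.05, 0.6, rt)
        fit = fit_two_state_titration(np.column_stack([grid, clean]))
        assert fit.extrapolated

    def test_molar_conversion(self):
        grid = np.arange(0, 51, 10.0)
        rt = C.R_KCAL * 293.15
        clean = two_state_model(grid, 27.0, 0.049, 0.05, 0.40, rt)
        fit = fit_two_state_titration(np.column_stack([grid, clean]))
        assert fit.m_value_molar == pytest.approx(0.049 / 0.1393, rel=1e-6)

    def test_recovery_bias_below_three_percent(self):
        # well-sampled transitions, dense grid, bias-corrected estimator
        grid = np.arange(0, 51, 5.0)
        n_rep = 150
        for cm_true, m_true in [(27.0, 0.049), (20.0, 0.06), (15.0, 0.1)]:
            _, curves, _ = gen_titration(
                cm_true, m_true, 0.05, 0.40, grid, 0.01, replicates=n_rep, seed=97
            )
            cms, ms = [], []
            for k, y in enumerate(curves):
                est = TwoStateTitration(
                    bias_correction="bootstrap", sigma=0.01, n_boot=40,
                    random_state=1000 + k,
                ).fit(grid, y)
                cms.append(est.cm_)
                ms.append(est.m_value_)
            assert abs(np.mean(cms) / cm_true - 1) < 0.03
            assert abs(np.mean(ms) / m_true - 1) < 0.03

    def test_estimator_params_round_trip(self):
        est = TwoStateTitration(temperature_k=300.0)
        clone = TwoStateTitration().set_params(**est.get_params())
        assert clone.get_params() == est.get_params()


class TestIsodichroic:
    def test_constructed_crossing_recovered(self):
        b1, b2 = make_crossing_bases(WL, 202.0)
        weights = [(w, 1 - w) for w in np.linspace(0, 1, 6)]
        spectra, _ = gen_cd_family([b1, b2], weights, WL, noise=0.0, seed=0)
        hit = detect_isodichroic(spectra)
        assert hit is not None
        assert hit[0] == pytest.approx(202.0, abs=1.0)

    def test_noisy_crossing_within_one_nm(self):
        b1, b2 = make_crossing_bases(WL, 202.0)
        weights = [(w, 1 - w) for w in np.linspace(0, 1, 6)]
        spectra, _ = gen_cd_family([b1, b2], weights, WL, noise=150.0, seed=3)
        hit = detect_isodichroic(spectra)
        assert hit is not None
        assert hit[0] == pytest.approx(202.0, abs=1.0)

    def test_identical_spectra_degenerate(self):
        sig = default_basis(WL)["unordered"]
        spectra = [CDSpectrum(wavelengths=WL, signal=sig, units="mre") for _ in range(4)]
        assert detect_isodichroic(spectra) is None

    def test_subset_selection(self):
        b1, b2 = make_crossing_bases(WL, 204.0)
        weights = [(w, 1 - w) for w in np.linspace(0, 1, 5)]
        spectra, _ = gen_cd_family([b1, b2], weights, WL, noise=0.0, seed=0)
        # an outlier spectrum (offset) destroys the crossing; excluding it restores it
        outlier = CDSpectrum(wavelengths=WL, signal=b1 + 5000.0, units="mre")
        assert detect_isodichroic(spectra)[0] == pytest.approx(204.0, abs=1.0)
        hit_all = detect_isodichroic(list(spectra) + [outlier])
        assert hit_all is None or abs(hit_all[0] - 204.0) > 0 or hit_all[1] > 0

    def test_requires_three_spectra(self):
        sig = default_basis(WL)["helix"]
        spectra = [CDSpectrum(wavelengths=WL, signal=sig, units="mre")] * 2
        with pytest.raises(ValueError):
            detect_isodichroic(spectra)


class TestThermal:
    def test_identical_traces_reversible(self):
        t = np.arange(20.0, 81.0, 2.0)
        h = -3000 + 10 * t
        slope, hyst, rev = thermal_reversibility(ThermalScan(t, h, cooling=h))
        assert hyst == 0.0 and rev

    def test_flat_trace_zero_slope(self):
        t = np.arange(20.0, 81.0, 2.0)
        h = np.full(t.size, -1500.0)
        slope, _, _ = thermal_reversibility(ThermalScan(t, h))
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_known_slope_recovered_under_noise(self, rng):
        t = np.arange(20.0, 81.0, 2.0)
        true_slope = 12.5
        h = true_slope * t + rng.normal(0, 30.0, t.size)
        slope, _, _ = thermal_reversibility(ThermalScan(t, h))
        # analytic standard error of the regression slope
        resid = h - (slope * t + np.mean(h - slope * t))
        se = np.sqrt(np.sum(resid**2) / (t.size - 2) / np.sum((t - t.mean()) ** 2))
        assert abs(slope - true_slope) < 2 * se + 1e-9

    def test_hysteretic_scan_flagged(self):
        t = np.arange(20.0, 81.0, 2.0)
        h = -3000 + 40 * t
        c = h + 500.0
        _, hyst, rev = thermal_reversibility(ThermalScan(t, h, cooling=c))
        assert hyst > 0.05 and not rev


class TestDeconvolution:
    def test_pure_basis_member(self):
        basis = default_basis(WL)
        spec = CDSpectrum(wavelengths=WL, signal=basis["helix"], units="mre")
        fractions, resid = deconvolve_basis(spec, basis)
        assert fractions["helix"] == pytest.approx(1.0, abs=1e-9)
        assert resid == pytest.approx(0.0, abs=1e-6)

    def test_exact_half_mixture(self):
        basis = default_basis(WL)
        mix = 0.5 * basis["helix"] + 0.5 * basis["unordered"]
        spec = CDSpectrum(wavelengths=WL, signal=mix, units="mre")
        fractions, _ = deconvolve_basis(spec, {"helix": basis["helix"], "unordered": basis["unordered"]})
        assert fractions["helix"] == pytest.approx(0.5, abs=1e-9)
        assert fractions["unordered"] == pytest.approx(0.5, abs=1e-9)

    def test_noisy_three_class_recovery(self, rng):
        basis = default_basis(WL)
        names = ["helix", "strand", "unordered"]
        truth = np.array([0.25, 0.30, 0.45])
        mix = sum(w * basis[k] for w, k in zip(truth, names))
        noise = 0.02 * np.abs(mix).max()
        spec = CDSpectrum(wavelengths=WL, signal=mix + rng.normal(0, noise, WL.size), units="mre")
        fractions, _ = deconvolve_basis(spec, {k: basis[k] for k in names})
        for w, k in zip(truth, names):
            assert fractions[k] == pytest.approx(w, abs=0.05)

    @given(st.floats(0, 1, allow_nan=False))
    def test_fractions_simplex(self, w):
        basis = default_basis(WL)
        mix = w * basis["helix"] + (1 - w) * basis["strand"]
        dec = BasisDeconvolver().fit({"helix": basis["helix"], "strand": basis["strand"]})
        fractions, _ = dec.transform(mix)
        assert all(0 <= v <= 1 for v in fractions.values())
        assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_ill_conditioned_basis_rejected(self):
        b = default_basis(WL)["helix"]
        with pytest.raises(ValueError):
            BasisDeconvolver().fit({"a": b, "b": b * (1 + 1e-14)})
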