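import numpy as np
import pytest

from mrsynth import (
    ModelParams,
    add_noise,
    apply_eddy,
    apply_phi0,
    apply_phi1,
    default_baseline_config,
    default_water_config,
    make_b0_map,
    make_toy_basis,
    scale_and_shape,
    simulate,
    sum_components,
    to_spectrum,
)
from mrsynth.model import _apply_phases_and_eddy

from _oracles import fwhm_hz, measured_snr, peak_freq


def _params(basis, **kwargs):
    base = dict(
        amplitude={n: 1.0 for n in basis.names},
        lorentz={n: 0.0 for n in basis.names},
    )
    base.update(kwargs)
    return ModelParams(**base)


class TestScaleAndShape:
    def test_identity_when_all_parameters_neutral(self, singlet_basis, axes):
        out = scale_and_shape(singlet_basis, _params(singlet_basis), axes)
        np.testing.assert_array_equal(out["NAA"], singlet_basis.fid("NAA"))

    def test_lorentzian_fwhm_closed_form(self, axes):
        """e^{-dt} corresponds to a Lorentzian of FWHM d/pi Hz."""
        basis = make_toy_basis(
            [("S", "metabolite", [(4.65, 1.0)])], 2000, 4096, 127.7, 4.65, decay_fwhm_hz=0.0
        )
        rng = np.random.default_rng(8)
        for d in rng.uniform(3.0, 60.0, 20):
            p = _params(basis, lorentz={"S": float(d)})
            fid = scale_and_shape(basis, p, axes)["S"]
            assert abs(fwhm_hz(fid, axes) - d / np.pi) <= axes.hz_per_bin

    def test_zero_amplitude_removes_component(self, multi_basis, axes):
        p = _params(multi_basis)
        p.amplitude["Cr"] = 0.0
        out = scale_and_shape(multi_basis, p, axes)
        assert np.all(out["Cr"] == 0)

    def test_gaussian_broadening_by_group(self, multi_basis, axes):
        p = _params(multi_basis, gauss_metab=50.0, gauss_mm=0.0)
        out = scale_and_shape(multi_basis, p, axes)
        t2 = axes.t**2
        np.testing.assert_allclose(
            out["NAA"], multi_basis.fid("NAA") * np.exp(-50.0 * t2), rtol=1e-12
        )
        # the macromolecule group has its own (here zero) gaussian term
        np.testing.assert_array_equal(out["MM09"], multi_basis.fid("MM09"))

    def test_per_name_frequency_shift(self, singlet_basis, axes):
        p = _params(singlet_basis, freq_shift={"NAA": 80.0})
        fid = scale_and_shape(singlet_basis, p, axes)["NAA"]
        shift = peak_freq(fid, axes) - peak_freq(singlet_basis.fid("NAA"), axes)
        assert abs(shift - 80.0) <= axes.hz_per_bin

    def test_missing_parameter_rejected(self, multi_basis, axes):
        p = _params(multi_basis)
        del p.amplitude["NAA"]
        with pytest.raises(ValueError, match="NAA"):
            scale_and_shape(multi_basis, p, axes)


class TestSumComponents:
    def test_reassociation(self):
        rng = np.random.default_rng(2)
        comps = [rng.normal(size=64) + 1j * rng.normal(size=64) for _ in range(10)]
        total = sum_components(comps)
        pairwise = comps[0]
        for c in comps[1:]:
            pairwise = pairwise + c
        np.testing.assert_allclose(total, pairwise, rtol=1e-12)

    def test_two_equal_components_double(self):
        x = np.ones(8, complex)
        np.testing.assert_array_equal(sum_components([x, x]), 2 * x)


class TestNoise:
    def test_sigma_definition(self, singlet_basis, axes):
        fid = singlet_basis.fid("NAA")
        _, noise_fid = add_noise(fid, snr0=10.0, ref_peak_height=1.0, rng=0)
        noise_spec = to_spectrum(noise_fid)
        # sigma = ref / snr0 = 0.1 in each spectral channel
        assert np.std(noise_spec.real) == pytest.approx(0.1, rel=0.05)
        assert np.std(noise_spec.imag) == pytest.approx(0.1, rel=0.05)

    @pytest.mark.parametrize("snr0", [5.0, 15.0, 50.0])
    def test_monte_carlo_snr_recovery(self, singlet_basis, axes, snr0):
        """Measured spectral SNR matches the request within 5% over 200 seeds."""
        fid = singlet_basis.fid("NAA")
        clean_spec = to_spectrum(fid)
        ref = float(np.max(clean_spec.real))
        k = int(np.argmax(clean_spec.real))  # ground-truth peak bin: unbiased at low SNR
        vals = [
            measured_snr(add_noise(fid, snr0, ref, rng=seed)[0], axes, peak_bin=k)
            for seed in range(200)
        ]
        assert np.mean(vals) == pytest.approx(snr0, rel=0.05)

    def test_correlated_noise_uses_quadrature_pair(self, singlet_basis):
        fid = singlet_basis.fid("NAA")
        _, noise_fid = add_noise(fid, 10.0, 1.0, noise_correlated=True, rng=1)
        from mrsynth.fourier import quadrature

        spec = to_spectrum(noise_fid)
        np.testing.assert_allclose(spec.imag, quadrature(spec.real).imag, atol=1e-9)

    def test_invalid_snr_rejected(self, singlet_basis):
        with pytest.raises(ValueError):
            add_noise(singlet_basis.fid("NAA"), 0.0, 1.0)


class TestPhases:
    def test_phi0_identity_and_negation(self, singlet_basis):
        fid = singlet_basis.fid("NAA")
        np.testing.assert_array_equal(apply_phi0(fid, 0.0), fid)
        np.testing.assert_allclose(apply_phi0(fid, 180.0), -fid, atol=1e-12)

    def test_phi0_90_converts_absorption_to_dispersion(self, axes):
        basis = make_toy_basis([("S", "metabolite", [(4.65, 1.0)])], 2000, 4096, 127.7, 4.65)
        spec = to_spectrum(apply_phi0(basis.fid("S"), 90.0))
        # dispersion real channel integrates to ~0 while absorption does not
        absorption = to_spectrum(basis.fid("S")).real
        assert abs(np.sum(spec.real)) < 1e-6 * np.sum(absorption)

    def test_phi1_reference_bin_invariant(self, multi_basis, axes):
        spec = to_spectrum(sum_components(scale_and_shape(multi_basis, _params(multi_basis), axes)))
        k_ref = axes.n_points // 2
        for phi1 in (15.0, 45.0, 170.0):
            phased = apply_phi1(spec, phi1, 4.65, axes)
            assert phased[k_ref] == spec[k_ref]
            np.testing.assert_allclose(np.abs(phased), np.abs(spec), rtol=1e-12)

    def test_phi1_rotation_one_ppm_from_pivot(self, axes):
        spec = np.ones(axes.n_points, complex)
        phased = apply_phi1(spec, 90.0, 4.65, axes)
        k = np.argmin(np.abs(axes.ppm - 5.65))
        expected = np.exp(-1j * np.pi / 2 * (axes.ppm[k] - 4.65))
        assert phased[k] == pytest.approx(expected, rel=1e-9)


class TestEddy:
    def test_zero_amplitude_identity(self, singlet_basis, axes):
        fid = singlet_basis.fid("NAA")
        np.testing.assert_array_equal(apply_eddy(fid, 0.0, -1.0, axes), fid)

    def test_long_time_constant_is_global_shift(self, singlet_basis, axes):
        fid = singlet_basis.fid("NAA")
        out = apply_eddy(fid, 5.0, 1e6, axes)
        shift = peak_freq(out, axes) - peak_freq(fid, axes)
        assert abs(shift - 5.0) <= axes.hz_per_bin

    def test_short_time_constant_distorts_but_preserves_magnitude(self, singlet_basis, axes):
        fid = singlet_basis.fid("NAA")
        out = apply_eddy(fid, 5.0, 0.15, axes)
        np.testing.assert_allclose(np.abs(out), np.abs(fid), rtol=1e-12)
        assert not np.allclose(out, fid)

    def test_invalid_time_constant_rejected(self, singlet_basis, axes):
        with pytest.raises(ValueError):
            apply_eddy(singlet_basis.fid("NAA"), 5.0, 0.0, axes)


class TestOperatorPowerConservation:
    def test_phase_and_eddy_preserve_spectral_power(self, multi_basis, axes):
        fid = sum_components(scale_and_shape(multi_basis, _params(multi_basis), axes))
        p0 = np.sum(np.abs(to_spectrum(fid)) ** 2)
        p_phi0 = np.sum(np.abs(to_spectrum(apply_phi0(fid, 37.0))) ** 2)
        p_phi1 = np.sum(np.abs(apply_phi1(to_spectrum(fid), 45.0, 4.65, axes)) ** 2)
        p_eddy = np.sum(np.abs(to_spectrum(apply_eddy(fid, 5.0, 0.15, axes))) ** 2)
        for p in (p_phi0, p_phi1, p_eddy):
            assert p == pytest.approx(p0, rel=1e-9)


class TestSimulate:
    def test_artifacts_off_returns_scaled_basis_sum(self, multi_basis, axes):
        p = _params(multi_basis)
        rec = simulate(multi_basis, p, axes, seed=0)
        expected = sum_components(scale_and_shape(multi_basis, p, axes))
        np.testing.assert_allclose(rec.fid, expected, rtol=1e-12)

    def test_linearity_in_amplitudes(self, multi_basis, axes):
        p1 = _params(multi_basis, amplitude={"NAA": 1.0, "Cr": 0.5, "MM09": 0.2})
        p2 = _params(multi_basis, amplitude={"NAA": 0.3, "Cr": 1.5, "MM09": 0.1})
        p12 = _params(
            multi_basis,
            amplitude={n: p1.amplitude[n] + p2.amplitude[n] for n in multi_basis.names},
        )
        f1 = simulate(multi_basis, p1, axes).fid
        f2 = simulate(multi_basis, p2, axes).fid
        f12 = simulate(multi_basis, p12, axes).fid
        np.testing.assert_allclose(f1 + f2, f12, rtol=1e-9, atol=1e-12)

    def test_reconstruction_audit(self, multi_basis, axes):
        """Recomposing the stored ground-truth parts reproduces the output."""
        p = _params(
            multi_basis,
            lorentz={n: 4.0 for n in multi_basis.names},
            phi0=20.0,
            phi1=30.0,
            eddy_amp=3.0,
            eddy_tc=0.15,
            snr=15.0,
            snr_ref="NAA",
            b0=make_b0_map((6, 6, 6), 0.25, 0.25, 0.25, 5.0),
            baseline=default_baseline_config(),
            residual_water=default_water_config(),
            freq_shift_nuisance=2.0,
        )
        rec = simulate(multi_basis, p, axes, seed=3)
        gt = rec.ground_truth
        parts = (
            gt["metabolite_fid"]
            + gt["baseline_fid"]
            + gt["residual_water_fid"]
            + gt["noise_fid"]
        )
        recomposed = _apply_phases_and_eddy(parts, p, axes)
        scale = np.max(np.abs(rec.fid))
        np.testing.assert_allclose(recomposed, rec.fid, atol=1e-6 * scale)

    def test_component_sum_matches_metabolite_fid(self, multi_basis, axes):
        rec = simulate(multi_basis, _params(multi_basis), axes, seed=0)
        np.testing.assert_allclose(
            sum(rec.ground_truth["components"].values()),
            rec.ground_truth["metabolite_fid"],
            rtol=1e-12,
        )

    def test_transient_stage_defers_noise(self, multi_basis, axes):
        from mrsynth import sample_coil_params

        p = _params(multi_basis, snr=15.0, coil=sample_coil_params(8, 1))
        rec = simulate(multi_basis, p, axes, seed=5, stage="transients")
        assert rec.transients.shape == (8, axes.n_points)
        # the stored record FID itself is noiseless
        assert np.all(rec.ground_truth["noise_fid"] == 0)

    def test_unknown_stage_rejected(self, multi_basis, axes):
        with pytest.raises(ValueError, match="stage"):
            simulate(multi_basis, _params(multi_basis), axes, stage="spectrum")

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(amplitude={"A": -1.0}, lorentz={"A": 0.0})
        with pytest.raises(ValueError):
            ModelParams(amplitude={"A": 1.0}, lorentz={"A": 0.0}, snr=-5.0)
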