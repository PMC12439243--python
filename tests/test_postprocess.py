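import numpy as np
import pytest

from mrsynth import (
    ModelParams,
    ProcessParams,
    apodize,
    crop_resample,
    export_record,
    from_spectrum,
    import_record,
    make_axes,
    make_b0_map,
    make_toy_basis,
    process_record,
    sample_coil_params,
    simulate,
    to_spectrum,
    zero_fill,
)

from _oracles import fwhm_hz


class TestApodize:
    def test_zero_is_identity(self, singlet_basis, axes):
        fid = singlet_basis.fid("NAA")
        np.testing.assert_array_equal(apodize(fid, 0.0, axes), fid)

    def test_broadening_matches_lorentzian_closed_form(self, axes):
        """exp(-t*TL) adds TL/pi Hz of Lorentzian width."""
        basis = make_toy_basis(
            [("S", "metabolite", [(4.65, 1.0)])], 2000, 4096, 127.7, 4.65, decay_fwhm_hz=1.0
        )
        fid = basis.fid("S")
        rng = np.random.default_rng(12)
        for tl in rng.uniform(3.0, 40.0, 10):
            out = apodize(fid, tl, axes)
            assert abs(fwhm_hz(out, axes) - (1.0 + tl / np.pi)) <= axes.hz_per_bin

    def test_magnitude_non_increasing(self, singlet_basis, axes):
        fid = singlet_basis.fid("NAA")
        out = apodize(fid, 10.0, axes)
        assert np.all(np.abs(out) <= np.abs(fid) + 1e-15)

    def test_negative_rejected(self, singlet_basis, axes):
        with pytest.raises(ValueError):
            apodize(singlet_basis.fid("NAA"), -1.0, axes)


class TestZeroFill:
    def test_same_length_identity(self, singlet_basis):
        fid = singlet_basis.fid("NAA")
        np.testing.assert_array_equal(zero_fill(fid, len(fid)), fid)

    def test_doubling_preserves_power(self, singlet_basis):
        fid = singlet_basis.fid("NAA")
        out = zero_fill(fid, 2 * len(fid))
        assert out.shape[-1] == 2 * len(fid)
        assert np.sum(np.abs(out) ** 2) == pytest.approx(np.sum(np.abs(fid) ** 2))

    def test_truncation_rejected(self, singlet_basis):
        with pytest.raises(ValueError):
            zero_fill(singlet_basis.fid("NAA"), 100)


class TestTransformConvention:
    def test_unit_exponential_lands_on_positive_bin(self, axes):
        """exp(+i 2 pi f t) peaks at +f: the declared sign convention."""
        f = 25 * axes.hz_per_bin
        fid = np.exp(2j * np.pi * f * axes.t)
        spec = to_spectrum(fid, axes)
        assert axes.freq[np.argmax(np.abs(spec))] == pytest.approx(f)

    def test_round_trip_identity(self, axes):
        rng = np.random.default_rng(1)
        fid = rng.normal(size=axes.n_points) + 1j * rng.normal(size=axes.n_points)
        np.testing.assert_allclose(from_spectrum(to_spectrum(fid, axes), axes), fid, atol=1e-12)

    def test_zeros_map_to_zeros(self, axes):
        assert np.all(to_spectrum(np.zeros(axes.n_points), axes) == 0)


class TestCropResample:
    def test_identity_on_same_grid(self, axes):
        rng = np.random.default_rng(3)
        spec = rng.normal(size=axes.n_points) + 1j * rng.normal(size=axes.n_points)
        out, ppm = crop_resample(
            spec, axes, (axes.ppm.min(), axes.ppm.max()), axes.n_points
        )
        np.testing.assert_allclose(out, spec, atol=1e-10)
        np.testing.assert_allclose(ppm, axes.ppm, atol=1e-12)

    def test_linear_ramp_reproduced_exactly(self, axes):
        spec = (2.0 * axes.ppm + 1.0) + 1j * (axes.ppm - 3.0)
        out, ppm = crop_resample(spec, axes, (1.0, 8.0), 777)
        np.testing.assert_allclose(out.real, 2.0 * ppm + 1.0, atol=1e-9)
        np.testing.assert_allclose(out.imag, ppm - 3.0, atol=1e-9)

    def test_window_limits_respected(self, axes):
        rng = np.random.default_rng(4)
        spec = rng.normal(size=axes.n_points).astype(complex)
        out, ppm = crop_resample(spec, axes, (1.2, 4.2), 256)
        assert ppm[0] == 1.2 and ppm[-1] == 4.2 and len(out) == 256

    def test_window_outside_span_rejected(self, axes):
        with pytest.raises(ValueError):
            crop_resample(np.ones(axes.n_points, complex), axes, (-20.0, 2.0), 64)


class TestRecordIO:
    def _record(self, multi_basis, axes):
        p = ModelParams(
            amplitude={n: 1.0 for n in multi_basis.names},
            lorentz={n: 3.0 for n in multi_basis.names},
            snr=15.0,
            snr_ref="NAA",
            b0=make_b0_map((4, 4, 4), 0.2, 0.2, 0.2, 3.0),
        )
        return simulate(multi_basis, p, axes, seed=7, stage="processed")

    def test_container_round_trip_bit_exact(self, multi_basis, axes, tmp_path):
        rec = self._record(multi_basis, axes)
        path = export_record(rec, tmp_path / "r.h5")
        rec2 = import_record(path)
        assert np.array_equal(rec2.fid, rec.fid)
        assert np.array_equal(rec2.spectrum, rec.spectrum)
        assert np.array_equal(
            rec2.ground_truth["baseline_fid"], rec.ground_truth["baseline_fid"]
        )
        assert rec2.params.snr == 15.0
        assert rec2.params.b0.mu == 3.0
        np.testing.assert_array_equal(rec2.params.b0.grid, rec.params.b0.grid)

    def test_nifti_mrs_round_trip(self, multi_basis, axes, tmp_path):
        rec = self._record(multi_basis, axes)
        path = export_record(rec, tmp_path / "r.nii", "nifti_mrs")
        rec2 = import_record(path)
        np.testing.assert_allclose(rec2.fid, rec.fid, rtol=1e-12)
        assert rec2.axes.dwell == axes.dwell  # dwell time preserved exactly
        assert rec2.axes.f0 == axes.f0

    def test_nifti_mrs_coil_dimension(self, multi_basis, axes, tmp_path):
        p = ModelParams(
            amplitude={n: 1.0 for n in multi_basis.names},
            lorentz={n: 3.0 for n in multi_basis.names},
            snr=15.0,
            coil=sample_coil_params(8, rng=0),
        )
        rec = simulate(multi_basis, p, axes, seed=1, stage="transients")
        path = export_record(rec, tmp_path / "t.nii", "nifti_mrs")
        rec2 = import_record(path)
        assert rec2.transients.shape == (8, axes.n_points)
        np.testing.assert_allclose(rec2.transients, rec.transients, rtol=1e-12)

    def test_malformed_container_names_missing_field(self, tmp_path):
        import h5py

        path = tmp_path / "bad.h5"
        with h5py.File(path, "w") as h:
            h.create_dataset("fid", data=np.ones(8, complex))
        with pytest.raises(ValueError, match="missing"):
            import_record(path)

    def test_unknown_format_rejected(self, multi_basis, axes, tmp_path):
        rec = self._record(multi_basis, axes)
        with pytest.raises(ValueError):
            export_record(rec, tmp_path / "r.xyz", "dicom")


class TestProcessRecord:
    def test_full_chain(self, multi_basis, axes):
        p = ModelParams(
            amplitude={n: 1.0 for n in multi_basis.names},
            lorentz={n: 3.0 for n in multi_basis.names},
        )
        rec = simulate(multi_basis, p, axes, seed=0)
        pp = ProcessParams(
            apodize_hz=2.0, zero_fill_len=2 * axes.n_points, ppm_window=(0.5, 4.2), out_points=512
        )
        out = process_record(rec, pp)
        assert out.spectrum.shape == (512,)
        assert out.ground_truth["ppm"][0] == 0.5
        np.testing.assert_array_equal(out.fid, rec.fid)  # raw FID untouched

    def test_zero_fill_changes_grid_density(self, multi_basis, axes):
        p = ModelParams(
            amplitude={n: 1.0 for n in multi_basis.names},
            lorentz={n: 3.0 for n in multi_basis.names},
        )
        rec = simulate(multi_basis, p, axes, seed=0)
        out = process_record(rec, ProcessParams(zero_fill_len=2 * axes.n_points))
        assert out.spectrum.shape == (2 * axes.n_points,)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            ProcessParams(apodize_hz=-1.0)
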