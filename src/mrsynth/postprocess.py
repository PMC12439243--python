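"""Post-processing (apodization, zero-fill, Fourier transform, crop/resample)
and record import/export (HDF5 container and NIfTI-MRS)."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import NamedTuple, Optional

import h5py
import nibabel as nib
import numpy as np
from scipy.interpolate import Akima1DInterpolator

from .b0 import B0Map
from .basis import Axes, make_axes
from .fourier import from_spectrum as _from_spectrum
from .fourier import to_spectrum as _to_spectrum
from .model import ModelParams, SimRecord
from .nuisance import WalkConfig
from .transients import CoilParams

__all__ = [
    "ProcessParams",
    "apodize",
    "zero_fill",
    "to_spectrum",
    "from_spectrum",
    "crop_resample",
    "ResampledSpectrum",
    "export_record",
    "import_record",
    "params_to_dict",
    "params_from_dict",
]

#: ecode registered for the NIfTI-MRS JSON header extension
_NIFTI_MRS_ECODE = 44


@dataclass(frozen=True)
class ProcessParams:
    """Post-processing knobs: apodization frequency (Hz), zero-fill target
    length, crop window (ppm) and resample length."""

    apodize_hz: float = 0.0  # TL
    zero_fill_len: Optional[int] = None
    ppm_window: Optional[tuple[float, float]] = None
    out_points: Optional[int] = None

    def __post_init__(self) -> None:
        if self.apodize_hz < 0:
            raise ValueError("apodization frequency must be >= 0")


def apodize(fid: np.ndarray, tl: float, axes: Axes) -> np.ndarray:
    """Multiply the FID by ``exp(-t * TL)``.

    Adds Lorentzian broadening of ``TL / pi`` Hz; TL = 0 is the identity.
    """
    if tl < 0:
        raise ValueError("apodization frequency must be >= 0")
    fid = np.asarray(fid)
    if fid.shape[-1] != axes.n_points:
        raise ValueError("FID length does not match the axes")
    return fid * np.exp(-axes.t * tl)


def zero_fill(fid: np.ndarray, length: int) -> np.ndarray:
    """Append zeros up to ``length`` samples (spectral interpolation only)."""
    fid = np.asarray(fid)
    n = fid.shape[-1]
    if length < n:
        raise ValueError(f"zero-fill target {length} is shorter than the FID ({n})")
    if length == n:
        return fid.copy()
    pad = [(0, 0)] * (fid.ndim - 1) + [(0, length - n)]
    return np.pad(fid, pad)


def to_spectrum(fid: np.ndarray, axes: Axes | None = None) -> np.ndarray:
    """Forward transform onto the ppm grid (zero frequency at ``ppm_ref``)."""
    fid = np.asarray(fid)
    if axes is not None and fid.shape[-1] != axes.n_points:
        raise ValueError("FID length does not match the axes")
    return _to_spectrum(fid)


def from_spectrum(spectrum: np.ndarray, axes: Axes | None = None) -> np.ndarray:
    """Inverse of :func:`to_spectrum`; round-trips to 1e-12."""
    spectrum = np.asarray(spectrum)
    if axes is not None and spectrum.shape[-1] != axes.n_points:
        raise ValueError("spectrum length does not match the axes")
    return _from_spectrum(spectrum)


class ResampledSpectrum(NamedTuple):
    spectrum: np.ndarray
    ppm: np.ndarray


def crop_resample(
    spectrum: np.ndarray,
    axes: Axes,
    ppm_window: tuple[float, float],
    out_points: int,
) -> ResampledSpectrum:
    """Crop to a ppm window and resample with modified-Akima interpolation.

    Real and imaginary channels are interpolated separately with the
    monotone-safe ``makima`` piecewise cubic, which is exact at original
    nodes and reproduces linear data exactly.
    """
    lo, hi = ppm_window
    if hi <= lo:
        raise ValueError("ppm_window must be an increasing interval")
    if lo < axes.ppm.min() - 1e-12 or hi > axes.ppm.max() + 1e-12:
        raise ValueError("ppm_window lies outside the axes span")
    if out_points < 2:
        raise ValueError("out_points must be >= 2")
    spectrum = np.asarray(spectrum)
    new_ppm = np.linspace(lo, hi, out_points)
    re = Akima1DInterpolator(axes.ppm, spectrum.real, method="makima")(new_ppm)
    im = Akima1DInterpolator(axes.ppm, spectrum.imag, method="makima")(new_ppm)
    return ResampledSpectrum(re + 1j * im, new_ppm)


# --------------------------------------------------------------------------
# parameter (de)serialization


def _walk_to_dict(cfg: WalkConfig | None):
    if cfg is None:
        return None
    d = asdict(cfg)
    if d["ppm_span"] is not None:
        d["ppm_span"] = list(d["ppm_span"])
    return d


def _walk_from_dict(d) -> WalkConfig | None:
    if d is None:
        return None
    if d.get("ppm_span") is not None:
        d = dict(d, ppm_span=tuple(d["ppm_span"]))
    return WalkConfig(**d)


def params_to_dict(p: ModelParams) -> dict:
    """JSON-serializable view of ModelParams (B0 grid stored separately)."""
    return {
        "amplitude": dict(p.amplitude),
        "lorentz": dict(p.lorentz),
        "gauss_metab": p.gauss_metab,
        "gauss_mm": p.gauss_mm,
        "freq_shift": dict(p.freq_shift),
        "freq_shift_global": p.freq_shift_global,
        "freq_shift_nuisance": p.freq_shift_nuisance,
        "phi0": p.phi0,
        "phi1": p.phi1,
        "eddy_amp": p.eddy_amp,
        "eddy_tc": p.eddy_tc,
        "snr": p.snr,
        "snr_ref": p.snr_ref,
        "noise_correlated": p.noise_correlated,
        "baseline": _walk_to_dict(p.baseline),
        "residual_water": _walk_to_dict(p.residual_water),
        "b0": None
        if p.b0 is None
        else {"dx": p.b0.dx, "dy": p.b0.dy, "dz": p.b0.dz, "mu": p.b0.mu},
        "coil": None
        if p.coil is None
        else {
            "n_transients": p.coil.n_transients,
            "sens": p.coil.sens.tolist(),
            "snr_scale": p.coil.snr_scale.tolist(),
            "freq_drift": p.coil.freq_drift.tolist(),
            "phase_drift": p.coil.phase_drift.tolist(),
        },
    }


def params_from_dict(d: dict, b0_grid: np.ndarray | None = None) -> ModelParams:
    d = dict(d)
    b0 = None
    if d.get("b0") is not None:
        if b0_grid is None:
            raise ValueError("parameter dict references a B0 map but no grid was provided")
        b0 = B0Map(b0_grid, d["b0"]["dx"], d["b0"]["dy"], d["b0"]["dz"], d["b0"]["mu"])
    coil = None
    if d.get("coil") is not None:
        c = d["coil"]
        coil = CoilParams(
            c["n_transients"],
            np.array(c["sens"]),
            np.array(c["snr_scale"]),
            np.array(c["freq_drift"]),
            np.array(c["phase_drift"]),
        )
    return ModelParams(
        amplitude=dict(d["amplitude"]),
        lorentz=dict(d["lorentz"]),
        gauss_metab=d["gauss_metab"],
        gauss_mm=d["gauss_mm"],
        freq_shift=dict(d["freq_shift"]),
        freq_shift_global=d["freq_shift_global"],
        freq_shift_nuisance=d["freq_shift_nuisance"],
        phi0=d["phi0"],
        phi1=d["phi1"],
        eddy_amp=d["eddy_amp"],
        eddy_tc=d["eddy_tc"],
        snr=d["snr"],
        snr_ref=d["snr_ref"],
        noise_correlated=d["noise_correlated"],
        b0=b0,
        baseline=_walk_from_dict(d.get("baseline")),
        residual_water=_walk_from_dict(d.get("residual_water")),
        coil=coil,
    )


# --------------------------------------------------------------------------
# record container


def _write_container(record: SimRecord, path: Path) -> None:
    with h5py.File(path, "w") as h:
        h.attrs["spectral_width"] = record.axes.spectral_width
        h.attrs["f0"] = record.axes.f0
        h.attrs["ppm_ref"] = record.axes.ppm_ref
        h.attrs["n_points"] = record.axes.n_points
        h.attrs["params"] = json.dumps(params_to_dict(record.params))
        h.create_dataset("fid", data=record.fid, track_times=False)
        if record.spectrum is not None:
            h.create_dataset("spectrum", data=record.spectrum, track_times=False)
        if record.transients is not None:
            h.create_dataset("transients", data=record.transients, track_times=False)
        gt = h.create_group("ground_truth")
        for key, value in record.ground_truth.items():
            if value is None:
                continue
            if key == "components":
                comp = gt.create_group("components")
                for name, arr in value.items():
                    comp.create_dataset(name, data=arr, track_times=False)
            elif np.isscalar(value):
                gt.attrs[key] = value
            else:
                gt.create_dataset(key, data=np.asarray(value), track_times=False)


def _read_container(path: Path) -> SimRecord:
    with h5py.File(path, "r") as h:
        for key in ("spectral_width", "f0", "ppm_ref", "params"):
            if key not in h.attrs:
                raise ValueError(f"record container {path} is missing field {key!r}")
        axes = make_axes(
            float(h.attrs["spectral_width"]),
            int(h.attrs["n_points"]),
            float(h.attrs["f0"]),
            float(h.attrs["ppm_ref"]),
        )
        gt: dict = {}
        if "ground_truth" in h:
            grp = h["ground_truth"]
            gt.update({k: grp.attrs[k] for k in grp.attrs})
            for k in grp:
                if k == "components":
                    gt["components"] = {name: grp["components"][name][()] for name in grp[k]}
                else:
                    gt[k] = grp[k][()]
        params = params_from_dict(json.loads(h.attrs["params"]), gt.get("b0_grid"))
        return SimRecord(
            fid=h["fid"][()],
            axes=axes,
            params=params,
            spectrum=h["spectrum"][()] if "spectrum" in h else None,
            transients=h["transients"][()] if "transients" in h else None,
            ground_truth=gt,
        )


# --------------------------------------------------------------------------
# NIfTI-MRS


def _write_nifti_mrs(record: SimRecord, path: Path) -> None:
    axes = record.axes
    header_json: dict = {
        "SpectrometerFrequency": [axes.f0],
        "ResonantNucleus": ["1H"],
        "SpectralWidth": axes.spectral_width,
        "PpmReference": axes.ppm_ref,
    }
    if record.transients is not None:
        # time dimension 4, tagged coil dimension 5
        data = record.transients.T.reshape(1, 1, 1, axes.n_points, -1)
        header_json["dim_5"] = "DIM_COIL"
    else:
        data = np.asarray(record.fid).reshape(1, 1, 1, axes.n_points)
    data = np.ascontiguousarray(data.astype(np.complex128))
    img = nib.Nifti2Image(data, np.eye(4))
    img.header.set_data_dtype(np.complex128)
    img.header["pixdim"][4] = axes.dwell
    img.header.extensions.append(
        nib.nifti1.Nifti1Extension(_NIFTI_MRS_ECODE, json.dumps(header_json).encode("utf-8"))
    )
    nib.save(img, str(path))


def _read_nifti_mrs(path: Path) -> SimRecord:
    img = nib.load(str(path))
    ext = None
    for e in img.header.extensions:
        if e.get_code() == _NIFTI_MRS_ECODE:
            ext = json.loads(e.get_content().decode("utf-8"))
            break
    if ext is None:
        raise ValueError(f"{path} carries no NIfTI-MRS JSON header extension")
    data = np.asanyarray(img.dataobj)
    dwell = float(img.header["pixdim"][4])
    n_points = data.shape[3]
    axes = make_axes(
        ext.get("SpectralWidth", 1.0 / dwell),
        n_points,
        float(ext["SpectrometerFrequency"][0]),
        float(ext.get("PpmReference", 4.65)),
    )
    transients = None
    if data.ndim >= 5 and data.shape[4] > 1:
        transients = data.reshape(n_points, -1).T
        fid = transients.mean(axis=0)
    else:
        fid = data.reshape(n_points)
    placeholder = ModelParams(amplitude={}, lorentz={})
    return SimRecord(fid=fid, axes=axes, params=placeholder, transients=transients)


def export_record(record: SimRecord, path: str | Path, format: str = "container") -> Path:
    """Write a record as an HDF5 container (lossless) or NIfTI-MRS file."""
    path = Path(path)
    if format == "container":
        _write_container(record, path)
    elif format == "nifti_mrs":
        _write_nifti_mrs(record, path)
    else:
        raise ValueError(f"unknown export format {format!r}")
    return path


def import_record(path: str | Path) -> SimRecord:
    """Read a record; format inferred from the extension (.h5 / .nii[.gz])."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_container(path)
    return _read_nifti_mrs(path)


def process_record(record: SimRecord, pp: ProcessParams) -> SimRecord:
    """Apply Eq.-style post-processing: apodize, zero-fill, transform, crop.

    Returns a new record whose ``spectrum`` (and, when cropped, ground-truth
    ``ppm`` grid) reflect the processing; the raw FID is kept.
    """
    axes = record.axes
    fid = apodize(record.fid, pp.apodize_hz, axes) if pp.apodize_hz > 0 else record.fid
    if pp.zero_fill_len is not None:
        fid = zero_fill(fid, pp.zero_fill_len)
        axes = make_axes(axes.spectral_width, pp.zero_fill_len, axes.f0, axes.ppm_ref)
    spectrum = to_spectrum(fid, axes)
    gt = dict(record.ground_truth)
    if pp.ppm_window is not None:
        out_points = pp.out_points if pp.out_points is not None else axes.n_points
        spectrum, ppm = crop_resample(spectrum, axes, pp.ppm_window, out_points)
        gt["ppm"] = ppm
    return replace_record(record, spectrum=spectrum, ground_truth=gt, axes=record.axes)


def replace_record(record: SimRecord, **kwargs) -> SimRecord:
    base = {
        "fid": record.fid,
        "axes": record.axes,
        "params": record.params,
        "spectrum": record.spectrum,
        "transients": record.transients,
        "ground_truth": record.ground_truth,
    }
    base.update(kwargs)
    return SimRecord(**base)
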