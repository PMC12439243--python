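"""The full spectral model: one FID from basis functions and parameters.

A simulated record is built operator by operator, mirroring acquisition:

1. amplitude scaling and Voigt lineshape per basis function,
   ``M_n fid_n(t) exp(-(d_n t + g t^2))``, with the Gaussian decay shared
   per group (one value for metabolites, one for macromolecules/lipids);
2. sub-voxel B0 phase-ensemble modulation;
3. per-name + global frequency shifts, then summation;
4. addition of baseline and residual-water nuisance signals (with their own
   global frequency shift) and Gaussian noise calibrated to a target
   spectral SNR;
5. zero-order phase (time domain), first-order phase (frequency domain,
   pivoting at the chemical-shift reference), and an exponentially decaying
   eddy-current phase modulation.

Every stochastic component is retained in the record's ground truth, so the
output can be recomposed exactly from its parts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .b0 import B0Map, apply_b0
from .basis import Axes, BasisSet, GROUP_METABOLITE
from .fourier import from_spectrum, quadrature, to_spectrum
from .nuisance import WalkConfig, make_baseline, make_residual_water

__all__ = [
    "ModelParams",
    "SimRecord",
    "scale_and_shape",
    "sum_components",
    "add_noise",
    "apply_phi0",
    "apply_phi1",
    "apply_eddy",
    "simulate",
]


@dataclass
class ModelParams:
    """All scalar knobs of one simulated record.

    amplitude
        Per-name scaling factor ``M_n`` (mM-equivalent if each basis
        function represents 1.0 mM of signal).
    lorentz
        Per-name Lorentzian decay ``d_n`` in s^-1 (spectral FWHM d/pi Hz).
    gauss_metab, gauss_mm
        Gaussian decay ``g`` in s^-2, one value per group.  Zero either term
        for a purely Lorentzian / purely Gaussian lineshape.
    freq_shift, freq_shift_global, freq_shift_nuisance
        Per-name and global frequency shifts in Hz; metabolites receive
        ``freq_shift[name] + freq_shift_global``, nuisance signals only
        ``freq_shift_nuisance``.
    phi0, phi1
        Zero-order phase (degrees) and first-order phase (degrees/ppm,
        pivot at ``Axes.ppm_ref``).
    eddy_amp, eddy_tc
        Eddy-current amplitude ``A0`` (Hz) and time constant ``tc`` (s).
    snr
        Target spectral SNR (max real peak of the reference metabolite over
        one noise standard deviation); ``None`` disables noise.
    snr_ref
        Name of the metabolite whose clean peak defines the SNR (defaults to
        the first basis name).
    """

    amplitude: dict[str, float]
    lorentz: dict[str, float]
    gauss_metab: float = 0.0
    gauss_mm: float = 0.0
    freq_shift: dict[str, float] = field(default_factory=dict)
    freq_shift_global: float = 0.0
    freq_shift_nuisance: float = 0.0
    phi0: float = 0.0
    phi1: float = 0.0
    eddy_amp: float = 0.0
    eddy_tc: float = 0.15
    snr: Optional[float] = None
    snr_ref: Optional[str] = None
    noise_correlated: bool = False
    b0: Optional[B0Map] = None
    baseline: Optional[WalkConfig] = None
    residual_water: Optional[WalkConfig] = None
    coil: Optional["CoilParams"] = None  # noqa: F821 - set for transient stage

    def __post_init__(self) -> None:
        for name, v in self.amplitude.items():
            if v < 0:
                raise ValueError(f"amplitude for {name!r} must be >= 0")
        for name, v in self.lorentz.items():
            if v < 0:
                raise ValueError(f"lorentz decay for {name!r} must be >= 0")
        if self.gauss_metab < 0 or self.gauss_mm < 0:
            raise ValueError("gaussian decays must be >= 0")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.eddy_amp != 0 and self.eddy_tc <= 0:
            raise ValueError("eddy_tc must be positive when eddy_amp is non-zero")


@dataclass
class SimRecord:
    """One simulated record with every ground-truth component retained."""

    fid: np.ndarray
    axes: Axes
    params: ModelParams
    spectrum: Optional[np.ndarray] = None
    transients: Optional[np.ndarray] = None  # (C, n_points)
    ground_truth: dict = field(default_factory=dict)


def scale_and_shape(basis: BasisSet, p: ModelParams, axes: Axes) -> dict[str, np.ndarray]:
    """Amplitude-scale, Voigt-shape and frequency-shift each basis function."""
    t = axes.t
    out: dict[str, np.ndarray] = {}
    for name, group in zip(basis.names, basis.groups):
        if name not in p.amplitude:
            raise ValueError(f"no amplitude given for basis function {name!r}")
        if name not in p.lorentz:
            raise ValueError(f"no lorentz decay given for basis function {name!r}")
        g = p.gauss_metab if group == GROUP_METABOLITE else p.gauss_mm
        shift = p.freq_shift.get(name, 0.0) + p.freq_shift_global
        env = np.exp(-(p.lorentz[name] * t + g * t**2))
        out[name] = p.amplitude[name] * basis.fid(name) * env * np.exp(2j * np.pi * shift * t)
    return out


def sum_components(components: dict[str, np.ndarray] | list[np.ndarray]) -> np.ndarray:
    """Linear sum of per-name FIDs."""
    arrs = list(components.values()) if isinstance(components, dict) else list(components)
    if not arrs:
        raise ValueError("no components to sum")
    return np.sum(np.stack(arrs), axis=0)


def add_noise(
    fid: np.ndarray,
    snr0: float,
    ref_peak_height: float,
    noise_correlated: bool = False,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Add complex Gaussian noise calibrated against a spectral peak height.

    The spectral SNR is the maximum real peak height over one noise standard
    deviation, so ``sigma = ref_peak_height / snr0`` in frequency-domain
    units.  Real and imaginary noise channels are independent N(0, sigma)
    vectors unless ``noise_correlated``, in which case a single real vector
    is drawn and its quadrature is used as the imaginary channel.  Noise is
    drawn in the frequency domain (where the SNR definition lives) and
    injected in the time domain via the inverse transform; with the
    package's unitary-up-to-1/n inverse, sigma_time = sigma / sqrt(n).

    Returns ``(noisy_fid, noise_fid)``; the second term is the realization.
    """
    if snr0 <= 0:
        raise ValueError("snr0 must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    fid = np.asarray(fid)
    n = fid.shape[-1]
    sigma = ref_peak_height / snr0
    if noise_correlated:
        noise_spec = quadrature(rng.normal(0.0, sigma, n))
    else:
        noise_spec = rng.normal(0.0, sigma, n) + 1j * rng.normal(0.0, sigma, n)
    noise_fid = from_spectrum(noise_spec)
    return fid + noise_fid, noise_fid


def apply_phi0(fid: np.ndarray, phi0_deg: float) -> np.ndarray:
    """Global zero-order phase: ``fid * exp(-i phi0 pi/180)``."""
    return np.asarray(fid) * np.exp(-1j * np.deg2rad(phi0_deg))


def apply_phi1(
    spectrum: np.ndarray, phi1_deg_per_ppm: float, ppm_ref: float, axes: Axes
) -> np.ndarray:
    """First-order phase in the frequency domain, pivoting at ``ppm_ref``.

    ``F(w) * exp(-i phi1 (pi/180) (ppm - ppm_ref))``; the bin at the
    reference shift is left unchanged and magnitudes are preserved
    everywhere.
    """
    spectrum = np.asarray(spectrum)
    if spectrum.shape[-1] != axes.n_points:
        raise ValueError("spectrum length does not match the axes")
    return spectrum * np.exp(-1j * np.deg2rad(phi1_deg_per_ppm) * (axes.ppm - ppm_ref))


def apply_eddy(fid: np.ndarray, a0_hz: float, tc_s: float, axes: Axes) -> np.ndarray:
    """Exponentially decaying eddy-current phase modulation.

    ``fid * exp(+i 2 pi A0 exp(-t/tc) t)``: a time-varying frequency shift
    that decays with time constant ``tc``.  Pointwise magnitudes are
    unchanged; as tc grows far beyond the readout the modulation degenerates
    to a plain A0 Hz frequency shift.
    """
    fid = np.asarray(fid)
    if a0_hz == 0:
        return fid.copy()
    if tc_s <= 0:
        raise ValueError("eddy time constant must be positive when the amplitude is non-zero")
    return fid * np.exp(2j * np.pi * a0_hz * np.exp(-axes.t / tc_s) * axes.t)


def _apply_phases_and_eddy(fid: np.ndarray, p: ModelParams, axes: Axes) -> np.ndarray:
    out = apply_phi0(fid, p.phi0)
    if p.phi1 != 0.0:
        out = from_spectrum(apply_phi1(to_spectrum(out), p.phi1, axes.ppm_ref, axes))
    return apply_eddy(out, p.eddy_amp, p.eddy_tc, axes)


def simulate(
    basis: BasisSet,
    p: ModelParams,
    axes: Axes | None = None,
    seed: int | np.random.Generator | None = None,
    stage: str = "processed",
) -> SimRecord:
    """Run the full pipeline and return a ground-truth-annotated record.

    ``stage``:

    - ``"fid"`` - time-domain record with noise applied;
    - ``"processed"`` - additionally stores the spectrum;
    - ``"transients"`` - noise is deferred to the per-transient stage:
      ``p.coil`` must be set and the record carries a (C, n) transient
      matrix instead of single-record noise.
    """
    if stage not in ("fid", "processed", "transients"):
        raise ValueError(f"unknown stage {stage!r}")
    if axes is None:
        axes = basis.axes()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    components = scale_and_shape(basis, p, axes)
    if p.b0 is not None:
        components = {k: apply_b0(v, p.b0, axes) for k, v in components.items()}
    metab_fid = sum_components(components)

    ref_name = p.snr_ref if p.snr_ref is not None else basis.names[0]
    if ref_name not in components:
        raise ValueError(f"snr_ref {ref_name!r} is not a basis function")
    ref_peak_height = float(np.max(to_spectrum(components[ref_name]).real))
    ref_magnitude = float(np.max(np.abs(to_spectrum(metab_fid))))

    nuis_shift = np.exp(2j * np.pi * p.freq_shift_nuisance * axes.t)
    baseline_fid = np.zeros(axes.n_points, dtype=complex)
    water_fid = np.zeros(axes.n_points, dtype=complex)
    if p.baseline is not None:
        baseline_fid = from_spectrum(make_baseline(p.baseline, axes, ref_magnitude, rng))
        baseline_fid *= nuis_shift
    if p.residual_water is not None:
        water_fid = from_spectrum(make_residual_water(p.residual_water, axes, ref_magnitude, rng))
        water_fid *= nuis_shift

    noiseless = metab_fid + baseline_fid + water_fid
    noise_fid = np.zeros(axes.n_points, dtype=complex)
    transients = None

    if stage == "transients":
        from .transients import make_transients  # local import avoids a cycle

        if p.coil is None:
            raise ValueError("stage='transients' requires ModelParams.coil")
        shaped = _apply_phases_and_eddy(noiseless, p, axes)
        transients = make_transients(shaped, p.snr, ref_peak_height, p.coil, axes, rng)
        out_fid = shaped
    else:
        if p.snr is not None:
            noisy, noise_fid = add_noise(
                noiseless, p.snr, ref_peak_height, p.noise_correlated, rng
            )
        else:
            noisy = noiseless
        out_fid = _apply_phases_and_eddy(noisy, p, axes)

    record = SimRecord(
        fid=out_fid,
        axes=axes,
        params=p,
        transients=transients,
        ground_truth={
            "metabolite_fid": metab_fid,
            "components": components,
            "baseline_fid": baseline_fid,
            "residual_water_fid": water_fid,
            "noise_fid": noise_fid,
            "ref_peak_height": ref_peak_height,
            "ref_magnitude": ref_magnitude,
            "b0_grid": None if p.b0 is None else p.b0.grid,
        },
    )
    if stage == "processed":
        record.spectrum = to_spectrum(out_fid)
    return record
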