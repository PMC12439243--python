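"""Multi-coil / multi-average transients and their combination.

One noiseless FID is expanded into C transients: each receives a coil
sensitivity weight, its own noise realization (per-transient SNR target
``snr0 / sqrt(C)`` so equal-weight averaging recovers ``snr0``), and
independent frequency and zero-order phase drifts.  Combination utilities
implement weighted averaging (the recommended route) and amplitude-preserving
normalized summation, plus exact ground-truth drift removal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .basis import Axes
from .fourier import from_spectrum

__all__ = [
    "CoilParams",
    "sample_coil_weights",
    "sample_coil_params",
    "make_transients",
    "combine_transients",
    "remove_known_drifts",
]


@dataclass
class CoilParams:
    """Per-transient parameters for C coil elements or signal averages."""

    n_transients: int
    sens: np.ndarray  # sensitivity weights
    snr_scale: np.ndarray  # multiplicative per-transient SNR factors (~1)
    freq_drift: np.ndarray  # Hz
    phase_drift: np.ndarray  # degrees

    def __post_init__(self) -> None:
        if self.n_transients < 1:
            raise ValueError("n_transients must be >= 1")
        for attr in ("sens", "snr_scale", "freq_drift", "phase_drift"):
            arr = np.atleast_1d(np.asarray(getattr(self, attr), dtype=float))
            if arr.shape != (self.n_transients,):
                raise ValueError(f"{attr} must have length n_transients={self.n_transients}")
            setattr(self, attr, arr)
        if np.any(self.snr_scale <= 0):
            raise ValueError("snr_scale factors must be positive")


def sample_coil_weights(
    n_transients: int,
    rng: np.random.Generator | int | None = None,
    mean: float = 1.0,
    std: float = 0.5,
    clamp: tuple[float, float] = (0.0, 2.0),
) -> np.ndarray:
    """Draw coil sensitivity weights from a clamped Gaussian.

    Default: N(1.0, 0.5^2) clamped to [0, 2].  The clamp is symmetric about
    the centre, so the empirical mean stays at 1.0.
    """
    if n_transients < 1:
        raise ValueError("n_transients must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return np.clip(rng.normal(mean, std, n_transients), clamp[0], clamp[1])


def sample_coil_params(
    n_transients: int,
    rng: np.random.Generator | int | None = None,
    snr_scale_std: float = 0.05,
    freq_drift_std: float = 3.0,
    phase_drift_std: float = 5.0,
    sens_mean: float = 1.0,
    sens_std: float = 0.5,
    sens_clamp: tuple[float, float] = (0.0, 2.0),
) -> CoilParams:
    """Sample a full CoilParams set with the default artifact distributions.

    The per-transient SNR factors come from a narrow normal N(1, 0.05^2)
    clamped positive; frequency drifts from N(0, 3 Hz); phase drifts from
    N(0, 5 degrees).  Any subset can be disabled by zeroing its std.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sens = sample_coil_weights(n_transients, rng, sens_mean, sens_std, sens_clamp)
    snr_scale = np.clip(rng.normal(1.0, snr_scale_std, n_transients), 1e-3, None)
    freq_drift = rng.normal(0.0, freq_drift_std, n_transients)
    phase_drift = rng.normal(0.0, phase_drift_std, n_transients)
    return CoilParams(n_transients, sens, snr_scale, freq_drift, phase_drift)


def make_transients(
    clean_fid: np.ndarray,
    snr0: Optional[float],
    ref_peak_height: float,
    cp: CoilParams,
    axes: Axes,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Expand one noiseless FID into C noisy transients.

    ``transient_c = sens_c * clean(t) * exp(+i 2 pi df_c t)
    * exp(-i dphi_c pi/180) + noise_c`` where the per-transient noise sigma
    targets SNR ``(snr0 / sqrt(C)) * snr_scale_c`` against the clean
    reference peak, so equal-weight averaging of the C transients recovers
    the target ``snr0``.  ``snr0=None`` disables noise.  Noise vectors are
    independent across transients (inter-coil correlation can be introduced
    by constructing correlated CoilParams noise externally).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    clean_fid = np.asarray(clean_fid)
    n = clean_fid.shape[-1]
    if n != axes.n_points:
        raise ValueError("FID length does not match the axes")
    c_count = cp.n_transients
    out = np.empty((c_count, n), dtype=complex)
    for c in range(c_count):
        mod = np.exp(2j * np.pi * cp.freq_drift[c] * axes.t) * np.exp(
            -1j * np.deg2rad(cp.phase_drift[c])
        )
        transient = cp.sens[c] * clean_fid * mod
        if snr0 is not None:
            target = (snr0 / np.sqrt(c_count)) * cp.snr_scale[c]
            sigma = ref_peak_height / target
            noise_spec = rng.normal(0.0, sigma, n) + 1j * rng.normal(0.0, sigma, n)
            transient = transient + from_spectrum(noise_spec)
        out[c] = transient
    return out


def combine_transients(
    transients: np.ndarray, weights: np.ndarray, mode: str = "average"
) -> np.ndarray:
    """Combine C transients into one FID.

    ``average`` takes the weighted mean; ``sum`` normalizes the weights by
    their total before summing so the overall amplitude is maintained.  Both
    return the input unchanged when combining identical noiseless transients
    with equal weights.
    """
    transients = np.atleast_2d(np.asarray(transients))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (transients.shape[0],):
        raise ValueError("one weight required per transient")
    total = weights.sum()
    if total == 0:
        raise ValueError("weights must not all be zero")
    if mode == "average":
        return np.average(transients, axis=0, weights=weights)
    if mode == "sum":
        return (weights / total) @ transients
    raise ValueError(f"unknown combination mode {mode!r}")


def remove_known_drifts(transients: np.ndarray, cp: CoilParams, axes: Axes) -> np.ndarray:
    """Invert the ground-truth frequency and phase drifts of each transient.

    This is exact removal of the known simulated drifts, not estimation:
    with noise off, the aligned transients differ only by their sensitivity
    scaling.
    """
    transients = np.atleast_2d(np.asarray(transients))
    if transients.shape[0] != cp.n_transients:
        raise ValueError("transient count does not match CoilParams")
    out = np.empty_like(transients)
    for c in range(cp.n_transients):
        mod = np.exp(-2j * np.pi * cp.freq_drift[c] * axes.t) * np.exp(
            1j * np.deg2rad(cp.phase_drift[c])
        )
        out[c] = transients[c] * mod
    return out
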