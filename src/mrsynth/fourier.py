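"""Fourier-transform conventions shared by every module.

One convention, fixed once: the spectrum is the forward DFT of the FID with
the zero-frequency bin shifted to the centre of the array, so a time-domain
resonance ``exp(+i 2 pi f t)`` produces a peak at ``+f`` Hz.  Frequency (and
hence ppm) increases with array index.  All frequency-modulation operators in
the package therefore use ``exp(+i 2 pi (Hz) t)`` so that a positive
frequency parameter displaces peaks toward higher ppm.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import hilbert

__all__ = ["to_spectrum", "from_spectrum", "phase_shift_90", "quadrature"]


def to_spectrum(fid: np.ndarray, axis: int = -1) -> np.ndarray:
    """Forward transform FID -> spectrum (zero frequency at index n//2)."""
    return np.fft.fftshift(np.fft.fft(fid, axis=axis), axes=axis)


def from_spectrum(spectrum: np.ndarray, axis: int = -1) -> np.ndarray:
    """Inverse transform spectrum -> FID; exact inverse of :func:`to_spectrum`."""
    return np.fft.ifft(np.fft.ifftshift(spectrum, axes=axis), axis=axis)


def phase_shift_90(spectrum: np.ndarray) -> np.ndarray:
    """Rotate the time-domain signal of a spectrum by -90 degrees.

    Inverse-transforms, multiplies by ``exp(-i pi / 2)`` and transforms back.
    By linearity this equals ``-1j * spectrum``; it is computed through the
    transforms to mirror the construction.  Applying it twice negates the
    input (``exp(-i pi) = -1``).
    """
    return to_spectrum(from_spectrum(np.asarray(spectrum)) * np.exp(-0.5j * np.pi))


def quadrature(real_spectrum: np.ndarray) -> np.ndarray:
    """Build the complex quadrature pair of a real spectral profile.

    The imaginary channel is obtained from a 90-degree time-domain phase
    shift whose rotation sign is symmetrized across t = 0 (equivalently, the
    discrete Hilbert transform): a uniform rotation of the full inverse
    transform would only return a scalar multiple of the input.  The real
    channel of the output equals the input bit-exactly.
    """
    x = np.asarray(real_spectrum, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("quadrature requires finite input")
    return x + 1j * np.imag(hilbert(x))
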