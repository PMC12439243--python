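"""Semi-parametric spectral baseline and residual-water generators.

No physics-based model exists for the in-vivo spectral baseline or for the
imperfectly suppressed water signal, so both are emulated with a smoothed,
bounded pseudo-random walk: cumulative Gaussian steps are re-expressed as
bounded deviations around a linear trend and smoothed with a uniform kernel.
A broad/smooth parameterization mimics baselines; a jagged, localized one
mimics residual-water regions.  The real walk is complexified with a
quadrature (90-degree time-domain phase-shift) imaginary channel, resampled
onto the acquisition ppm grid, and scaled relative to the metabolite
spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.interpolate import Akima1DInterpolator

from .basis import Axes
from .fourier import quadrature

__all__ = [
    "WalkConfig",
    "bounded_walk",
    "complexify",
    "make_baseline",
    "make_residual_water",
    "default_baseline_config",
    "default_water_config",
]


@dataclass(frozen=True)
class WalkConfig:
    """Parameters of the smoothed bounded pseudo-random walk.

    ``start``/``end`` are the endpoints of the linear trend (amplitude
    units); ``std`` the standard deviation of the raw Gaussian steps;
    ``lower_bound``/``upper_bound`` the hard bounds of the walk; ``length``
    the number of walk samples; ``window_size`` the smoothing-kernel size as
    a fraction of ``length``; ``scale`` the final amplitude multiplier
    relative to the metabolite spectrum magnitude; ``ppm_span`` the ppm
    interval onto which the walk is resampled (zero outside).
    """

    start: float = 0.0
    end: float = 0.0
    std: float = 1.0
    lower_bound: float = -1.0
    upper_bound: float = 1.0
    length: int = 256
    window_size: float = 0.1
    scale: float = 1.0
    ppm_span: Optional[tuple[float, float]] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.upper_bound <= self.lower_bound:
            raise ValueError("upper_bound must exceed lower_bound")
        if self.length < 8:
            raise ValueError("length must be >= 8")
        if not (0.0 < self.window_size < 1.0):
            raise ValueError("window_size must lie in (0, 1)")
        if self.std < 0:
            raise ValueError("std must be non-negative")
        if self.scale < 0:
            raise ValueError("scale must be non-negative")
        if self.ppm_span is not None and self.ppm_span[1] <= self.ppm_span[0]:
            raise ValueError("ppm_span must be an increasing interval")


def bounded_walk(cfg: WalkConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Generate one smoothed bounded pseudo-random walk.

    Steps: cumulative sum of N(0, std) steps; linear trend from ``start`` to
    ``end``; deltas = walk - trend, rescaled so their range equals the bound
    width; trend + deltas clipped into the bounds (the conditional
    adjustment); uniform smoothing with a reflect-padded kernel of size
    ``round(window_size * length)``.  Clipping plus convex smoothing keeps
    the output inside ``[lower_bound, upper_bound]``; deterministic given
    the seed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.length
    walk = np.cumsum(rng.normal(0.0, cfg.std, n) if cfg.std > 0 else np.zeros(n))
    trend = np.linspace(cfg.start, cfg.end, n)
    deltas = walk - trend
    width = deltas.max() - deltas.min()
    if cfg.std == 0 or np.ptp(walk) == 0 or width == 0:
        # degenerate walk: no random structure, keep the pure trend
        deltas = np.zeros(n)
    else:
        deltas *= (cfg.upper_bound - cfg.lower_bound) / width
    out = np.clip(trend + deltas, cfg.lower_bound, cfg.upper_bound)
    k = max(1, int(round(cfg.window_size * n)))
    if k > 1:
        padded = np.pad(out, (k // 2, k - 1 - k // 2), mode="reflect")
        out = np.convolve(padded, np.full(k, 1.0 / k), mode="valid")
    return out


def complexify(real_spectrum: np.ndarray) -> np.ndarray:
    """Attach the quadrature imaginary channel to a real spectral profile.

    The imaginary part is the 90-degree time-domain phase shift of the real
    profile (sign-symmetrized across t = 0, i.e. the discrete Hilbert
    transform); the real channel of the output equals the input exactly.
    """
    return quadrature(real_spectrum)


def _resample_to_axes(signal: np.ndarray, cfg: WalkConfig, axes: Axes) -> np.ndarray:
    """Place a walk-grid signal onto the axes ppm grid, zero outside its span."""
    span = cfg.ppm_span if cfg.ppm_span is not None else (axes.ppm.min(), axes.ppm.max())
    lo, hi = span
    if lo < axes.ppm.min() - 1e-12 or hi > axes.ppm.max() + 1e-12:
        raise ValueError(
            f"ppm_span {span} lies outside the axes span "
            f"[{axes.ppm.min():.3f}, {axes.ppm.max():.3f}]"
        )
    walk_ppm = np.linspace(lo, hi, len(signal))
    out = np.zeros(axes.n_points, dtype=signal.dtype)
    mask = (axes.ppm >= lo) & (axes.ppm <= hi)
    if mask.any():
        interp = Akima1DInterpolator(walk_ppm, signal, method="makima")
        out[mask] = interp(axes.ppm[mask])
    return out


def _make_nuisance(
    cfg: WalkConfig,
    axes: Axes,
    ref_magnitude: float,
    rng: np.random.Generator | None,
) -> np.ndarray:
    walk = bounded_walk(cfg, rng)
    cplx = complexify(walk)
    sampled = _resample_to_axes(cplx.real, cfg, axes) + 1j * _resample_to_axes(
        cplx.imag, cfg, axes
    )
    return cfg.scale * ref_magnitude * sampled


def make_baseline(
    cfg: WalkConfig,
    axes: Axes,
    ref_magnitude: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Complex baseline on the full spectral grid.

    ``ref_magnitude`` is the magnitude the walk is scaled against (the
    maximum of the metabolite magnitude spectrum when called from the
    simulator), making ``cfg.scale`` a dimensionless knob.
    """
    return _make_nuisance(cfg, axes, ref_magnitude, rng)


def make_residual_water(
    cfg: WalkConfig,
    axes: Axes,
    ref_magnitude: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Complex residual-water signal, localized to ``cfg.ppm_span``."""
    return _make_nuisance(cfg, axes, ref_magnitude, rng)


def default_baseline_config(**overrides) -> WalkConfig:
    """Broad, smooth profile: small step noise, wide smoothing window.

    Spans the metabolite region (0.2-4.2 ppm) by default.
    """
    cfg = WalkConfig(
        start=0.0,
        end=0.0,
        std=1.0,
        lower_bound=-1.0,
        upper_bound=1.0,
        length=256,
        window_size=0.20,
        scale=0.05,
        ppm_span=(0.2, 4.2),
    )
    return replace(cfg, **overrides)


def default_water_config(ppm_ref: float = 4.65, **overrides) -> WalkConfig:
    """Irregular, localized profile around the water resonance.

    Larger step noise and a narrow smoothing window produce the jagged
    structure typical of imperfect water suppression; the span is centred on
    the chemical-shift reference.
    """
    cfg = WalkConfig(
        start=0.0,
        end=0.0,
        std=5.0,
        lower_bound=-1.0,
        upper_bound=1.0,
        length=512,
        window_size=0.02,
        scale=0.15,
        ppm_span=(ppm_ref - 0.45, ppm_ref + 0.45),
    )
    return replace(cfg, **overrides)
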