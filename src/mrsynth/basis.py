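"""Metabolite basis sets and the time/ppm axes every other module consumes.

A basis set holds one complex time-domain signal (FID) per named component
(metabolite, macromolecule, or lipid) together with the acquisition metadata
needed to place it on a chemical-shift axis.  Basis functions are normally
pre-simulated with a density-matrix simulator for a specific pulse sequence;
this module additionally provides an analytic toy generator (sums of damped
complex exponentials) so the whole pipeline can run self-contained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

__all__ = [
    "Axes",
    "BasisSet",
    "BasisFormatError",
    "GROUP_METABOLITE",
    "GROUP_MM_LIPID",
    "TOY_DECAY_FWHM_HZ",
    "make_axes",
    "make_toy_basis",
    "load_basis",
    "save_basis",
]

GROUP_METABOLITE = "metabolite"
GROUP_MM_LIPID = "mm_lipid"
_VALID_GROUPS = (GROUP_METABOLITE, GROUP_MM_LIPID)

#: Full width at half maximum, in Hz, of the fixed Lorentzian decay applied to
#: toy basis functions so their spectra are integrable.  Real basis sets come
#: pre-simulated; any mild smooth default suffices here.
TOY_DECAY_FWHM_HZ = 1.0


class BasisFormatError(ValueError):
    """A basis container is malformed (names the missing/invalid field)."""


@dataclass(frozen=True)
class Axes:
    """Time and chemical-shift axes of one acquisition grid.

    ``t[k] = k / spectral_width`` seconds.  ``ppm`` ascends with array index;
    the zero-frequency bin (index ``n_points // 2``) sits exactly at
    ``ppm_ref``.  The grid spans ``spectral_width / f0`` ppm in total.
    """

    spectral_width: float  # Hz
    n_points: int
    f0: float  # spectrometer frequency, MHz
    ppm_ref: float  # ppm
    t: np.ndarray = field(repr=False)
    freq: np.ndarray = field(repr=False)  # Hz offsets, ascending
    ppm: np.ndarray = field(repr=False)

    @property
    def dwell(self) -> float:
        """Sampling interval in seconds."""
        return 1.0 / self.spectral_width

    @property
    def hz_per_bin(self) -> float:
        return self.spectral_width / self.n_points

    @property
    def ppm_span(self) -> float:
        """Total ppm width of the grid (including one bin width)."""
        return self.spectral_width / self.f0


def make_axes(spectral_width: float, n_points: int, f0: float, ppm_ref: float) -> Axes:
    """Build the shared time/frequency/ppm axes.

    Parameters
    ----------
    spectral_width : Hz, sampling bandwidth (1 / dwell time).
    n_points : number of complex points, >= 2.
    f0 : spectrometer frequency in MHz.
    ppm_ref : chemical-shift reference mapped to the 0 Hz bin (water at
        4.65 ppm by convention).
    """
    if spectral_width <= 0 or f0 <= 0:
        raise ValueError("spectral_width and f0 must be positive")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if ppm_ref <= 0:
        raise ValueError("ppm_ref must be positive")
    n_points = int(n_points)
    t = np.arange(n_points) / spectral_width
    freq = np.fft.fftshift(np.fft.fftfreq(n_points, d=1.0 / spectral_width))
    ppm = ppm_ref + freq / f0
    return Axes(float(spectral_width), n_points, float(f0), float(ppm_ref), t, freq, ppm)


@dataclass
class BasisSet:
    """Named complex time-domain basis functions plus acquisition metadata."""

    names: list[str]
    fids: np.ndarray  # (n_names, n_points) complex
    spectral_width: float  # Hz
    f0: float  # MHz
    ppm_ref: float  # ppm
    groups: list[str]  # per-name, "metabolite" or "mm_lipid"
    meta: dict = field(default_factory=dict)  # free-form sequence metadata

    def __post_init__(self) -> None:
        self.fids = np.atleast_2d(np.asarray(self.fids, dtype=complex))
        if len(self.names) != self.fids.shape[0]:
            raise ValueError("one FID required per name")
        if len(set(self.names)) != len(self.names):
            raise ValueError("basis names must be unique")
        if len(self.groups) != len(self.names):
            raise ValueError("one group tag required per name")
        for g in self.groups:
            if g not in _VALID_GROUPS:
                raise ValueError(f"unknown group tag {g!r}; expected one of {_VALID_GROUPS}")
        if self.n_points < 2:
            raise ValueError("basis FIDs must have >= 2 points")
        if self.spectral_width <= 0 or self.f0 <= 0:
            raise ValueError("spectral_width and f0 must be positive")

    @property
    def n_points(self) -> int:
        return self.fids.shape[1]

    def group_of(self, name: str) -> str:
        return self.groups[self.names.index(name)]

    def fid(self, name: str) -> np.ndarray:
        return self.fids[self.names.index(name)]

    def axes(self) -> Axes:
        return make_axes(self.spectral_width, self.n_points, self.f0, self.ppm_ref)


def make_toy_basis(
    spec: Sequence[tuple[str, str, Sequence[tuple[float, float]]]],
    spectral_width: float,
    n_points: int,
    f0: float,
    ppm_ref: float,
    seed: int | None = None,
    decay_fwhm_hz: float = TOY_DECAY_FWHM_HZ,
) -> BasisSet:
    """Synthesize an analytic basis set from (shift, amplitude) peak lists.

    Each entry of ``spec`` is ``(name, group, [(shift_ppm, rel_amplitude),
    ...])``.  The FID of a peak at chemical shift ``delta`` is
    ``a * exp(+i 2 pi (delta - ppm_ref) f0 t) * exp(-pi * decay_fwhm_hz * t)``
    so its magnitude spectrum peaks at ``delta`` with Lorentzian FWHM
    ``decay_fwhm_hz``.  The generator is fully deterministic; ``seed`` is
    accepted for interface symmetry and currently unused.
    """
    del seed  # deterministic: peak lists are explicit inputs
    if len(spec) == 0:
        raise ValueError("toy basis spec must contain at least one entry")
    axes = make_axes(spectral_width, n_points, f0, ppm_ref)
    lo, hi = axes.ppm.min(), axes.ppm.max()
    d = np.pi * decay_fwhm_hz  # e^{-dt} <-> Lorentzian of FWHM d/pi Hz
    names, groups, fids = [], [], []
    for name, group, peaks in spec:
        fid = np.zeros(axes.n_points, dtype=complex)
        for shift, amp in peaks:
            if not (lo <= shift <= hi):
                raise ValueError(
                    f"peak at {shift} ppm for {name!r} lies outside the axis span "
                    f"[{lo:.3f}, {hi:.3f}] ppm"
                )
            f_off = (shift - ppm_ref) * f0  # Hz
            fid += amp * np.exp(2j * np.pi * f_off * axes.t)
        fid *= np.exp(-d * axes.t)
        names.append(name)
        groups.append(group)
        fids.append(fid)
    return BasisSet(names, np.array(fids), spectral_width, f0, ppm_ref, groups)


_REQUIRED_FIELDS = ("names", "fids", "spectral_width", "f0", "ppm_ref", "group")


def save_basis(basis: BasisSet, path: str | Path) -> Path:
    """Write a basis set; ``.h5`` keyed container or ``.json`` portable text."""
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            "names": basis.names,
            "fids_real": basis.fids.real.tolist(),
            "fids_imag": basis.fids.imag.tolist(),
            "spectral_width": basis.spectral_width,
            "f0": basis.f0,
            "ppm_ref": basis.ppm_ref,
            "group": basis.groups,
            "meta": basis.meta,
        }
        path.write_text(json.dumps(payload))
        return path
    with h5py.File(path, "w") as h:
        h.create_dataset("names", data=[n.encode() for n in basis.names], track_times=False)
        h.create_dataset("fids", data=basis.fids, track_times=False)
        h.create_dataset("group", data=[g.encode() for g in basis.groups], track_times=False)
        h.attrs["spectral_width"] = basis.spectral_width
        h.attrs["f0"] = basis.f0
        h.attrs["ppm_ref"] = basis.ppm_ref
        h.attrs["n_points"] = basis.n_points
        h.attrs["meta"] = json.dumps(basis.meta)
    return path


def load_basis(path: str | Path) -> BasisSet:
    """Read a basis set written by :func:`save_basis` (lossless round-trip)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        for key in ("names", "fids_real", "fids_imag", "spectral_width", "f0", "ppm_ref", "group"):
            if key not in payload:
                raise BasisFormatError(f"basis file {path} is missing field {key!r}")
        fids = np.array(payload["fids_real"]) + 1j * np.array(payload["fids_imag"])
        return BasisSet(
            list(payload["names"]),
            fids,
            float(payload["spectral_width"]),
            float(payload["f0"]),
            float(payload["ppm_ref"]),
            list(payload["group"]),
            dict(payload.get("meta", {})),
        )
    with h5py.File(path, "r") as h:
        for key in ("names", "fids", "group"):
            if key not in h:
                raise BasisFormatError(f"basis file {path} is missing field {key!r}")
        for key in ("spectral_width", "f0", "ppm_ref"):
            if key not in h.attrs:
                raise BasisFormatError(f"basis file {path} is missing field {key!r}")
        names = [n.decode() for n in h["names"][()]]
        groups = [g.decode() for g in h["group"][()]]
        fids = h["fids"][()]
        meta = json.loads(h.attrs.get("meta", "{}"))
        return BasisSet(
            names,
            fids,
            float(h.attrs["spectral_width"]),
            float(h.attrs["f0"]),
            float(h.attrs["ppm_ref"]),
            groups,
            meta,
        )
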