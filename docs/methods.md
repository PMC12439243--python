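# Methods

This note documents the model conventions, defaults, and numerical choices
behind `mrsynth`, and what the synthetic test conditions do and do not show
about real data.

## Conventions fixed once

**Fourier transform.** The spectrum is the forward DFT of the FID with the
zero-frequency bin shifted to the array centre; a resonance
`exp(+i2πft)` peaks at `+f` Hz. Frequency and ppm increase with array
index; the zero-frequency bin maps exactly to the chemical-shift reference
`ppm_ref` (4.65 ppm, the water position, by default). The ppm axis is
stored ascending because every resampling step requires monotone
abscissae; descending display order is left to plotting code.

**Signs.** All frequency-modulation operators (per-metabolite shifts,
B0 ensemble, transient drifts, eddy currents) use `exp(+i2π(Hz)·t)` so a
positive Hz parameter displaces peaks toward higher frequency/ppm — this
makes "a 10 Hz mean field offset shifts the spectrum by 10 Hz" literally
true. The phase operators use `exp(-iϕ)` with ϕ in degrees: `ϕ0` rotates
globally in the time domain; `ϕ1` rotates per-bin in the frequency domain
proportionally to `(ppm − ppm_ref)`, so the reference bin is invariant.

## Basis sets

Basis functions are normally pre-simulated externally for a specific pulse
sequence; `mrsynth` treats them as opaque complex FIDs with metadata
(spectral width, spectrometer frequency, reference shift, and a group tag
per name — `metabolite` or `mm_lipid` — that selects which Gaussian
broadening applies). The analytic toy generator builds each FID as a sum of
complex exponentials at `(shift − ppm_ref)·f0` Hz with a fixed mild
Lorentzian decay (default 1 Hz FWHM) so spectra are integrable; it is the
self-contained stand-in for externally simulated basis sets, and its unit
convention is "amplitude 1 ⇒ unit time-domain amplitude at t = 0".

## B0 field maps

A map is `grid[i,j,k] = μ + 2dx(i/(nx−1) − ½) + ...`: the half-ranges are
met exactly at the voxel faces, singleton axes contribute nothing, and the
isotropic spread is quoted as `Δ = 2dx = 2dy = 2dz`. Application multiplies
the FID by the ensemble mean `(1/R) Σ_r exp(+i2πΔω_r t)`. The mean (rather
than the bare sum) is used so that grid resolution — a numerical choice —
never rescales amplitude, and the zero map is an exact identity. The output
depends only on the multiset of offsets; only a linear profile is shipped,
but `profile` is an explicit extension point.

## Nuisance signals (baseline, residual water)

Neither has a physics-based model, so both come from one generator: a
cumulative-sum Gaussian walk is re-expressed as deviations around a linear
trend, the deviations rescaled to the configured bound width, the sum
clipped into `[lower, upper]` (the bound-enforcement step; clipping was
chosen because it preserves interior structure and the subsequent smoothing
removes clip plateaus), and smoothed with a reflect-padded uniform kernel of
`window_size · length` samples. Convexity of the kernel keeps the output
bounded. With `std = 0` the walk degenerates to the smoothed trend.

The real walk is complexified by a 90° time-domain phase shift whose
rotation sign is symmetrized across t = 0 — the discrete Hilbert transform.
A uniform 90° rotation of the whole inverse transform would return only a
scalar multiple of the input, so the symmetrized form is used to obtain a
genuine quadrature (dispersion-like) channel; the real channel is preserved
bit-exactly.

Profiles are resampled onto the acquisition ppm grid (zero outside their
span) and scaled by `scale × max|metabolite spectrum|`, making `scale` a
dimensionless knob. Defaults: baseline — std 1.0, window 0.20, span
0.2–4.2 ppm, scale 0.05 (broad and smooth); residual water — std 5.0,
window 0.02, span `ppm_ref ± 0.45`, scale 0.15 (jagged and localized).
These defaults are illustrative of the two regimes, not claims about true
in-vivo baselines, which remain uncharacterized.

## Noise and SNR

Spectral SNR is the maximum real peak height of a designated reference
metabolite divided by one noise standard deviation. Noise is drawn in the
frequency domain — where that definition lives — as independent real and
imaginary N(0, σ) vectors with `σ = ref_peak/snr0`, then injected in the
time domain through the inverse transform (σ_time = σ/√n with the 1/n
inverse). The optional correlated mode draws a single real vector and uses
its Hilbert quadrature as the imaginary channel. Noise is added before the
phase/eddy operators, matching the model's composition order; since those
operators are unitary per bin, noise statistics are unaffected.

## Transients

Each of C transients gets: a sensitivity weight from N(1.0, 0.5²) clamped
to [0, 2] (symmetric clamp, mean stays 1.0); an SNR target
`(snr0/√C)·snr_scale_c` with `snr_scale_c` from a narrow N(1, 0.05²)
(clamped positive); and frequency/phase drifts, default N(0, 3 Hz) and
N(0, 5°). The `snr0/√C` scaling is chosen so equal-weight averaging
recovers `snr0`, i.e. the √C gain of averaging. All four knobs apply to
every transient; profiles emulating pure multi-average data (drifts only)
or pure multi-coil data (sensitivity/SNR only) just zero the others.
Combination offers the weighted mean (recommended) and a
normalized-weight sum; for ground-truth weights the two coincide — the
normalization exists to keep unnormalized summation from inflating
amplitude. Drift removal applies the exact inverse rotations (ground-truth
alignment, not estimation).

## Post-processing and export

Apodization multiplies by `exp(-t·TL)` (adds `TL/π` Hz of Lorentzian
width); zero-filling appends zeros (denser grid, no new information);
crop/resampling uses scipy's modified-Akima (`makima`) piecewise cubic on
real and imaginary channels separately — monotone-safe, exact at original
nodes. The HDF5 container stores the record bit-exactly (datasets written
without timestamps so identical runs produce identical bytes). NIfTI-MRS
export writes complex time-domain data in a NIfTI-2 image with the dwell
time in `pixdim[4]` and a JSON header extension (ecode 44) carrying
spectrometer frequency, nucleus, and a `DIM_COIL` tag for the transient
dimension.

## Parameter sampling and distribution analysis

Sampling schemes map parameter names (dotted keys for per-metabolite
entries) to constant/uniform/normal/truncated-normal rules; draws are
deterministic given a seed and validated against their bounds. The inverse
tool fits each candidate scipy.stats family by maximum likelihood and ranks
by the sum of squared errors between fitted density and a 50-bin histogram,
with AIC as tiebreak; both scores are reported. The default candidate list
(normal, truncated normal, uniform, gamma, lognormal) is deliberately
small and user-extensible. Families whose MLE fails on a given sample
(support mismatch) are kept in the report with an infinite score rather
than dropped silently.

## Batch runs

Per-record random streams derive from `(master seed, record index)` only,
so batch size never changes outputs and reruns are byte-identical. Every
sampled parameter is stored in the record — the parameters are the ground
truth.

## Test conditions and problem sizes

Tests and the calibration script run on analytic toy singlets under the
standard short-echo 3 T conditions: 2000 Hz spectral width, 4096 complex
points, 127.7 MHz, reference 4.65 ppm, SNR fixed to 15. Monte-Carlo checks
use 200 noise seeds (SNR recovery), 10⁶ draws (coil weights), 10⁴ random
configurations (walk boundedness), and 60 seeds at C ∈ {4, 16, 64}
(√C gain). Sub-bin effects are handled by measurement, not by changing the
model: peak displacements are read from 8× zero-filled spectra, and
low-SNR Monte-Carlo checks read the peak at its known ground-truth bin to
avoid max-selection bias.

## What the toy conditions do not show

Toy basis functions are isolated singlets; real basis sets carry J-coupled
multiplets, overlapping resonances, and sequence-specific spatial effects,
so passing tests demonstrate the correctness of the operators, not the
realism of any particular dataset. Realism lives in the parameter values,
which are the user's responsibility (ideally informed by the distribution
tools). Known limitations: no density-matrix simulation, no spectral
fitting or artifact correction, no susceptibility-derived or acquired field
maps (only parametric gradients), no vendor raw formats, and no claim that
the random-walk nuisance profiles are physically true — only that their
variety brackets what fitting methods extract in practice.
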