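# mrsynth

Simulation of in-vivo-like proton magnetic resonance spectroscopy (MRS)
spectra with complete ground-truth annotation.

In-vivo MRS data is expensive, privacy-restricted, and — crucially — comes
without ground truth, which makes it hard to validate spectral fitting
pipelines or to train learning-based methods. `mrsynth` generates synthetic
spectra that carry the artifacts real acquisitions do, while retaining every
component (noise realization, baseline, residual water, field map, all
parameters) for auditing.

## The physics model

Starting from a basis set of per-metabolite time-domain signals
(FIDs) `basisfcn_n(t)`, one record is assembled as

```
f(t) = [ Σ_n  M_n · basisfcn_n(t) · e^{-(d_n t + g t²)} · e^{i2π Δf_n t}
             · (1/R) Σ_r e^{i2π Δω_r t}
         + baseline(t) + resH₂O(t) + noise ] · phases(ϕ0, ϕ1) · eddy(A0, tc)
```

- **Amplitudes** `M_n` are mM-equivalent concentrations (each basis function
  is taken to represent 1.0 mM of signal).
- **Voigt lineshape**: per-metabolite Lorentzian decay `d_n` (linewidth
  `d_n/π` Hz) times a group-level Gaussian decay `g` (one value for
  metabolites, one for macromolecules/lipids).
- **B0 inhomogeneity**: a 3D sub-voxel field map (linear gradients `dx, dy,
  dz` around a mean offset `μ`, all in Hz); summing the sub-voxel phase
  evolutions produces broadening, signal damping, and a global shift of
  `μ` Hz.
- **Nuisance signals**: the spectral baseline and residual water have no
  physical model, so both are drawn from a smoothed bounded pseudo-random
  walk, with a broad/smooth profile for the baseline and a jagged,
  water-region-localized profile for residual water.
- **Noise** is complex Gaussian calibrated to a target spectral SNR
  (max real peak of a reference metabolite / noise σ).
- **Phases and eddy currents**: zero-order phase `ϕ0` (degrees), first-order
  phase `ϕ1` (degrees/ppm, pivoting at the 4.65 ppm reference), and an
  exponentially decaying eddy-current phase modulation `A0·e^{-t/tc}`.
- **Transients**: one noiseless FID can be expanded into C coil/average
  transients with clamped-normal sensitivity weights (N(1, 0.5²) → [0, 2]),
  per-transient SNR `snr0/√C`, and frequency/phase drifts; averaging them
  back recovers the `√C` SNR gain.
- **Post-processing**: apodization `e^{-t·TL}`, zero-filling, Fourier
  transform, and crop/resampling with a modified-Akima interpolator.

Records export losslessly to an HDF5 container (data + every ground-truth
component) and to NIfTI-MRS (complex time-domain data, dwell time,
spectrometer frequency, tagged coil dimension).

## Worked example

`examples/02_b0_inhomogeneity.py` applies 20×20×20 sub-voxel field maps to a
5 Hz-wide singlet at 2.01 ppm (2000 Hz spectral width, 4096 points,
127.7 MHz):

```
mu [Hz]  delta [Hz]   peak shift [Hz]   relative height
   10.0        0.0             9.77             1.004
   10.0        0.5             9.77             0.993
   10.0        5.0             9.77             0.633
   10.0       15.0             9.77             0.306
  -50.0        0.5           -50.29             0.992
```

The voxel-mean offset `μ` sets the peak displacement (9.77 Hz is 10 Hz
quantized to the 0.49 Hz grid); growing the intra-voxel spread `Δ` at fixed
`μ` leaves the position unchanged but progressively damps the peak — the
signature of intravoxel dephasing. The other scripts in `examples/`
demonstrate lineshapes, nuisance generation, the full model with export,
transient combination, and distribution analysis, each printing the
quantities it verifies.

Batch generation is available from the shell:

```bash
mrsynth simulate --config run.yaml --out simulated/ --n 100 --seed 7
mrsynth analyze-params --table fits.csv --out report.json
```

## Scope

Basis functions themselves are produced by external density-matrix
simulators; this package manipulates pre-simulated (or analytic toy) basis
sets. No spectral fitting, artifact-correction, or pulse-sequence modelling
is included. See `docs/methods.md` for model details, defaults, and
limitations.
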