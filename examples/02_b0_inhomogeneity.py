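"""B0 field inhomogeneity: mean offset shifts, spread damps and broadens.

Applies 20x20x20 sub-voxel field maps to a toy singlet and reports the
induced frequency shift and peak-height damping.
"""

import numpy as np

from mrsynth import apply_b0, make_b0_map, make_toy_basis, to_spectrum

# a 5 Hz-wide singlet: broad enough that peak heights are sampled cleanly
basis = make_toy_basis(
    [("NAA", "metabolite", [(2.01, 1.0)])], 2000.0, 4096, 127.7, 4.65, decay_fwhm_hz=5.0
)
axes = basis.axes()
fid = basis.fid("NAA")
h0 = np.max(np.abs(to_spectrum(fid)))
f0 = axes.freq[np.argmax(np.abs(to_spectrum(fid)))]

print("mu [Hz]  delta [Hz]   peak shift [Hz]   relative height")
for mu, delta in [(10.0, 0.0), (10.0, 0.5), (10.0, 5.0), (10.0, 15.0), (-50.0, 0.5)]:
    d = delta / 2.0  # isotropic convention: delta = 2*dx = 2*dy = 2*dz
    b0 = make_b0_map((20, 20, 20), d, d, d, mu)
    spec = np.abs(to_spectrum(apply_b0(fid, b0, axes)))
    shift = axes.freq[np.argmax(spec)] - f0
    print(f"{mu:7.1f}  {delta:9.1f}   {shift:14.2f}   {np.max(spec) / h0:15.3f}")

# The voxel-mean offset mu displaces the peak by mu Hz; increasing the
# intra-voxel spread delta leaves the position set by mu but damps the
# signal, exactly the behaviour expected from intravoxel dephasing.
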