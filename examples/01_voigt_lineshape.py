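"""Voigt lineshape: Lorentzian decay sets a metabolite's linewidth.

Builds a toy singlet with no intrinsic decay, applies a per-metabolite
Lorentzian decay d, and verifies the absorption linewidth d/pi Hz.
"""

import numpy as np

from mrsynth import ModelParams, make_toy_basis, scale_and_shape, to_spectrum

basis = make_toy_basis(
    [("NAA", "metabolite", [(2.01, 1.0)])], 2000.0, 4096, 127.7, 4.65, decay_fwhm_hz=0.0
)
axes = basis.axes()

for d in (np.pi * 2, np.pi * 5, np.pi * 10):
    p = ModelParams(amplitude={"NAA": 1.0}, lorentz={"NAA": d}, gauss_metab=0.0)
    fid = scale_and_shape(basis, p, axes)["NAA"]
    prof = to_spectrum(fid).real
    k = int(np.argmax(prof))
    half = prof[k] / 2

    def crossing(sign):
        i = k
        while prof[i + sign] > half:
            i += sign
        j = i + sign
        frac = (prof[i] - half) / (prof[i] - prof[j])
        return axes.freq[i] + frac * (axes.freq[j] - axes.freq[i])

    fwhm = crossing(+1) - crossing(-1)
    print(f"lorentz d = {d:6.2f} s^-1  ->  linewidth {fwhm:5.2f} Hz (expect {d/np.pi:.2f})")

# The linewidth of an exponentially decaying resonance equals d/pi Hz; adding
# a Gaussian term (gauss_metab > 0) would convolve this with a Gaussian,
# giving the Voigt profile used to model in-vivo peaks.
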