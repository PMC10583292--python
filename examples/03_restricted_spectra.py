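"""Restricted-diffusion spectra: Lorentzian expansion for confined water.

D_rest(w) rises from the long-range diffusivity (zero for impermeable
walls) at w=0 to the bulk diffusivity at frequencies far above the first
Lorentzian width Gamma_1 = xi_1^2 D0 / r^2.  Cell-sized compartments put
Gamma_1 in the range probed by the waveform family, which is what makes
the centroid-frequency dimension informative.
"""

import numpy as np

import dorwave as dw

for d, name in ((1, "planar"), (2, "cylinder"), (3, "sphere")):
    xi1 = dw.bessel_roots(d, 1)[0]
    print(f"{name:8s} (d={d}): first eigenvalue xi_1 = {xi1:.4f}")

print()
for r_um in (1.0, 2.5, 5.0):
    m = dw.RestrictedModel(d=3, r=r_um * 1e-6, D0=1e-9, Dinf=0.0)
    f1 = m.Gamma[0] / (2 * np.pi)
    om = 2 * np.pi * np.array([0.0, 20.0, 100.0, 260.0, 1e4])
    dr = dw.restricted_spectrum(m, om) / 1e-9
    print(f"sphere r={r_um:4.1f} um: Gamma_1/2pi = {f1:8.1f} Hz;  "
          f"D(w)/D0 at [0, 20, 100, 260, 1e4] Hz = "
          + ", ".join(f"{x:.3f}" for x in dr))

print()
print("A 2.5 um sphere attenuates the 20-260 Hz window differentially --")
print("small cells look nearly static at 20 Hz but recover most of the")
print("bulk diffusivity by a few kHz.")
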