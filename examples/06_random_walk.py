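"""Monte Carlo validation of the Gaussian phase approximation.

Simulates spins diffusing inside a reflecting sphere under a DOR
waveform and compares the phase-variance attenuation exponent beta with
the independent spectral prediction int b(w):D(w) dw built from the
Lorentzian restricted spectrum.  Agreement to a few percent confirms
both the walker engine and the frequency-domain signal theory.
"""

import numpy as np

import dorwave as dw

w = dw.generate(dw.WaveformSpec(tau=25e-3, n_ratio=2, b_delta=1.0,
                                b=3e8, n_samples=2**13))

for geometry in ("cylinder", "sphere"):
    rep = dw.gpa_validate(geometry, w, radius=3e-6, D0=2e-9,
                          n_spins=10_000, seed=42)
    print(f"{geometry:8s}: beta_MC = {rep['beta_mc']:.4f} "
          f"+/- {rep['beta_se']:.4f},  "
          f"beta_spectral = {rep['beta_spectral']:.4f}  "
          f"({rep['beta_rel_dev']:+.2%})")
    print(f"          |E| = {abs(rep['E']):.4f}, exp(-beta) = "
          f"{np.exp(-rep['beta_mc']):.4f}, "
          f"Gaussian-phase OK: {rep['normality']['gpa_ok']}")

print()
print("The free diffusivity would give beta = b*D0 =", f"{3e8 * 2e-9:.2f};")
print("restriction inside 3 um compartments removes roughly a third of it")
print("at this waveform's centroid frequency.")
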