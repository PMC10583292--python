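"""End-to-end phantom analyses: protocol -> synthetic data -> fits.

Reproduces the three reference analyses on synthetic data: a
two-component isotropic liquid (bi-exponential, shape- and frequency-
blind), a lamellar liquid-crystal powder (stratified by b_delta), and a
yeast-cell sediment (spherically restricted + free pool, sensitive to
the centroid frequency).  With 1% noise the fits recover the generating
parameters to a few percent.
"""

import dorwave as dw

protocol = dw.build_protocol(tau=25e-3, g_max=3.0)
print(f"protocol: {len(protocol.entries)} entries "
      f"(24 waveforms x 8 b x 15 orientations), "
      f"b_max = {protocol.b_max:.3e} s/m^2")

for phantom in ("two_iso", "lamellar_powder", "yeast"):
    report = dw.run_end_to_end(phantom, seed=1, noise_sd=0.01,
                               protocol=protocol)
    print(f"\n{phantom} (1% noise):")
    for key, rec in report["recovery"].items():
        print(f"  {key:9s} true={rec['true']:.3e}  "
              f"fitted={rec['fitted']:.3e}  "
              f"rel.err={rec['rel_error']:+.2%}")
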