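# Methods

This note documents the models implemented in `dorwave`, the numerical
choices behind them, what the synthetic phantoms do and do not emulate,
and the known limitations.  Everything quantitative stated here is
computed by the test suite or the example scripts; nothing is quoted
from elsewhere.

## Waveform synthesis

**Scalar waveform.**  The base waveform `g1D(t)` is a dephasing lobe at
the start of the interval and its inversion/time-reversal at the end.
The lobe has a quarter-sine ramp-up of duration ε_up·τ and a raised-
cosine ("half-cosine") ramp-down of duration ε_down·τ; by default the
lobe is exactly ε_up + ε_down long, so the gradient is zero between the
lobes while the dephasing magnitude q(t) sits on its plateau.  This
approximates the impulsive (delta-pulse) limit in which the
double-rotation algebra is exact; the lobe can optionally be widened
(`lobe_width`), which also covers the rectangular degenerate case
ε_up = ε_down = 0 with an explicit pulse width.  Since the lobe pair is
antisymmetric about τ/2, q(t) is symmetric; the implementation computes
the cumulative integral over the first half and mirrors it, which makes
the refocusing condition q(τ) = 0 exact by construction.

**Double rotation.**  The q-vector direction is
u(t) = Rz(ψ₂)Ry(ζ₂)Rz(ψ₁)Ry(ζ₁)ẑ with Z–Y *active* rotations applied
right to left, seeded on the unit z vector.  The outer angle follows
the accumulated diffusion weighting, ψ₂(t) = Δψ₂∫₀ᵗq²dt′/b, so equal
shares of b are spent at equal rotation angles; ψ₁ = nψ₂.  Expanding
the matrix product gives harmonics at ψ₂, ψ₁ and ψ± = (n±1)ψ₂ with
amplitudes

    a₀ = cosζ₁cosζ₂,  a₁ = sinζ₁sinζ₂,  a₂ = cosζ₁sinζ₂,
    a± = sinζ₁(cosζ₂ ± 1)/2 .

The a± expression was re-derived from the rotation product rather than
transcribed: at ζ₁ = 0 the inner rotation acts on its own axis and the
trajectory must collapse to a single-rotation cone, which forces
a± = 0 there (a form with a detached ±1/2 term would not).  At
ζ₁ = 90°, ζ₂ = −54.7356° the values are a₀ = a₂ = 0, a₁ = −0.8165,
a₊ = 0.7887, a₋ = −0.2113, and for n ≥ 2 with Δψ₂ a multiple of 2π the
impulsive-limit b tensor is isotropic to machine precision (the test
suite checks |b_Δ| < 10⁻⁶; the observed values are ~10⁻¹⁵).  n = 1 is
special twice over: its impulsive tensor is *not* isotropic (principal
values 0.356/0.311/0.333 of b), and its ψ₋ harmonic is a DC term, so
the b_Δ = 0 member retains a finite flow sensitivity q_v.  n = 0
degenerates to single-axis spinning and uses ζ₁ = 0, ζ₂ = +54.7° (the
magic-angle cone); n ≥ 1 uses ζ₁ = 90°, ζ₂ = −54.7°.

**Gradient.**  The closed-form gradient is
g = g1D·u + g_rot·du/dψ₂ with g_rot = Δψ₂q³/(γb).  The closed form and
the numerical route (differentiating q(t)u(t)) agree to better than
10⁻⁶ of the peak dephasing on the default grid; the tests enforce this
equivalence by integrating the gradient back to the stored trajectory.

**Shape and normalization.**  Component scaling by
√(1−b_Δ(1+b_η)), √(1−b_Δ(1−b_η)), √(1+2b_Δ) sets the tensor shape; the
admissible region is where all radicands are non-negative.  Scaling is
applied before amplitude normalization, which targets either a b value
or a peak gradient.  Bracketing pairs are emitted as *effective*
gradients (the second copy already carries the sign flip imposed by the
refocusing pulse), with a configurable zero-gradient gap defaulting to
zero since the pulse duration is hardware-specific.

**Grid and quadrature.**  Uniform time grid, 2¹⁴ samples per waveform
by default (the default ramps at 0.015τ are then resolved by ~250
points; a guard rejects grids that resolve any ramp by fewer than 8).
Cumulative integrals (q from g1D, ψ₂ from q²) use cumulative Simpson;
definite integrals (b matrix, spectra, attenuation) use the trapezoidal
rule.  The higher-order cumulative rule is what makes the closed-form /
trajectory equivalence hold at the 10⁻⁶ level on this grid; trapezoidal
accumulation would plateau near 10⁻⁵.

## Encoding spectra and metrics

q(ω) = ∫q(t)e^{iωt}dt is approximated by an FFT times the grid step,
zero-padded ≥ 8× to the next power of two.  b(ω) = q(ω)q(ω)†/2π is
Hermitian positive semidefinite; its frequency integral reproduces the
time-domain b matrix to better than 10⁻⁶ (Parseval check in the suite).
Shape metrics use the Haeberlen convention
|b_ZZ−b/3| ≥ |b_XX−b/3| ≥ |b_YY−b/3|, with degenerate deviations
tie-broken by descending eigenvalue and b_η defined as 0 at the
isotropic point where the anisotropy denominator vanishes.

**Centroid frequency.**  The literal two-sided first moment of the
(even) trace spectrum is zero; `dorwave` uses the standard convention —
the first moment of the one-sided spectrum normalized by its own area.
Internally ω_cent is in rad/s; every interface reports Hz.

For the 24-waveform protocol the reported ω_cent is computed on the
*single* waveform while b and the attenuation spectra refer to the
bracketing pair.  The two differ only for the lowest-frequency members:
the zero-gap pair's interference fringes (spacing ~1/τ) overlap the
envelope of the nearly static n = 0, b_Δ = 1 member and drag its pair
centroid from 17.3 down to 13.4 Hz, whereas for n ≥ 2 single and pair
agree to ~0.1%.  The single-waveform value is the one the main-
frequency formulas predict and is the meaningful per-waveform label.

Finite lobes chirp the rotation: the instantaneous frequency is
(n±1)Δψ₂q²/b, larger on the q plateau than the nominal (n±1)Δψ₂/τ.
The default family's spectral peaks therefore sit ~15% above ω₁/ω₊
(185 Hz vs 160 Hz for n = 4, b_Δ = 1), and the family spans
ω_cent ≈ 17–264 Hz at τ = 25 ms.

## Acquisition protocol

The default protocol is the full factorial n = 0…5 ×
b_Δ ∈ {−0.5, 0, 0.5, 1} at τ = 25 ms, ε_up = 0.03, ε_down = 0.12,
Δψ₂ = 360° per waveform, b_η = 0, as bracketing pairs.  All members are
scaled to the identical b attainable by the most gradient-demanding
member (n = 5, b_Δ = 1) at the 3 T/m peak-gradient limit, which gives
b_max = 6.43×10⁹ s/m².  Eight b values are linearly spaced from
b_max/8 to b_max (the zero-gradient reference S₀ is a separate
normalization, not a protocol entry), with 15 orientations per
waveform from a deterministic electrostatic-repulsion point set
(Fibonacci seed, fixed relaxation steps) — 2880 entries in total.
Metadata (b_Δ, ω_cent) is recomputed from the generated waveforms, not
taken from the request; the recomputed b_Δ deviates from the nominal by
< 0.001 except for the n = 1 members (≤ 0.034, the impulsive-tensor
effect above).

## Diffusion models

Restricted diffusion in planar (d = 1), cylindrical (d = 2) or
spherical (d = 3) compartments of radius r uses the Lorentzian
expansion D_rest(ω) = D₀ − Σ_k w_k(D₀−D_∞)/(1+ω²/Γ_k²) with
Γ_k = ξ_k²D₀/r² and w_k = 2/(ξ_k²+1−d), where ξ_k solves
ξJ_{d/2−1}(ξ) = (d−1)J_{d/2}(ξ).  d = 1 uses the analytic roots
(k−½)π; d = 2, 3 bracket roots by a π/50 sign-change scan refined with
Brent's method to 10⁻¹² (first roots 1.8412 and 2.0816).  The series is
truncated at K = 50 terms and the weights renormalized to sum exactly
to 1, so D_rest(0) = D_∞ holds despite truncation (raw-weight mode is
available for convergence studies; the raw K = 50 residual is below
10⁻²).  D_∞ defaults to 0 (impermeable walls).  Axisymmetric tensor
spectra place D_rest/D₀ on the restricted/free axes and rotate by
(θ, φ); Gaussian tensors use (D_∥, D_⊥) with
D_iso = (D_∥+2D_⊥)/3 and D_Δ = (D_∥−D_⊥)/(3D_iso).

## Signals, powder average, fits

The general attenuation exponent is β = ∫b(ω):D(ω)dω on the two-sided
grid; for ω-independent D it reduces to b:D, and to bD when also
isotropic (the suite checks these reductions to 10⁻⁸).  Multicomponent
signals are fraction-weighted sums of per-component attenuations, with
an optional common flow phase exp(iq_v·⟨v⟩).

The powder average of an axisymmetric Gaussian component is
S/S₀ = e^{−bD_iso}·h(A), A = 3bD_iso b_Δ D_Δ, with
h(A) = (√π/2)e^{A/3}erf(√A)/√A.  For A < 0 (mixed-sign shape and
anisotropy — the lamellar phantom measured with prolate encoding is
exactly this case) the analytic continuation replaces erf by erfi; for
|A| < 10⁻⁴ a fourth-order series avoids the 0/0.  The closed form
matches a 10⁵-point numerical orientation average to < 0.1% over the
full (b_Δ, D_Δ) grid.

**Phantoms.**  Three synthetic datasets emulate the reference samples:

| phantom | model | defaults |
|---|---|---|
| `two_iso` | two isotropic Gaussian pools | D = 2.0/0.4 ×10⁻⁹ m²/s, f_fast = 0.6 |
| `lamellar_powder` | powder of planar Gaussian domains | D_⊥ = 1.5×10⁻⁹, D_∥ = 0 (D_Δ = −½) |
| `yeast` | impermeable spheres + free pool | r = 2.5 µm, D₀ = 1.0×10⁻⁹, f_intra = 0.55, D_free = 1.2×10⁻⁹ |

Defaults are water-like diffusivities and cell-scale radii typical of
such phantoms at room temperature.  The restricted pool's attenuation
integrates the waveform's normalized trace encoding spectrum against
the isotropic D_rest(ω); the directional dependence of restriction
sensitivity (the transverse and longitudinal channels peak at different
frequencies) is not modelled, consistent with fitting powder-averaged
data only.  Noise is Gaussian on the magnitude signal by default
(Rician optional), quoted relative to S₀ and seeded.  The phantoms
capture shape/frequency stratification of ideal powder-averaged data;
they do not emulate relaxation weighting, imaging artifacts,
orientation-dispersion that is only partially random, exchange, or
Rice-floor bias at very low SNR — passing recovery tests therefore
demonstrates the correctness of the estimation chain, not robustness to
every experimental confound.

**Fits.**  All fits are trust-region (`scipy.optimize.least_squares`,
TRF) with 8 seeded multi-starts on powder-averaged data.  Residuals are
linear in S/S₀: log-residuals weight the deepest-attenuation points
hardest, and with noise those points can fall below the noise floor (or
zero), which in testing drove the anisotropy fit into a wrong-sign
basin.  Diffusivities and the radius are fitted as log₁₀ so the random
starts cover the physically distinguishable decades; bounds are
D ∈ [10⁻¹², 5×10⁻⁹] m²/s, r ∈ [0.1, 20] µm, fractions ∈ [0, 1].
Degenerate outcomes are flagged rather than hidden: near-equal
diffusivities or extreme fractions in the two-pool fit raise an
identifiability warning, and a fitted radius beyond 15 µm (restriction
invisible in the sampled frequency window) raises a Gaussian-regime
warning.

## Random-walk validation

Spins take Gaussian steps of per-axis standard deviation √(2D₀dt) plus
a constant drift, inside reflecting free/planar/cylindrical/spherical
geometries (compartment axis along z).  Planar reflection folds the
coordinate exactly; radial geometries backtrack the sub-step to the
boundary crossing and mirror the remainder about the tangent plane,
iterated for rare multiple crossings.  Phase accrues as the trapezoidal
integral of −γg·r.  Defaults: 10⁴ spins, the waveform grid capped at
8192 steps (guards reject steps longer than r/5 or fewer than 50 steps
per gradient oscillation).  The phase statistics α = ⟨φ⟩,
β = ½var(φ), E = ⟨e^{iφ}⟩ carry bootstrap standard errors, plus
skewness/kurtosis and the relative gap between |E| and e^{−β} as
Gaussian-phase diagnostics.  Cross-validation against
β = ∫b(ω):D(ω)dω with the Lorentzian spectra agrees to well under 5%
at moderate attenuation for cylinders and spheres; the suite also
exercises the bulk high-frequency limit, the motional-narrowing limit,
and a deliberately non-Gaussian deep-attenuation case that the
diagnostics must flag.

## Problem sizes and determinism

The defaults used throughout the tests and the acceptance script are
desk-scale choices: 2¹⁴ samples per waveform, 8× FFT padding, K = 50
Lorentzian terms, 10⁴ walkers × ≤ 8192 steps, 8 fit starts.  The full
test suite runs in about three minutes on one CPU and the acceptance
script in well under a minute.  All randomness (phantom noise, fit
starts, walker steps, bootstrap) flows through seeded
`numpy.random.default_rng` generators; identical configuration and
seeds give byte-identical outputs, and each workflow writes a
provenance record (package version, seed, configuration).

## Known limitations

- Hardware constraints beyond the peak gradient (slew rate, duty cycle,
  eddy currents, concomitant fields) are out of scope; the waveforms
  are not numerically optimized for maximal b at a given hardware.
- The q-space picture ignores imaging gradients and their cross terms.
- The walker has impermeable walls only; finite permeability (D_∞ > 0)
  is handled analytically, not by the simulation.
- Exchange between compartments, surface relaxation and susceptibility-
  induced internal gradients are not modelled.
- The n = 1 family member is a structural outlier (anisotropy offset
  ~0.03 and finite flow sensitivity at b_Δ = 0); analyses that need
  clean b_Δ = 0 encoding should prefer n ≥ 2.
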