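"""Synthesis of double-rotation (DOR) diffusion-encoding gradient waveforms.

A DOR waveform is built in four steps: (1) a scalar dephasing/rephasing
waveform ``g1D(t)`` whose time integral gives the dephasing magnitude
``q(t)``; (2) a pair of simultaneous rotations of the q-vector direction
about two inclined axes, with rotation angles advancing in proportion to
the accumulated diffusion weighting; (3) closed-form evaluation of the
3-component gradient ``g(t)`` that produces the rotating trajectory
``q(t) = q(t) u(t)``; (4) component-wise scaling that morphs the encoding
tensor shape between planar (b_delta = -1/2), spherical (0) and linear (1)
without changing the per-axis frequency content.

At the inclinations zeta1 = 90 deg, zeta2 = -54.7 deg (the magic angle)
and integer frequency ratio n >= 2 the time-averaged q-vector outer
product is isotropic, so the unscaled waveform carries a spherical
b tensor; n = 0 with zeta1 = 0, zeta2 = 54.7 deg reduces to magic-angle
spinning of the q vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_simpson

__all__ = [
    "GAMMA_1H",
    "MAGIC_ANGLE",
    "WaveformSpec",
    "Waveform1D",
    "Waveform3D",
    "RotationAngles",
    "make_g1d",
    "rotation_angles",
    "dor_amplitudes",
    "assemble_dor",
    "shape_scale",
    "orient",
    "bracket_pair",
    "normalize",
    "generate",
    "unit_qtrajectory",
]

#: 1H gyromagnetic ratio (rad s^-1 T^-1)
GAMMA_1H = 2.6752218744e8

#: magic angle, zero of the second Legendre polynomial (rad)
MAGIC_ANGLE = float(np.arccos(1.0 / np.sqrt(3.0)))


class InvalidSpecError(ValueError):
    """Waveform specification violates a structural constraint."""


class InvalidWaveformError(ValueError):
    """Waveform fails a requirement of the requested operation."""


@dataclass(frozen=True)
class WaveformSpec:
    """Geometric and timing parameters of one DOR waveform.

    Parameters
    ----------
    tau : float
        Duration of a single encoding waveform (s).
    n_ratio : int
        Double-rotation frequency ratio n (inner rotation angle is n times
        the outer one); n = 0 degenerates to single-axis spinning.
    b_delta, b_eta : float
        Target encoding anisotropy (in [-1/2, 1]) and asymmetry (>= 0) of
        the b tensor, realised by component scaling of the base waveform.
    zeta1, zeta2 : float, optional
        Rotation-axis inclinations (rad).  Defaults follow the frequency
        ratio: (0, +magic) for n = 0 and (pi/2, -magic) for n >= 1, the
        inclinations that make the impulsive-limit b tensor isotropic.
    dpsi2 : float
        Total outer rotation angle over tau (rad); a positive multiple of
        2*pi for a refocused rotation.
    eps_up, eps_down : float
        Quarter-sine ramp-up and half-cosine ramp-down durations of the
        dephasing lobe, as fractions of tau.
    lobe_width : float, optional
        Total lobe duration as a fraction of tau.  Defaults to
        ``eps_up + eps_down`` (no flat gradient inside the lobe); values up
        to 1/2 insert a constant-gradient plateau, and it must be set
        explicitly for the rectangular degenerate case eps_up=eps_down=0.
    n_samples : int
        Uniform time-grid size per single waveform.
    gamma : float
        Gyromagnetic ratio (rad s^-1 T^-1).
    b : float, optional
        Target b value (s m^-2) for amplitude normalization.
    g_max : float, optional
        Peak-gradient limit (T m^-1) for amplitude normalization;
        ignored when ``b`` is given.
    pair : bool
        Emit the waveform as a pair of identical copies bracketing a
        refocusing pulse (effective gradient, i.e. the second copy already
        carries the sign flip imposed by the 180 deg pulse).
    pair_gap : float
        Zero-gradient gap between the two copies of a pair (s).
    """

    tau: float = 25e-3
    n_ratio: int = 4
    b_delta: float = 0.0
    b_eta: float = 0.0
    zeta1: Optional[float] = None
    zeta2: Optional[float] = None
    dpsi2: float = 2.0 * np.pi
    eps_up: float = 0.03
    eps_down: float = 0.12
    lobe_width: Optional[float] = None
    n_samples: int = 2**14
    gamma: float = GAMMA_1H
    b: Optional[float] = None
    g_max: Optional[float] = None
    pair: bool = False
    pair_gap: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise InvalidSpecError("tau must be positive")
        if self.n_ratio < 0 or int(self.n_ratio) != self.n_ratio:
            raise InvalidSpecError("n_ratio must be a non-negative integer")
        if not (-0.5 <= self.b_delta <= 1.0):
            raise InvalidSpecError("b_delta must lie in [-1/2, 1]")
        if self.b_eta < 0:
            raise InvalidSpecError("b_eta must be non-negative")
        if self.eps_up < 0 or self.eps_down < 0:
            raise InvalidSpecError("ramp fractions must be non-negative")
        if self.eps_up + self.eps_down > 0.5 + 1e-12:
            raise InvalidSpecError(
                "eps_up + eps_down must not exceed 1/2 (each lobe must fit "
                "in half the waveform)"
            )
        lw = self.lobe_frac
        if not (0 < lw <= 0.5 + 1e-12):
            raise InvalidSpecError("lobe width must lie in (0, tau/2]")
        if lw + 1e-12 < self.eps_up + self.eps_down:
            raise InvalidSpecError("lobe width smaller than its ramps")
        if self.dpsi2 <= 0:
            raise InvalidSpecError("dpsi2 must be positive")

    @property
    def lobe_frac(self) -> float:
        if self.lobe_width is not None:
            return self.lobe_width
        return self.eps_up + self.eps_down

    @property
    def inclinations(self) -> tuple[float, float]:
        """Rotation-axis inclinations, defaulted per frequency ratio."""
        if self.zeta1 is not None and self.zeta2 is not None:
            return self.zeta1, self.zeta2
        if self.n_ratio == 0:
            return 0.0, MAGIC_ANGLE
        return np.pi / 2.0, -MAGIC_ANGLE


@dataclass
class Waveform1D:
    """Scalar dephasing/rephasing waveform and its dephasing magnitude."""

    t: np.ndarray          # time samples (s)
    g1d: np.ndarray        # scalar gradient (T m^-1)
    q: np.ndarray          # dephasing magnitude (rad m^-1)
    gamma: float = GAMMA_1H

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def b(self) -> float:
        """Diffusion weighting of the scalar waveform (s m^-2)."""
        return float(np.trapezoid(self.q**2, self.t))


@dataclass
class RotationAngles:
    """Time series of the DOR rotation angles psi2, psi1, psi+ and psi-."""

    psi2: np.ndarray
    psi1: np.ndarray
    psi_plus: np.ndarray
    psi_minus: np.ndarray


@dataclass
class Waveform3D:
    """Sampled 3-component gradient with its dephasing trajectory."""

    t: np.ndarray          # (N,) time samples (s)
    g: np.ndarray          # (N, 3) gradient (T m^-1)
    q: np.ndarray          # (N, 3) dephasing trajectory (rad m^-1)
    gamma: float = GAMMA_1H
    spec: Optional[WaveformSpec] = None
    orientation: tuple[float, float] = (0.0, 0.0)   # (Theta, Phi), rad
    meta: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def tau(self) -> float:
        return float(self.t[-1])

    def copy(self) -> "Waveform3D":
        return replace(self, t=self.t.copy(), g=self.g.copy(), q=self.q.copy(),
                       meta=dict(self.meta))


def _lobe(tt: np.ndarray, L1: float, L2: float, L: float) -> np.ndarray:
    """Unit-amplitude dephasing lobe on local time tt in [0, L]."""
    g = np.zeros_like(tt)
    if L1 > 0:
        m = tt <= L1
        g[m] = np.sin(np.pi * tt[m] / (2.0 * L1))
    if L2 > 0:
        m = (tt > L - L2) & (tt <= L)
        g[m] = 0.5 * (1.0 + np.cos(np.pi * (tt[m] - (L - L2)) / L2))
    m = (tt > L1) & (tt <= L - L2)
    g[m] = 1.0
    return g


def make_g1d(spec: WaveformSpec) -> Waveform1D:
    """Build the scalar dephasing/rephasing waveform at unit amplitude.

    The dephasing lobe occupies ``[0, lobe_frac * tau]`` with a
    quarter-sine ramp-up of duration ``eps_up * tau`` and a half-cosine
    (raised-cosine) ramp-down of duration ``eps_down * tau``; the
    rephasing lobe is its inversion and time reversal at the end of the
    interval.  Between the lobes the gradient is zero and the dephasing
    magnitude q(t) sits at its maximum.
    """
    if spec.n_samples < 1000:
        raise InvalidSpecError("n_samples must be at least 1000")
    tau = spec.tau
    L = spec.lobe_frac * tau
    L1 = spec.eps_up * tau
    L2 = spec.eps_down * tau
    n_ramp = min(x for x in (L1, L2, L) if x > 0)
    if n_ramp / (tau / spec.n_samples) < 8:
        raise InvalidSpecError(
            "n_samples too small to resolve the lobe ramps"
        )
    t = np.linspace(0.0, tau, spec.n_samples)
    g = _lobe(t, L1, L2, L) - _lobe(tau - t, L1, L2, L)
    q = spec.gamma * cumulative_simpson(g, x=t, initial=0.0)
    # the lobe pair is antisymmetric about tau/2, so q(t) = q(tau - t)
    # exactly; mirroring the first half enforces q(tau) = 0 by construction
    half = spec.n_samples // 2
    q[spec.n_samples - half:] = q[:half][::-1]
    return Waveform1D(t=t, g1d=g, q=q, gamma=spec.gamma)


def rotation_angles(w: Waveform1D, dpsi2: float, n_ratio: int) -> RotationAngles:
    """Time-dependent DOR rotation angles driven by the accumulated b.

    The outer angle advances as ``psi2(t) = dpsi2 * int_0^t q^2 dt' / b``
    so that equal shares of diffusion weighting are spent at equal
    rotation angles; the inner and combination angles are the multiples
    ``psi1 = n psi2`` and ``psi± = (n ± 1) psi2``.
    """
    b = np.trapezoid(w.q**2, w.t)
    if b <= 0:
        raise InvalidWaveformError("waveform has zero diffusion weighting")
    psi2 = dpsi2 * cumulative_simpson(w.q**2, x=w.t, initial=0.0) / b
    psi2[-1] = dpsi2  # endpoint exact by construction
    return RotationAngles(
        psi2=psi2,
        psi1=n_ratio * psi2,
        psi_plus=(n_ratio + 1) * psi2,
        psi_minus=(n_ratio - 1) * psi2,
    )


def dor_amplitudes(zeta1: float, zeta2: float) -> dict[str, float]:
    """Amplitudes of the oscillating terms of the DOR gradient.

    With the unit q-vector built from Z-Y active rotations
    ``u = Rz(psi2) Ry(zeta2) Rz(psi1) Ry(zeta1) (0,0,1)^T`` the Cartesian
    components reduce to harmonics at psi1, psi2 and psi± with constant
    amplitudes::

        a0 = cos z1 cos z2          a1 = sin z1 sin z2
        a2 = cos z1 sin z2          a± = sin z1 (cos z2 ± 1) / 2

    At zeta1 = 90 deg, zeta2 = -54.7 deg this gives a0 = a2 = 0,
    a1 = -0.816, a+ = 0.789, a- = -0.211.
    """
    return {
        "a0": np.cos(zeta1) * np.cos(zeta2),
        "a1": np.sin(zeta1) * np.sin(zeta2),
        "a2": np.cos(zeta1) * np.sin(zeta2),
        "a+": np.sin(zeta1) * (np.cos(zeta2) + 1.0) / 2.0,
        "a-": np.sin(zeta1) * (np.cos(zeta2) - 1.0) / 2.0,
    }


def _unit_vector(a: dict[str, float], ang: RotationAngles) -> np.ndarray:
    """u(t) of the double rotation from its harmonic expansion, (N, 3)."""
    p2, p1 = ang.psi2, ang.psi1
    pp, pm = ang.psi_plus, ang.psi_minus
    ux = a["a+"] * np.cos(pp) + a["a-"] * np.cos(pm) + a["a2"] * np.cos(p2)
    uy = a["a+"] * np.sin(pp) - a["a-"] * np.sin(pm) + a["a2"] * np.sin(p2)
    uz = a["a0"] - a["a1"] * np.cos(p1)
    return np.stack([ux, uy, uz], axis=1)


def assemble_dor(spec: WaveformSpec, w: Optional[Waveform1D] = None) -> Waveform3D:
    """Assemble the 3D DOR gradient from the scalar waveform.

    The gradient follows the closed form

    ``g(t) = g1D(t) u(t) + grot(t) du/dpsi2``,

    with ``grot = dpsi2 * q^3 / (gamma * b)`` the magnitude of the rotating
    part.  The stored trajectory is the analytic ``q(t) = q(t) u(t)``; the
    cumulative integral of the returned gradient reproduces it to grid
    tolerance (this equivalence is enforced by the test suite, which
    differentiates the trajectory numerically).
    """
    if w is None:
        w = make_g1d(spec)
    n = spec.n_ratio
    z1, z2 = spec.inclinations
    ang = rotation_angles(w, spec.dpsi2, n)
    a = dor_amplitudes(z1, z2)
    b = np.trapezoid(w.q**2, w.t)
    grot = spec.dpsi2 * w.q**3 / (w.gamma * b)
    p2, p1 = ang.psi2, ang.psi1
    pp, pm = ang.psi_plus, ang.psi_minus
    u = _unit_vector(a, ang)
    # du/dpsi2 (per unit outer angle)
    dux = (-(n + 1) * a["a+"] * np.sin(pp)
           - (n - 1) * a["a-"] * np.sin(pm)
           - a["a2"] * np.sin(p2))
    duy = ((n + 1) * a["a+"] * np.cos(pp)
           - (n - 1) * a["a-"] * np.cos(pm)
           + a["a2"] * np.cos(p2))
    duz = n * a["a1"] * np.sin(p1)
    du = np.stack([dux, duy, duz], axis=1)
    g = w.g1d[:, None] * u + grot[:, None] * du
    q = w.q[:, None] * u
    return Waveform3D(t=w.t.copy(), g=g, q=q, gamma=w.gamma, spec=spec)


def shape_scale(w: Waveform3D, b_delta: float, b_eta: float = 0.0) -> Waveform3D:
    """Scale Cartesian components to set the encoding-tensor shape.

    X, Y and Z are multiplied by sqrt(1 - b_delta (1 + b_eta)),
    sqrt(1 - b_delta (1 - b_eta)) and sqrt(1 + 2 b_delta).  Starting from
    an isotropic-capable base waveform this realises encoding anisotropy
    ``b_delta`` and asymmetry ``b_eta`` exactly in the impulsive limit,
    while leaving the normalized spectral content of each component
    untouched.
    """
    radicands = np.array([
        1.0 - b_delta * (1.0 + b_eta),
        1.0 - b_delta * (1.0 - b_eta),
        1.0 + 2.0 * b_delta,
    ])
    if np.any(radicands < -1e-12):
        raise InvalidSpecError(
            f"(b_delta={b_delta}, b_eta={b_eta}) outside the admissible "
            "shape region (negative scaling radicand)"
        )
    s = np.sqrt(np.clip(radicands, 0.0, None))
    out = w.copy()
    out.g = w.g * s
    out.q = w.q * s
    out.meta["shape_scaled"] = (b_delta, b_eta)
    return out


def rotation_matrix(theta: float, phi: float) -> np.ndarray:
    """Z-Y active rotation R = Rz(phi) @ Ry(theta)."""
    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(phi), np.sin(phi)
    ry = np.array([[ct, 0.0, st], [0.0, 1.0, 0.0], [-st, 0.0, ct]])
    rz = np.array([[cp, -sp, 0.0], [sp, cp, 0.0], [0.0, 0.0, 1.0]])
    return rz @ ry

def orient(w: Waveform3D, theta: float, phi: float) -> Waveform3D:
    """Rigidly rotate the waveform to orientation (Theta, Phi).

    The trace, eigenvalues and all shape metrics of the b tensor, as well
    as the centroid frequency, are invariant under this rotation.
    """
    R = rotation_matrix(theta, phi)
    out = w.copy()
    out.g = w.g @ R.T
    out.q = w.q @ R.T
    out.orientation = (theta, phi)
    return out


def bracket_pair(w: Waveform3D, gap: float = 0.0) -> Waveform3D:
    """Duplicate a self-refocusing waveform around a refocusing pulse.

    Returns the *effective* gradient waveform: the refocusing pulse flips
    the sign of all phase accumulated afterwards, so the second copy of
    the physically identical waveform enters with the same effective
    polarity and the total b value doubles.  An optional zero-gradient gap
    models the finite duration of the refocusing pulse.
    """
    qmax = np.max(np.linalg.norm(w.q, axis=1))
    if np.linalg.norm(w.q[-1]) > 1e-6 * qmax:
        raise InvalidWaveformError("bracket_pair requires a refocused input")
    dt = w.dt
    n_gap = int(round(gap / dt))
    zeros3 = np.zeros((n_gap, 3))
    g = np.concatenate([w.g, zeros3, w.g[1:]])
    q = np.concatenate([w.q, np.tile(w.q[-1], (n_gap, 1)), w.q[1:]])
    t = np.arange(len(g)) * dt
    out = replace(w, t=t, g=g, q=q, meta=dict(w.meta))
    out.meta["pair"] = {"gap": n_gap * dt, "tau_single": w.tau}
    return out


def normalize(w: Waveform3D, b: Optional[float] = None,
              g_max: Optional[float] = None) -> Waveform3D:
    """Scale the amplitude to a target b value or a peak-gradient limit.

    b scales with the square of the gradient amplitude, so a target b is
    reached with the factor sqrt(b_target / b_current).
    """
    if b is None and g_max is None:
        return w
    if b is not None:
        b_cur = float(np.trapezoid(np.sum(w.q**2, axis=1), w.t))
        if b_cur <= 0:
            raise InvalidWaveformError("cannot normalize a zero waveform")
        s = np.sqrt(b / b_cur)
    else:
        g_cur = float(np.max(np.linalg.norm(w.g, axis=1)))
        if g_cur <= 0:
            raise InvalidWaveformError("cannot normalize a zero waveform")
        s = g_max / g_cur
    out = w.copy()
    out.g = w.g * s
    out.q = w.q * s
    return out


def generate(spec: WaveformSpec, theta: float = 0.0, phi: float = 0.0) -> Waveform3D:
    """Full pipeline: scalar lobes -> DOR assembly -> shape -> pair -> norm."""
    w = assemble_dor(spec)
    w = shape_scale(w, spec.b_delta, spec.b_eta)
    if theta or phi:
        w = orient(w, theta, phi)
    if spec.pair:
        w = bracket_pair(w, spec.pair_gap)
    return normalize(w, b=spec.b, g_max=spec.g_max)


def unit_qtrajectory(n_ratio: int, zeta1: float, zeta2: float,
                     dpsi2: float = 2.0 * np.pi,
                     n_samples: int = 2**14) -> tuple[np.ndarray, np.ndarray]:
    """Impulsive-limit q-vector trajectory with constant unit magnitude.

    Corresponds to ``g1D(t)`` proportional to delta(t) - delta(t - tau):
    q jumps to its plateau instantly, so the outer angle advances linearly
    in time.  Returns dimensionless time in [0, 1] and the (N, 3) unit
    trajectory; the integral of its outer product (times b) is the
    impulsive-limit b tensor, which is isotropic for zeta1 = 90 deg,
    zeta2 = -54.7 deg and n_ratio >= 2.
    """
    t = np.linspace(0.0, 1.0, n_samples)
    psi2 = dpsi2 * t
    ang = RotationAngles(psi2=psi2, psi1=n_ratio * psi2,
                         psi_plus=(n_ratio + 1) * psi2,
                         psi_minus=(n_ratio - 1) * psi2)
    u = _unit_vector(dor_amplitudes(zeta1, zeta2), ang)
    return t, u
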