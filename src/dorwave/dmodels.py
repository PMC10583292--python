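"""Diffusion spectra for restricted and Gaussian compartments.

Restricted diffusion in planar (d=1), cylindrical (d=2) or spherical
(d=3) compartments of radius r has a velocity-autocorrelation spectrum
that is a sum of Lorentzians,

    D_rest(w) = D0 - sum_k w_k (D0 - Dinf) / (1 + w^2 / Gamma_k^2),

with widths Gamma_k = xi_k^2 D0 / r^2 set by the eigenvalues xi_k of the
reflecting-boundary diffusion problem and weights w_k = 2/(xi_k^2+1-d).
D_rest rises monotonically from the long-range diffusivity Dinf at w = 0
(zero for impermeable walls) to the bulk diffusivity D0 at frequencies
far above Gamma_1.  Axisymmetric tensor spectra are built by placing
D_rest and D0 on the restricted and free axes and rotating to the
compartment orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import jv

from .waveform import rotation_matrix

__all__ = [
    "RestrictedModel",
    "TensorSpectrumModel",
    "bessel_roots",
    "lorentzian_terms",
    "restricted_spectrum",
    "tensor_spectrum",
    "iso_aniso_metrics",
]


def bessel_roots(d: int, K: int = 50) -> np.ndarray:
    """First K positive roots of xi J_{d/2-1}(xi) - (d-1) J_{d/2}(xi) = 0.

    These are the radial eigenvalues of diffusion with reflecting walls:
    (k-1/2)pi between plates (d=1, analytic), the extrema of J1 for a
    cylinder (d=2, first root 1.8412) and of the first spherical Bessel
    function for a sphere (d=3, first root 2.0816).  Non-analytic cases
    are bracketed by a sign-change scan and refined by root polishing.
    Results are memoized; a fresh copy is returned to the caller.
    """
    return _bessel_roots_cached(int(d), int(K)).copy()


@lru_cache(maxsize=32)
def _bessel_roots_cached(d: int, K: int) -> np.ndarray:
    if d not in (1, 2, 3):
        raise ValueError("restriction dimensionality d must be 1, 2 or 3")
    if K < 1:
        raise ValueError("K must be at least 1")
    if d == 1:
        return (np.arange(1, K + 1) - 0.5) * np.pi

    nu = d / 2.0 - 1.0

    def f(x: float) -> float:
        return x * jv(nu, x) - (d - 1) * jv(d / 2.0, x)

    roots: list[float] = []
    step = np.pi / 50.0
    xs = np.arange(step, (K + 2) * np.pi + step, step)
    fs = np.array([f(x) for x in xs])
    for i in range(len(xs) - 1):
        if fs[i] == 0.0:
            roots.append(xs[i])
        elif fs[i] * fs[i + 1] < 0:
            roots.append(brentq(f, xs[i], xs[i + 1], xtol=1e-12, rtol=1e-15))
        if len(roots) >= K:
            break
    if len(roots) < K:
        raise RuntimeError(
            f"bracketed only {len(roots)} of {K} roots for d={d}; "
            "scan range exhausted"
        )
    return np.asarray(roots[:K])


@dataclass
class RestrictedModel:
    """Lorentzian expansion of restricted diffusion in one compartment.

    Parameters
    ----------
    d : int
        Restricted dimensionality: 1 planar, 2 cylindrical, 3 spherical.
    r : float
        Compartment radius (m); half the plate separation for d = 1.
    D0 : float
        Bulk diffusivity (m^2 s^-1).
    Dinf : float
        Long-range diffusivity (m^2 s^-1); 0 for impermeable walls.
    K : int
        Number of Lorentzian terms retained.
    renormalize : bool
        Rescale the truncated weights to sum to exactly 1 so that the
        w = 0 limit equals Dinf despite truncation (default).  Disable
        for convergence studies on the raw partial sums.
    """

    d: int = 3
    r: float = 2.5e-6
    D0: float = 1.0e-9
    Dinf: float = 0.0
    K: int = 50
    renormalize: bool = True
    xi: np.ndarray = field(init=False, repr=False)
    Gamma: np.ndarray = field(init=False, repr=False)
    w: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("radius must be positive")
        if not (0.0 <= self.Dinf <= self.D0):
            raise ValueError("need 0 <= Dinf <= D0")
        self.xi = bessel_roots(self.d, self.K)
        terms = lorentzian_terms(self)
        self.Gamma = terms["Gamma"]
        self.w = terms["w"]

    @property
    def truncation_residual(self) -> float:
        """1 - sum of raw weights; shrinks as K grows."""
        raw = 2.0 / (self.xi**2 + 1.0 - self.d)
        return float(1.0 - raw.sum())


def lorentzian_terms(m: RestrictedModel) -> dict[str, np.ndarray]:
    """Widths Gamma_k = xi_k^2 D0 / r^2 and weights w_k = 2/(xi_k^2+1-d)."""
    Gamma = m.xi**2 * m.D0 / m.r**2
    w = 2.0 / (m.xi**2 + 1.0 - m.d)
    if m.renormalize:
        w = w / w.sum()
    return {"Gamma": Gamma, "w": w}


def restricted_spectrum(m: RestrictedModel, omega: np.ndarray) -> np.ndarray:
    """D_rest(w) on the given (rad/s) grid; even in w."""
    omega = np.abs(np.asarray(omega, dtype=float))
    lor = m.w[:, None] / (1.0 + (omega[None, :] / m.Gamma[:, None]) ** 2)
    return m.D0 - (m.D0 - m.Dinf) * lor.sum(axis=0)


@dataclass
class TensorSpectrumModel:
    """Axisymmetric tensor-valued diffusion spectrum D(w).

    ``geometry`` selects how the scalar spectra populate the principal
    frame: 'cylinder' -> diag(D_rest, D_rest, D0); 'planar' ->
    diag(D0, D0, D_rest); 'sphere' -> D_rest * I; 'gaussian' ->
    frequency-independent diag(Dperp, Dperp, Dpar).  (theta, phi) orient
    the symmetry axis in the lab frame.
    """

    geometry: str = "cylinder"
    theta: float = 0.0
    phi: float = 0.0
    restricted: Optional[RestrictedModel] = None
    Dpar: Optional[float] = None
    Dperp: Optional[float] = None

    def __post_init__(self) -> None:
        if self.geometry not in ("cylinder", "planar", "sphere", "gaussian"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.geometry == "gaussian":
            if self.Dpar is None or self.Dperp is None:
                raise ValueError("gaussian geometry needs Dpar and Dperp")
        elif self.restricted is None:
            raise ValueError(f"{self.geometry} geometry needs a RestrictedModel")

    @property
    def iso_aniso(self) -> dict[str, float]:
        if self.Dpar is None or self.Dperp is None:
            raise ValueError("Dpar/Dperp not defined for this geometry")
        return iso_aniso_metrics(self.Dpar, self.Dperp)


def tensor_spectrum(tm: TensorSpectrumModel, omega: np.ndarray) -> np.ndarray:
    """D(w) as an (Nf, 3, 3) array on the given frequency grid."""
    omega = np.asarray(omega, dtype=float)
    nf = len(omega)
    D = np.zeros((nf, 3, 3))
    if tm.geometry == "gaussian":
        diag = np.array([tm.Dperp, tm.Dperp, tm.Dpar])
        D[:] = np.diag(diag)
    else:
        dr = restricted_spectrum(tm.restricted, omega)
        if tm.geometry == "sphere":
            D[:, 0, 0] = D[:, 1, 1] = D[:, 2, 2] = dr
            return D
        d0 = np.full(nf, tm.restricted.D0)
        if tm.geometry == "cylinder":
            D[:, 0, 0] = D[:, 1, 1] = dr
            D[:, 2, 2] = d0
        else:  # planar
            D[:, 0, 0] = D[:, 1, 1] = d0
            D[:, 2, 2] = dr
    R = rotation_matrix(tm.theta, tm.phi)
    return np.einsum("ij,fjk,lk->fil", R, D, R)


def iso_aniso_metrics(Dpar: float, Dperp: float) -> dict[str, float]:
    """Isotropic diffusivity and normalized anisotropy of an axisymmetric D.

    Diso = (Dpar + 2 Dperp) / 3 and Ddelta = (Dpar - Dperp) / (3 Diso),
    spanning -1/2 (planar, Dpar = 0) to 1 (stick, Dperp = 0).
    """
    if Dpar < 0 or Dperp < 0:
        raise ValueError("diffusivities must be non-negative")
    Diso = (Dpar + 2.0 * Dperp) / 3.0
    if Diso == 0.0:
        raise ValueError("Ddelta undefined at Diso = 0")
    return {"Diso": Diso, "Ddelta": (Dpar - Dperp) / (3.0 * Diso)}
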