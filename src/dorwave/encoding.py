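"""Tensor-valued encoding spectra and scalar encoding metrics.

The dephasing trajectory q(t) of a gradient waveform determines every
motion-encoding property used here: its Fourier transform q(w) gives the
tensor-valued encoding spectrum b(w) = q(w) q(w)^H / 2pi, whose integral
over frequency is the conventional b matrix; the trace of b(w) is the
dephasing power spectrum whose first moment over w >= 0 is the centroid
frequency; and the time integral of q(t) is the flow-encoding vector,
proportional to the w = 0 amplitude of the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.integrate import cumulative_simpson

from .waveform import Waveform3D

__all__ = [
    "EncodingSpectrum",
    "BTensor",
    "dephasing_trajectory",
    "flow_vector",
    "dephasing_spectrum",
    "encoding_spectrum",
    "btensor",
    "btensor_from_q",
    "shape_metrics",
    "haeberlen_eigenvalues",
    "centroid_frequency",
    "main_frequencies",
    "analyze",
]


@dataclass
class EncodingSpectrum:
    """b(w) on a symmetric two-sided frequency grid.

    ``b_omega[k]`` is the Hermitian positive-semidefinite 3x3 matrix at
    ``omega[k]`` (units s m^-2 per rad s^-1); ``trace`` is the dephasing
    power spectrum trace b(w).
    """

    omega: np.ndarray          # (Nf,) rad s^-1, ascending, symmetric
    b_omega: np.ndarray        # (Nf, 3, 3) complex
    trace: np.ndarray          # (Nf,) real

    def one_sided(self) -> tuple[np.ndarray, np.ndarray]:
        """(omega >= 0, trace) pair for scalar spectral summaries."""
        m = self.omega >= 0
        return self.omega[m], self.trace[m]

    @property
    def b_matrix(self) -> np.ndarray:
        """Frequency integral of b(w): the 3x3 b matrix (s m^-2)."""
        return np.real(np.trapezoid(self.b_omega, self.omega, axis=0))


@dataclass
class BTensor:
    """b matrix with Haeberlen-ordered eigenvalues and shape metrics."""

    matrix: np.ndarray                 # 3x3 symmetric (s m^-2)
    eigenvalues: np.ndarray            # (bZZ, bXX, bYY) Haeberlen order
    b: float                           # trace (s m^-2)
    b_delta: float
    b_eta: float
    omega_cent: Optional[float] = None     # rad s^-1
    q_v: Optional[np.ndarray] = None       # flow-encoding vector (s rad m^-1)

    @property
    def omega_cent_hz(self) -> Optional[float]:
        if self.omega_cent is None:
            return None
        return self.omega_cent / (2.0 * np.pi)


def _tq(w: Union[Waveform3D, tuple[np.ndarray, np.ndarray]]):
    if isinstance(w, Waveform3D):
        return w.t, w.q
    t, q = w
    return np.asarray(t), np.asarray(q)


def dephasing_trajectory(w: Waveform3D) -> np.ndarray:
    """q(t) recomputed from the gradient: gamma * cumulative integral of g."""
    return w.gamma * cumulative_simpson(w.g, x=w.t, initial=0.0, axis=0)


def flow_vector(w: Union[Waveform3D, tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Flow-encoding vector q_v = int_0^tau q(t) dt (s rad m^-1).

    Zero exactly when the waveform is flow-compensated; the mean phase
    under plug flow is q_v . <v>.
    """
    t, q = _tq(w)
    return np.trapezoid(q, t, axis=0)


def dephasing_spectrum(
    w: Union[Waveform3D, tuple[np.ndarray, np.ndarray]],
    pad_factor: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous-time Fourier transform q(w) = int q(t) exp(iwt) dt.

    Approximated by an FFT times the grid step, on a grid zero-padded by
    at least ``pad_factor`` for smooth spectra.  Returns (omega, q_omega)
    with omega ascending and symmetric about zero; for the real-valued
    q(t), q(-w) is the complex conjugate of q(w).
    """
    t, q = _tq(w)
    dt = float(t[1] - t[0])
    n = len(t)
    n_pad = int(2 ** np.ceil(np.log2(max(n * pad_factor, n))))
    # numpy's forward FFT uses exp(-iwt); conjugate afterwards for exp(+iwt)
    qw = np.conj(np.fft.fft(q, n=n_pad, axis=0)) * dt
    omega = 2.0 * np.pi * np.fft.fftfreq(n_pad, dt)
    order = np.argsort(omega)
    return omega[order], qw[order]


def encoding_spectrum(
    w: Union[Waveform3D, tuple[np.ndarray, np.ndarray]],
    pad_factor: int = 8,
    max_omega: Optional[float] = None,
) -> EncodingSpectrum:
    """Tensor-valued encoding spectrum b(w) = q(w) q(-w)^T / 2pi.

    For real q(t) this is the Hermitian outer product of q(w) with its
    conjugate, positive semidefinite at every frequency.  ``max_omega``
    optionally crops the stored grid to |w| <= max_omega (the neglected
    tail power of smooth waveforms is negligible).
    """
    omega, qw = dephasing_spectrum(w, pad_factor=pad_factor)
    if max_omega is not None:
        m = np.abs(omega) <= max_omega
        omega, qw = omega[m], qw[m]
    b_omega = qw[:, :, None] * np.conj(qw[:, None, :]) / (2.0 * np.pi)
    trace = np.sum(np.abs(qw) ** 2, axis=1) / (2.0 * np.pi)
    return EncodingSpectrum(omega=omega, b_omega=b_omega, trace=trace)


def haeberlen_eigenvalues(matrix: np.ndarray) -> np.ndarray:
    """Eigenvalues ordered as (bZZ, bXX, bYY) by the Haeberlen convention.

    |bZZ - b/3| >= |bXX - b/3| >= |bYY - b/3|; degenerate deviations are
    tie-broken by descending eigenvalue for continuity at the isotropic
    point.
    """
    ev = np.linalg.eigvalsh(np.asarray(matrix, dtype=float))
    iso = ev.sum() / 3.0
    dev = np.abs(ev - iso)
    # sort by (deviation desc, eigenvalue desc)
    order = np.lexsort((-ev, -dev))
    return ev[order]


def shape_metrics(matrix: np.ndarray) -> dict[str, float]:
    """Trace b, encoding anisotropy b_delta and asymmetry b_eta.

    b_delta = (bZZ - (bXX + bYY)/2) / b and
    b_eta = 3 (bYY - bXX) / (2 b b_delta) with Haeberlen-ordered
    eigenvalues; b_eta is defined as 0 at the isotropic point where the
    anisotropy vanishes.
    """
    ev = haeberlen_eigenvalues(matrix)
    b = float(ev.sum())
    if b == 0.0:
        raise ValueError("shape metrics undefined for a zero-trace matrix")
    bzz, bxx, byy = ev
    b_delta = (bzz - (bxx + byy) / 2.0) / b
    if abs(b_delta) < 1e-12:
        b_eta = 0.0
    else:
        b_eta = 1.5 * (byy - bxx) / (b * b_delta)
    return {"b": b, "b_delta": float(b_delta), "b_eta": float(b_eta)}


def btensor_from_q(t: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Time-domain b matrix int q(t) q(t)^T dt (s m^-2)."""
    q = np.asarray(q)
    return np.trapezoid(q[:, :, None] * q[:, None, :], np.asarray(t), axis=0)


def centroid_frequency(
    es: Union[EncodingSpectrum, tuple[np.ndarray, np.ndarray]],
) -> float:
    """Centroid frequency: first moment of trace b(w) over w >= 0 (rad/s).

    The two-sided spectrum of a real waveform is even, so the literal
    two-sided first moment vanishes; the standard convention is the
    moment of the one-sided spectrum, normalized by its own area.
    """
    if isinstance(es, EncodingSpectrum):
        omega, trace = es.one_sided()
    else:
        omega, trace = es
        m = omega >= 0
        omega, trace = omega[m], trace[m]
    denom = np.trapezoid(trace, omega)
    if denom <= 0:
        raise ValueError("centroid frequency undefined for zero spectrum")
    return float(np.trapezoid(omega * trace, omega) / denom)


def main_frequencies(n_ratio: int, dpsi2: float, tau: float) -> dict[str, float]:
    """Nominal spectral peak positions (rad/s) of the impulsive-limit DOR.

    omega_1 = n dpsi2 / tau sits in the longitudinal (Z) channel and
    omega_± = (n ± 1) dpsi2 / tau in the transverse (X, Y) channels.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    return {
        "omega_1": n_ratio * dpsi2 / tau,
        "omega_plus": (n_ratio + 1) * dpsi2 / tau,
        "omega_minus": (n_ratio - 1) * dpsi2 / tau,
    }


def btensor(w: Waveform3D, with_spectral: bool = True,
            pad_factor: int = 8) -> BTensor:
    """Full b-tensor analysis of a waveform.

    Computes the time-domain b matrix, Haeberlen shape metrics, and (when
    ``with_spectral``) the centroid frequency from the encoding spectrum
    together with the flow-encoding vector.
    """
    B = btensor_from_q(w.t, w.q)
    metrics = shape_metrics(B)
    omega_cent = None
    if with_spectral:
        omega, qw = dephasing_spectrum(w, pad_factor=pad_factor)
        trace = np.sum(np.abs(qw) ** 2, axis=1) / (2.0 * np.pi)
        omega_cent = centroid_frequency((omega, trace))
    return BTensor(
        matrix=B,
        eigenvalues=haeberlen_eigenvalues(B),
        b=metrics["b"],
        b_delta=metrics["b_delta"],
        b_eta=metrics["b_eta"],
        omega_cent=omega_cent,
        q_v=flow_vector(w),
    )


#: alias used in reports and the CLI
analyze = btensor
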