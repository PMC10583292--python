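"""Forward signal models, acquisition protocol, phantoms and fits.

Implements the attenuation integral beta = int b(w):D(w) dw with its
Gaussian special cases, the closed-form powder average for axisymmetric
b and D tensors, the 24-waveform acquisition protocol spanning the
centroid-frequency/anisotropy plane, synthetic datasets emulating three
reference phantoms (two-component isotropic liquids, a polydomain
lamellar liquid crystal, a yeast-cell sediment), and least-squares fits
recovering the generating parameters of each.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import erf, erfi

from . import encoding, waveform as wfm
from .dmodels import RestrictedModel, iso_aniso_metrics
from .waveform import Waveform3D, WaveformSpec

__all__ = [
    "AcquisitionProtocol",
    "SignalDataset",
    "ComponentModel",
    "attenuation_general",
    "signal",
    "powder_average_factor",
    "powder_average_signal",
    "sphere_orientations",
    "build_protocol",
    "synth_phantom",
    "fit_two_iso",
    "fit_powder_aniso",
    "fit_restricted_plus_free",
    "PHANTOM_DEFAULTS",
]


# ---------------------------------------------------------------------------
# forward models

def attenuation_general(es: encoding.EncodingSpectrum,
                        D_omega: np.ndarray,
                        omega: Optional[np.ndarray] = None) -> float:
    """General attenuation exponent beta = int b(w):D(w) dw.

    ``D_omega`` is an (Nf, 3, 3) tensor spectrum on the spectrum's own
    grid, or on ``omega`` from which each element is interpolated.  For a
    frequency-independent D the integral reduces to the tensor dot
    product b:D, and further to b*D for isotropic D.
    """
    bw = np.real(es.b_omega)
    if omega is not None:
        if (es.omega.min() < omega.min()) or (es.omega.max() > omega.max()):
            raise ValueError("encoding spectrum extends beyond the D(w) grid")
        D_omega = np.stack(
            [np.interp(es.omega, omega, D_omega[:, i, j])
             for i in range(3) for j in range(3)], axis=1
        ).reshape(-1, 3, 3)
    integrand = np.einsum("fij,fij->f", bw, D_omega)
    return float(np.trapezoid(integrand, es.omega))


@dataclass
class ComponentModel:
    """One sub-ensemble of a multicomponent signal model."""

    kind: str                       # 'iso_gaussian' | 'aniso_gaussian' | 'iso_restricted'
    fraction: float = 1.0
    D: Optional[float] = None                    # iso_gaussian
    Diso: Optional[float] = None                 # aniso_gaussian
    Ddelta: Optional[float] = None
    restricted: Optional[RestrictedModel] = None  # iso_restricted

    def __post_init__(self) -> None:
        if self.kind not in ("iso_gaussian", "aniso_gaussian", "iso_restricted"):
            raise ValueError(f"unknown component kind {self.kind!r}")
        if self.fraction < 0:
            raise ValueError("component fractions must be non-negative")


def _component_attenuation(comp: ComponentModel, b: float, b_delta: float,
                           spectrum: Optional[tuple[np.ndarray, np.ndarray]]) -> float:
    """E = S/S0 of one powder-averaged component at one protocol entry."""
    if comp.kind == "iso_gaussian":
        return float(np.exp(-b * comp.D))
    if comp.kind == "aniso_gaussian":
        return float(powder_average_signal(b, b_delta, comp.Diso, comp.Ddelta))
    # isotropic restricted: beta = b * int bhat(w) D_rest(w) dw with the
    # normalized trace spectrum bhat of the waveform
    if spectrum is None:
        raise ValueError(
            "restricted components need the per-waveform encoding spectrum; "
            "regenerate the protocol with spectra enabled"
        )
    omega, bhat = spectrum
    from .dmodels import restricted_spectrum
    beta = b * np.trapezoid(bhat * restricted_spectrum(comp.restricted, omega), omega)
    return float(np.exp(-beta))


def signal(b: float, components: Sequence[ComponentModel], S0: float = 1.0,
           b_delta: float = 0.0,
           spectrum: Optional[tuple[np.ndarray, np.ndarray]] = None,
           q_v: Optional[np.ndarray] = None,
           v_mean: Optional[np.ndarray] = None) -> complex:
    """Multicomponent signal S = S0 sum_i f_i exp(-beta_i) (+ flow phase).

    Fractions must sum to 1.  When a mean velocity is supplied the common
    flow phase factor exp(i q_v . <v>) multiplies the attenuated sum and
    the return value is complex; otherwise it is real.
    """
    fr = np.array([c.fraction for c in components], dtype=float)
    if np.any(fr < 0):
        raise ValueError("negative component fraction")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("component fractions must sum to 1")
    s = S0 * sum(c.fraction * _component_attenuation(c, b, b_delta, spectrum)
                 for c in components)
    if v_mean is not None:
        if q_v is None:
            raise ValueError("flow phase requires the flow-encoding vector q_v")
        return s * np.exp(1j * float(np.dot(q_v, v_mean)))
    return s


def powder_average_factor(A):
    """Orientation-average factor h(A) = (sqrt(pi)/2) exp(A/3) erf(sqrt A)/sqrt A.

    A = 3 b Diso b_delta Ddelta.  For A < 0 the analytic continuation
    replaces erf by the imaginary error function; near A = 0 a series
    expansion avoids the 0/0.  h(0) = 1 recovers isotropic attenuation.
    """
    A = np.asarray(A, dtype=float)
    out = np.empty_like(A)
    small = np.abs(A) < 1e-4
    As = A[small]
    # (sqrt(pi)/2) erf(sqrt A)/sqrt A = 1 - A/3 + A^2/10 - A^3/42 + ...
    out[small] = np.exp(As / 3.0) * (1.0 - As / 3.0 + As**2 / 10.0 - As**3 / 42.0)
    pos = (~small) & (A > 0)
    Ap = A[pos]
    out[pos] = (np.sqrt(np.pi) / 2.0 * np.exp(Ap / 3.0)
                * erf(np.sqrt(Ap)) / np.sqrt(Ap))
    neg = (~small) & (A < 0)
    An = -A[neg]
    out[neg] = (np.sqrt(np.pi) / 2.0 * np.exp(-An / 3.0)
                * erfi(np.sqrt(An)) / np.sqrt(An))
    return out if out.ndim else float(out)


def powder_average_signal(b, b_delta, Diso, Ddelta, S0: float = 1.0):
    """Powder-averaged signal of an axisymmetric Gaussian component.

    S = S0 exp(-b Diso) h(A), the orientation average of exp(-b:D) over
    uniformly distributed symmetry axes, exact for axisymmetric b and D.
    """
    b = np.asarray(b, dtype=float)
    A = 3.0 * b * Diso * b_delta * Ddelta
    return S0 * np.exp(-b * Diso) * powder_average_factor(A)


# ---------------------------------------------------------------------------
# orientations

def sphere_orientations(n: int, n_iter: int = 150) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors by electrostatic repulsion.

    Seeds a Fibonacci spiral and relaxes it with a fixed number of
    inverse-square repulsion steps; fully deterministic.
    """
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(1.0 - z**2)
    p = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    for _ in range(n_iter):
        d = p[:, None, :] - p[None, :, :]
        r2 = np.sum(d * d, axis=2) + np.eye(n)
        f = np.sum(d / r2[:, :, None] ** 1.5, axis=1)
        p = p + 0.02 * f
        p /= np.linalg.norm(p, axis=1, keepdims=True)
    return p


# ---------------------------------------------------------------------------
# protocol

@dataclass
class AcquisitionProtocol:
    """Waveform set plus the (b, orientation) sampling grid.

    ``entries`` has one row per acquisition:
    (waveform_id, n_ratio, b_delta_nominal, b_delta, omega_cent_Hz, b,
    theta, phi).  Metadata (b_delta, omega_cent) is recomputed from the
    generated waveforms, never taken on trust from the request.
    ``spectra`` maps waveform id to (omega, bhat): the normalized
    one-sided trace encoding spectrum of the bracketing pair, with
    int bhat dw = 1, used for restricted-diffusion attenuation integrals.
    """

    tau: float
    gamma: float
    entries: pd.DataFrame
    waveforms: dict[str, Waveform3D] = field(default_factory=dict)
    spectra: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    b_max: float = 0.0

    @property
    def waveform_ids(self) -> list[str]:
        return list(dict.fromkeys(self.entries["waveform_id"]))


def build_protocol(tau: float = 25e-3,
                   g_max: float = 3.0,
                   n_list: Sequence[int] = (0, 1, 2, 3, 4, 5),
                   b_delta_list: Sequence[float] = (-0.5, 0.0, 0.5, 1.0),
                   n_b: int = 8,
                   n_orient: int = 15,
                   eps_up: float = 0.03,
                   eps_down: float = 0.12,
                   dpsi2: float = 2.0 * np.pi,
                   pair_gap: float = 0.0,
                   n_samples: int = 2**14,
                   gamma: float = wfm.GAMMA_1H,
                   keep_waveforms: bool = False) -> AcquisitionProtocol:
    """Build the identical-b multidimensional acquisition protocol.

    Generates one waveform per (n, b_delta) on the default grid (24 in
    total), as bracketing pairs, and scales all of them to the largest b
    that the most gradient-demanding member can reach at the peak
    gradient ``g_max``.  Each waveform is sampled at ``n_b`` b values
    (linearly spaced up to the protocol b) and ``n_orient`` orientations
    from a deterministic repulsion scheme.  The centroid frequency in the
    metadata is that of the single waveform (the quantity the spectral
    peak positions predict); b values and attenuation spectra refer to
    the pair.
    """
    if g_max <= 0:
        raise ValueError("g_max must be positive")
    ids, rows = [], []
    waveforms: dict[str, Waveform3D] = {}
    spectra: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    b_capacity: dict[str, float] = {}
    meta: dict[str, dict] = {}
    for n in n_list:
        for bd in b_delta_list:
            spec = WaveformSpec(tau=tau, n_ratio=n, b_delta=bd, b_eta=0.0,
                                eps_up=eps_up, eps_down=eps_down, dpsi2=dpsi2,
                                n_samples=n_samples, gamma=gamma,
                                pair=True, pair_gap=pair_gap)
            wid = f"n{n}_bd{bd:+.1f}"
            w_pair = wfm.generate(spec)          # unit amplitude pair
            w_single = wfm.normalize(
                wfm.shape_scale(wfm.assemble_dor(spec), bd, 0.0))
            gmax_unit = float(np.max(np.linalg.norm(w_pair.g, axis=1)))
            b_unit = float(np.trapezoid(np.sum(w_pair.q**2, axis=1), w_pair.t))
            b_capacity[wid] = (g_max / gmax_unit) ** 2 * b_unit
            bt_pair = encoding.btensor(w_pair, with_spectral=False)
            oc_single = encoding.btensor(w_single).omega_cent
            om, qw = encoding.dephasing_spectrum(w_pair)
            m = om >= 0
            tr = np.sum(np.abs(qw[m]) ** 2, axis=1) / (2.0 * np.pi)
            omp = om[m]
            # crop the stored spectrum; keep >= 99.9999% of the power
            cum = np.cumsum(tr) / tr.sum()
            hi = int(np.searchsorted(cum, 1.0 - 1e-8)) + 2
            omp, tr = omp[:hi], tr[:hi]
            bhat = tr / np.trapezoid(tr, omp)
            spectra[wid] = (omp, bhat)
            meta[wid] = {"n": n, "bd_nom": bd, "bd": bt_pair.b_delta,
                         "oc_hz": oc_single / (2.0 * np.pi)}
            if keep_waveforms:
                waveforms[wid] = w_pair
            ids.append(wid)
    b_protocol = min(b_capacity.values())
    if keep_waveforms:
        for wid in ids:
            waveforms[wid] = wfm.normalize(waveforms[wid], b=b_protocol)
    b_values = np.linspace(b_protocol / n_b, b_protocol, n_b)
    orientations = sphere_orientations(n_orient)
    theta = np.arccos(np.clip(orientations[:, 2], -1.0, 1.0))
    phi = np.arctan2(orientations[:, 1], orientations[:, 0])
    for wid in ids:
        for b in b_values:
            for th, ph in zip(theta, phi):
                rows.append((wid, meta[wid]["n"], meta[wid]["bd_nom"],
                             meta[wid]["bd"], meta[wid]["oc_hz"], b, th, ph))
    entries = pd.DataFrame(rows, columns=[
        "waveform_id", "n_ratio", "b_delta_nominal", "b_delta",
        "omega_cent_Hz", "b", "theta", "phi"])
    return AcquisitionProtocol(tau=tau, gamma=gamma, entries=entries,
                               waveforms=waveforms, spectra=spectra,
                               b_max=b_protocol)


# ---------------------------------------------------------------------------
# synthetic phantoms

PHANTOM_DEFAULTS = {
    # water / concentrated brine tube-in-tube: two isotropic Gaussian pools
    "two_iso": {"D_fast": 2.0e-9, "D_slow": 0.4e-9, "f_fast": 0.6},
    # polydomain lamellar liquid crystal: powder of planar domains
    "lamellar_powder": {"Dpar": 0.0, "Dperp": 1.5e-9},
    # yeast sediment: impermeable spheres + extracellular Gaussian pool
    "yeast": {"r": 2.5e-6, "D0_intra": 1.0e-9, "f_intra": 0.55,
              "D_free": 1.2e-9},
}


@dataclass
class SignalDataset:
    """Signals per protocol entry with powder-averaged view."""

    data: pd.DataFrame          # entries + S column
    S0: float = 1.0
    phantom: Optional[str] = None
    params: dict = field(default_factory=dict)

    @property
    def E(self) -> np.ndarray:
        return self.data["S"].to_numpy() / self.S0

    def powder_view(self) -> pd.DataFrame:
        """Mean S/S0 over orientations per (waveform, b) group."""
        g = (self.data.groupby(["waveform_id", "b"], sort=True)
             .agg(E=("S", "mean"),
                  b_delta=("b_delta", "first"),
                  b_delta_nominal=("b_delta_nominal", "first"),
                  omega_cent_Hz=("omega_cent_Hz", "first"),
                  n_orient=("S", "size"))
             .reset_index())
        g["E"] = g["E"] / self.S0
        return g


def _phantom_components(phantom: str, params: dict) -> list[ComponentModel]:
    if phantom == "two_iso":
        return [
            ComponentModel("iso_gaussian", fraction=params["f_fast"],
                           D=params["D_fast"]),
            ComponentModel("iso_gaussian", fraction=1.0 - params["f_fast"],
                           D=params["D_slow"]),
        ]
    if phantom == "lamellar_powder":
        ia = iso_aniso_metrics(params["Dpar"], params["Dperp"])
        return [ComponentModel("aniso_gaussian", fraction=1.0,
                               Diso=ia["Diso"], Ddelta=ia["Ddelta"])]
    if phantom == "yeast":
        rm = RestrictedModel(d=3, r=params["r"], D0=params["D0_intra"],
                             Dinf=0.0)
        return [
            ComponentModel("iso_restricted", fraction=params["f_intra"],
                           restricted=rm),
            ComponentModel("iso_gaussian", fraction=1.0 - params["f_intra"],
                           D=params["D_free"]),
        ]
    raise ValueError(f"unknown phantom {phantom!r}")


def synth_phantom(protocol: AcquisitionProtocol,
                  phantom: str,
                  params: Optional[dict] = None,
                  noise_sd: float = 0.0,
                  seed: Optional[int] = None,
                  S0: float = 1.0,
                  noise_model: str = "gaussian") -> SignalDataset:
    """Forward-model signals for one reference phantom plus noise.

    All three phantoms are orientationally isotropic at the level of the
    measured signal (isotropic pools, or a powder of domains), so each
    protocol entry depends only on (b, waveform).  ``noise_sd`` is the
    noise standard deviation relative to S0; 'gaussian' adds it to the
    magnitude signal, 'rician' applies it to both quadratures.
    """
    p = dict(PHANTOM_DEFAULTS.get(phantom) or {})
    if not p:
        raise ValueError(f"unknown phantom {phantom!r}")
    if params:
        p.update(params)
    comps = _phantom_components(phantom, p)
    df = protocol.entries.copy()
    cache: dict[tuple[str, float], float] = {}
    S = np.empty(len(df))
    for i, (wid, b, bd) in enumerate(zip(df["waveform_id"], df["b"],
                                         df["b_delta"])):
        key = (wid, b)
        if key not in cache:
            cache[key] = float(np.real(signal(
                b, comps, S0=S0, b_delta=bd,
                spectrum=protocol.spectra.get(wid))))
        S[i] = cache[key]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        if noise_model == "rician":
            S = np.hypot(S + rng.normal(0.0, noise_sd * S0, S.shape),
                         rng.normal(0.0, noise_sd * S0, S.shape))
        else:
            S = S + rng.normal(0.0, noise_sd * S0, S.shape)
    df["S"] = S
    return SignalDataset(data=df, S0=S0, phantom=phantom, params=p)


# ---------------------------------------------------------------------------
# fitting

def _multistart_least_squares(residual, bounds_lo, bounds_hi, n_starts=8,
                              seed=0):
    rng = np.random.default_rng(seed)
    lo = np.asarray(bounds_lo, dtype=float)
    hi = np.asarray(bounds_hi, dtype=float)
    best = None
    reports = []
    for k in range(n_starts):
        if k == 0:
            x0 = 0.5 * (lo + hi)
        else:
            x0 = lo + rng.random(len(lo)) * (hi - lo)
        try:
            res = least_squares(residual, x0, bounds=(lo, hi),
                                method="trf", x_scale=hi - lo,
                                xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                max_nfev=5000)
        except Exception as exc:     # pragma: no cover - diagnostic path
            reports.append(f"start {k}: {exc}")
            continue
        reports.append(f"start {k}: cost={res.cost:.6e} status={res.status}")
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all fit starts failed:\n" + "\n".join(reports))
    return best, reports


def _resid(model: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Linear-signal residuals.

    Fitting log-signals overweights deep-attenuation points; with noisy
    data the powder-averaged signal can drop below the noise floor (or
    zero) at the highest b, where a logarithm diverges.  Uniform linear
    residuals stay well defined at any SNR.
    """
    return model - data


def fit_two_iso(ds: SignalDataset, n_starts: int = 8, seed: int = 0) -> dict:
    """Bi-exponential fit of two isotropic Gaussian pools.

    Fits E(b) = f exp(-b D_fast) + (1 - f) exp(-b D_slow) to the
    powder-averaged data; flags near-degenerate solutions where the two
    diffusivities (or the fractions) are not separately identifiable.
    """
    pv = ds.powder_view()
    b = pv["b"].to_numpy()
    E = pv["E"].to_numpy()

    # diffusivities are fitted as log10(D/m^2 s^-1) so that multi-start
    # points spread evenly over the decades the data can distinguish
    def model(x):
        f, ld1, ld2 = x
        return f * np.exp(-b * 10.0**ld1) + (1.0 - f) * np.exp(-b * 10.0**ld2)

    res, reports = _multistart_least_squares(
        lambda x: _resid(model(x), E),
        [0.0, -12.0, -12.0], [1.0, np.log10(5e-9), np.log10(5e-9)],
        n_starts=n_starts, seed=seed)
    f, d1, d2 = res.x[0], 10.0 ** res.x[1], 10.0 ** res.x[2]
    if d1 < d2:                      # report the faster pool first
        f, d1, d2 = 1.0 - f, d2, d1
    degenerate = (abs(d1 - d2) < 0.05 * max(d1, d2)) or f < 1e-3 or f > 1 - 1e-3
    return {"D_fast": d1, "D_slow": d2, "f_fast": f,
            "residual_rms": float(np.sqrt(np.mean(res.fun**2))),
            "identifiability_warning": bool(degenerate),
            "starts": reports}


def fit_powder_aniso(ds: SignalDataset, n_starts: int = 8, seed: int = 0) -> dict:
    """Fit of the axisymmetric powder average across all (b, b_delta).

    Estimates (Diso, Ddelta) from the closed-form powder signal and
    back-computes Dpar = Diso (1 + 2 Ddelta), Dperp = Diso (1 - Ddelta).
    Requires at least two distinct encoding anisotropies, without which
    Ddelta is not identifiable.
    """
    pv = ds.powder_view()
    if pv["b_delta_nominal"].round(6).nunique() < 2:
        raise ValueError("Ddelta unidentifiable: need >= 2 distinct b_delta")
    b = pv["b"].to_numpy()
    bd = pv["b_delta"].to_numpy()
    E = pv["E"].to_numpy()

    def model(x):
        ldiso, dd = x
        return powder_average_signal(b, bd, 10.0**ldiso, dd)

    res, reports = _multistart_least_squares(
        lambda x: _resid(model(x), E),
        [-12.0, -0.5], [np.log10(5e-9), 1.0], n_starts=n_starts, seed=seed)
    diso, dd = 10.0 ** res.x[0], res.x[1]
    return {"Diso": diso, "Ddelta": dd,
            "Dpar": diso * (1.0 + 2.0 * dd),
            "Dperp": diso * (1.0 - dd),
            "residual_rms": float(np.sqrt(np.mean(res.fun**2))),
            "starts": reports}


def fit_restricted_plus_free(ds: SignalDataset,
                             protocol: AcquisitionProtocol,
                             n_starts: int = 8, seed: int = 0,
                             K: int = 50) -> dict:
    """Two-pool fit: spherically restricted (impermeable) + free Gaussian.

    The restricted pool's attenuation is the numerical integral of the
    waveform's trace encoding spectrum against the Lorentzian restricted
    spectrum (d = 3, Dinf = 0); the free pool is mono-exponential.  Fits
    (f_intra, r, D0_intra, D_free); the large-r limit where restriction
    becomes invisible on the sampled frequency window is flagged.
    """
    if not protocol.spectra:
        raise ValueError(
            "protocol carries no encoding spectra; rebuild it so that the "
            "per-waveform b(w) is available")
    pv = ds.powder_view()
    wids = pv["waveform_id"].to_numpy()
    b = pv["b"].to_numpy()
    E = pv["E"].to_numpy()
    uids = list(dict.fromkeys(wids))
    idx = np.array([uids.index(w) for w in wids])

    def model(x):
        f, lr, ld0, ldfree = x
        rm = RestrictedModel(d=3, r=10.0**lr, D0=10.0**ld0, Dinf=0.0, K=K)
        from .dmodels import restricted_spectrum
        integ = np.array([
            np.trapezoid(protocol.spectra[w][1]
                         * restricted_spectrum(rm, protocol.spectra[w][0]),
                         protocol.spectra[w][0])
            for w in uids])
        return (f * np.exp(-b * integ[idx])
                + (1.0 - f) * np.exp(-b * 10.0**ldfree))

    res, reports = _multistart_least_squares(
        lambda x: _resid(model(x), E),
        [0.0, np.log10(0.1e-6), -11.0, -12.0],
        [1.0, np.log10(20e-6), np.log10(5e-9), np.log10(5e-9)],
        n_starts=n_starts, seed=seed)
    f, r, d0, dfree = (res.x[0], 10.0 ** res.x[1], 10.0 ** res.x[2],
                       10.0 ** res.x[3])
    return {"f_intra": f, "r": r, "D0_intra": d0, "D_free": dfree,
            "residual_rms": float(np.sqrt(np.mean(res.fun**2))),
            "gaussian_regime_warning": bool(r > 15e-6),
            "starts": reports}
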