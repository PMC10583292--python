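"""Tests for forward signal models, the protocol, phantoms and fits."""

import numpy as np
import pytest

import dorwave as dw
from dorwave.signal_fit import ComponentModel, powder_average_factor


# ---------------------------------------------------------------------------
# powder average vs an independent numerical orientation average

def orientation_average_oracle(b, b_delta, Diso, Ddelta, n_axes=100_000):
    """Quasi-uniform orientation average of exp(-b:D).

    For axisymmetric b (axis z) and axisymmetric D with axis at polar
    angle theta, b:D = b Diso (1 + 2 b_delta Ddelta P2(cos theta)); the
    uniform orientation measure is flat in cos theta.
    """
    x = (np.arange(n_axes) + 0.5) / n_axes * 2.0 - 1.0   # cos theta
    p2 = 0.5 * (3.0 * x**2 - 1.0)
    return np.mean(np.exp(-b * Diso * (1.0 + 2.0 * b_delta * Ddelta * p2)))


class TestPowderAverage:
    @pytest.mark.parametrize("b_delta", [-0.5, 0.0, 0.5, 1.0])
    @pytest.mark.parametrize("Ddelta", [-0.5, 0.0, 0.5, 1.0])
    def test_closed_form_matches_orientation_oracle(self, b_delta, Ddelta):
        """Closed form within 0.1% of the numerical orientation average
        over the full shape grid at bDiso = 3."""
        Diso = 1e-9
        b = 3e9
        closed = dw.powder_average_signal(b, b_delta, Diso, Ddelta)
        oracle = orientation_average_oracle(b, b_delta, Diso, Ddelta)
        assert closed == pytest.approx(oracle, rel=1e-3)

    def test_stick_stick_case(self):
        """b_delta = Ddelta = 1 at bDiso = 3, the strongest stratification."""
        closed = dw.powder_average_signal(3e9, 1.0, 1e-9, 1.0)
        oracle = orientation_average_oracle(3e9, 1.0, 1e-9, 1.0)
        assert closed == pytest.approx(oracle, rel=1e-3)

    def test_isotropic_limits(self):
        for bd, dd in ((0.0, 1.0), (1.0, 0.0)):
            s = dw.powder_average_signal(2e9, bd, 1e-9, dd)
            assert s == pytest.approx(np.exp(-2.0), rel=1e-12)

    def test_factor_continuous_across_zero(self):
        """The series branch used for |A| < 1e-4 joins the erf/erfi
        branches smoothly; h(A) = 1 + O(A^2) near zero."""
        a = np.linspace(-5e-4, 5e-4, 2001)
        h = powder_average_factor(a)
        assert np.max(np.abs(np.diff(h))) < 1e-9      # no branch jumps
        assert np.max(np.abs(h - 1.0)) < 1e-7         # quadratic flatness
        assert powder_average_factor(0.0) == 1.0

    def test_negative_branch_matches_oracle(self):
        """Mixed-sign shape/anisotropy (A < 0) uses the erfi continuation."""
        closed = dw.powder_average_signal(4e9, 1.0, 1e-9, -0.5)
        oracle = orientation_average_oracle(4e9, 1.0, 1e-9, -0.5)
        assert closed == pytest.approx(oracle, rel=1e-3)


# ---------------------------------------------------------------------------
# attenuation and multicomponent signal

class TestAttenuation:
    def test_isotropic_gaussian_reduces_to_bD(self, example_waveform):
        es = dw.encoding_spectrum(example_waveform)
        D = 1.3e-9
        Dw = np.broadcast_to(D * np.eye(3), (len(es.omega), 3, 3))
        beta = dw.attenuation_general(es, Dw)
        b = dw.btensor_from_q(example_waveform.t, example_waveform.q).trace()
        assert beta == pytest.approx(b * D, rel=1e-8)

    def test_tensor_gaussian_reduces_to_bD_dot(self, example_waveform):
        es = dw.encoding_spectrum(example_waveform)
        Dmat = np.diag([0.5e-9, 1.0e-9, 2.0e-9])
        Dw = np.broadcast_to(Dmat, (len(es.omega), 3, 3))
        beta = dw.attenuation_general(es, Dw)
        B = dw.btensor_from_q(example_waveform.t, example_waveform.q)
        assert beta == pytest.approx(np.sum(B * Dmat), rel=1e-8)

    def test_restriction_sensitivity_grows_with_frequency(self):
        """At equal b, a high-frequency waveform samples more of the
        restricted spectrum of a small sphere than a low-frequency one."""
        rm = dw.RestrictedModel(d=3, r=2e-6, D0=2e-9, Dinf=0.0)
        betas = {}
        for n in (0, 5):
            w = dw.generate(dw.WaveformSpec(n_ratio=n, b_delta=0.0, b=1e9))
            es = dw.encoding_spectrum(w)
            Dw = dw.tensor_spectrum(
                dw.TensorSpectrumModel("sphere", restricted=rm), es.omega)
            betas[n] = dw.attenuation_general(es, Dw)
        assert betas[5] > betas[0]


class TestSignal:
    def test_b_zero_returns_s0(self):
        c = [ComponentModel("iso_gaussian", D=1e-9)]
        assert dw.signal(0.0, c, S0=3.7) == pytest.approx(3.7)

    def test_unit_bD(self):
        c = [ComponentModel("iso_gaussian", D=1e-9)]
        assert dw.signal(1e9, c) == pytest.approx(np.exp(-1.0))

    def test_fraction_validation(self):
        bad = [ComponentModel("iso_gaussian", fraction=0.7, D=1e-9)]
        with pytest.raises(ValueError):
            dw.signal(1e9, bad)

    def test_biexponential_log_convexity(self):
        comps = [ComponentModel("iso_gaussian", fraction=0.5, D=2e-9),
                 ComponentModel("iso_gaussian", fraction=0.5, D=1e-9)]
        b = np.linspace(0, 5e9, 40)
        logE = np.log([dw.signal(bi, comps) for bi in b])
        assert np.all(np.diff(logE, 2) > 0)

    def test_flow_phase(self):
        c = [ComponentModel("iso_gaussian", D=0.0)]
        qv = np.array([0.0, 0.0, 1e4])
        v = np.array([0.0, 0.0, 1e-4])
        s = dw.signal(0.0, c, q_v=qv, v_mean=v)
        assert np.angle(s) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# protocol

class TestProtocol:
    def test_entry_count(self, protocol):
        """24 waveforms x 8 b values x 15 orientations = 2880 entries."""
        assert len(protocol.entries) == 2880
        assert len(protocol.waveform_ids) == 24
        assert protocol.entries["b"].nunique() == 8

    def test_attainable_b(self, protocol):
        """Identical-b bracketing pairs at 3 T/m, tau = 25 ms reach about
        6.4e9 s/m^2."""
        assert 5.8e9 < protocol.b_max < 7.1e9

    def test_identical_b_across_waveforms(self, tmp_path):
        table = dw.make_waveform_grid(tmp_path, write_waveforms=False)
        assert len(table) == 24
        b = table["b"].to_numpy()
        assert np.max(np.abs(b / b.mean() - 1.0)) < 1e-6

    def test_recomputed_anisotropy_close_to_nominal(self, protocol):
        """Finite lobes perturb b_delta only slightly; the n=1 member is
        the worst case (~0.034) because its impulsive-limit tensor is not
        exactly isotropic."""
        first = protocol.entries.drop_duplicates("waveform_id")
        err = np.abs(first["b_delta"] - first["b_delta_nominal"])
        assert err.max() < 0.05
        not_n1 = first[first["n_ratio"] != 1]
        err1 = np.abs(not_n1["b_delta"] - not_n1["b_delta_nominal"])
        assert err1.max() < 0.02

    def test_orientations_quasi_uniform(self):
        p = dw.sphere_orientations(15)
        np.testing.assert_allclose(np.linalg.norm(p, axis=1), 1.0,
                                   rtol=1e-12)
        dots = p @ p.T - 2 * np.eye(15)
        assert np.arccos(np.clip(dots.max(), -1, 1)) > np.deg2rad(25)

    def test_spectra_normalized(self, protocol):
        for wid in protocol.waveform_ids[:4]:
            om, bhat = protocol.spectra[wid]
            assert np.trapezoid(bhat, om) == pytest.approx(1.0, rel=1e-9)


# ---------------------------------------------------------------------------
# synthetic phantoms

class TestSynthPhantom:
    def test_two_iso_master_curve(self, protocol):
        """Isotropic Gaussian diffusion is blind to waveform shape and
        frequency: all 24 waveforms give identical signals at equal b."""
        ds = dw.synth_phantom(protocol, "two_iso", noise_sd=0.0)
        pv = ds.powder_view()
        for b, grp in pv.groupby("b"):
            assert grp["E"].std() < 1e-14

    def test_lamellar_stratifies_by_bdelta(self, protocol):
        """Powdered anisotropic domains stratify into one curve per
        b_delta, independent of the centroid frequency."""
        ds = dw.synth_phantom(protocol, "lamellar_powder", noise_sd=0.0)
        pv = ds.powder_view()
        bmax = pv["b"].max()
        hi = pv[pv["b"] == bmax]
        # exclude n=1, whose actual b_delta deviates by ~0.03
        clean = hi[~hi["waveform_id"].str.startswith("n1_")]
        within = clean.groupby("b_delta_nominal")["E"].std().max()
        across = clean.groupby("b_delta_nominal")["E"].mean().std()
        assert within < 0.02 * across
        assert across > 0.0

    def test_yeast_depends_on_frequency(self, protocol):
        """Restricted diffusion makes the signal at fixed (b, b_delta)
        increase with the centroid frequency."""
        ds = dw.synth_phantom(protocol, "yeast", noise_sd=0.0)
        pv = ds.powder_view()
        bmax = pv["b"].max()
        hi = pv[(pv["b"] == bmax) & (pv["b_delta_nominal"] == 0.0)]
        hi = hi.sort_values("omega_cent_Hz")
        E = hi["E"].to_numpy()
        assert E[-1] < E[0]          # higher frequency -> more attenuation
        assert (E.max() - E.min()) / E.mean() > 0.2

    def test_noise_seeded_reproducible(self, protocol):
        a = dw.synth_phantom(protocol, "two_iso", noise_sd=0.01, seed=5)
        c = dw.synth_phantom(protocol, "two_iso", noise_sd=0.01, seed=5)
        np.testing.assert_array_equal(a.data["S"], c.data["S"])
        d = dw.synth_phantom(protocol, "two_iso", noise_sd=0.01, seed=6)
        assert not np.array_equal(a.data["S"], d.data["S"])

    def test_unknown_phantom_rejected(self, protocol):
        with pytest.raises(ValueError):
            dw.synth_phantom(protocol, "agar")


# ---------------------------------------------------------------------------
# fits

class TestFits:
    def test_two_iso_noiseless_recovery(self, protocol):
        ds = dw.synth_phantom(protocol, "two_iso", noise_sd=0.0)
        fit = dw.fit_two_iso(ds, seed=0)
        assert fit["D_fast"] == pytest.approx(2.0e-9, rel=1e-3)
        assert fit["D_slow"] == pytest.approx(0.4e-9, rel=1e-3)
        assert fit["f_fast"] == pytest.approx(0.6, abs=1e-3)
        assert not fit["identifiability_warning"]

    def test_two_iso_noisy_recovery(self, protocol):
        ds = dw.synth_phantom(protocol, "two_iso", noise_sd=0.01, seed=7)
        fit = dw.fit_two_iso(ds, seed=7)
        assert fit["D_fast"] == pytest.approx(2.0e-9, rel=0.05)
        assert fit["D_slow"] == pytest.approx(0.4e-9, rel=0.05)
        assert fit["f_fast"] == pytest.approx(0.6, abs=0.05)

    def test_two_iso_degenerate_flagged(self, protocol):
        ds = dw.synth_phantom(protocol, "two_iso",
                              params={"D_fast": 1e-9, "D_slow": 1e-9,
                                      "f_fast": 0.5},
                              noise_sd=0.0)
        fit = dw.fit_two_iso(ds, seed=0)
        assert fit["identifiability_warning"]

    def test_powder_aniso_noiseless_recovery(self, protocol):
        ds = dw.synth_phantom(protocol, "lamellar_powder", noise_sd=0.0)
        fit = dw.fit_powder_aniso(ds, seed=0)
        assert fit["Diso"] == pytest.approx(1.0e-9, rel=1e-3)
        assert fit["Ddelta"] == pytest.approx(-0.5, abs=5e-3)
        assert fit["Dpar"] == pytest.approx(0.0, abs=2e-11)
        assert fit["Dperp"] == pytest.approx(1.5e-9, rel=1e-2)

    def test_powder_aniso_noisy_recovery(self, protocol):
        ds = dw.synth_phantom(protocol, "lamellar_powder", noise_sd=0.01,
                              seed=7)
        fit = dw.fit_powder_aniso(ds, seed=7)
        assert fit["Diso"] == pytest.approx(1.0e-9, rel=0.03)
        assert fit["Ddelta"] == pytest.approx(-0.5, abs=0.05)

    def test_powder_aniso_consistent_with_isotropic_data(self, protocol):
        ds = dw.synth_phantom(protocol, "lamellar_powder",
                              params={"Dpar": 1.2e-9, "Dperp": 1.2e-9},
                              noise_sd=0.0)
        fit = dw.fit_powder_aniso(ds, seed=0)
        assert fit["Diso"] == pytest.approx(1.2e-9, rel=1e-3)
        assert abs(fit["Ddelta"]) < 0.05

    def test_powder_aniso_single_bdelta_rejected(self, protocol):
        ds = dw.synth_phantom(protocol, "lamellar_powder", noise_sd=0.0)
        sub = ds.data[ds.data["b_delta_nominal"] == 1.0]
        ds_single = dw.SignalDataset(data=sub)
        with pytest.raises(ValueError):
            dw.fit_powder_aniso(ds_single)

    def test_restricted_noiseless_recovery(self, protocol):
        ds = dw.synth_phantom(protocol, "yeast", noise_sd=0.0)
        fit = dw.fit_restricted_plus_free(ds, protocol, seed=0)
        assert fit["r"] == pytest.approx(2.5e-6, rel=1e-3)
        assert fit["D0_intra"] == pytest.approx(1.0e-9, rel=1e-3)
        assert fit["f_intra"] == pytest.approx(0.55, abs=1e-3)
        assert fit["D_free"] == pytest.approx(1.2e-9, rel=1e-3)

    def test_restricted_noisy_recovery(self, protocol):
        ds = dw.synth_phantom(protocol, "yeast", noise_sd=0.01, seed=7)
        fit = dw.fit_restricted_plus_free(ds, protocol, seed=7)
        assert fit["r"] == pytest.approx(2.5e-6, rel=0.05)
        assert fit["D0_intra"] == pytest.approx(1.0e-9, rel=0.05)
        assert fit["f_intra"] == pytest.approx(0.55, abs=0.05)
        assert fit["D_free"] == pytest.approx(1.2e-9, rel=0.05)

    def test_restricted_gaussian_regime_flagged(self, protocol):
        """Data generated with omega-independent diffusion pushes the
        fitted radius into the large-r regime where restriction is
        invisible, and the fit flags it."""
        ds = dw.synth_phantom(protocol, "two_iso",
                              params={"D_fast": 1.0e-9, "D_slow": 1.0e-9,
                                      "f_fast": 0.55},
                              noise_sd=0.0)
        fit = dw.fit_restricted_plus_free(ds, protocol, seed=0)
        assert fit["gaussian_regime_warning"] or fit["f_intra"] < 0.05 \
            or abs(fit["D0_intra"] - fit["D_free"]) < 0.05e-9

    def test_restricted_requires_spectra(self, protocol):
        ds = dw.synth_phantom(protocol, "yeast", noise_sd=0.0)
        bare = dw.AcquisitionProtocol(tau=protocol.tau, gamma=protocol.gamma,
                                      entries=protocol.entries)
        with pytest.raises(ValueError):
            dw.fit_restricted_plus_free(ds, bare)
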