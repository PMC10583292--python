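import numpy as np
import pytest

import dorwave as dw


@pytest.fixture(scope="session")
def protocol():
    """Full 24-waveform identical-b acquisition protocol (tau=25 ms, 3 T/m)."""
    return dw.build_protocol()


@pytest.fixture(scope="session")
def example_waveform():
    """Worked-example waveform: n=4, b_delta=0.5, b_eta=0.25, short ramps."""
    spec = dw.WaveformSpec(tau=25e-3, n_ratio=4, b_delta=0.5, b_eta=0.25,
                           eps_up=0.015, eps_down=0.06)
    return dw.generate(spec)


def rect_stejskal_tanner(g0=0.1, delta=5e-3, Delta=15e-3, n_per_ms=2000,
                         axis=2):
    """Rectangular pulsed-gradient pair with *analytic* q(t).

    The dephasing magnitude of the rectangular pair is the exact
    trapezoid gamma*g0*(min(t, delta) - max(t - Delta, 0)), so the
    waveform carries no numerical integration error; grid points are
    aligned with the pulse edges.
    """
    tau = Delta + delta
    n = int(round(tau * n_per_ms * 1e3)) + 1
    t = np.linspace(0.0, tau, n)
    g = np.zeros((n, 3))
    g[t < delta, axis] = g0
    g[(t >= Delta) & (t < Delta + delta), axis] = -g0
    q = np.zeros((n, 3))
    q[:, axis] = dw.GAMMA_1H * g0 * (np.minimum(t, delta)
                                     - np.maximum(t - Delta, 0.0))
    return dw.Waveform3D(t=t, g=g, q=q), g0, delta, Delta


@pytest.fixture(scope="session")
def st_waveform():
    return rect_stejskal_tanner()
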