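"""Plain-text and JSON I/O for waveforms, protocols, datasets and reports.

Canonical formats are diff-friendly text: waveforms as a commented header
plus four columns (t gx gy gz) in SI units, specs and protocols as JSON,
datasets as CSV.  Numeric round-trips are stable to 12 significant
digits.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .encoding import BTensor
from .waveform import Waveform3D, WaveformSpec

__all__ = [
    "write_waveform_text", "read_waveform_text",
    "spec_to_dict", "spec_from_dict", "write_specs", "read_specs",
    "write_report", "write_spectrum_text", "write_dataset", "read_dataset",
]

_FMT = "%.12e"


def spec_to_dict(spec: WaveformSpec) -> dict:
    d = dataclasses.asdict(spec)
    return {k: v for k, v in d.items() if v is not None}


def spec_from_dict(d: dict) -> WaveformSpec:
    fields = {f.name for f in dataclasses.fields(WaveformSpec)}
    return WaveformSpec(**{k: v for k, v in d.items() if k in fields})


def write_waveform_text(path: Union[str, Path], w: Waveform3D) -> None:
    path = Path(path)
    lines = [
        f"#tau_s {w.t[-1]:.12e}",
        f"#dt_s {w.dt:.12e}",
        f"#gamma {w.gamma:.12e}",
    ]
    if w.spec is not None:
        lines.append("#spec " + json.dumps(spec_to_dict(w.spec), sort_keys=True))
    lines.append("#columns t gx gy gz")
    body = np.column_stack([w.t, w.g])
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, body, fmt=_FMT)


def read_waveform_text(path: Union[str, Path]) -> Waveform3D:
    path = Path(path)
    gamma = None
    spec = None
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(" ")
            if key == "gamma":
                gamma = float(val)
            elif key == "spec":
                spec = spec_from_dict(json.loads(val))
    data = np.loadtxt(path)
    t, g = data[:, 0], data[:, 1:4]
    if gamma is None:
        gamma = spec.gamma if spec is not None else 2.6752218744e8
    from scipy.integrate import cumulative_simpson
    q = gamma * cumulative_simpson(g, x=t, initial=0.0, axis=0)
    return Waveform3D(t=t, g=g, q=q, gamma=gamma, spec=spec)


def write_specs(path: Union[str, Path], specs: list[WaveformSpec],
                extra: Optional[dict] = None) -> None:
    """Protocol file: list of spec objects plus optional (b, Theta, Phi) lists."""
    payload: dict = {"waveforms": [spec_to_dict(s) for s in specs]}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_specs(path: Union[str, Path]) -> tuple[list[WaveformSpec], dict]:
    payload = json.loads(Path(path).read_text())
    specs = [spec_from_dict(d) for d in payload.pop("waveforms")]
    return specs, payload


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, complex):
        return {"re": x.real, "im": x.imag}
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def write_report(path: Union[str, Path], bt: Union[BTensor, dict]) -> None:
    """JSON metric report for one waveform (or an arbitrary dict)."""
    if isinstance(bt, BTensor):
        payload = {
            "b": bt.b,
            "b_delta": bt.b_delta,
            "b_eta": bt.b_eta,
            "omega_cent_Hz": bt.omega_cent_hz,
            "q_v": None if bt.q_v is None else bt.q_v.tolist(),
            "eigenvalues": bt.eigenvalues.tolist(),
        }
    else:
        payload = bt
    Path(path).write_text(json.dumps(_jsonable(payload), indent=1,
                                     sort_keys=True) + "\n")


def write_spectrum_text(path: Union[str, Path], omega: np.ndarray,
                        b_omega: np.ndarray, trace: np.ndarray) -> None:
    """Delimited spectrum export: omega_Hz, 6 independent b(w) elements, trace."""
    bw = np.real(b_omega)
    cols = np.column_stack([
        omega / (2.0 * np.pi),
        bw[:, 0, 0], bw[:, 1, 1], bw[:, 2, 2],
        bw[:, 0, 1], bw[:, 0, 2], bw[:, 1, 2],
        trace,
    ])
    header = "omega_Hz bxx byy bzz bxy bxz byz trace"
    np.savetxt(path, cols, fmt=_FMT, header=header)


def write_dataset(path: Union[str, Path], df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def read_dataset(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path)
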