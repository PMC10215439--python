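"""Fourier-series representation of pulsatile inflow waveforms.

A waveform is a truncated real Fourier series on a period ``T``:

    v(t) = a0 + sum_k a_k cos(2 pi k t / T) + b_k sin(2 pi k t / T)

Fitting is done by linear least squares on the trigonometric design matrix,
so non-uniform sample times are supported.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Waveform", "fit_waveform", "evaluate_waveform"]


@dataclass
class Waveform:
    """Truncated Fourier series with period ``period`` (s).

    ``a[k-1]``/``b[k-1]`` are the cosine/sine coefficients of harmonic k.
    ``unit`` is a physical tag only ("m/s" velocity or "L/min" flow rate).
    """

    period: float
    a0: float
    a: np.ndarray
    b: np.ndarray
    unit: str = "m/s"
    fit_rms: float | None = None

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if self.a.shape != self.b.shape:
            raise ValueError("cosine and sine coefficient arrays must match")

    @property
    def n_harmonics(self) -> int:
        return len(self.a)

    def __call__(self, t):
        return evaluate_waveform(self, t)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "period_s": self.period,
            "a0": self.a0,
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "unit": self.unit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Waveform":
        return cls(period=d["period_s"], a0=d["a0"], a=np.array(d["a"]),
                   b=np.array(d["b"]), unit=d.get("unit", "m/s"))

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load_json(cls, path) -> "Waveform":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _design_matrix(t: np.ndarray, period: float, n_harmonics: int) -> np.ndarray:
    omega = 2.0 * np.pi / period
    cols = [np.ones_like(t)]
    for k in range(1, n_harmonics + 1):
        cols.append(np.cos(k * omega * t))
        cols.append(np.sin(k * omega * t))
    return np.column_stack(cols)


def fit_waveform(times, values, n_harmonics: int, period: float | None = None,
                 unit: str = "m/s") -> Waveform:
    """Least-squares Fourier fit of ``(times, values)`` samples.

    ``period`` defaults to the sample span assuming the samples cover one
    period on ``[0, T)`` uniformly; pass it explicitly for non-uniform data.
    Requires at least ``2*n_harmonics + 1`` samples with strictly
    increasing times.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise ValueError("times and values must be 1-D arrays of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("sample times must be strictly increasing")
    if len(t) < 2 * n_harmonics + 1:
        raise ValueError(
            f"need at least {2 * n_harmonics + 1} samples for {n_harmonics} harmonics"
        )
    if period is None:
        # uniform samples on [0, T): T = span + one spacing
        dt = np.diff(t)
        period = float(t[-1] - t[0] + np.median(dt))
    design = _design_matrix(t, period, n_harmonics)
    coeffs, *_ = np.linalg.lstsq(design, v, rcond=None)
    a0 = float(coeffs[0])
    a = coeffs[1::2]
    b = coeffs[2::2]
    rms = float(np.sqrt(np.mean((design @ coeffs - v) ** 2)))
    return Waveform(period=period, a0=a0, a=a, b=b, unit=unit, fit_rms=rms)


def evaluate_waveform(w: Waveform, t):
    """Evaluate the series at time(s) ``t`` (s); exactly T-periodic."""
    tt = np.mod(np.asarray(t, dtype=float), w.period)
    omega = 2.0 * np.pi / w.period
    k = np.arange(1, w.n_harmonics + 1)
    phase = np.multiply.outer(tt, k * omega)
    out = w.a0 + np.cos(phase) @ w.a + np.sin(phase) @ w.b
    if np.isscalar(t):
        return float(out)
    return out


def read_waveform_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (time_s, value) CSV, with or without header."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("waveform CSV needs two columns: time_s, value")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def write_waveform_csv(path, times, values) -> None:
    import pandas as pd

    pd.DataFrame({"time_s": times, "value": values}).to_csv(path, index=False)
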