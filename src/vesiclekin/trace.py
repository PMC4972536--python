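"""Uniformly sampled signal traces.

A :class:`Trace` holds one channel of an electrophysiological recording:
amperometric current (pA) or whole-cell membrane capacitance (fF), sampled
at a fixed rate. Traces are read and written as plain two-column delimited
text (time in seconds, signal), the exchange format used throughout the
package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Trace", "gaussian_lowpass"]


@dataclass
class Trace:
    """A uniformly sampled signal.

    Parameters
    ----------
    samples : ndarray
        Signal values (pA for ``kind='current'``, fF for
        ``kind='capacitance'``).
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds.
    kind : str
        ``'current'`` or ``'capacitance'``.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    kind: str = "current"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.kind not in ("current", "capacitance"):
            raise ValueError(f"unknown trace kind {self.kind!r}")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def dt(self) -> float:
        """Sample interval in seconds."""
        return 1.0 / self.fs

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n) / self.fs

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (seconds)."""
        i = int(round((t - self.t0) * self.fs))
        return min(max(i, 0), self.n - 1)

    def segment(self, t_start: float, t_end: float) -> np.ndarray:
        """Samples in the half-open time window [t_start, t_end)."""
        i0 = self.index_at(t_start)
        i1 = self.index_at(t_end)
        if i1 <= i0:
            raise ValueError("empty or inverted time window")
        return self.samples[i0:i1]

    def copy_with(self, samples: np.ndarray) -> "Trace":
        return Trace(samples=np.asarray(samples, dtype=float), fs=self.fs,
                     t0=self.t0, kind=self.kind, meta=dict(self.meta))

    # -- I/O ---------------------------------------------------------------

    def save(self, path: str | Path, sidecar: dict | None = None) -> None:
        """Write as two-column delimited text (time_s, signal).

        An optional JSON sidecar (``<path>.json``) stores ground truth or
        run metadata alongside the trace.
        """
        path = Path(path)
        data = np.column_stack([self.times, self.samples])
        header = f"time_s\t{'current_pA' if self.kind == 'current' else 'cm_fF'}"
        np.savetxt(path, data, delimiter="\t", header=header, comments="# ")
        if sidecar is not None:
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(sidecar, indent=2, default=_jsonify))

    @classmethod
    def load(cls, path: str | Path, kind: str | None = None) -> "Trace":
        """Read a two-column delimited trace; sampling rate is inferred."""
        path = Path(path)
        data = np.loadtxt(path, delimiter=None)
        if data.ndim != 2 or data.shape[1] < 2:
            raise ValueError(f"{path} is not a two-column time-series file")
        t, x = data[:, 0], data[:, 1]
        dts = np.diff(t)
        if dts.size == 0:
            raise ValueError("trace must have at least two samples")
        dt = float(np.median(dts))
        if not np.allclose(dts, dt, rtol=1e-3, atol=1e-9):
            raise ValueError("trace is not uniformly sampled")
        if kind is None:
            header = path.read_text().splitlines()[0] if path.exists() else ""
            kind = "capacitance" if "fF" in header or "cm" in header.lower() \
                else "current"
        return cls(samples=x, fs=1.0 / dt, t0=float(t[0]), kind=kind)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def gaussian_lowpass(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    """Zero-phase Gaussian low-pass filter specified by its -3 dB cutoff.

    The Gaussian kernel introduces no phase distortion (symmetric impulse
    response), which keeps rise times and derivative timing unbiased. The
    kernel sigma is chosen so the amplitude response is 1/sqrt(2) at
    ``cutoff``: sigma_t = sqrt(ln 2)/(2 pi f_c).
    """
    from scipy.ndimage import gaussian_filter1d

    if cutoff >= fs / 2:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below the Nyquist rate {fs / 2} Hz")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sigma_samples = np.sqrt(np.log(2.0)) / (2.0 * np.pi * cutoff) * fs
    return gaussian_filter1d(np.asarray(x, dtype=float), sigma_samples,
                             mode="nearest")
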