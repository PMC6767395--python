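"""Small interpolation helpers shared by the generators."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PhaseInterp:
    """Linear interpolation of an unwrapped phase sampled on a uniform grid."""

    t0: float
    fs: float
    unwrapped_rad: np.ndarray

    def at(self, t: np.ndarray) -> np.ndarray:
        """Unwrapped phase (rad) at arbitrary times, clipped to the grid span."""
        idx = (np.asarray(t, dtype=float) - self.t0) * self.fs
        idx = np.clip(idx, 0.0, len(self.unwrapped_rad) - 1.0)
        lo = np.floor(idx).astype(int)
        hi = np.minimum(lo + 1, len(self.unwrapped_rad) - 1)
        frac = idx - lo
        return (1.0 - frac) * self.unwrapped_rad[lo] + frac * self.unwrapped_rad[hi]

    def deg_at(self, t: np.ndarray) -> np.ndarray:
        return np.degrees(self.at(t)) % 360.0


@dataclass
class StepSeries:
    """Piecewise-constant series on half-open windows [edges[i], edges[i+1])."""

    edges: np.ndarray  # (n+1,)
    values: np.ndarray  # (n,) or (n, k)

    def at(self, t: np.ndarray) -> np.ndarray:
        i = np.searchsorted(self.edges, np.asarray(t), side="right") - 1
        i = np.clip(i, 0, len(self.values) - 1)
        return self.values[i]


def ar1_series(n: int, sd: float, tau_s: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary OU (AR(1)) noise with SD ``sd`` and time constant ``tau_s``."""
    from scipy.signal import lfilter

    a = np.exp(-1.0 / (tau_s * fs))
    kick = sd * np.sqrt(1.0 - a * a)
    w = kick * rng.standard_normal(n)
    w[0] = rng.normal(0.0, sd)  # start from the stationary distribution
    return lfilter([1.0], [1.0, -a], w)


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = 1.0 / np.sqrt(f[nz])
    spec *= scale
    x = np.fft.irfft(spec, n)
    return x / x.std()


def intervals_to_mask(intervals: np.ndarray, n: int, fs: float, t0: float = 0.0) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for s, e in np.atleast_2d(np.asarray(intervals, dtype=float)):
        i0 = max(0, int(np.ceil((s - t0) * fs)))
        i1 = min(n, int(np.floor((e - t0) * fs)) + 1)
        if i1 > i0:
            mask[i0:i1] = True
    return mask
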