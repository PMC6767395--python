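"""Bayesian position reconstruction from place-cell population vectors.

Posterior over spatial bins x given the spike-count vector n of one
250 ms window:

    P(x | n) = P(n | x) P(x) / P(n)

with a uniform prior P(x) over visited bins and independent-Poisson
likelihood P(n | x) = prod_c Poisson(n_c; lambda_c(x) * tau).  Windows
slide by 125 ms, windows without spikes are skipped, and the decoded
position is the centre of the maximum-posterior bin; the error is the
Euclidean distance to the animal's true position at the window centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .behavior import sample_speed
from .placemaps import RateMap
from .session import TRACKING_DT

RATE_FLOOR_HZ = 0.01  # regularisation so log(lambda) is finite everywhere


def poisson_log_posterior(
    counts: np.ndarray, rates: np.ndarray, tau: float
) -> tuple[np.ndarray, np.ndarray]:
    """Log posterior over bins for each count vector, plus log P(n).

    ``counts`` is (n_windows, n_cells); ``rates`` (n_cells, n_bins) in Hz.
    The prior is uniform over bins.  Returns (log_post (n_windows, n_bins),
    log_evidence (n_windows,)); the log n! term is retained so the
    evidence is the true marginal likelihood.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    lam_tau = np.asarray(rates, dtype=float) * tau
    log_like = counts @ np.log(lam_tau) - lam_tau.sum(axis=0)
    log_like -= gammaln(counts + 1.0).sum(axis=1, keepdims=True)
    log_prior = -np.log(lam_tau.shape[1])
    log_joint = log_like + log_prior
    log_evidence = logsumexp(log_joint, axis=1)
    return log_joint - log_evidence[:, None], log_evidence


@dataclass
class DecodeResult:
    """Per-window decodes plus (optionally) the full posteriors."""

    windows: pd.DataFrame  # t, x_true, y_true, x_dec, y_dec, error_cm
    bin_xy: np.ndarray  # (n_bins_used, 2) centres of the visited bins
    posteriors: np.ndarray | None = None  # (n_windows, n_bins_used)

    @property
    def errors_cm(self) -> np.ndarray:
        return self.windows["error_cm"].to_numpy()


def decode(
    tracking: pd.DataFrame,
    spikes_by_cell: list[np.ndarray],
    rate_maps: list[RateMap],
    *,
    epoch: tuple[float, float],
    window_s: float = 0.25,
    step_s: float = 0.125,
    rate_floor_hz: float = RATE_FLOOR_HZ,
    speed_floor_cm_s: float | None = 5.0,
    keep_posteriors: bool = False,
    dt: float = TRACKING_DT,
) -> DecodeResult:
    """Decode position in sliding windows across an exploration epoch.

    All rate maps must share the grid of the first map; decoding runs over
    its visited bins.  ``speed_floor_cm_s`` restricts windows to running
    periods (the same 5 cm/s filter as the maps); pass None to disable.
    Ties in the posterior argmax break to the smallest row-major bin index.
    """
    if len(rate_maps) == 0:
        raise ValueError("need at least one place cell with a rate map")
    base = rate_maps[0]
    visited = base.visited
    centers = base.bin_centers
    xc, yc = np.meshgrid(centers, centers, indexing="ij")
    bin_xy = np.c_[xc[visited], yc[visited]]
    rates = np.stack([np.maximum(m.smoothed_rate[visited], rate_floor_hz) for m in rate_maps])

    sel = (tracking["t"] >= epoch[0]) & (tracking["t"] < epoch[1])
    tracking = tracking.loc[sel]
    t = tracking["t"].to_numpy()
    speeds = sample_speed(tracking, dt)

    t_starts = np.arange(epoch[0], epoch[1] - window_s + 1e-9, step_s)
    t_centers = t_starts + window_s / 2.0
    ok = (t_centers >= t[0]) & (t_centers <= t[-1])
    if speed_floor_cm_s is not None:
        v = np.interp(t_centers, t, speeds)
        ok &= v >= speed_floor_cm_s
    t_starts, t_centers = t_starts[ok], t_centers[ok]

    counts = np.stack(
        [
            np.searchsorted(np.sort(st), t_starts + window_s) - np.searchsorted(np.sort(st), t_starts)
            for st in spikes_by_cell
        ],
        axis=1,
    ).astype(float)
    has_spike = counts.sum(axis=1) > 0
    counts, t_centers = counts[has_spike], t_centers[has_spike]

    log_post, _ = poisson_log_posterior(counts, rates, window_s)
    best = np.argmax(log_post, axis=1)  # first occurrence = smallest index
    x_dec, y_dec = bin_xy[best, 0], bin_xy[best, 1]
    x_true = np.interp(t_centers, t, tracking["x"].to_numpy())
    y_true = np.interp(t_centers, t, tracking["y"].to_numpy())
    err = np.hypot(x_dec - x_true, y_dec - y_true)
    windows = pd.DataFrame(
        {
            "t": t_centers,
            "x_true": x_true,
            "y_true": y_true,
            "x_dec": x_dec,
            "y_dec": y_dec,
            "error_cm": err,
        }
    )
    post = np.exp(log_post) if keep_posteriors else None
    return DecodeResult(windows=windows, bin_xy=bin_xy, posteriors=post)


def decoding_error_summary(result: DecodeResult) -> dict:
    err = result.errors_cm
    if err.size == 0:
        raise ValueError("no decoded windows")
    return {
        "median_error_cm": float(np.median(err)),
        "mean_error_cm": float(err.mean()),
        "n_windows": int(err.size),
    }
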