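"""Noise correlations, speed-compensated partial correlations, stability.

The noise correlation of a cell pair removes spatial (signal) correlation
by correlating instantaneous firing-rate counts (IFRCs) only *within*
spatial bins of a 20 x 20 grid and averaging the per-bin coefficients.
The speed-compensated variant partials the window's running speed out of
each within-bin correlation:

    r_xy.v = (r_xy - r_xv r_yv) / sqrt((1 - r_xv^2)(1 - r_yv^2))
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr

from .behavior import sample_speed
from .session import TRACKING_DT, Arena


@dataclass
class CofiringMatrix:
    """Pairwise cofiring coefficients (upper-triangle pairs only)."""

    pairs: pd.DataFrame  # columns: i, j, r, n
    variant: str
    params: dict = field(default_factory=dict)

    def mean_r(self) -> float:
        return float(self.pairs["r"].mean())

    def common_pairs(self, other: "CofiringMatrix") -> pd.DataFrame:
        return self.pairs.merge(other.pairs, on=["i", "j"], suffixes=("_1", "_2"))


def _window_counts(
    tracking: pd.DataFrame,
    spikes_by_cell: list[np.ndarray],
    epoch: tuple[float, float],
    window_s: float,
    dt: float,
):
    t = tracking["t"].to_numpy()
    n_win = int((epoch[1] - epoch[0]) / window_s)
    edges = epoch[0] + np.arange(n_win + 1) * window_s
    centers = edges[:-1] + window_s / 2.0
    ok = (centers >= t[0]) & (centers <= t[-1])
    counts = np.stack(
        [np.diff(np.searchsorted(np.sort(st), edges)) for st in spikes_by_cell], axis=1
    ).astype(float)
    speeds = sample_speed(tracking, dt)
    wx = np.interp(centers, t, tracking["x"].to_numpy())
    wy = np.interp(centers, t, tracking["y"].to_numpy())
    wv = np.interp(centers, t, speeds)
    return counts[ok], wx[ok], wy[ok], wv[ok]


def noise_correlation(
    tracking: pd.DataFrame,
    spikes_by_cell: list[np.ndarray],
    arena: Arena | None = None,
    *,
    epoch: tuple[float, float],
    window_s: float = 0.25,
    n_spatial_bins: int = 20,
    min_windows_per_bin: int = 5,
    min_bins_per_pair: int = 3,
    speed_compensated: bool = False,
    dt: float = TRACKING_DT,
) -> CofiringMatrix:
    """Pairwise noise correlation of IFRCs, averaged over 20 x 20 bins.

    Windows are assigned to the spatial bin containing the window-centre
    position; bins with fewer than 5 windows are skipped, and pairs with
    fewer than 3 contributing bins are excluded.  With
    ``speed_compensated=True`` each within-bin coefficient is the partial
    correlation given the window's running speed.
    """
    arena = arena or Arena()
    n_cells = len(spikes_by_cell)
    if n_cells < 2:
        raise ValueError("need at least two cells")
    counts, wx, wy, wv = _window_counts(tracking, spikes_by_cell, epoch, window_s, dt)
    r_ar = arena.radius_cm
    edges = np.linspace(-r_ar, r_ar, n_spatial_bins + 1)
    bx = np.clip(np.searchsorted(edges, wx, side="right") - 1, 0, n_spatial_bins - 1)
    by = np.clip(np.searchsorted(edges, wy, side="right") - 1, 0, n_spatial_bins - 1)
    bin_id = bx * n_spatial_bins + by

    r_sum = np.zeros((n_cells, n_cells))
    r_cnt = np.zeros((n_cells, n_cells), dtype=int)
    for b in np.unique(bin_id):
        sel = bin_id == b
        if sel.sum() < min_windows_per_bin:
            continue
        c = counts[sel]
        sd = c.std(axis=0)
        active = sd > 0
        if active.sum() < 2:
            continue
        if speed_compensated:
            v = wv[sel]
            if v.std() == 0:
                continue
            full = np.corrcoef(np.c_[c[:, active], v].T)
            k = active.sum()
            r_cc = full[:k, :k]
            r_cv = full[:k, k]
            denom = np.sqrt(np.outer(1 - r_cv**2, 1 - r_cv**2))
            with np.errstate(divide="ignore", invalid="ignore"):
                r_bin = (r_cc - np.outer(r_cv, r_cv)) / denom
            r_bin[~np.isfinite(r_bin)] = np.nan
        else:
            r_bin = np.corrcoef(c[:, active].T)
        idx = np.flatnonzero(active)
        for a_pos, a in enumerate(idx):
            for b_pos, bb in enumerate(idx):
                if bb <= a:
                    continue
                val = r_bin[a_pos, b_pos]
                if np.isfinite(val):
                    r_sum[a, bb] += val
                    r_cnt[a, bb] += 1

    rows = []
    for i, j in combinations(range(n_cells), 2):
        if r_cnt[i, j] >= min_bins_per_pair:
            rows.append({"i": i, "j": j, "r": r_sum[i, j] / r_cnt[i, j], "n": r_cnt[i, j]})
    variant = "speed_compensated" if speed_compensated else "noise"
    return CofiringMatrix(
        pairs=pd.DataFrame(rows, columns=["i", "j", "r", "n"]),
        variant=variant,
        params={"window_s": window_s, "n_spatial_bins": n_spatial_bins},
    )


def speed_compensated_noise_correlation(*args, **kwargs) -> CofiringMatrix:
    """Noise correlation with the window speed partialled out per bin."""
    return noise_correlation(*args, speed_compensated=True, **kwargs)


def partial_correlation(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """First-order partial correlation r_xy.z."""
    r_xy = pearsonr(x, y).statistic
    r_xz = pearsonr(x, z).statistic
    r_yz = pearsonr(y, z).statistic
    denom = np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    if denom == 0:
        return float("nan")
    return float((r_xy - r_xz * r_yz) / denom)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sample Z-test on Fisher-transformed Pearson coefficients."""
    if min(n1, n2) < 4:
        raise ValueError("need at least 4 samples per correlation")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    z = (z1 - z2) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)


def stability_correlation(
    half1: CofiringMatrix, half2: CofiringMatrix, *, min_pairs: int = 10
) -> dict:
    """Pearson r between per-pair cofiring of two session halves."""
    merged = half1.common_pairs(half2)
    if len(merged) < min_pairs:
        raise ValueError("fewer than 10 pairs common to both halves")
    res = pearsonr(merged["r_1"], merged["r_2"])
    return {"r": float(res.statistic), "n_pairs": int(len(merged)), "p": float(res.pvalue)}
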