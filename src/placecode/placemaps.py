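"""Rate maps and place-coding statistics.

Maps are 70 x 70 occupancy-normalised firing grids over the arena's
bounding square, speed-filtered at 5 cm/s and smoothed with a mask-aware
2-bin Gaussian.  On top of them: Skaggs spatial information (bits/spike),
field-size fraction, spatial coherence, sparsity (the place-cell selection
criteria are coherence > 0.5 and sparsity < 0.3), a rate remapping score,
the per-pass index of dispersion and the 500 ms speed-rate correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import convolve, gaussian_filter
from scipy.stats import pearsonr

from .behavior import sample_speed
from .session import TRACKING_DT, Arena

COHERENCE_CRITERION = 0.5
SPARSITY_CRITERION = 0.3


@dataclass
class RateMap:
    """Occupancy-normalised firing map (raw and smoothed) for one cell."""

    raw_rate: np.ndarray  # (n, n) Hz, NaN off the visited mask
    smoothed_rate: np.ndarray
    occupancy_s: np.ndarray
    visited: np.ndarray  # bool mask
    bin_edges: np.ndarray  # (n+1,) cm, shared by both axes

    @property
    def n_bins(self) -> int:
        return self.raw_rate.shape[0]

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def occupancy_share(self) -> np.ndarray:
        """p_i over visited bins (sums to 1)."""
        p = np.where(self.visited, self.occupancy_s, 0.0)
        return p / p.sum()

    def rate(self, smoothed: bool = True) -> np.ndarray:
        return self.smoothed_rate if smoothed else self.raw_rate

    def mean_rate(self, smoothed: bool = True) -> float:
        p = self.occupancy_share()
        lam = np.where(self.visited, self.rate(smoothed), 0.0)
        return float((p * lam).sum())


def _masked_smooth(rate: np.ndarray, visited: np.ndarray, sigma_bins: float) -> np.ndarray:
    filled = np.where(visited, rate, 0.0)
    num = gaussian_filter(filled, sigma_bins, mode="constant")
    den = gaussian_filter(visited.astype(float), sigma_bins, mode="constant")
    out = np.full_like(rate, np.nan)
    ok = visited & (den > 0)
    out[ok] = num[ok] / den[ok]
    return out


def build_rate_map(
    tracking: pd.DataFrame,
    spike_times: np.ndarray,
    arena: Arena | None = None,
    *,
    epoch: tuple[float, float] | None = None,
    n_bins: int = 70,
    speed_floor_cm_s: float = 5.0,
    smooth_sigma_bins: float = 2.0,
    dt: float = TRACKING_DT,
) -> RateMap:
    """Build a cell's rate map over an exploration epoch.

    Tracking samples (and spikes, positioned by linear interpolation at
    their times) slower than the 5 cm/s floor are excluded before binning.
    """
    arena = arena or Arena()
    if epoch is not None:
        sel = (tracking["t"] >= epoch[0]) & (tracking["t"] < epoch[1])
        tracking = tracking.loc[sel]
        spike_times = np.asarray(spike_times)
        spike_times = spike_times[(spike_times >= epoch[0]) & (spike_times < epoch[1])]
    t = tracking["t"].to_numpy()
    x = tracking["x"].to_numpy()
    y = tracking["y"].to_numpy()
    speeds = sample_speed(tracking, dt)
    fast = speeds >= speed_floor_cm_s
    if not fast.any():
        raise ValueError("no qualifying samples after the speed filter")

    r = arena.radius_cm
    edges = np.linspace(-r, r, n_bins + 1)
    occ, _, _ = np.histogram2d(x[fast], y[fast], bins=(edges, edges))
    occ *= dt
    visited = occ > 0

    sx = np.interp(spike_times, t, x)
    sy = np.interp(spike_times, t, y)
    s_speed = np.interp(spike_times, t, speeds)
    keep = s_speed >= speed_floor_cm_s
    spk, _, _ = np.histogram2d(sx[keep], sy[keep], bins=(edges, edges))

    raw = np.full_like(occ, np.nan)
    raw[visited] = spk[visited] / occ[visited]
    smoothed = _masked_smooth(raw, visited, smooth_sigma_bins)
    return RateMap(
        raw_rate=raw, smoothed_rate=smoothed, occupancy_s=occ, visited=visited, bin_edges=edges
    )


# ---------------------------------------------------------------------------
# scalar statistics
# ---------------------------------------------------------------------------

def skaggs_information(rate_map: RateMap, smoothed: bool = True) -> float:
    """Spatial information in bits/spike: sum_i p_i (l_i/L) log2(l_i/L)."""
    p = rate_map.occupancy_share()[rate_map.visited]
    lam = rate_map.rate(smoothed)[rate_map.visited]
    mean = float((p * lam).sum())
    if mean <= 0:
        return float("nan")
    ratio = lam / mean
    nz = ratio > 0
    return float((p[nz] * ratio[nz] * np.log2(ratio[nz])).sum())


def field_size_fraction(rate_map: RateMap, threshold: float = 0.1, smoothed: bool = True) -> float:
    """Fraction of visited bins with rate above ``threshold`` times the peak."""
    lam = rate_map.rate(smoothed)[rate_map.visited]
    peak = np.nanmax(lam)
    if peak <= 0:
        return float("nan")
    return float(np.mean(lam > threshold * peak))


def coherence(rate_map: RateMap) -> float:
    """Correlation of each visited bin's raw rate with its 8-neighbour mean."""
    visited = rate_map.visited
    if visited.sum() < 9:
        raise ValueError("need at least 9 visited bins")
    raw = np.where(visited, rate_map.raw_rate, 0.0)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    nsum = convolve(raw, kernel, mode="constant")
    ncnt = convolve(visited.astype(float), kernel, mode="constant")
    sel = visited & (ncnt > 0)
    a = raw[sel]
    b = nsum[sel] / ncnt[sel]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(pearsonr(a, b).statistic)


def sparsity(rate_map: RateMap, smoothed: bool = True) -> float:
    """(sum p_i l_i)^2 / sum p_i l_i^2 over visited bins, in (0, 1]."""
    p = rate_map.occupancy_share()[rate_map.visited]
    lam = rate_map.rate(smoothed)[rate_map.visited]
    denom = float((p * lam**2).sum())
    if denom <= 0:
        return float("nan")
    return float((p * lam).sum() ** 2 / denom)


def is_place_cell(rate_map: RateMap) -> bool:
    """Place-cell selection: coherence > 0.5 and sparsity < 0.3."""
    c = coherence(rate_map)
    s = sparsity(rate_map)
    return bool(np.isfinite(c) and np.isfinite(s) and c > COHERENCE_CRITERION and s < SPARSITY_CRITERION)


@dataclass
class PlaceCellStats:
    spatial_info_bits_per_spike: float
    field_size_fraction: float
    coherence: float
    sparsity: float
    peak_rate_hz: float
    is_place_cell: bool


def place_cell_stats(rate_map: RateMap) -> PlaceCellStats:
    c = coherence(rate_map)
    s = sparsity(rate_map)
    ok = bool(np.isfinite(c) and np.isfinite(s) and c > COHERENCE_CRITERION and s < SPARSITY_CRITERION)
    return PlaceCellStats(
        spatial_info_bits_per_spike=skaggs_information(rate_map),
        field_size_fraction=field_size_fraction(rate_map),
        coherence=c,
        sparsity=s,
        peak_rate_hz=float(np.nanmax(rate_map.smoothed_rate)),
        is_place_cell=ok,
    )


def remapping_score(fr_c1: float, fr_c2: float) -> float:
    """|FR_C1 - FR_C2| / (FR_C1 + FR_C2); NaN when both rates are zero."""
    if fr_c1 < 0 or fr_c2 < 0:
        raise ValueError("rates must be non-negative")
    total = fr_c1 + fr_c2
    if total == 0:
        return float("nan")
    return abs(fr_c1 - fr_c2) / total


# ---------------------------------------------------------------------------
# pass-based dispersion and speed-rate coupling
# ---------------------------------------------------------------------------

def field_passes(
    tracking: pd.DataFrame,
    rate_map: RateMap,
    level: float,
    *,
    min_samples: int = 2,
    dt: float = TRACKING_DT,
) -> np.ndarray:
    """(start, end) intervals of passes through the field at one threshold.

    The field is the smoothed-map region above ``level`` times the peak; a
    pass is a maximal run of at least two consecutive in-field samples.
    """
    lam = rate_map.smoothed_rate
    peak = np.nanmax(lam)
    mask = np.where(np.isnan(lam), False, lam > level * peak)
    edges = rate_map.bin_edges
    ix = np.clip(np.searchsorted(edges, tracking["x"].to_numpy(), side="right") - 1, 0, rate_map.n_bins - 1)
    iy = np.clip(np.searchsorted(edges, tracking["y"].to_numpy(), side="right") - 1, 0, rate_map.n_bins - 1)
    in_field = mask[ix, iy]
    t = tracking["t"].to_numpy()
    # passes must be contiguous in time (no tracking gaps > 1.5 samples)
    contiguous = np.r_[True, np.diff(t) < 1.5 * dt]
    d = np.diff(np.r_[0, in_field.astype(np.int8), 0])
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    out = [
        (t[a], t[b - 1] + dt)
        for a, b in zip(starts, ends)
        if b - a >= min_samples and np.all(contiguous[a + 1 : b])
    ]
    return np.array(out) if out else np.empty((0, 2))


def index_of_dispersion(
    tracking: pd.DataFrame,
    spike_times: np.ndarray,
    rate_map: RateMap,
    levels: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    *,
    min_passes: int = 10,
) -> pd.DataFrame:
    """Variance/mean of per-pass spike counts, per field-threshold level."""
    spike_times = np.sort(np.asarray(spike_times))
    rows = []
    for level in levels:
        passes = field_passes(tracking, rate_map, level)
        n = len(passes)
        if n < min_passes:
            rows.append({"level": level, "dispersion": np.nan, "n_passes": n, "sufficient": False})
            continue
        counts = np.searchsorted(spike_times, passes[:, 1]) - np.searchsorted(spike_times, passes[:, 0])
        mean = counts.mean()
        disp = counts.var(ddof=1) / mean if mean > 0 else np.nan
        rows.append({"level": level, "dispersion": disp, "n_passes": n, "sufficient": True})
    return pd.DataFrame(rows)


def speed_rate_correlation(
    tracking: pd.DataFrame,
    spikes_by_cell: list[np.ndarray],
    *,
    epoch: tuple[float, float] | None = None,
    window_s: float = 0.5,
    min_windows: int = 20,
    dt: float = TRACKING_DT,
) -> np.ndarray:
    """Per-cell Pearson r between z-scored 500 ms spike counts and speed."""
    if epoch is not None:
        sel = (tracking["t"] >= epoch[0]) & (tracking["t"] < epoch[1])
        tracking = tracking.loc[sel]
    t = tracking["t"].to_numpy()
    speeds = sample_speed(tracking, dt)
    t0, t1 = t[0], t[-1]
    n_win = int((t1 - t0) / window_s)
    if n_win < min_windows:
        raise ValueError("too few windows for a speed-rate correlation")
    edges = t0 + np.arange(n_win + 1) * window_s
    win_speed = np.array(
        [speeds[(t >= a) & (t < b)].mean() for a, b in zip(edges[:-1], edges[1:])]
    )
    out = np.full(len(spikes_by_cell), np.nan)
    for c, st in enumerate(spikes_by_cell):
        st = np.sort(np.asarray(st))
        counts = np.diff(np.searchsorted(st, edges)).astype(float)
        if counts.std() == 0 or np.nanstd(win_speed) == 0:
            continue
        z = (counts - counts.mean()) / counts.std()
        out[c] = pearsonr(z, win_speed).statistic
    return out
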