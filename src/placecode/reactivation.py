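"""Peri-SWR firing and exploration-to-sleep reactivation.

Reactivation is quantified by cofiring similarity: spike counts in 100 ms
windows give each cell pair a cofiring coefficient separately during
waking theta periods and during sleep/rest SWRs; the Pearson correlation
of the two pairwise patterns is the reactivation strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .correlations import CofiringMatrix, fisher_z_compare


@dataclass
class PeriEventRate:
    """Mean firing rate around event centres, per relative-time bin."""

    time_s: np.ndarray  # bin centres relative to the SWR centre
    rate_hz: np.ndarray  # mean rate per cell
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_events: int
    n_cells: int

    def peak_rate(self, half_width_s: float = 0.025) -> float:
        sel = np.abs(self.time_s) <= half_width_s
        return float(self.rate_hz[sel].mean())

    def baseline_rate(self, from_s: float = 0.15) -> float:
        sel = np.abs(self.time_s) >= from_s
        return float(self.rate_hz[sel].mean())


def peri_swr_rates(
    units,
    event_centers: np.ndarray,
    *,
    cell_class: str | None = None,
    window_s: float = 0.25,
    bin_s: float = 0.01,
    n_boot: int = 200,
    seed: int | np.random.Generator | None = 0,
) -> PeriEventRate:
    """Event-aligned population firing rate with a bootstrap band.

    Counts spikes of all units of ``cell_class`` in 10 ms bins within
    +/- 250 ms of each event centre, averages over events and divides by
    bin width and cell count; the confidence band bootstraps over events.
    """
    centers = np.sort(np.asarray(event_centers, dtype=float))
    if centers.size < 10:
        raise ValueError("need at least 10 SWR events")
    if cell_class is not None:
        units = [u for u in units if u.cell_class == cell_class]
    if not units:
        raise ValueError("no units of the requested class")
    n_bins = int(round(2 * window_s / bin_s))
    edges = -window_s + np.arange(n_bins + 1) * bin_s
    per_event = np.zeros((centers.size, n_bins))
    for u in units:
        st = u.spike_times
        i0 = np.searchsorted(st, centers - window_s)
        i1 = np.searchsorted(st, centers + window_s)
        for e, (a, b) in enumerate(zip(i0, i1)):
            if b > a:
                per_event[e] += np.histogram(st[a:b] - centers[e], bins=edges)[0]
    denom = bin_s * len(units)
    rate = per_event.mean(axis=0) / denom
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, n_bins))
    for k in range(n_boot):
        pick = rng.integers(0, centers.size, centers.size)
        boots[k] = per_event[pick].mean(axis=0) / denom
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    return PeriEventRate(
        time_s=edges[:-1] + bin_s / 2.0,
        rate_hz=rate,
        ci_lower=lo,
        ci_upper=hi,
        n_events=int(centers.size),
        n_cells=len(units),
    )


def _tile_windows(intervals: np.ndarray, window_s: float) -> np.ndarray:
    """(start, end) of 100 ms windows tiling each interval.

    Intervals shorter than one window contribute a single window centred on
    the interval (SWR events are often briefer than 100 ms).
    """
    out = []
    for s, e in np.atleast_2d(np.asarray(intervals, dtype=float)):
        dur = e - s
        if dur <= 0:
            continue
        if dur < window_s:
            mid = (s + e) / 2.0
            out.append((mid - window_s / 2.0, mid + window_s / 2.0))
            continue
        n = int(dur / window_s)
        for k in range(n):
            out.append((s + k * window_s, s + (k + 1) * window_s))
    return np.array(out) if out else np.empty((0, 2))


def cofiring(
    spikes_by_cell: list[np.ndarray],
    intervals: np.ndarray,
    *,
    window_s: float = 0.1,
    min_spikes: int = 10,
) -> CofiringMatrix:
    """Pairwise Pearson correlation of 100 ms counts within the intervals.

    Cells with zero count variance or fewer than ``min_spikes`` in-window
    spikes are excluded (their pairs are dropped).
    """
    wins = _tile_windows(intervals, window_s)
    if wins.size == 0:
        raise ValueError("no intervals to tile")
    counts = np.stack(
        [
            np.searchsorted(np.sort(st), wins[:, 1]) - np.searchsorted(np.sort(st), wins[:, 0])
            for st in spikes_by_cell
        ],
        axis=1,
    ).astype(float)
    ok = (counts.std(axis=0) > 0) & (counts.sum(axis=0) >= min_spikes)
    rows = []
    for i, j in combinations(np.flatnonzero(ok), 2):
        r = pearsonr(counts[:, i], counts[:, j]).statistic
        rows.append({"i": int(i), "j": int(j), "r": float(r), "n": len(wins)})
    return CofiringMatrix(
        pairs=pd.DataFrame(rows, columns=["i", "j", "r", "n"]),
        variant="cofire",
        params={"window_s": window_s, "n_windows": int(len(wins))},
    )


@dataclass
class ReactivationResult:
    reactivation_r: float
    p: float
    n_pairs: int
    pairs: pd.DataFrame = field(repr=False, default=None)


def reactivation_strength(
    waking_cofire: CofiringMatrix, swr_cofire: CofiringMatrix, *, min_pairs: int = 10
) -> ReactivationResult:
    """Correlation across pairs of waking vs SWR cofiring coefficients."""
    merged = waking_cofire.common_pairs(swr_cofire)
    if len(merged) < min_pairs:
        raise ValueError("fewer than 10 pairs common to both conditions")
    res = pearsonr(merged["r_1"], merged["r_2"])
    return ReactivationResult(
        reactivation_r=float(res.statistic),
        p=float(res.pvalue),
        n_pairs=int(len(merged)),
        pairs=merged,
    )


def compare_reactivation(a: ReactivationResult, b: ReactivationResult) -> tuple[float, float]:
    """Fisher-z comparison of two groups' reactivation strengths."""
    return fisher_z_compare(a.reactivation_r, a.n_pairs, b.reactivation_r, b.n_pairs)
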