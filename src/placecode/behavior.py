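"""Movement-speed, immobility and arena-coverage statistics from tracking.

Speed follows the 25.6 ms / 256 ms windowing convention: the distance
travelled between consecutive 25.6 ms tracking samples is averaged over ten
consecutive steps (zeros excluded, to suppress tracking dropouts) and
converted to cm/s; one speed value is produced per 256 ms window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session import TRACKING_DT, Arena


@dataclass
class BehaviorSummary:
    mean_speed_cm_s: float
    immobility_fraction: float
    uncovered_fraction: float


def step_distances(tracking: pd.DataFrame) -> np.ndarray:
    x = tracking["x"].to_numpy()
    y = tracking["y"].to_numpy()
    return np.hypot(np.diff(x), np.diff(y))


def windowed_speed(tracking: pd.DataFrame, dt: float = TRACKING_DT) -> pd.DataFrame:
    """Per-256 ms speed: mean of 10 consecutive step distances, zeros excluded.

    A window whose ten distances are all zero scores 0 cm/s.  Windows are
    non-overlapping and aligned to the first tracking sample.
    """
    if len(tracking) < 11:
        raise ValueError("need at least 11 tracking samples")
    d = step_distances(tracking)
    n_win = len(d) // 10
    d = d[: n_win * 10].reshape(n_win, 10)
    nonzero = d > 0
    cnt = nonzero.sum(axis=1)
    mean_d = np.zeros(n_win)
    has = cnt > 0
    mean_d[has] = d.sum(axis=1)[has] / cnt[has]
    speed = mean_d / dt
    t = tracking["t"].to_numpy()
    centers = t[0] + (np.arange(n_win) + 0.5) * 10 * dt
    return pd.DataFrame({"t": centers, "speed": speed})


def mean_session_speed(tracking: pd.DataFrame, dt: float = TRACKING_DT) -> float:
    return float(windowed_speed(tracking, dt)["speed"].mean())


def sample_speed(tracking: pd.DataFrame, dt: float = TRACKING_DT) -> np.ndarray:
    """Speed assigned to every tracking sample (its 256 ms window's value).

    Trailing samples beyond the last full window inherit the last value.
    Used for the 5 cm/s speed filter of rate maps and decoding.
    """
    ws = windowed_speed(tracking, dt)["speed"].to_numpy()
    idx = np.minimum(np.arange(len(tracking)) // 10, len(ws) - 1)
    return ws[idx]


def immobility_fraction(
    tracking: pd.DataFrame, dt: float = TRACKING_DT, threshold_cm: float = 2.0
) -> float:
    """Fraction of non-overlapping 1 s windows travelling < 2 cm."""
    d = step_distances(tracking)
    per_win = int(round(1.0 / dt))
    n_win = len(d) // per_win
    if n_win < 1:
        raise ValueError("need at least 1 s of tracking")
    travelled = d[: n_win * per_win].reshape(n_win, per_win).sum(axis=1)
    return float(np.mean(travelled < threshold_cm))


def coverage_deficit(
    tracking: pd.DataFrame,
    arena: Arena | None = None,
    bin_cm: float = 5.0,
    max_empty_neighbors: int = 5,
) -> float:
    """Unvisited fraction of the arena from 5 cm binned tracking.

    Empty bins are split into in-arena (unvisited) versus outside-arena by a
    neighbourhood rule: an empty bin with fewer than ``max_empty_neighbors``
    empty 8-neighbours is declared an unvisited area *within* the arena.
    Bins beyond the grid edge count as empty neighbours.
    """
    arena = arena or Arena()
    r = arena.radius_cm
    n_bins = int(np.ceil(arena.diameter_cm / bin_cm))
    edges = np.linspace(-r, r, n_bins + 1)
    occ, _, _ = np.histogram2d(
        tracking["x"].to_numpy(), tracking["y"].to_numpy(), bins=(edges, edges)
    )
    visited = occ > 0
    empty = ~visited
    # count empty 8-neighbours, with out-of-grid padding treated as empty
    pad = np.pad(empty, 1, constant_values=True)
    n_empty = np.zeros_like(occ)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            n_empty += pad[1 + di : 1 + di + n_bins, 1 + dj : 1 + dj + n_bins]
    unvisited_in_arena = empty & (n_empty < max_empty_neighbors)
    n_in_arena = visited.sum() + unvisited_in_arena.sum()
    if n_in_arena == 0:
        return 1.0
    return float(unvisited_in_arena.sum() / n_in_arena)


def behavior_summary(tracking: pd.DataFrame, arena: Arena | None = None) -> BehaviorSummary:
    return BehaviorSummary(
        mean_speed_cm_s=mean_session_speed(tracking),
        immobility_fraction=immobility_fraction(tracking),
        uncovered_fraction=coverage_deficit(tracking, arena),
    )
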