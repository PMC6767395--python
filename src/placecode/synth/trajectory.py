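"""Open-field foraging trajectories.

An Ornstein-Uhlenbeck velocity random walk, integrated on the 25.6 ms
tracking clock and reflected at the circular arena wall, gives smooth
foraging paths whose speed distribution matches a freely moving rat well
enough for the downstream behavioural and place-map statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..session import TRACKING_DT, Arena

# mean of a 2-D isotropic Gaussian speed with per-component SD s is s*sqrt(pi/2)
_SPEED_OF_SD = np.sqrt(np.pi / 2.0)


def generate_trajectory(
    duration_s: float,
    arena: Arena | None = None,
    *,
    mean_speed_cm_s: float = 12.0,
    tau_s: float = 0.7,
    dt: float = TRACKING_DT,
    t0: float = 0.0,
    seed: int | np.random.Generator | None = 0,
    pause_fraction: float = 0.0,
    pause_mean_s: float = 2.0,
) -> pd.DataFrame:
    """Simulate foraging tracking samples.

    Parameters
    ----------
    duration_s:
        Length of the trajectory (s); must be positive.
    mean_speed_cm_s:
        Stationary mean speed of the OU velocity process.  0 gives a
        stationary animal.
    tau_s:
        Velocity autocorrelation time constant.
    pause_fraction:
        Fraction of time spent in planted immobility bouts (velocity frozen
        at zero), used to emulate resting/grooming pauses.

    Returns
    -------
    DataFrame with columns ``t, x, y`` sampled every ``dt`` seconds.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    arena = arena or Arena()
    r_max = arena.radius_cm

    n = int(round(duration_s / dt))
    s = mean_speed_cm_s / _SPEED_OF_SD  # per-component stationary SD
    a = np.exp(-dt / tau_s)
    kick = s * np.sqrt(1.0 - a * a)

    # planted pause bouts: alternate moving/paused with exponential durations
    paused = np.zeros(n, dtype=bool)
    if pause_fraction > 0:
        move_mean = pause_mean_s * (1.0 - pause_fraction) / pause_fraction
        t_cur, is_pause = 0.0, False
        while t_cur < duration_s:
            dur = rng.exponential(pause_mean_s if is_pause else move_mean)
            i0 = int(t_cur / dt)
            i1 = min(n, int((t_cur + dur) / dt))
            if is_pause:
                paused[i0:i1] = True
            t_cur += dur
            is_pause = not is_pause

    # start at a uniform point well inside the arena, stationary velocity draw
    rr = 0.8 * r_max * np.sqrt(rng.uniform())
    ang = rng.uniform(0, 2 * np.pi)
    pos = np.array([rr * np.cos(ang), rr * np.sin(ang)])
    vel = rng.normal(0.0, s, size=2) if s > 0 else np.zeros(2)

    noise = rng.standard_normal((n, 2))
    xy = np.empty((n, 2))
    for i in range(n):
        if paused[i]:
            xy[i] = pos
            continue
        vel = vel * a + kick * noise[i]
        pos = pos + vel * dt
        rho = np.hypot(pos[0], pos[1])
        if rho > r_max:
            # reflect position across the wall and velocity about the normal
            nvec = pos / rho
            pos = pos - 2.0 * (rho - r_max) * nvec
            vel = vel - 2.0 * np.dot(vel, nvec) * nvec
        xy[i] = pos

    t = t0 + np.arange(n) * dt
    return pd.DataFrame({"t": t, "x": xy[:, 0], "y": xy[:, 1]})
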