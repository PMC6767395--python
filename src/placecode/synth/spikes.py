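"""Inhomogeneous-Poisson spike trains for synthetic CA1 units.

Waking firing of a pyramidal cell follows

    lambda(t) = baseline + peak * exp(-d(t)^2 / 2 sigma_f^2)
                * (1 + beta * (v(t) - v_mean))_+
                * exp(kappa * cos(theta(t) - phi_pref)) / I0(kappa)
                * g(t)

with d the distance to the field centre, v the running speed, theta the
theta phase and g an optional shared (assembly) gain.  Spikes are drawn by
Lewis-Shedler thinning with the bound recomputed per cell; the intensity is
evaluated at candidate spike times (positions and phase interpolated), so
phase modulation is not smeared by the 25.6 ms tracking clock.

Sleep/rest firing is a low constant rate with a multiplicative burst gain
inside sharp-wave-ripple events and von Mises theta modulation inside REM
intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import i0

from ..behavior import sample_speed
from ..session import Arena
from .presets import GenotypePreset
from .util import PhaseInterp, StepSeries


@dataclass
class CellParams:
    """Ground-truth parameter arrays for one population of cells."""

    cell_class: str
    center_xy: np.ndarray  # (n, 2) cm
    sigma_cm: np.ndarray  # np.inf -> spatially untuned
    peak_hz: np.ndarray
    baseline_hz: np.ndarray
    beta: np.ndarray  # speed gain per (cm/s)
    kappa_familiar: np.ndarray
    kappa_novel: np.ndarray
    phase_pref_familiar_deg: np.ndarray
    phase_pref_novel_deg: np.ndarray
    rem_kappa: np.ndarray
    swr_gain: np.ndarray
    assembly: np.ndarray  # int assembly id per cell

    @property
    def n_cells(self) -> int:
        return len(self.peak_hz)


@dataclass
class GroundTruth:
    """Everything the generator planted, for parameter-recovery tests."""

    preset_label: str
    pyr: CellParams
    inter: CellParams
    swr_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    swr_intervals: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    rem_intervals: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    gamma_gate_phase_deg: float = 240.0
    theta_band_hz: tuple[float, float] = (6.0, 10.0)

    def to_json(self) -> str:
        def conv(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        payload = {
            "preset_label": self.preset_label,
            "pyr": {k: conv(v) for k, v in asdict(self.pyr).items()},
            "inter": {k: conv(v) for k, v in asdict(self.inter).items()},
            "swr_times": self.swr_times.tolist(),
            "swr_intervals": np.asarray(self.swr_intervals).tolist(),
            "rem_intervals": np.asarray(self.rem_intervals).tolist(),
            "gamma_gate_phase_deg": self.gamma_gate_phase_deg,
            "theta_band_hz": list(self.theta_band_hz),
        }
        return json.dumps(payload)


def sample_cell_params(
    n_cells: int,
    preset: GenotypePreset,
    arena: Arena,
    rng: np.random.Generator,
    cell_class: str = "pyr",
) -> CellParams:
    """Draw per-cell tuning parameters around the preset's population values."""
    r = 0.9 * arena.radius_cm
    rho = r * np.sqrt(rng.uniform(size=n_cells))
    ang = rng.uniform(0, 2 * np.pi, n_cells)
    centers = np.c_[rho * np.cos(ang), rho * np.sin(ang)]
    pop_phase = 180.0
    if cell_class == "pyr":
        phase_fam = (
            pop_phase + preset.preferred_phase_spread_deg * rng.standard_normal(n_cells)
        ) % 360.0
        phase_nov = (
            phase_fam + preset.novelty_phase_shift_deg + 10.0 * rng.standard_normal(n_cells)
        ) % 360.0
        return CellParams(
            cell_class="pyr",
            center_xy=centers,
            sigma_cm=preset.field_sigma_cm * np.exp(0.10 * rng.standard_normal(n_cells)),
            peak_hz=preset.mean_rate_hz * np.exp(0.30 * rng.standard_normal(n_cells)),
            baseline_hz=np.full(n_cells, 0.15),
            beta=preset.speed_gain_beta * np.exp(0.20 * rng.standard_normal(n_cells)),
            kappa_familiar=preset.theta_kappa_familiar
            * np.exp(0.15 * rng.standard_normal(n_cells)),
            kappa_novel=preset.theta_kappa_novel * np.exp(0.15 * rng.standard_normal(n_cells)),
            phase_pref_familiar_deg=phase_fam,
            phase_pref_novel_deg=phase_nov,
            rem_kappa=preset.rem_theta_kappa * np.exp(0.15 * rng.standard_normal(n_cells)),
            swr_gain=preset.swr_rate_gain * np.exp(0.20 * rng.standard_normal(n_cells)),
            assembly=rng.integers(0, 5, n_cells),
        )
    # interneurons: spatially untuned, fast firing, preset-independent SWR gain
    phase = (330.0 + 60.0 * rng.standard_normal(n_cells)) % 360.0
    return CellParams(
        cell_class="int",
        center_xy=centers,
        sigma_cm=np.full(n_cells, np.inf),
        peak_hz=15.0 * np.exp(0.25 * rng.standard_normal(n_cells)),
        baseline_hz=np.full(n_cells, 1.0),
        beta=np.full(n_cells, 0.02),
        kappa_familiar=np.full(n_cells, 1.0),
        kappa_novel=np.full(n_cells, 1.0),
        phase_pref_familiar_deg=phase,
        phase_pref_novel_deg=phase,
        rem_kappa=np.full(n_cells, 1.0),
        swr_gain=np.full(n_cells, 2.5),
        assembly=rng.integers(0, 5, n_cells),
    )


def thinned_poisson(
    rate_fn: Callable[[np.ndarray], np.ndarray],
    t0: float,
    t1: float,
    rate_max: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Lewis-Shedler thinning of an inhomogeneous Poisson process."""
    if t1 <= t0 or rate_max <= 0:
        return np.empty(0)
    n_cand = rng.poisson(rate_max * (t1 - t0))
    if n_cand == 0:
        return np.empty(0)
    tt = np.sort(rng.uniform(t0, t1, n_cand))
    lam = rate_fn(tt)
    if np.any(lam > rate_max * (1 + 1e-9)):
        raise RuntimeError("intensity exceeded the thinning bound")
    keep = rng.uniform(0.0, rate_max, n_cand) < lam
    return tt[keep]


def _position_interp(tracking: pd.DataFrame):
    t = tracking["t"].to_numpy()
    x = tracking["x"].to_numpy()
    y = tracking["y"].to_numpy()

    def pos(tt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return np.interp(tt, t, x), np.interp(tt, t, y)

    return pos


def waking_rate_fn(
    tracking: pd.DataFrame,
    *,
    center: np.ndarray,
    sigma_cm: float,
    peak_hz: float,
    baseline_hz: float,
    beta: float,
    kappa: float,
    phase_pref_deg: float,
    phase: PhaseInterp | None = None,
    gain: StepSeries | None = None,
    v_mean: float | None = None,
) -> tuple[Callable[[np.ndarray], np.ndarray], float]:
    """Build the waking intensity function of one cell and its thinning bound."""
    t = tracking["t"].to_numpy()
    speeds = sample_speed(tracking)
    v_mean = float(np.mean(speeds)) if v_mean is None else v_mean
    pos = _position_interp(tracking)
    phi = np.radians(phase_pref_deg)
    inv_i0 = 1.0 / i0(kappa)

    def rate(tt: np.ndarray) -> np.ndarray:
        xx, yy = pos(tt)
        if np.isfinite(sigma_cm):
            d2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2
            g_spatial = np.exp(-d2 / (2.0 * sigma_cm**2))
        else:
            g_spatial = 1.0
        v = np.interp(tt, t, speeds)
        g_speed = np.maximum(0.0, 1.0 + beta * (v - v_mean))
        lam = peak_hz * g_spatial * g_speed
        if kappa > 0 and phase is not None:
            th = phase.at(tt)
            lam = lam * np.exp(kappa * np.cos(th - phi)) * inv_i0
        if gain is not None:
            lam = lam * gain.at(tt)
        return baseline_hz + lam

    speed_max = 1.0 + max(0.0, beta) * max(0.0, float(speeds.max()) - v_mean)
    phase_max = np.exp(kappa) * inv_i0 if (kappa > 0 and phase is not None) else 1.0
    gain_max = float(np.max(gain.values)) if gain is not None else 1.0
    bound = baseline_hz + peak_hz * speed_max * phase_max * gain_max
    return rate, bound


def generate_place_cells(
    tracking: pd.DataFrame,
    params: CellParams,
    *,
    epoch: str = "familiar",
    phase: PhaseInterp | None = None,
    assembly_gains: StepSeries | None = None,
    seed: int | np.random.Generator | None = 0,
) -> list[np.ndarray]:
    """Spike trains for a population of cells over one exploration epoch.

    ``assembly_gains`` holds one gain column per assembly (values shaped
    ``(n_windows, n_assemblies)``); each cell reads its own column.
    """
    rng = np.random.default_rng(seed)
    t0, t1 = float(tracking["t"].iloc[0]), float(tracking["t"].iloc[-1])
    kappas = params.kappa_familiar if epoch == "familiar" else params.kappa_novel
    phases = (
        params.phase_pref_familiar_deg if epoch == "familiar" else params.phase_pref_novel_deg
    )
    speeds = sample_speed(tracking)
    v_mean = float(speeds.mean())
    trains = []
    for c in range(params.n_cells):
        gain = None
        if assembly_gains is not None:
            gain = StepSeries(assembly_gains.edges, assembly_gains.values[:, params.assembly[c]])
        fn, bound = waking_rate_fn(
            tracking,
            center=params.center_xy[c],
            sigma_cm=float(params.sigma_cm[c]),
            peak_hz=float(params.peak_hz[c]),
            baseline_hz=float(params.baseline_hz[c]),
            beta=float(params.beta[c]),
            kappa=float(kappas[c]),
            phase_pref_deg=float(phases[c]),
            phase=phase,
            gain=gain,
            v_mean=v_mean,
        )
        trains.append(thinned_poisson(fn, t0, t1, bound, rng))
    return trains


def generate_sleep_spikes(
    params: CellParams,
    sleep_intervals: np.ndarray,
    *,
    base_rate_hz: float,
    swr_intervals: np.ndarray,
    swr_event_gains: np.ndarray,  # (n_events, n_assemblies)
    rem_intervals: np.ndarray,
    rem_rate_hz: float,
    phase: PhaseInterp | None = None,
    seed: int | np.random.Generator | None = 0,
) -> list[np.ndarray]:
    """Sleep/rest spike trains: SWR burst gains plus REM theta modulation."""
    rng = np.random.default_rng(seed)
    swr_intervals = np.atleast_2d(np.asarray(swr_intervals, dtype=float))
    rem_intervals = np.atleast_2d(np.asarray(rem_intervals, dtype=float))
    have_swr = swr_intervals.size > 0
    have_rem = rem_intervals.size > 0
    swr_starts = swr_intervals[:, 0] if have_swr else np.empty(0)
    swr_ends = swr_intervals[:, 1] if have_swr else np.empty(0)
    rem_starts = rem_intervals[:, 0] if have_rem else np.empty(0)
    rem_ends = rem_intervals[:, 1] if have_rem else np.empty(0)

    trains: list[np.ndarray] = []
    for c in range(params.n_cells):
        kappa = float(params.rem_kappa[c])
        phi = np.radians(params.phase_pref_familiar_deg[c])
        inv_i0 = 1.0 / i0(kappa)
        swr_gain = float(params.swr_gain[c])
        asm = int(params.assembly[c])

        def rate(tt: np.ndarray) -> np.ndarray:
            lam = np.full(tt.shape, base_rate_hz)
            if have_swr:
                ev = np.searchsorted(swr_starts, tt, side="right") - 1
                in_ev = (ev >= 0) & (tt < swr_ends[np.clip(ev, 0, None)])
                if np.any(in_ev):
                    lam[in_ev] = (
                        base_rate_hz * swr_gain * swr_event_gains[ev[in_ev], asm]
                    )
            if have_rem:
                iv = np.searchsorted(rem_starts, tt, side="right") - 1
                in_rem = (iv >= 0) & (tt < rem_ends[np.clip(iv, 0, None)])
                if np.any(in_rem):
                    lam_rem = rem_rate_hz
                    if kappa > 0 and phase is not None:
                        th = phase.at(tt[in_rem])
                        lam[in_rem] = lam_rem * np.exp(kappa * np.cos(th - phi)) * inv_i0
                    else:
                        lam[in_rem] = lam_rem
            return lam

        gmax = float(swr_event_gains[:, asm].max()) if have_swr else 1.0
        bound = max(
            base_rate_hz * max(1.0, swr_gain * gmax),
            rem_rate_hz * (np.exp(kappa) * inv_i0 if kappa > 0 and phase is not None else 1.0),
        )
        pieces = [
            thinned_poisson(rate, s, e, bound, rng)
            for s, e in np.atleast_2d(sleep_intervals)
        ]
        trains.append(np.sort(np.concatenate(pieces)) if pieces else np.empty(0))
    return trains


def assembly_gain_windows(
    intervals: np.ndarray,
    n_assemblies: int,
    sigma: float,
    rng: np.random.Generator,
    window_s: float = 0.1,
) -> StepSeries:
    """Shared lognormal gain per assembly, constant over 100 ms windows.

    Gains have mean 1 (``exp(sigma*z - sigma^2/2)``); windows outside the
    given intervals get gain 1 for every assembly.
    """
    edges: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    cur = -np.inf
    ones = np.ones((1, n_assemblies))
    for s, e in np.atleast_2d(np.asarray(intervals, dtype=float)):
        edges.append(np.array([cur]))  # gap segment [cur, s) with gain 1
        vals.append(ones)
        n_win = max(1, int((e - s) / window_s))
        edges.append(s + np.arange(n_win) * window_s)
        vals.append(np.exp(sigma * rng.standard_normal((n_win, n_assemblies)) - sigma**2 / 2.0))
        cur = s + n_win * window_s
    edges.append(np.array([cur]))  # tail segment with gain 1
    vals.append(ones)
    return StepSeries(edges=np.concatenate(edges), values=np.concatenate(vals, axis=0))
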