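"""Composite synthetic LFP: theta, theta-gated gamma, delta, and SWRs.

Exploration (and REM) segments carry a 6-10 Hz theta oscillation with
slowly wandering frequency plus 30-80 Hz gamma bursts whose amplitude is
gated at a fixed theta phase.  NREM sleep segments are delta-dominated
noise with 150-250 Hz ripple transients injected on the pyramidal-layer
channel only; the reference channel shares the broadband noise but never
the ripples, so reference subtraction cancels common-mode artifacts.

Ripple amplitude is calibrated against the background's own ripple-band
RMS statistics so that an event peaks at a requested z-score (default 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, filtfilt

from ..session import LfpData
from .util import PhaseInterp, ar1_series, intervals_to_mask, pink_noise


@dataclass
class LfpGroundTruth:
    theta_phase: PhaseInterp
    theta_intervals: np.ndarray  # where theta amplitude is on (explore + REM)
    rem_intervals: np.ndarray
    nrem_intervals: np.ndarray
    swr_times: np.ndarray
    swr_intervals: np.ndarray
    gamma_gate_phase_deg: float
    params: dict = field(default_factory=dict)


def sleep_stage_plan(
    sleep_epochs: np.ndarray,
    *,
    nrem_block_s: float = 100.0,
    rem_block_s: float = 25.0,
    min_rem_s: float = 15.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating NREM/REM blocks within each sleep epoch (NREM first)."""
    nrem, rem = [], []
    for s, e in np.atleast_2d(np.asarray(sleep_epochs, dtype=float)):
        t = s
        while t < e:
            n_end = min(t + nrem_block_s, e)
            nrem.append((t, n_end))
            t = n_end
            if t >= e:
                break
            r_end = min(t + rem_block_s, e)
            if r_end - t >= min_rem_s:
                rem.append((t, r_end))
            else:
                nrem.append((t, r_end))
            t = r_end
    return (
        np.array(nrem) if nrem else np.empty((0, 2)),
        np.array(rem) if rem else np.empty((0, 2)),
    )


def draw_swr_times(
    nrem_intervals: np.ndarray,
    rng: np.random.Generator,
    *,
    rate_hz: float = 0.25,
    min_gap_s: float = 0.3,
    margin_s: float = 2.0,
) -> np.ndarray:
    """Poisson-like SWR centre times inside NREM, with a refractory gap."""
    times = []
    for s, e in np.atleast_2d(np.asarray(nrem_intervals, dtype=float)):
        t = s + margin_s
        while True:
            t = t + max(min_gap_s, rng.exponential(1.0 / rate_hz))
            if t >= e - margin_s:
                break
            times.append(t)
    return np.array(times)


def generate_lfp(
    epochs: pd.DataFrame,
    *,
    fs: float = 1250.0,
    seed: int | np.random.Generator | None = 0,
    swr_times: np.ndarray | None = None,
    swr_rate_hz: float = 0.25,
    swr_amplitude_z: float = 10.0,
    swr_duration_range: tuple[float, float] = (0.05, 0.09),
    theta_amp: float = 1.0,
    gamma_amp: float = 0.35,
    delta_amp: float = 1.0,
    shared_noise_amp: float = 0.30,
    own_noise_amp: float = 0.25,
    gamma_gate_phase_deg: float = 240.0,
    theta_freq_hz: float = 8.0,
    gamma_freq_hz: float = 55.0,
) -> tuple[LfpData, LfpGroundTruth]:
    """Two-channel LFP (pyramidal layer + above-layer reference).

    ``swr_times`` may be supplied explicitly; every time must fall inside a
    sleep/rest epoch, otherwise a ValueError is raised.  By default ripple
    times are drawn within NREM blocks at ``swr_rate_hz``.
    """
    if fs < 1000:
        raise ValueError("fs must be at least 1000 Hz to carry the ripple band")
    rng = np.random.default_rng(seed)
    t_end = float(epochs["end"].max())
    n = int(round(t_end * fs))
    t = np.arange(n) / fs

    explore_iv = epochs.loc[
        epochs["label"].str.contains("explore"), ["start", "end"]
    ].to_numpy(dtype=float)
    sleep_iv = epochs.loc[
        epochs["label"].str.startswith(("sleep", "rest")), ["start", "end"]
    ].to_numpy(dtype=float)
    swr_allowed_iv = epochs.loc[
        epochs["label"].str.startswith("sleep"), ["start", "end"]
    ].to_numpy(dtype=float)
    nrem_iv, rem_iv = sleep_stage_plan(swr_allowed_iv)
    # rest epochs behave like NREM background but carry no planted ripples
    rest_iv = epochs.loc[epochs["label"].str.startswith("rest"), ["start", "end"]].to_numpy(
        dtype=float
    )
    nrem_like_iv = np.vstack([nrem_iv, rest_iv]) if rest_iv.size else nrem_iv

    theta_on_iv = np.vstack([explore_iv, rem_iv]) if rem_iv.size else explore_iv

    # --- oscillatory phases with slowly wandering frequency ---------------
    f_theta = np.clip(theta_freq_hz + ar1_series(n, 0.8, 2.0, fs, rng), 6.0, 10.0)
    phi_theta = np.cumsum(2.0 * np.pi * f_theta / fs)
    f_gamma = np.clip(gamma_freq_hz + ar1_series(n, 8.0, 1.0, fs, rng), 30.0, 80.0)
    phi_gamma = np.cumsum(2.0 * np.pi * f_gamma / fs)

    theta_mask = gaussian_filter1d(
        intervals_to_mask(theta_on_iv, n, fs).astype(float), 0.05 * fs
    )
    nrem_mask = gaussian_filter1d(
        intervals_to_mask(nrem_like_iv, n, fs).astype(float), 0.05 * fs
    )

    gate = np.radians(gamma_gate_phase_deg)
    theta_comp = theta_amp * theta_mask * np.cos(phi_theta)
    gamma_env = gamma_amp * theta_mask * ((1.0 + np.cos(phi_theta - gate)) / 2.0) ** 2
    gamma_comp = gamma_env * np.cos(phi_gamma)

    white = rng.standard_normal(n)
    b, a = butter(2, [2.0 / (fs / 2), 4.0 / (fs / 2)], btype="band")
    delta = filtfilt(b, a, white)
    delta = delta_amp * nrem_mask * delta / delta.std()

    shared = shared_noise_amp * pink_noise(n, rng)
    pyr = theta_comp + gamma_comp + delta + shared + own_noise_amp * pink_noise(n, rng)
    ref = shared + own_noise_amp * pink_noise(n, rng)

    # --- ripples, calibrated against the noise floor ----------------------
    if swr_times is None:
        swr_times = draw_swr_times(nrem_iv, rng, rate_hz=swr_rate_hz)
    else:
        swr_times = np.sort(np.asarray(swr_times, dtype=float))
        if swr_times.size and swr_allowed_iv.size == 0:
            raise ValueError("SWR times supplied but the session has no sleep epoch")
        if swr_times.size:
            from ..lfp_events import times_in_intervals

            if not times_in_intervals(swr_times, swr_allowed_iv).all():
                raise ValueError("every SWR time must fall inside a sleep epoch")

    swr_intervals = np.empty((0, 2))
    if len(swr_times):
        from ..lfp_events import bandpass_fir, moving_rms

        band = bandpass_fir(pyr, fs, 150.0, 250.0)
        rms = moving_rms(band, fs, 0.010)
        base_mask = intervals_to_mask(swr_allowed_iv, n, fs)
        mu, sd = rms[base_mask].mean(), rms[base_mask].std()
        target = mu + swr_amplitude_z * sd
        amp = np.sqrt(max(2.0 * (target**2 - mu**2), 0.0))
        iv = []
        for tc in swr_times:
            dur = rng.uniform(*swr_duration_range)
            f_r = rng.uniform(160.0, 220.0)
            ph0 = rng.uniform(0, 2 * np.pi)
            i0 = max(0, int((tc - dur / 2) * fs))
            i1 = min(n, int((tc + dur / 2) * fs))
            tt = t[i0:i1]
            env = np.hanning(i1 - i0)
            pyr[i0:i1] += amp * env * np.cos(2 * np.pi * f_r * (tt - tc) + ph0)
            iv.append((tc - dur / 2, tc + dur / 2))
        swr_intervals = np.array(iv)

    lfp = LfpData(
        fs=fs,
        data=np.vstack([pyr, ref]),
        roles=("pyramidal_layer", "reference_above_layer"),
    )
    gt = LfpGroundTruth(
        theta_phase=PhaseInterp(t0=0.0, fs=fs, unwrapped_rad=phi_theta),
        theta_intervals=theta_on_iv,
        rem_intervals=rem_iv,
        nrem_intervals=nrem_iv,
        swr_times=np.asarray(swr_times, dtype=float),
        swr_intervals=swr_intervals,
        gamma_gate_phase_deg=gamma_gate_phase_deg,
        params={"fs": fs, "swr_amplitude_z": swr_amplitude_z},
    )
    return lfp, gt
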