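"""LFP oscillation analysis: theta/gamma/SWR epoch detection and PSDs.

Conventions
-----------
* Band-pass filters are zero-phase symmetric FIR filters whose order is set
  by a three-cycle rule at the band's low edge.
* Theta phase is taken from the analytic signal of the 5-28 Hz filtered
  LFP; 0 deg sits on the positive peak of the filtered trace and phase
  increases with time over [0, 360).
* All detector thresholds are z-scores of a sliding RMS amplitude, so
  detection is invariant to overall LFP rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .session import LfpData
from .synth.util import PhaseInterp


# ---------------------------------------------------------------------------
# filtering primitives
# ---------------------------------------------------------------------------

def bandpass_fir(x: np.ndarray, fs: float, lo: float, hi: float, cycles: float = 3.0) -> np.ndarray:
    """Zero-phase FIR band-pass (symmetric kernel, FFT convolution)."""
    # three cycles at the low edge, but never shorter than 150 ms: high bands
    # still need a narrow transition so out-of-band noise stays out
    numtaps = max(int(cycles * fs / lo), int(0.15 * fs))
    numtaps += 1 - numtaps % 2  # odd length -> integer group delay, zero phase
    taps = signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)
    return signal.fftconvolve(x, taps, mode="same")


def moving_rms(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Root-mean-square amplitude in a centred sliding window."""
    size = max(1, int(round(window_s * fs)))
    return np.sqrt(uniform_filter1d(x * x, size=size, mode="nearest"))


def _mask_to_intervals(mask: np.ndarray, times: np.ndarray) -> np.ndarray:
    """(start, end) times of maximal True runs of ``mask``."""
    if not mask.any():
        return np.empty((0, 2))
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, len(mask)]
    return np.c_[times[starts], times[ends - 1]]


def merge_intervals(intervals: np.ndarray, gap: float = 0.0) -> np.ndarray:
    """Merge overlapping intervals and those separated by less than ``gap``."""
    iv = np.atleast_2d(np.asarray(intervals, dtype=float))
    if iv.size == 0:
        return np.empty((0, 2))
    iv = iv[np.argsort(iv[:, 0])]
    out = [iv[0].copy()]
    for s, e in iv[1:]:
        if s <= out[-1][1] + gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e]))
    return np.array(out)


def intervals_intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise intersection of two sorted, non-overlapping interval sets."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            s, e = max(s1, s2), min(e1, e2)
            if e > s:
                out.append((s, e))
    return np.array(out) if out else np.empty((0, 2))


def times_in_intervals(t: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Boolean mask of which times fall inside any [start, end) interval."""
    t = np.asarray(t)
    iv = np.atleast_2d(np.asarray(intervals, dtype=float))
    if iv.size == 0:
        return np.zeros(t.shape, dtype=bool)
    starts, ends = iv[:, 0], iv[:, 1]
    i = np.searchsorted(starts, t, side="right") - 1
    ok = i >= 0
    out = np.zeros(t.shape, dtype=bool)
    out[ok] = t[ok] < ends[i[ok]]
    return out


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class EventIntervals:
    """Detected oscillation epochs of one band, with per-event peak stats."""

    band: str  # "theta" | "gamma" | "swr"
    intervals: np.ndarray  # (n, 2) start/end in s
    peak_stat: np.ndarray  # per-event theta/delta ratio or peak z
    centers: np.ndarray | None = None  # peak-power times (SWRs)
    params: dict = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return len(self.intervals)

    @property
    def durations(self) -> np.ndarray:
        return self.intervals[:, 1] - self.intervals[:, 0] if self.n_events else np.empty(0)

    @property
    def total_time(self) -> float:
        return float(self.durations.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.band,
                "start_s": self.intervals[:, 0] if self.n_events else [],
                "end_s": self.intervals[:, 1] if self.n_events else [],
                "peak_stat": self.peak_stat,
            }
        )


@dataclass
class PsdResult:
    freq_hz: np.ndarray  # 1 Hz bins
    norm_power: np.ndarray  # sums to 1

    def band_power(self, lo: float, hi: float) -> float:
        sel = (self.freq_hz >= lo) & (self.freq_hz <= hi)
        return float(self.norm_power[sel].sum())


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------

def detect_theta_epochs(
    lfp: LfpData,
    epoch: tuple[float, float],
    *,
    channel: str = "pyramidal_layer",
    seg_s: float = 1.6,
    step_s: float = 0.8,
    ratio_threshold: float = 2.0,
    theta_band: tuple[float, float] = (6.0, 10.0),
    delta_band: tuple[float, float] = (2.0, 4.0),
    nw: float = 3.0,
    n_tapers: int = 5,
) -> EventIntervals:
    """Theta epochs from the theta/delta power ratio of multitaper spectra.

    The ratio is measured in 1600 ms segments stepped by 800 ms; segments at
    or above the threshold are marked and adjacent marked segments merged.
    """
    x = lfp.channel(channel)
    fs = lfp.fs
    i0, i1 = lfp.sample_index(np.array(epoch))
    seg_n = int(round(seg_s * fs))
    step_n = int(round(step_s * fs))
    n_seg = (i1 - i0 - seg_n) // step_n + 1
    if n_seg < 1:
        return EventIntervals("theta", np.empty((0, 2)), np.empty(0),
                              params={"warning": "epoch shorter than one segment"})
    tapers = signal.windows.dpss(seg_n, NW=nw, Kmax=n_tapers)
    freqs = np.fft.rfftfreq(seg_n, 1.0 / fs)
    th_sel = (freqs >= theta_band[0]) & (freqs <= theta_band[1])
    de_sel = (freqs >= delta_band[0]) & (freqs <= delta_band[1])
    starts = i0 + np.arange(n_seg) * step_n
    segs = np.stack([x[s : s + seg_n] for s in starts])
    segs = segs - segs.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(segs[:, None, :] * tapers[None, :, :], axis=-1)
    psd = (np.abs(spec) ** 2).mean(axis=1)
    ratio = psd[:, th_sel].mean(axis=1) / psd[:, de_sel].mean(axis=1)
    marked = ratio >= ratio_threshold
    t_start = lfp.t0 + starts / fs
    iv = np.c_[t_start[marked], t_start[marked] + seg_s]
    merged = merge_intervals(iv)
    # per merged interval keep the max ratio of its member segments
    peak = np.array(
        [ratio[marked][(t_start[marked] >= s - 1e-9) & (t_start[marked] < e)].max()
         for s, e in merged]
    ) if len(merged) else np.empty(0)
    return EventIntervals(
        "theta", merged, peak,
        params={"seg_s": seg_s, "step_s": step_s, "threshold": ratio_threshold},
    )


def theta_phase(
    lfp: LfpData,
    *,
    channel: str = "pyramidal_layer",
    band: tuple[float, float] = (5.0, 28.0),
) -> PhaseInterp:
    """Instantaneous phase (rad, unwrapped) of the band-filtered LFP.

    Wrapped phase is 0 at the positive peak of the filtered signal and
    advances with time; use ``.deg_at(times)`` for degrees in [0, 360).
    """
    x = bandpass_fir(lfp.channel(channel), lfp.fs, band[0], band[1])
    analytic = signal.hilbert(x)
    unwrapped = np.unwrap(np.angle(analytic))
    return PhaseInterp(t0=lfp.t0, fs=lfp.fs, unwrapped_rad=unwrapped)


def detect_gamma_epochs(
    lfp: LfpData,
    epoch: tuple[float, float],
    *,
    channel: str = "pyramidal_layer",
    band: tuple[float, float] = (30.0, 80.0),
    rms_window_s: float = 0.025,
    z_threshold: float = 2.0,
) -> EventIntervals:
    """Gamma epochs: 30-80 Hz RMS exceeding mean + 2 SD within the epoch."""
    fs = lfp.fs
    i0, i1 = lfp.sample_index(np.array(epoch))
    x = bandpass_fir(lfp.channel(channel), fs, band[0], band[1])
    rms = moving_rms(x, fs, rms_window_s)[i0:i1]
    if rms.size == 0 or rms.std() == 0:
        return EventIntervals("gamma", np.empty((0, 2)), np.empty(0))
    z = (rms - rms.mean()) / rms.std()
    times = lfp.t0 + (i0 + np.arange(len(z))) / fs
    iv = _mask_to_intervals(z > z_threshold, times)
    peaks = np.array([z[int((s - times[0]) * fs) : int((e - times[0]) * fs) + 1].max()
                      for s, e in iv]) if len(iv) else np.empty(0)
    return EventIntervals("gamma", iv, peaks,
                          params={"band": band, "z": z_threshold, "rms_s": rms_window_s})


def detect_swrs(
    lfp: LfpData,
    sleep_epochs: np.ndarray,
    *,
    pyr_channel: str = "pyramidal_layer",
    ref_channel: str | None = "reference_above_layer",
    band: tuple[float, float] = (150.0, 250.0),
    rms_window_s: float = 0.010,
    z_peak: float = 7.0,
    z_edge: float = 2.0,
    min_duration_s: float = 0.030,
    merge_gap_s: float = 0.050,
    baseline_epoch: tuple[float, float] | None = None,
) -> EventIntervals:
    """Sharp-wave-ripple detection with reference-channel subtraction.

    The reference signal is subtracted before 150-250 Hz filtering to cancel
    common-mode artifacts; the sliding RMS must exceed ``z_peak`` SD above
    the baseline mean, with baseline statistics frozen from the first sleep
    epoch.  Boundaries extend to the ``z_edge`` crossings; events shorter
    than 30 ms are discarded and gaps under 50 ms merged.
    """
    sleep_epochs = np.atleast_2d(np.asarray(sleep_epochs, dtype=float))
    if sleep_epochs.size == 0:
        raise ValueError("SWR detection requires at least one sleep epoch")
    fs = lfp.fs
    x = lfp.channel(pyr_channel).astype(float)
    if ref_channel is not None:
        x = x - lfp.channel(ref_channel)
    filt = bandpass_fir(x, fs, band[0], band[1])
    rms = moving_rms(filt, fs, rms_window_s)
    base = baseline_epoch if baseline_epoch is not None else tuple(sleep_epochs[0])
    b0, b1 = lfp.sample_index(np.array(base))
    # two-pass background estimate: ripples themselves must not inflate the
    # baseline, so samples beyond 3 SD of the first pass are excluded
    seg = rms[b0:b1]
    mu, sd = seg.mean(), seg.std()
    if sd > 0:
        quiet = seg[np.abs(seg - mu) < 3 * sd]
        if quiet.size > 100:
            mu, sd = quiet.mean(), quiet.std()
    if sd == 0:
        return EventIntervals("swr", np.empty((0, 2)), np.empty(0), centers=np.empty(0))
    z = (rms - mu) / sd

    all_iv, all_peak, all_center = [], [], []
    for s, e in sleep_epochs:
        i0, i1 = lfp.sample_index(np.array([s, e]))
        zz = z[i0:i1]
        above_peak = zz > z_peak
        if not above_peak.any():
            continue
        above_edge = zz > z_edge
        # extend every z_peak run to the surrounding z_edge run
        edge_iv = _mask_to_intervals(above_edge, np.arange(len(zz)))
        keep = []
        for a, b in edge_iv.astype(int):
            if above_peak[a : b + 1].any():
                keep.append((a, b + 1))
        iv = merge_intervals(np.array(keep, dtype=float), gap=merge_gap_s * fs)
        for a, b in iv:
            a, b = int(a), int(b)
            if (b - a) / fs < min_duration_s:
                continue
            peak_i = a + int(np.argmax(zz[a:b]))
            all_iv.append((lfp.t0 + (i0 + a) / fs, lfp.t0 + (i0 + b) / fs))
            all_peak.append(zz[a:b].max())
            all_center.append(lfp.t0 + (i0 + peak_i) / fs)
    return EventIntervals(
        "swr",
        np.array(all_iv) if all_iv else np.empty((0, 2)),
        np.array(all_peak),
        centers=np.array(all_center),
        params={"z_peak": z_peak, "z_edge": z_edge, "band": band,
                "baseline_epoch": tuple(base)},
    )


def welch_psd(
    lfp: LfpData,
    epoch: tuple[float, float],
    *,
    channel: str = "pyramidal_layer",
    window_s: float = 0.5,
    overlap: float = 0.5,
    max_freq_hz: float = 500.0,
    bin_hz: float = 1.0,
) -> PsdResult:
    """Welch PSD (Hanning, 500 ms, 50% overlap) in 1 Hz bins, sum-normalised."""
    fs = lfp.fs
    i0, i1 = lfp.sample_index(np.array(epoch))
    if (i1 - i0) / fs < 1.0:
        raise ValueError("epoch must be at least 1 s long")
    nperseg = int(round(window_s * fs))
    nfft = int(round(fs / bin_hz))  # zero-pad so bins land on a 1 Hz grid
    f, p = signal.welch(
        lfp.channel(channel)[i0:i1],
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
        nfft=max(nfft, nperseg),
    )
    sel = f <= max_freq_hz
    f, p = f[sel], p[sel]
    return PsdResult(freq_hz=f, norm_power=p / p.sum())


def gamma_peak_theta_locking(
    lfp: LfpData,
    theta_epochs: EventIntervals,
    gamma_epochs: EventIntervals | None = None,
    *,
    channel: str = "pyramidal_layer",
    gamma_band: tuple[float, float] = (30.0, 80.0),
    phase: PhaseInterp | None = None,
) -> tuple[float, float, np.ndarray]:
    """Theta phase at which gamma cycles peak.

    Local maxima of the gamma-filtered LFP are located within detected
    gamma epochs (the high-power periods; cycle peaks outside them are
    noise-driven and uniform in theta phase) that overlap theta epochs, and
    the theta phase at each peak extracted.  Returns (circular mean angle
    deg, resultant length, all peak phases deg); the angle is NaN when no
    qualifying peaks exist.
    """
    fs = lfp.fs
    g = bandpass_fir(lfp.channel(channel), fs, gamma_band[0], gamma_band[1])
    peaks, _ = signal.find_peaks(g)
    t_peaks = lfp.t0 + peaks / fs
    inside = times_in_intervals(t_peaks, theta_epochs.intervals)
    if gamma_epochs is not None:
        inside &= times_in_intervals(t_peaks, gamma_epochs.intervals)
    t_peaks = t_peaks[inside]
    if t_peaks.size == 0:
        return float("nan"), 0.0, np.empty(0)
    ph = phase if phase is not None else theta_phase(lfp, channel=channel)
    ang = np.radians(ph.deg_at(t_peaks))
    vec = np.exp(1j * ang).mean()
    return float(np.degrees(np.angle(vec)) % 360.0), float(np.abs(vec)), np.degrees(ang) % 360.0
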