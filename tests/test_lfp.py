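"""Oscillation detectors on constructed signals and generator ground truth."""

import numpy as np
import pytest

from placecode import lfp_events as le
from placecode.session import LfpData, make_epoch_table
from placecode.synth import generate_lfp
from placecode.synth.util import pink_noise

FS = 1250.0


def _lfp(x, fs=FS):
    return LfpData(fs=fs, data=np.asarray(x)[None, :], roles=("pyramidal_layer",))


def _tone(freq, duration, fs=FS, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.cos(2 * np.pi * freq * t)


class TestThetaDetection:
    def test_pure_theta_marks_whole_epoch(self, rng):
        x = _tone(8.0, 60.0) + 0.05 * rng.standard_normal(int(60 * FS))
        ev = le.detect_theta_epochs(_lfp(x), (0.0, 60.0))
        assert ev.total_time >= 0.95 * 60.0
        assert (ev.peak_stat > 2.0).all()

    def test_pure_delta_yields_nothing(self, rng):
        x = _tone(3.0, 60.0) + 0.05 * rng.standard_normal(int(60 * FS))
        ev = le.detect_theta_epochs(_lfp(x), (0.0, 60.0))
        assert ev.n_events == 0

    def test_generated_session_staging_recovered(self):
        # >= 90% of planted theta time marked, <= 5% of NREM time falsely marked
        ep = make_epoch_table([("familiar_explore", 0.0, 200.0), ("sleep_familiar", 200.0, 500.0)])
        lfp, gt = generate_lfp(ep, seed=14)
        ev = le.detect_theta_epochs(lfp, (0.0, 500.0))
        grid = np.arange(0.0, 500.0, 0.1) + 0.05
        marked = le.times_in_intervals(grid, ev.intervals)
        truth = le.times_in_intervals(grid, gt.theta_intervals)
        nrem = le.times_in_intervals(grid, gt.nrem_intervals)
        assert marked[truth].mean() >= 0.90
        assert marked[nrem].mean() <= 0.05


class TestThetaPhase:
    def test_zero_phase_at_tone_peaks(self):
        x = _tone(8.0, 20.0)
        phase = le.theta_phase(_lfp(x))
        peaks = np.arange(1, 150) / 8.0  # cosine peaks at multiples of the period
        ph = phase.deg_at(peaks)
        ph = (ph + 180) % 360 - 180
        assert np.abs(ph[5:-5]).max() < 1.0

    def test_phase_advances_monotonically(self):
        x = _tone(7.0, 10.0)
        phase = le.theta_phase(_lfp(x))
        assert (np.diff(phase.unwrapped_rad[100:-100]) > 0).all()

    def test_planted_preference_recovered_from_lfp(self):
        # spikes generated at 120 deg of the generator phase recover a
        # circular mean within 5 deg when the phase is re-estimated by
        # filtering the composite LFP
        from placecode.phase_locking import resultant_vector
        from placecode.synth import CellParams, generate_place_cells, generate_trajectory

        ep = make_epoch_table([("familiar_explore", 0.0, 300.0)])
        lfp, gt = generate_lfp(ep, seed=5)
        tr = generate_trajectory(300.0, seed=2)
        pars = CellParams(
            "pyr", np.zeros((1, 2)), np.array([np.inf]), np.array([8.0]), np.array([0.0]),
            np.array([0.0]), np.array([2.0]), np.array([2.0]), np.array([120.0]),
            np.array([120.0]), np.array([0.0]), np.array([1.0]), np.array([0]),
        )
        spikes = generate_place_cells(tr, pars, phase=gt.theta_phase, seed=4)[0]
        est = le.theta_phase(lfp)
        _, ang = resultant_vector(est.deg_at(spikes))
        assert abs((ang - 120.0 + 180) % 360 - 180) < 5.0


class TestGammaDetection:
    def test_noise_floor_fraction(self, rng):
        x = rng.standard_normal(int(600 * FS))
        ev = le.detect_gamma_epochs(_lfp(x), (0.0, 600.0))
        assert 0.015 < ev.total_time / 600.0 < 0.045

    def test_injected_bursts_recovered(self, rng):
        # 100 bursts calibrated to 4 SD of the background RMS distribution,
        # sparse enough (1.3% duty cycle) not to inflate the threshold stats
        dur = 900.0
        bg = 0.4 * pink_noise(int(dur * FS), rng)
        band = le.bandpass_fir(bg, FS, 30.0, 80.0)
        r = le.moving_rms(band, FS, 0.025)
        mu, sd = r.mean(), r.std()
        amp = np.sqrt(2 * ((mu + 4 * sd) ** 2 - mu**2))
        x = bg.copy()
        t = np.arange(len(x)) / FS
        centers = 5.0 + 9.0 * np.arange(100)
        for tc in centers:
            sl = slice(int((tc - 0.06) * FS), int((tc + 0.06) * FS))
            x[sl] += amp * np.hanning(sl.stop - sl.start) * np.cos(2 * np.pi * 55 * (t[sl] - tc))
        ev = le.detect_gamma_epochs(_lfp(x), (0.0, dur))
        hits = sum(
            1
            for tc in centers
            if ((ev.intervals[:, 0] < tc + 0.06) & (ev.intervals[:, 1] > tc - 0.06)).any()
        )
        assert hits >= 95

    def test_silent_signal_has_no_events(self):
        ev = le.detect_gamma_epochs(_lfp(np.zeros(int(10 * FS))), (0.0, 10.0))
        assert ev.n_events == 0

    def test_amplitude_rescaling_invariance(self, rng):
        x = rng.standard_normal(int(120 * FS))
        a = le.detect_gamma_epochs(_lfp(x), (0.0, 120.0))
        b = le.detect_gamma_epochs(_lfp(25.0 * x), (0.0, 120.0))
        np.testing.assert_allclose(a.intervals, b.intervals)


class TestWelchPsd:
    def test_tone_peaks_in_its_bin(self, rng):
        x = _tone(8.0, 30.0) + 0.01 * rng.standard_normal(int(30 * FS))
        psd = le.welch_psd(_lfp(x), (0.0, 30.0))
        assert psd.freq_hz[np.argmax(psd.norm_power)] == pytest.approx(8.0, abs=1.0)

    def test_normalised_to_unit_sum(self, rng):
        x = rng.standard_normal(int(10 * FS))
        psd = le.welch_psd(_lfp(x), (0.0, 10.0))
        assert psd.norm_power.sum() == pytest.approx(1.0, abs=1e-9)
        assert (psd.norm_power >= 0).all()

    def test_white_noise_roughly_flat(self, rng):
        x = rng.standard_normal(int(60 * FS))
        psd = le.welch_psd(_lfp(x), (0.0, 60.0))
        body = psd.norm_power[5:495]
        assert body.max() < 3.0 * np.median(body)

    def test_band_powers_track_planted_snr(self):
        ep = make_epoch_table([("familiar_explore", 0.0, 120.0)])
        lfp, _ = generate_lfp(ep, seed=6)
        psd = le.welch_psd(lfp, (0.0, 120.0))
        assert psd.band_power(6, 10) > psd.band_power(30, 80) > 0


class TestSwrDetection:
    def test_common_reference_subtraction_is_exact(self, rng):
        # identical pyramidal and reference channels cancel entirely
        x = rng.standard_normal(int(60 * FS))
        lfp = LfpData(
            fs=FS, data=np.vstack([x, x]), roles=("pyramidal_layer", "reference_above_layer")
        )
        ev = le.detect_swrs(lfp, np.array([[0.0, 60.0]]))
        assert ev.n_events == 0

    def test_no_sleep_epoch_raises(self, rng):
        x = rng.standard_normal(int(10 * FS))
        with pytest.raises(ValueError):
            le.detect_swrs(_lfp(x), np.empty((0, 2)))


class TestGammaThetaCoupling:
    def test_planted_gate_phase_recovered(self):
        ep = make_epoch_table([("familiar_explore", 0.0, 300.0)])
        lfp, gt = generate_lfp(ep, seed=5)
        theta = le.detect_theta_epochs(lfp, (0.0, 300.0))
        gamma = le.detect_gamma_epochs(lfp, (0.0, 300.0))
        ang, r, phases = le.gamma_peak_theta_locking(lfp, theta, gamma)
        assert len(phases) > 100
        assert r > 0.3
        assert abs((ang - gt.gamma_gate_phase_deg + 180) % 360 - 180) < 10.0

    def test_ungated_gamma_shows_no_locking(self, rng):
        # gamma bursts at random times of a theta carrier: resultant ~ 0
        n = int(300 * FS)
        t = np.arange(n) / FS
        x = np.cos(2 * np.pi * 8 * t) + 0.1 * rng.standard_normal(n)
        for tc in rng.uniform(2, 298, 300):
            sl = slice(int((tc - 0.03) * FS), int((tc + 0.03) * FS))
            x[sl] += 0.8 * np.hanning(sl.stop - sl.start) * np.cos(2 * np.pi * 55 * (t[sl] - tc))
        lfp = _lfp(x)
        theta = le.detect_theta_epochs(lfp, (0.0, 300.0))
        gamma = le.detect_gamma_epochs(lfp, (0.0, 300.0))
        _, r, phases = le.gamma_peak_theta_locking(lfp, theta, gamma)
        assert len(phases) > 100
        assert r < 0.15


class TestFilters:
    def test_zero_phase_filtering_preserves_tone_phase(self):
        x = _tone(8.0, 20.0)
        y = le.bandpass_fir(x, FS, 5.0, 28.0)
        mid = slice(int(5 * FS), int(15 * FS))
        num = np.vdot(x[mid], y[mid])
        shift = np.degrees(np.arccos(num / (np.linalg.norm(x[mid]) * np.linalg.norm(y[mid]))))
        assert shift < 1.0
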