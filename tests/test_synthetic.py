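"""Generator correctness: confinement, Poisson statistics, determinism."""

import numpy as np
import pandas as pd
import pytest

from placecode import lfp_events as le
from placecode.session import Arena, make_epoch_table
from placecode.synth import (
    CONTROL,
    CellParams,
    generate_lfp,
    generate_place_cells,
    generate_trajectory,
    simulate_session,
    sleep_stage_plan,
    thinned_poisson,
)
from placecode.synth.util import PhaseInterp


def _flat_cell(peak_hz, kappa=0.0, beta=0.0, phase_pref=120.0, baseline=0.0):
    return CellParams(
        "pyr",
        center_xy=np.zeros((1, 2)),
        sigma_cm=np.array([np.inf]),
        peak_hz=np.array([float(peak_hz)]),
        baseline_hz=np.array([float(baseline)]),
        beta=np.array([float(beta)]),
        kappa_familiar=np.array([float(kappa)]),
        kappa_novel=np.array([float(kappa)]),
        phase_pref_familiar_deg=np.array([float(phase_pref)]),
        phase_pref_novel_deg=np.array([float(phase_pref)]),
        rem_kappa=np.array([0.0]),
        swr_gain=np.array([1.0]),
        assembly=np.array([0]),
    )


def _ramp_phase(duration_s, freq_hz=8.0, fs=1250.0):
    n = int(duration_s * fs)
    return PhaseInterp(0.0, fs, np.cumsum(np.full(n, 2 * np.pi * freq_hz / fs)))


class TestTrajectory:
    def test_confined_to_arena(self, foraging_tracking):
        r = np.hypot(foraging_tracking["x"], foraging_tracking["y"])
        assert (r <= Arena().radius_cm + 1e-9).all()

    def test_zero_noise_is_stationary(self):
        tr = generate_trajectory(30.0, mean_speed_cm_s=0.0, seed=1)
        assert np.ptp(tr["x"]) == 0.0 and np.ptp(tr["y"]) == 0.0

    def test_seed_determinism(self):
        a = generate_trajectory(60.0, seed=123)
        b = generate_trajectory(60.0, seed=123)
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_trajectory(0.0)


class TestSpikeGeneration:
    def test_homogeneous_poisson_fano_factor(self):
        # kappa = 0, beta = 0, flat field -> homogeneous Poisson; Fano factor
        # of 1 s counts should be 1
        tr = generate_trajectory(1200.0, seed=4)
        spikes = generate_place_cells(tr, _flat_cell(5.0), seed=11)[0]
        counts = np.histogram(spikes, bins=np.arange(0.0, 1201.0))[0]
        fano = counts.var() / counts.mean()
        assert fano == pytest.approx(1.0, abs=0.1)

    def test_rate_matches_time_integrated_intensity(self):
        tr = generate_trajectory(1000.0, seed=5)
        spikes = generate_place_cells(tr, _flat_cell(12.0), seed=2)[0]
        assert len(spikes) / (12.0 * 1000.0) == pytest.approx(1.0, abs=0.05)

    def test_phase_preference_recovered(self):
        # kappa = 2, ~5000 spikes: circular mean within 10 deg of the pref
        tr = generate_trajectory(700.0, seed=6)
        phase = _ramp_phase(700.0)
        spikes = generate_place_cells(
            tr, _flat_cell(8.0, kappa=2.0, phase_pref=120.0), phase=phase, seed=3
        )[0]
        assert len(spikes) > 4000
        ang = np.angle(np.exp(1j * phase.at(spikes)).mean(), deg=True) % 360
        assert abs((ang - 120.0 + 180) % 360 - 180) < 10.0

    def test_thinning_bound_violation_raises(self):
        rng = np.random.default_rng(0)
        with pytest.raises(RuntimeError):
            thinned_poisson(lambda t: np.full(t.shape, 10.0), 0.0, 10.0, 5.0, rng)


class TestLfp:
    def test_exploration_psd_peaks_in_theta_band(self):
        ep = make_epoch_table([("familiar_explore", 0.0, 120.0)])
        lfp, _ = generate_lfp(ep, seed=8)
        psd = le.welch_psd(lfp, (0.0, 120.0))
        f_peak = psd.freq_hz[np.argmax(psd.norm_power)]
        assert 6.0 <= f_peak <= 10.0

    def test_swr_outside_sleep_rejected(self):
        ep = make_epoch_table([("familiar_explore", 0.0, 60.0), ("sleep_familiar", 60.0, 120.0)])
        with pytest.raises(ValueError):
            generate_lfp(ep, seed=1, swr_times=np.array([30.0]))

    def test_common_mode_artifact_cancelled(self):
        # a 60 Hz-band transient added to BOTH channels must not create SWR
        # detections beyond those of the clean signal
        ep = make_epoch_table([("sleep_familiar", 0.0, 300.0)])
        lfp, gt = generate_lfp(ep, seed=9)
        clean = le.detect_swrs(lfp, np.array([[0.0, 300.0]]))
        fs = lfp.fs
        t = np.arange(lfp.n_samples) / fs
        burst = np.zeros(lfp.n_samples)
        for tc in (50.0, 150.0, 250.0):
            sel = slice(int((tc - 0.1) * fs), int((tc + 0.1) * fs))
            burst[sel] = 30.0 * np.hanning(sel.stop - sel.start) * np.cos(2 * np.pi * 60 * t[sel])
        dirty = lfp
        dirty.data = lfp.data + burst
        noisy = le.detect_swrs(dirty, np.array([[0.0, 300.0]]))
        assert noisy.n_events == clean.n_events

    def test_sleep_stage_plan_tiles_epoch(self):
        nrem, rem = sleep_stage_plan(np.array([[0.0, 300.0]]))
        iv = np.vstack([nrem, rem])
        iv = iv[np.argsort(iv[:, 0])]
        assert iv[0, 0] == 0.0 and iv[-1, 1] == 300.0
        assert np.allclose(iv[1:, 0], iv[:-1, 1])

    def test_generator_determinism(self):
        ep = make_epoch_table([("familiar_explore", 0.0, 30.0), ("sleep_familiar", 30.0, 90.0)])
        a, _ = generate_lfp(ep, seed=77)
        b, _ = generate_lfp(ep, seed=77)
        assert np.array_equal(a.data, b.data)


class TestSessionBundle:
    def test_spikes_within_session_and_epochs_ordered(self, short_bundle):
        t_end = float(short_bundle.epochs["end"].max())
        for u in short_bundle.units:
            assert ((u.spike_times >= 0) & (u.spike_times <= t_end)).all()
            assert (np.diff(u.spike_times) >= 0).all()
        starts = short_bundle.epochs["start"].to_numpy()
        assert (np.diff(starts) > 0).all()

    def test_roundtrip_serialization(self, short_bundle, tmp_path):
        short_bundle.save(tmp_path / "bundle")
        loaded = type(short_bundle).load(tmp_path / "bundle")
        assert len(loaded.units) == len(short_bundle.units)
        np.testing.assert_allclose(
            loaded.units[3].spike_times, short_bundle.units[3].spike_times
        )
        np.testing.assert_allclose(loaded.lfp.data, short_bundle.lfp.data)
        assert list(loaded.epochs["label"]) == list(short_bundle.epochs["label"])
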