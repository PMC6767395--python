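"""Circular statistics: closed forms, von Mises oracles, invariances."""

import numpy as np
import pytest

from placecode.phase_locking import (
    MeanVector,
    circular_mean_deg,
    population_locking_strength,
    preferred_phase_concentration,
    resultant_vector,
    spike_phase_mean_vector,
    variance_ratio_test,
    vm_expected_length,
    watson_williams_test,
)
from placecode.synth.util import PhaseInterp


def _mv(angle, length=0.5, p=0.01, uid=0):
    return MeanVector(uid, "theta", angle, length, 100, p)


def _phase_of_times(freq=8.0, duration=600.0, fs=1250.0):
    return PhaseInterp(0.0, fs, np.arange(int(duration * fs)) * (2 * np.pi * freq / fs))


class TestMeanVector:
    def test_identical_phases_lock_perfectly(self):
        # spikes exactly at the 90 deg point of every cycle
        phase = _phase_of_times()
        cycle = 1.0 / 8.0
        spikes = (np.arange(100) + 0.25) * cycle  # 90 deg after each peak
        mv = spike_phase_mean_vector(spikes, phase, np.array([[0.0, 600.0]]))
        assert mv.length == pytest.approx(1.0, abs=1e-6)
        assert mv.angle_deg == pytest.approx(90.0, abs=0.1)
        assert mv.significant

    def test_uniform_phases_not_locked(self, rng):
        phase = _phase_of_times()
        spikes = np.sort(rng.uniform(0.0, 600.0, 1000))
        mv = spike_phase_mean_vector(spikes, phase, np.array([[0.0, 600.0]]))
        assert mv.length < 0.06

    def test_too_few_spikes_excluded(self):
        phase = _phase_of_times()
        assert spike_phase_mean_vector(np.arange(5.0), phase, np.array([[0.0, 600.0]])) is None

    def test_von_mises_length_oracle(self, rng):
        # independent oracle: numpy's von Mises sampler, length A(kappa)
        for kappa in (0.5, 1.0, 2.0, 4.0):
            angles = np.degrees(rng.vonmises(1.0, kappa, 5000)) % 360
            length, _ = resultant_vector(angles)
            assert length == pytest.approx(vm_expected_length(kappa), abs=0.02)

    def test_rotation_invariance(self, rng):
        angles = np.degrees(rng.vonmises(0.5, 1.5, 400)) % 360
        l0, a0 = resultant_vector(angles)
        l1, a1 = resultant_vector((angles + 77.0) % 360)
        assert l1 == pytest.approx(l0, abs=1e-12)
        assert (a1 - a0) % 360 == pytest.approx(77.0, abs=1e-9)


class TestPopulationStatistics:
    def test_locking_strength_is_plain_mean(self):
        mvs = [_mv(0, 0.2), _mv(10, 0.4)]
        assert population_locking_strength(mvs) == pytest.approx(0.3)

    def test_uniform_population_shows_rayleigh_bias(self, rng):
        # each unit uniform: per-unit length concentrates near sqrt(pi/(4n))
        n = 500
        lengths = [resultant_vector(rng.uniform(0, 360, n))[0] for _ in range(200)]
        expected = np.sqrt(np.pi / (4 * n))
        assert np.mean(lengths) == pytest.approx(expected, rel=0.15)

    def test_concentration_closed_form(self):
        mvs = [_mv(0.0), _mv(90.0)]
        conc = preferred_phase_concentration(mvs, min_units=2)
        assert conc.r == pytest.approx(np.sqrt(0.5), abs=1e-12)
        assert conc.s2 == pytest.approx(1 - np.sqrt(0.5), abs=1e-12)

    def test_identical_angles_have_zero_variance(self):
        mvs = [_mv(33.0, uid=i) for i in range(6)]
        conc = preferred_phase_concentration(mvs)
        assert conc.r == pytest.approx(1.0)
        assert conc.s2 == pytest.approx(0.0, abs=1e-12)

    def test_uniform_angles_have_high_variance(self, rng):
        mvs = [_mv(a, uid=i) for i, a in enumerate(rng.uniform(0, 360, 500))]
        conc = preferred_phase_concentration(mvs)
        assert conc.s2 > 0.9
        assert conc.ci_lower <= conc.r <= conc.ci_upper

    def test_too_few_significant_units_raises(self):
        mvs = [_mv(10.0, p=0.5, uid=i) for i in range(10)]
        with pytest.raises(ValueError):
            preferred_phase_concentration(mvs)


class TestVarianceRatio:
    def test_equal_variances_give_unit_f(self):
        out = variance_ratio_test(0.4, 50, 0.4, 50)
        assert out["F"] == pytest.approx(1.0)
        assert out["p"] == pytest.approx(1.0)

    def test_power_against_strong_contrast(self, rng):
        # kappa 4 vs 0.5 at n = 100 per group: reject at alpha = 0.05
        a = rng.vonmises(0.0, 4.0, 100)
        b = rng.vonmises(0.0, 0.5, 100)
        s2a = 1 - abs(np.exp(1j * a).mean())
        s2b = 1 - abs(np.exp(1j * b).mean())
        assert variance_ratio_test(s2a, 100, s2b, 100)["p"] < 0.05


class TestWatsonWilliams:
    def test_identical_groups_not_rejected(self, rng):
        a = np.degrees(rng.vonmises(1.0, 2.0, 50)) % 360
        out = watson_williams_test(a, a.copy())
        assert out["F"] == pytest.approx(0.0, abs=1e-9)
        assert out["p"] > 0.99

    def test_opposite_means_strongly_rejected(self, rng):
        a = np.degrees(rng.vonmises(0.0, 2.0, 50)) % 360
        b = np.degrees(rng.vonmises(np.pi, 2.0, 50)) % 360
        assert watson_williams_test(a, b)["p"] < 0.001

    def test_low_concentration_flagged(self, rng):
        a = np.degrees(rng.vonmises(0.0, 0.3, 60)) % 360
        b = np.degrees(rng.vonmises(0.5, 0.3, 60)) % 360
        assert watson_williams_test(a, b)["low_concentration"]

    def test_planted_novelty_shift_recovered(self, rng):
        # two populations of preferred phases 30 deg apart
        fam = [_mv(a, p=0.01, uid=i) for i, a in enumerate(np.degrees(rng.vonmises(np.radians(180), 20, 100)) % 360)]
        nov = [_mv(a, p=0.01, uid=i) for i, a in enumerate(np.degrees(rng.vonmises(np.radians(210), 20, 100)) % 360)]
        from placecode.phase_locking import novelty_phase_shift

        out = novelty_phase_shift(fam, nov)
        assert out["shift_deg"] == pytest.approx(30.0, abs=5.0)
        assert out["ww_p"] < 0.01
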