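"""Rate-map statistics against closed forms and planted ground truth."""

import numpy as np
import pytest

from placecode import placemaps as pm
from placecode.session import Arena
from placecode.synth import CONTROL, generate_place_cells, generate_trajectory, sample_cell_params


def _manual_map(rate_grid, occupancy, edges=None):
    rate_grid = np.asarray(rate_grid, dtype=float)
    occ = np.asarray(occupancy, dtype=float)
    visited = occ > 0
    raw = np.where(visited, rate_grid, np.nan)
    n = rate_grid.shape[0]
    edges = edges if edges is not None else np.linspace(-40, 40, n + 1)
    return pm.RateMap(
        raw_rate=raw, smoothed_rate=raw.copy(), occupancy_s=occ, visited=visited, bin_edges=edges
    )


class TestSkaggsInformation:
    def test_uniform_map_carries_no_information(self):
        m = _manual_map(np.full((10, 10), 3.0), np.ones((10, 10)))
        assert pm.skaggs_information(m) == pytest.approx(0.0, abs=1e-12)

    def test_half_occupancy_active_gives_one_bit(self):
        rate = np.zeros((10, 10))
        rate[:5] = 1.0
        m = _manual_map(rate, np.ones((10, 10)))
        assert pm.skaggs_information(m) == pytest.approx(1.0, rel=1e-12)

    def test_invariant_under_rate_rescaling(self):
        rng = np.random.default_rng(3)
        rate = rng.exponential(2.0, (10, 10))
        occ = rng.uniform(0.5, 2.0, (10, 10))
        a = pm.skaggs_information(_manual_map(rate, occ))
        b = pm.skaggs_information(_manual_map(7.5 * rate, occ))
        assert a == pytest.approx(b, rel=1e-12)


class TestFieldSizeAndSparsity:
    def test_uniform_map_extremes(self):
        m = _manual_map(np.full((10, 10), 2.0), np.ones((10, 10)))
        assert pm.field_size_fraction(m) == 1.0
        assert pm.sparsity(m) == pytest.approx(1.0, rel=1e-12)

    def test_single_active_bin(self):
        rate = np.zeros((10, 10))
        rate[4, 4] = 5.0
        occ = np.ones((10, 10))
        occ[4, 4] = 3.0  # occupancy share q = 3/102
        m = _manual_map(rate, occ)
        assert pm.field_size_fraction(m) == pytest.approx(1.0 / 100.0)
        assert pm.sparsity(m) == pytest.approx(3.0 / 102.0, rel=1e-12)

    def test_gaussian_field_matches_analytic_threshold_area(self):
        # lambda = exp(-d^2 / 2 sigma^2) on a fully visited disk: the area
        # above 0.1*peak is a circle of radius sigma*sqrt(2 ln 10)
        n = 70
        edges = np.linspace(-40, 40, n + 1)
        c = 0.5 * (edges[:-1] + edges[1:])
        xx, yy = np.meshgrid(c, c, indexing="ij")
        inside = np.hypot(xx, yy) <= 40.0
        sigma = 10.0
        rate = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
        m = _manual_map(np.where(inside, rate, 0.0), inside.astype(float), edges)
        predicted = np.pi * (sigma**2 * 2 * np.log(10)) / (np.pi * 40.0**2)
        assert pm.field_size_fraction(m) == pytest.approx(predicted, rel=0.05)


class TestCoherence:
    def test_smooth_planted_field_is_coherent(self, foraging_tracking):
        rng = np.random.default_rng(1)
        pars = sample_cell_params(1, CONTROL, Arena(), rng, "pyr")
        pars.center_xy[0] = (0.0, 0.0)
        spikes = generate_place_cells(foraging_tracking, pars, seed=5)[0]
        m = pm.build_rate_map(foraging_tracking, spikes, epoch=(0.0, 1200.0))
        assert pm.coherence(m) > 0.5

    def test_shuffled_rates_are_incoherent(self):
        rng = np.random.default_rng(8)
        rate = rng.exponential(1.0, (70, 70))
        m = _manual_map(rate, np.ones((70, 70)))
        assert abs(pm.coherence(m)) < 0.1

    def test_striped_map_is_anticoherent(self):
        # alternating rows: each bin's 8-neighbour mean is dominated by the
        # opposite stripe, so bin rate and neighbour mean anti-correlate
        rate = np.zeros((20, 20))
        rate[::2] = 2.0
        m = _manual_map(rate, np.ones((20, 20)))
        assert pm.coherence(m) < -0.5


class TestRemappingScore:
    @pytest.mark.parametrize(
        "fr1,fr2,expected", [(2.0, 2.0, 0.0), (3.0, 0.0, 1.0), (3.0, 1.0, 0.5)]
    )
    def test_closed_form(self, fr1, fr2, expected):
        assert pm.remapping_score(fr1, fr2) == pytest.approx(expected)

    def test_silent_in_both_conditions_is_undefined(self):
        assert np.isnan(pm.remapping_score(0.0, 0.0))


class TestRateMapConstruction:
    def test_spike_count_conserved(self, short_bundle):
        ep = short_bundle.epoch_interval("familiar_explore")
        u = short_bundle.units_of_class("pyr")[0]
        m = pm.build_rate_map(short_bundle.tracking, u.spike_times, short_bundle.arena, epoch=ep)
        recovered = np.nansum(m.raw_rate * m.occupancy_s)
        assert recovered == int(round(recovered))  # integer spike count
        assert 0 < recovered <= len(u.spike_times)

    def test_planted_center_recovered(self, foraging_tracking):
        rng = np.random.default_rng(2)
        pars = sample_cell_params(1, CONTROL, Arena(), rng, "pyr")
        pars.center_xy[0] = (5.0, -8.0)
        pars.sigma_cm[0] = 10.0
        spikes = generate_place_cells(foraging_tracking, pars, seed=9)[0]
        m = pm.build_rate_map(foraging_tracking, spikes, epoch=(0.0, 1200.0))
        i, j = np.unravel_index(np.nanargmax(m.smoothed_rate), m.smoothed_rate.shape)
        c = m.bin_centers
        assert np.hypot(c[i] - 5.0, c[j] + 8.0) < 5.0

    def test_all_slow_samples_raises(self):
        import pandas as pd

        from placecode.session import TRACKING_DT

        tr = pd.DataFrame({"t": np.arange(100) * TRACKING_DT, "x": 0.0, "y": 0.0})
        with pytest.raises(ValueError):
            pm.build_rate_map(tr, np.array([1.0]), epoch=(0.0, 2.0))


class TestSpeedRateCorrelation:
    def test_beta_increases_correlation(self, foraging_tracking):
        from placecode.synth import CellParams

        def cell(beta):
            return CellParams(
                "pyr", np.zeros((1, 2)), np.array([np.inf]), np.array([6.0]), np.array([0.0]),
                np.array([beta]), np.array([0.0]), np.array([0.0]), np.array([0.0]),
                np.array([0.0]), np.array([0.0]), np.array([1.0]), np.array([0]),
            )

        rs = []
        for beta in (0.0, 0.03, 0.08):
            spikes = generate_place_cells(foraging_tracking, cell(beta), seed=13)[0]
            r = pm.speed_rate_correlation(foraging_tracking, [spikes], epoch=(0.0, 1200.0))[0]
            rs.append(r)
        assert abs(rs[0]) < 0.08  # no modulation -> no correlation
        assert rs[0] < rs[1] < rs[2]
        assert rs[2] > 0.3


class TestIndexOfDispersion:
    def test_deterministic_equal_counts_give_zero(self, foraging_tracking):
        m = _field_map(sigma=12.0)
        passes = pm.field_passes(foraging_tracking, m, 0.1)
        assert len(passes) >= 10
        spikes = np.sort(np.concatenate([np.linspace(s, e, 3, endpoint=False) for s, e in passes]))
        out = pm.index_of_dispersion(foraging_tracking, spikes, m, levels=(0.1,))
        assert out["dispersion"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_passes_flagged(self, foraging_tracking):
        short = foraging_tracking.head(200)  # ~5 s cannot produce 10 passes
        m = _field_map(sigma=12.0)
        out = pm.index_of_dispersion(short, np.array([1.0]), m, levels=(0.9,))
        assert not out["sufficient"].iloc[0]


def _field_map(sigma):
    n = 70
    edges = np.linspace(-40, 40, n + 1)
    c = 0.5 * (edges[:-1] + edges[1:])
    xx, yy = np.meshgrid(c, c, indexing="ij")
    rate = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
    return pm.RateMap(
        raw_rate=rate, smoothed_rate=rate, occupancy_s=np.ones((n, n)),
        visited=np.ones((n, n), dtype=bool), bin_edges=edges,
    )
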