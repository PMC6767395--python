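"""End-to-end session analysis: the standard per-epoch metric battery.

Composes the module-level operations into the quantities a session-level
comparison needs: place-cell statistics and decoding error for an
exploration epoch, theta phase-locking of the pyramidal population, and
peri-SWR firing during the following sleep epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import lfp_events as le
from . import phase_locking as pl
from . import placemaps as pm
from . import reactivation as ra
from .decoder import decode, decoding_error_summary
from .session import SessionBundle


@dataclass
class EpochMetrics:
    n_cells: int
    n_place_cells: int
    median_field_size_fraction: float
    median_spatial_info_bits: float
    median_decoding_error_cm: float
    mean_speed_rate_r: float
    mean_theta_vector_length: float
    preferred_phase_s2: float
    n_locked: int
    peri_swr_peak_rate_hz: float
    n_swr: int


def explore_sleep_metrics(
    bundle: SessionBundle,
    explore_label: str,
    sleep_label: str,
    *,
    epoch_key: str | None = None,
) -> EpochMetrics:
    """Run the full battery on one exploration epoch and its sleep epoch.

    Place cells are selected by the coherence/sparsity criteria on the
    exploration rate maps; decoding uses the selected cells only, while the
    speed-rate correlation and phase locking use all pyramidal cells.
    """
    ep = bundle.epoch_interval(explore_label)
    sleep_ep = bundle.epoch_interval(sleep_label)
    pyr = bundle.units_of_class("pyr")
    trains = [u.spike_times for u in pyr]

    maps = [pm.build_rate_map(bundle.tracking, s, bundle.arena, epoch=ep) for s in trains]
    stats = [pm.place_cell_stats(m) for m in maps]
    keep = [i for i, s in enumerate(stats) if s.is_place_cell]
    if keep:
        field = float(np.median([stats[i].field_size_fraction for i in keep]))
        info = float(np.median([stats[i].spatial_info_bits_per_spike for i in keep]))
        res = decode(
            bundle.tracking, [trains[i] for i in keep], [maps[i] for i in keep], epoch=ep
        )
        derr = decoding_error_summary(res)["median_error_cm"]
    else:
        field = info = derr = float("nan")

    speed_r = float(np.nanmean(pm.speed_rate_correlation(bundle.tracking, trains, epoch=ep)))

    theta = le.detect_theta_epochs(bundle.lfp, ep)
    phase = le.theta_phase(bundle.lfp)
    mvs = pl.population_mean_vectors(pyr, phase, theta.intervals)
    length = pl.population_locking_strength(mvs) if mvs else float("nan")
    try:
        conc = pl.preferred_phase_concentration(mvs)
        s2, n_locked = conc.s2, conc.n
    except ValueError:
        s2, n_locked = float("nan"), 0

    swrs = le.detect_swrs(bundle.lfp, np.array([sleep_ep]))
    if swrs.n_events >= 10:
        peri = ra.peri_swr_rates(bundle.units, swrs.centers, cell_class="pyr")
        peak = peri.peak_rate()
    else:
        peak = float("nan")

    return EpochMetrics(
        n_cells=len(pyr),
        n_place_cells=len(keep),
        median_field_size_fraction=field,
        median_spatial_info_bits=info,
        median_decoding_error_cm=derr,
        mean_speed_rate_r=speed_r,
        mean_theta_vector_length=length,
        preferred_phase_s2=s2,
        n_locked=n_locked,
        peri_swr_peak_rate_hz=peak,
        n_swr=swrs.n_events,
    )
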