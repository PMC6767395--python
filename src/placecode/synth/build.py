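"""Assemble complete synthetic recording sessions.

``simulate_session`` reproduces the recording-day protocol (rest, familiar
exploration, sleep, novel exploration, sleep) with known ground truth:
trajectories and LFP are preset-independent (so paired genotype contrasts
are not confounded by behaviour), while spike trains carry the preset's
place-field widths, speed gains, theta-phase coupling and SWR burst gains.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..session import TRACKING_DT, Arena, SessionBundle, Unit, make_epoch_table
from .lfp import generate_lfp
from .presets import CONTROL, GenotypePreset
from .spikes import (
    GroundTruth,
    assembly_gain_windows,
    generate_place_cells,
    generate_sleep_spikes,
    sample_cell_params,
)
from .trajectory import generate_trajectory

DEFAULT_EPOCH_PLAN = (
    ("rest_pre", 600.0),
    ("familiar_explore", 1200.0),
    ("sleep_familiar", 1200.0),
    ("novel_explore", 1200.0),
    ("sleep_novel", 1200.0),
)


def _stationary_tracking(t0: float, t1: float, xy: tuple[float, float]) -> pd.DataFrame:
    n = int(round((t1 - t0) / TRACKING_DT))
    t = t0 + np.arange(n) * TRACKING_DT
    return pd.DataFrame({"t": t, "x": np.full(n, xy[0]), "y": np.full(n, xy[1])})


def simulate_session(
    preset: GenotypePreset = CONTROL,
    *,
    seed: int = 0,
    n_pyr: int = 40,
    n_int: int = 8,
    epoch_plan=DEFAULT_EPOCH_PLAN,
    fs: float = 1250.0,
    arena: Arena | None = None,
    mean_speed_cm_s: float = 12.0,
    pause_fraction: float = 0.1,
    swr_rate_hz: float = 0.25,
    sleep_base_rate_pyr_hz: float = 1.0,
    sleep_base_rate_int_hz: float = 8.0,
    rem_rate_pyr_hz: float = 1.5,
    swr_event_gain_sigma: float = 0.8,
    n_assemblies: int = 5,
    reactivation: bool = True,
) -> SessionBundle:
    """Simulate one recording day.

    ``seed`` drives independent child generators for trajectory, LFP and
    spikes, so two presets simulated with the same seed share behaviour and
    field potentials exactly.  ``reactivation=False`` shuffles assembly
    membership during sleep, destroying exploration-to-SWR cofiring
    similarity while leaving single-cell statistics intact.
    """
    arena = arena or Arena()
    ss = np.random.SeedSequence(seed)
    s_traj, s_lfp, s_cells, s_spk, s_gain = [np.random.default_rng(c) for c in ss.spawn(5)]

    epochs = []
    t_cur = 0.0
    for label, dur in epoch_plan:
        epochs.append((label, t_cur, t_cur + dur))
        t_cur += dur
    epochs = make_epoch_table(epochs)

    # --- tracking: foraging in explorations, immobile elsewhere ----------
    frames = []
    rest_xy = (0.0, -arena.radius_cm + 6.0)
    for _, row in epochs.iterrows():
        if "explore" in row["label"]:
            tr = generate_trajectory(
                row["end"] - row["start"],
                arena,
                mean_speed_cm_s=mean_speed_cm_s,
                pause_fraction=pause_fraction,
                t0=row["start"],
                seed=s_traj,
            )
        else:
            tr = _stationary_tracking(row["start"], row["end"], rest_xy)
        frames.append(tr)
    tracking = pd.concat(frames, ignore_index=True)

    # --- LFP --------------------------------------------------------------
    lfp, lfp_gt = generate_lfp(epochs, fs=fs, seed=s_lfp, swr_rate_hz=swr_rate_hz)

    # --- cells ------------------------------------------------------------
    pyr = sample_cell_params(n_pyr, preset, arena, s_cells, "pyr")
    pyr.assembly = s_cells.integers(0, n_assemblies, n_pyr)
    inter = sample_cell_params(n_int, preset, arena, s_cells, "int")
    inter.assembly = s_cells.integers(0, n_assemblies, n_int)

    pyr_trains = [np.empty(0)] * n_pyr
    int_trains = [np.empty(0)] * n_int

    def extend(trains, new):
        return [np.concatenate([a, b]) for a, b in zip(trains, new)]

    for label, key in (("familiar_explore", "familiar"), ("novel_explore", "novel")):
        if label not in set(epochs["label"]):
            continue
        row = epochs[epochs["label"] == label].iloc[0]
        tr = tracking[(tracking["t"] >= row["start"]) & (tracking["t"] < row["end"])]
        gains = assembly_gain_windows(
            np.array([[row["start"], row["end"]]]),
            n_assemblies,
            preset.assembly_gain_sigma,
            s_gain,
        )
        pyr_trains = extend(
            pyr_trains,
            generate_place_cells(
                tr, pyr, epoch=key, phase=lfp_gt.theta_phase, assembly_gains=gains,
                seed=s_spk,
            ),
        )
        int_trains = extend(
            int_trains,
            generate_place_cells(
                tr, inter, epoch=key, phase=lfp_gt.theta_phase, assembly_gains=gains,
                seed=s_spk,
            ),
        )

    # --- sleep/rest spiking ----------------------------------------------
    sleep_iv = epochs.loc[
        epochs["label"].str.startswith(("sleep", "rest")), ["start", "end"]
    ].to_numpy(dtype=float)
    if sleep_iv.size:
        n_events = len(lfp_gt.swr_intervals)
        event_gains = np.exp(
            swr_event_gain_sigma * s_spk.standard_normal((max(n_events, 1), n_assemblies))
            - swr_event_gain_sigma**2 / 2.0
        )
        pyr_sleep = pyr
        if not reactivation:
            import copy

            pyr_sleep = copy.copy(pyr)
            pyr_sleep.assembly = s_spk.permutation(pyr.assembly)
        pyr_trains = extend(
            pyr_trains,
            generate_sleep_spikes(
                pyr_sleep,
                sleep_iv,
                base_rate_hz=sleep_base_rate_pyr_hz,
                swr_intervals=lfp_gt.swr_intervals,
                swr_event_gains=event_gains,
                rem_intervals=lfp_gt.rem_intervals,
                rem_rate_hz=rem_rate_pyr_hz,
                phase=lfp_gt.theta_phase,
                seed=s_spk,
            ),
        )
        int_trains = extend(
            int_trains,
            generate_sleep_spikes(
                inter,
                sleep_iv,
                base_rate_hz=sleep_base_rate_int_hz,
                swr_intervals=lfp_gt.swr_intervals,
                swr_event_gains=event_gains,
                rem_intervals=lfp_gt.rem_intervals,
                rem_rate_hz=sleep_base_rate_int_hz,
                phase=lfp_gt.theta_phase,
                seed=s_spk,
            ),
        )

    units = [Unit(i, "pyr", np.sort(tt)) for i, tt in enumerate(pyr_trains)]
    units += [Unit(n_pyr + i, "int", np.sort(tt)) for i, tt in enumerate(int_trains)]

    gt = GroundTruth(
        preset_label=preset.label,
        pyr=pyr,
        inter=inter,
        swr_times=lfp_gt.swr_times,
        swr_intervals=lfp_gt.swr_intervals,
        rem_intervals=lfp_gt.rem_intervals,
        gamma_gate_phase_deg=lfp_gt.gamma_gate_phase_deg,
    )
    return SessionBundle(
        tracking=tracking, units=units, lfp=lfp, epochs=epochs, arena=arena, ground_truth=gt
    )
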