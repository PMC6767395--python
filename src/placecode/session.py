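"""Core data containers for one recording day.

A session bundles animal tracking, sorted unit spike trains, one or more LFP
channels and an epoch table (rest / exploration / sleep blocks).  Tracking is
sampled on a fixed 25.6 ms clock, the convention all behavioural arithmetic
in :mod:`placecode.behavior` relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: tracking sample interval in seconds (fixed by the acquisition convention)
TRACKING_DT = 0.0256

PYR = "pyr"
INT = "int"

EPOCH_ORDER = (
    "rest_pre",
    "familiar_explore",
    "sleep_familiar",
    "novel_explore",
    "sleep_novel",
)


@dataclass(frozen=True)
class Arena:
    """Circular open-field arena, centred on the origin."""

    diameter_cm: float = 80.0
    shape: str = "circle"

    @property
    def radius_cm(self) -> float:
        return self.diameter_cm / 2.0

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return np.hypot(np.asarray(x), np.asarray(y)) <= self.radius_cm + 1e-9


@dataclass
class Unit:
    """One sorted unit: spike times (s) plus its cell-class label."""

    unit_id: int
    cell_class: str  # "pyr" or "int"
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.cell_class not in (PYR, INT):
            raise ValueError(f"unknown cell class {self.cell_class!r}")

    def spikes_in(self, start: float, end: float) -> np.ndarray:
        i0, i1 = np.searchsorted(self.spike_times, (start, end))
        return self.spike_times[i0:i1]


@dataclass
class LfpData:
    """Multichannel LFP block starting at ``t0`` with sampling rate ``fs``."""

    fs: float
    data: np.ndarray  # (n_channels, n_samples)
    roles: Sequence[str]  # e.g. ("pyramidal_layer", "reference_above_layer")
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.roles):
            raise ValueError("one role per channel required")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, role: str) -> np.ndarray:
        try:
            idx = list(self.roles).index(role)
        except ValueError as err:
            raise KeyError(f"no channel with role {role!r}") from err
        return self.data[idx]

    def sample_index(self, t: np.ndarray) -> np.ndarray:
        idx = np.round((np.asarray(t) - self.t0) * self.fs).astype(int)
        return np.clip(idx, 0, self.n_samples - 1)


def make_epoch_table(spans: Iterable[tuple[str, float, float]]) -> pd.DataFrame:
    df = pd.DataFrame(list(spans), columns=["label", "start", "end"])
    if (df["end"] <= df["start"]).any():
        raise ValueError("epoch end must exceed start")
    df = df.sort_values("start", ignore_index=True)
    if (df["start"].to_numpy()[1:] < df["end"].to_numpy()[:-1] - 1e-9).any():
        raise ValueError("epochs overlap")
    return df


@dataclass
class SessionBundle:
    """All data recorded on one day.

    ``tracking`` is a DataFrame with columns t, x, y (s / cm), ``units`` a list
    of :class:`Unit`, ``epochs`` a label/start/end table, ``ground_truth`` the
    generator's parameter record when the session is synthetic.
    """

    tracking: pd.DataFrame
    units: list[Unit]
    lfp: LfpData
    epochs: pd.DataFrame
    arena: Arena = field(default_factory=Arena)
    ground_truth: object | None = None

    def epoch_interval(self, label: str) -> tuple[float, float]:
        rows = self.epochs[self.epochs["label"] == label]
        if rows.empty:
            raise KeyError(f"no epoch labelled {label!r}")
        return float(rows["start"].iloc[0]), float(rows["end"].iloc[0])

    def epoch_intervals(self, labels: Iterable[str]) -> np.ndarray:
        out = [self.epoch_interval(lb) for lb in labels]
        return np.array(out, dtype=float)

    def tracking_in(self, start: float, end: float) -> pd.DataFrame:
        t = self.tracking["t"].to_numpy()
        i0, i1 = np.searchsorted(t, (start, end))
        return self.tracking.iloc[i0:i1]

    def units_of_class(self, cell_class: str) -> list[Unit]:
        return [u for u in self.units if u.cell_class == cell_class]

    # -- serialization ----------------------------------------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.tracking.to_csv(d / "tracking.csv", index=False)
        rows = []
        for u in self.units:
            rows.append(
                pd.DataFrame(
                    {"unit_id": u.unit_id, "class": u.cell_class, "t": u.spike_times}
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(d / "spikes.csv", index=False)
        np.savez(
            d / "lfp.npz",
            fs=self.lfp.fs,
            t0=self.lfp.t0,
            data=self.lfp.data,
            roles=np.array(self.lfp.roles, dtype=object),
        )
        self.epochs.to_csv(d / "epochs.csv", index=False)
        meta = {"arena_diameter_cm": self.arena.diameter_cm, "arena_shape": self.arena.shape}
        (d / "arena.json").write_text(json.dumps(meta))
        if self.ground_truth is not None and hasattr(self.ground_truth, "to_json"):
            (d / "ground_truth.json").write_text(self.ground_truth.to_json())

    @classmethod
    def load(cls, directory: str | Path) -> "SessionBundle":
        d = Path(directory)
        tracking = pd.read_csv(d / "tracking.csv")
        spikes = pd.read_csv(d / "spikes.csv")
        units = [
            Unit(int(uid), str(grp["class"].iloc[0]), grp["t"].to_numpy())
            for uid, grp in spikes.groupby("unit_id")
        ]
        z = np.load(d / "lfp.npz", allow_pickle=True)
        lfp = LfpData(
            fs=float(z["fs"]), data=z["data"], roles=list(z["roles"]), t0=float(z["t0"])
        )
        epochs = pd.read_csv(d / "epochs.csv")
        meta = json.loads((d / "arena.json").read_text())
        arena = Arena(diameter_cm=meta["arena_diameter_cm"], shape=meta["arena_shape"])
        return cls(tracking=tracking, units=units, lfp=lfp, epochs=epochs, arena=arena)
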