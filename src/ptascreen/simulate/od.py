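"""Synthetic 96-well OD600 curves: logistic growth over a background offset."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class WellSpec:
    """One well: logistic growth parameters plus instrument background.

    OD(t) = K / (1 + ((K - O0)/O0) * exp(-rate * t)) + background + noise,
    with K the carrying capacity and O0 the initial OD.
    """

    initial_od: float
    carrying_capacity: float
    rate_per_min: float
    background_od: float = 0.08
    noise_sd: float = 0.002

    def __post_init__(self) -> None:
        if not 0 < self.initial_od < self.carrying_capacity:
            raise ValueError("require 0 < initial_od < carrying_capacity")
        if self.rate_per_min < 0:
            raise ValueError("rate_per_min must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticODSpec:
    """A plate-reader run: read cadence, duration and the wells to simulate."""

    wells: list[WellSpec] = field(default_factory=list)
    read_interval_min: float = 10.0
    duration_min: float = 960.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.read_interval_min <= 0 or self.duration_min <= 0:
            raise ValueError("read_interval_min and duration_min must be positive")

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(0.0, self.duration_min + 1e-9, self.read_interval_min)


@dataclass
class ODTruth:
    """Per-well true growth rates (and full well specs), keyed by well id."""

    rates_per_min: dict[str, float]
    wells: dict[str, WellSpec]
    rng_seed: int


def logistic_od(well: WellSpec, t_min: np.ndarray) -> np.ndarray:
    """Noiseless OD of a well at the given times (background included)."""
    k, o0 = well.carrying_capacity, well.initial_od
    return k / (1.0 + ((k - o0) / o0) * np.exp(-well.rate_per_min * np.asarray(t_min))) + well.background_od


def simulate_od(spec: SyntheticODSpec) -> tuple[pd.DataFrame, ODTruth]:
    """Simulate the run; returns a long-format table (well, time_min, od)."""
    rng = np.random.default_rng(spec.rng_seed)
    t = spec.times_min
    rows = []
    rates: dict[str, float] = {}
    wells: dict[str, WellSpec] = {}
    for i, w in enumerate(spec.wells):
        well_id = f"W{i + 1:02d}"
        od = logistic_od(w, t)
        if w.noise_sd > 0:
            od = od + rng.normal(0.0, w.noise_sd, size=t.shape)
        rows.append(pd.DataFrame({"well": well_id, "time_min": t, "od": od}))
        rates[well_id] = w.rate_per_min
        wells[well_id] = w
    table = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["well", "time_min", "od"])
    )
    return table, ODTruth(rates, wells, spec.rng_seed)
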