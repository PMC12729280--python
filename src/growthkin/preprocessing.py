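"""Convert raw optical-density records into volume-corrected biomass series.

The measurement chain is: absorbance at 750 nm, times a calibration
coefficient, times the dilution factor, gives biomass concentration in g/L.
Evaporation concentrates the suspension between top-up events, so measured
concentrations are additionally normalized to the nominal working volume via
a piecewise-linear volume ledger.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    CalibrationRangeWarning,
    EmptySeriesError,
    InconsistentLedgerError,
    InvalidInputError,
    ParseError,
)

#: Columns required in a series CSV, in canonical order.
CSV_COLUMNS = [
    "reactor_id",
    "time_h",
    "od750",
    "dilution_factor",
    "temperature_C",
    "added_mL",
]

_REQUIRED_COLUMNS = ["reactor_id", "time_h", "od750", "dilution_factor"]


@dataclass(frozen=True)
class CalibrationSpec:
    """OD-to-biomass calibration: X = od * k_cal * dilution.

    Parameters
    ----------
    k_cal : float
        Calibration coefficient in g/L per OD unit.
    od_linear_range : tuple of float
        (low, high) absorbance bounds of the instrument's linear range;
        readings outside it trigger a :class:`CalibrationRangeWarning`.
    """

    k_cal: float = 0.4
    od_linear_range: tuple[float, float] = (0.3, 0.6)

    def __post_init__(self) -> None:
        if self.k_cal <= 0:
            raise InvalidInputError(f"k_cal must be > 0, got {self.k_cal}")
        low, high = self.od_linear_range
        if not low < high:
            raise InvalidInputError(
                f"od_linear_range must satisfy low < high, got {self.od_linear_range}"
            )


@dataclass(frozen=True)
class VolumeEvent:
    """A recorded water addition (top-up) at ``time_h`` of ``added_mL``."""

    time_h: float
    added_mL: float

    def __post_init__(self) -> None:
        if self.added_mL < 0:
            raise InvalidInputError(f"added_mL must be >= 0, got {self.added_mL}")


@dataclass
class GrowthSeries:
    """One reactor's biomass-vs-time observations.

    Parallel arrays indexed by sample. ``biomass_gL`` holds the as-measured
    concentration; ``biomass_corrected_gL`` and ``volume_L`` are filled by
    :func:`apply_volume_correction`.
    """

    reactor_id: str
    time_h: np.ndarray
    od750: np.ndarray
    dilution_factor: np.ndarray
    biomass_gL: np.ndarray
    temperature_C: np.ndarray | None = None
    biomass_corrected_gL: np.ndarray | None = None
    volume_L: np.ndarray | None = None
    warnings_: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od750 = np.asarray(self.od750, dtype=float)
        self.dilution_factor = np.asarray(self.dilution_factor, dtype=float)
        self.biomass_gL = np.asarray(self.biomass_gL, dtype=float)
        if self.temperature_C is not None:
            self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        n = len(self.time_h)
        for name in ("od750", "dilution_factor", "biomass_gL"):
            if len(getattr(self, name)) != n:
                raise InvalidInputError(f"length mismatch: {name} vs time_h")
        if self.temperature_C is not None and len(self.temperature_C) != n:
            raise InvalidInputError("length mismatch: temperature_C vs time_h")
        if n and np.any(np.diff(self.time_h) <= 0):
            raise InvalidInputError("time_h must be strictly increasing")
        if np.any(self.biomass_gL < 0):
            raise InvalidInputError("biomass_gL must be non-negative")

    def __len__(self) -> int:
        return len(self.time_h)

    @property
    def biomass_for_fitting(self) -> np.ndarray:
        """Volume-corrected biomass when available, measured otherwise."""
        if self.biomass_corrected_gL is not None:
            return self.biomass_corrected_gL
        return self.biomass_gL

    def to_frame(self) -> pd.DataFrame:
        """Tabular view using the documented CSV column schema."""
        n = len(self)
        df = pd.DataFrame(
            {
                "reactor_id": [self.reactor_id] * n,
                "time_h": self.time_h,
                "od750": self.od750,
                "dilution_factor": self.dilution_factor,
                "temperature_C": (
                    self.temperature_C if self.temperature_C is not None else [""] * n
                ),
                "added_mL": [""] * n,
            }
        )
        return df


def od_to_biomass(od: float, n: float, cal: CalibrationSpec) -> float:
    """Biomass concentration (g/L) from an OD750 reading and dilution factor.

    Emits :class:`CalibrationRangeWarning` when ``od`` is outside the
    calibrated linear range; raises for physically impossible inputs.
    """
    od = float(od)
    n = float(n)
    if od < 0:
        raise InvalidInputError(f"od must be >= 0, got {od}")
    if n < 1:
        raise InvalidInputError(f"dilution factor must be >= 1, got {n}")
    low, high = cal.od_linear_range
    if od > 0 and not (low <= od <= high):
        warnings.warn(
            f"OD750={od:g} outside linear range [{low:g}, {high:g}]",
            CalibrationRangeWarning,
            stacklevel=2,
        )
    return od * cal.k_cal * n


def volume_ledger(
    times_h: np.ndarray,
    events: Sequence[VolumeEvent],
    nominal_volume_L: float,
    evaporation_rate_mL_per_h: float = 0.0,
) -> np.ndarray:
    """Actual suspension volume (L) at each sample time.

    V(t) = nominal - evaporation_rate * t + sum of additions at or before t,
    i.e. evaporation is linear in time between recorded top-ups.
    """
    if nominal_volume_L <= 0:
        raise InvalidInputError("nominal_volume_L must be > 0")
    times_h = np.asarray(times_h, dtype=float)
    ev_times = np.array([e.time_h for e in events], dtype=float)
    ev_added = np.array([e.added_mL for e in events], dtype=float) / 1000.0
    if len(ev_times) and np.any(np.diff(ev_times) < 0):
        raise InvalidInputError("volume events must be sorted by time")
    evap_L_h = evaporation_rate_mL_per_h / 1000.0
    added_cum = np.array(
        [ev_added[ev_times <= t].sum() for t in times_h], dtype=float
    )
    vol = nominal_volume_L - evap_L_h * times_h + added_cum
    if np.any(vol <= 0):
        t_bad = times_h[vol <= 0][0]
        raise InconsistentLedgerError(
            f"ledger volume <= 0 at t={t_bad:g} h; check events/evaporation rate"
        )
    return vol


def apply_volume_correction(
    series: GrowthSeries,
    events: Sequence[VolumeEvent],
    nominal_volume_L: float,
    evaporation_rate_mL_per_h: float = 0.0,
) -> GrowthSeries:
    """Normalize measured concentrations to the nominal working volume.

    X_corr(t) = X_meas(t) * V(t) / V_nominal, conserving biomass mass
    exactly. Returns a new series carrying both the measured and corrected
    traces plus the volume ledger.
    """
    vol = volume_ledger(
        series.time_h, events, nominal_volume_L, evaporation_rate_mL_per_h
    )
    corrected = series.biomass_gL * vol / nominal_volume_L
    return replace(
        series,
        biomass_corrected_gL=corrected,
        volume_L=vol,
        warnings_=list(series.warnings_),
    )


def load_series(path: str | Path | io.TextIOBase, cal: CalibrationSpec) -> GrowthSeries:
    """Load one reactor's series from a CSV file matching :data:`CSV_COLUMNS`.

    Biomass is filled via :func:`od_to_biomass`; out-of-range OD rows are
    collected as warning records on the returned series (with line numbers)
    rather than raised.
    """
    try:
        df = pd.read_csv(path, dtype={"reactor_id": str})
    except pd.errors.EmptyDataError as exc:
        raise EmptySeriesError(f"no data in {path}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing required columns: {missing}")
    if df.empty:
        raise EmptySeriesError(f"empty data section in {path}")

    bad = df.index[df["time_h"].isna() | df["od750"].isna() | df["dilution_factor"].isna()]
    if len(bad):
        # +2: header line plus 1-based numbering
        lines = ", ".join(str(i + 2) for i in bad)
        raise ParseError(f"malformed rows at lines {lines}")

    times = df["time_h"].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ParseError("time_h must be strictly increasing")

    reactor_ids = df["reactor_id"].unique()
    if len(reactor_ids) > 1:
        raise ParseError(f"multiple reactor_ids in one file: {list(reactor_ids)}")

    warn_records: list[str] = []
    biomass = np.empty(len(df))
    for i, (od, n) in enumerate(zip(df["od750"], df["dilution_factor"])):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", CalibrationRangeWarning)
            biomass[i] = od_to_biomass(od, n, cal)
        for w in caught:
            warn_records.append(f"line {i + 2}: {w.message}")

    temp = None
    if "temperature_C" in df.columns:
        temp = pd.to_numeric(df["temperature_C"], errors="coerce").to_numpy(dtype=float)

    series = GrowthSeries(
        reactor_id=str(reactor_ids[0]),
        time_h=times,
        od750=df["od750"].to_numpy(dtype=float),
        dilution_factor=df["dilution_factor"].to_numpy(dtype=float),
        biomass_gL=biomass,
        temperature_C=temp,
    )
    series.warnings_ = warn_records
    return series


def extract_events(path: str | Path) -> list[VolumeEvent]:
    """Read top-up events from the optional ``added_mL`` column of a series CSV."""
    df = pd.read_csv(path)
    if "added_mL" not in df.columns:
        return []
    added = pd.to_numeric(df["added_mL"], errors="coerce")
    mask = added.notna() & (added > 0)
    return [
        VolumeEvent(time_h=float(t), added_mL=float(a))
        for t, a in zip(df.loc[mask, "time_h"], added[mask])
    ]


def write_series(series: GrowthSeries, path: str | Path) -> None:
    """Write a series back to the documented CSV schema (round-trip safe)."""
    series.to_frame().to_csv(path, index=False)
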