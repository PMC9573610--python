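"""Growth-window temperature summaries.

Heat stress over a crop's growth period is summarised three ways: the mean
daily temperature, the number of days with mean temperature strictly above
a set of thresholds (16/20/22/30 °C are the agronomically meaningful ones
for pea), and growing-degree-day accumulation (thermal units) above a base
temperature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from peaheat.simdata import TemperatureSeries

#: Thresholds (°C) conventionally reported for pea heat stress.
DEFAULT_THRESHOLDS = (16.0, 20.0, 22.0, 30.0)


@dataclass(frozen=True)
class GrowthWindow:
    """Sowing → flowering → maturity dates of one accession × stage."""

    sowing_date: np.datetime64
    flowering_date: np.datetime64
    maturity_date: np.datetime64

    def __post_init__(self) -> None:
        s = np.datetime64(self.sowing_date, "D")
        f = np.datetime64(self.flowering_date, "D")
        m = np.datetime64(self.maturity_date, "D")
        object.__setattr__(self, "sowing_date", s)
        object.__setattr__(self, "flowering_date", f)
        object.__setattr__(self, "maturity_date", m)
        if not (s < f < m):
            raise ValueError("require sowing < flowering < maturity")

    @property
    def vegetative(self) -> tuple[np.datetime64, np.datetime64]:
        """[sowing, flowering) as an inclusive day range."""
        return self.sowing_date, self.flowering_date - np.timedelta64(1, "D")

    @property
    def reproductive(self) -> tuple[np.datetime64, np.datetime64]:
        """[flowering, maturity] as an inclusive day range."""
        return self.flowering_date, self.maturity_date


@dataclass
class ThermalSummary:
    mean_daily_t: float
    days_above: dict[float, int]
    thermal_units: float


def _slice(series: TemperatureSeries, start: np.datetime64, end: np.datetime64) -> np.ndarray:
    if start < series.dates[0] or end > series.dates[-1]:
        raise ValueError("window outside the temperature series span")
    mask = (series.dates >= start) & (series.dates <= end)
    return series.t_mean[mask]


def heat_stress_days(
    series: TemperatureSeries, window: GrowthWindow, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> dict[float, int]:
    """Days within [sowing, maturity] with mean temperature strictly above each threshold."""
    t = _slice(series, window.sowing_date, window.maturity_date)
    return {float(th): int(np.sum(t > th)) for th in thresholds}


def thermal_units(series: TemperatureSeries, window: GrowthWindow, base_temp: float = 0.0) -> float:
    """Growing-degree-day sum Σ max(0, t_mean − base) over [sowing, maturity]."""
    if not np.isfinite(base_temp):
        raise ValueError("base_temp must be finite")
    t = _slice(series, window.sowing_date, window.maturity_date)
    return float(np.sum(np.maximum(0.0, t - base_temp)))


def window_mean(series: TemperatureSeries, window: GrowthWindow) -> float:
    """Arithmetic mean of daily means over [sowing, maturity]."""
    t = _slice(series, window.sowing_date, window.maturity_date)
    if t.size == 0:
        raise ValueError("empty window")
    return float(np.mean(t))


def summarize(
    series: TemperatureSeries,
    window: GrowthWindow,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    base_temp: float = 0.0,
) -> ThermalSummary:
    return ThermalSummary(
        mean_daily_t=window_mean(series, window),
        days_above=heat_stress_days(series, window, thresholds),
        thermal_units=thermal_units(series, window, base_temp),
    )
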