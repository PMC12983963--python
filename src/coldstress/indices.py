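"""Environmental cold-stress indices: THI and wind-chill temperature.

The temperature-humidity index follows the common livestock form

    THI = (1.8 T + 32) - (0.55 - 0.0055 RH) (1.8 T - 26)

with T in deg C and RH in percent; alternate forms can be registered via
:func:`register_thi_formula`.  Wind chill uses the JAG/TI formulation
adopted by the US and Canadian weather services (wind in km/h, valid for
wind above 4.8 km/h; calm air returns the air temperature unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError

__all__ = [
    "EnvironmentReading",
    "thi",
    "wct",
    "thi_category",
    "register_thi_formula",
    "add_indices",
    "WCT_CALM_LIMIT_KMH",
]

#: Below this wind speed (km/h) the wind-chill convention returns T.
WCT_CALM_LIMIT_KMH = 4.8


@dataclass(frozen=True)
class EnvironmentReading:
    """One reading of temperature (deg C), RH (%) and wind speed (km/h)."""

    temperature: float
    relative_humidity: float
    wind_speed: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.relative_humidity <= 100.0:
            raise DomainError(
                f"relative humidity must be in [0, 100] %, got "
                f"{self.relative_humidity}"
            )
        if self.wind_speed < 0:
            raise DomainError(f"wind speed must be >= 0, got {self.wind_speed}")


def _thi_nrc(t: float, rh: float) -> float:
    return (1.8 * t + 32.0) - (0.55 - 0.0055 * rh) * (1.8 * t - 26.0)


_THI_FORMULAS: dict[str, Callable[[float, float], float]] = {"nrc": _thi_nrc}


def register_thi_formula(name: str, fn: Callable[[float, float], float]) -> None:
    """Register an alternate THI formula ``fn(temperature_c, rh_pct)``."""
    _THI_FORMULAS[name] = fn


def thi(reading: EnvironmentReading, formula: str = "nrc") -> float:
    """Temperature-humidity index of one reading."""
    try:
        fn = _THI_FORMULAS[formula]
    except KeyError:
        raise ConfigurationError(
            f"unknown THI formula {formula!r}; registered: "
            f"{sorted(_THI_FORMULAS)}"
        ) from None
    return float(fn(reading.temperature, reading.relative_humidity))


def wct(reading: EnvironmentReading) -> float:
    """Wind-chill temperature (deg C) of one reading.

    Continuous in wind speed except at the 4.8 km/h calm-air convention
    boundary, where it jumps from T to the formula value.
    """
    t, v = reading.temperature, reading.wind_speed
    if v <= WCT_CALM_LIMIT_KMH:
        return float(t)
    v16 = v**0.16
    return float(13.12 + 0.6215 * t - 11.37 * v16 + 0.3965 * t * v16)


def thi_category(
    thi_value: float, cutpoints: Sequence[float]
) -> int:
    """Bin a THI value against strictly increasing cutpoints.

    Bins are right-open: a value equal to a cutpoint falls in the lower
    bin; values above the last cutpoint get the top category.  Returns
    the 0-based category index.
    """
    cuts = list(cutpoints)
    if not cuts:
        raise ConfigurationError("at least one cutpoint is required")
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise ConfigurationError("cutpoints must be strictly increasing")
    return int(np.searchsorted(cuts, thi_value, side="left"))


def add_indices(records: pd.DataFrame, formula: str = "nrc") -> pd.DataFrame:
    """Append ``thi`` and ``wct`` columns to a records table.

    Expects ``temperature_c``, ``humidity_pct`` and ``wind`` columns in
    the standard record schema; returns a copy.
    """
    out = records.copy()
    readings = [
        EnvironmentReading(t, h, w)
        for t, h, w in zip(out["temperature_c"], out["humidity_pct"], out["wind"])
    ]
    out["thi"] = [thi(r, formula=formula) for r in readings]
    out["wct"] = [wct(r) for r in readings]
    return out
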