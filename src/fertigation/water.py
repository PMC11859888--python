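"""Seasonal water budget for a drip-irrigated crop.

Crop water consumption (evapotranspiration, ET) is estimated by the water
balance over the growth period,

    ET = I + Pr + U - D - R - dW,

where all terms are depths in mm: ``I`` irrigation, ``Pr`` effective
precipitation, ``U`` groundwater recharge, ``D`` deep drainage, ``R``
surface runoff and ``dW`` the change in 0-80 cm soil water storage
(storage at harvest minus storage at planting, so a drawdown is negative
and *adds* to ET).  On flat ground with deep groundwater the U, D and R
terms are negligible and the budget simplifies to ``ET = I + Pr - dW``.

Total water input (TWI) is simply ``I + Pr`` and is the covariate used by
the pooled response-surface analysis.  Irrigation doses are commonly
quoted in m3/ha; 1 mm of depth over one hectare is exactly 10 m3, so the
unit bridge is a factor of 10.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

__all__ = [
    "SeasonWater",
    "IncompleteBudgetError",
    "evapotranspiration",
    "total_water_input",
    "mm_to_m3ha",
    "m3ha_to_mm",
    "effective_precipitation",
]


class IncompleteBudgetError(ValueError):
    """A full water-balance computation was requested with missing terms."""


MM_PER_M3HA = 0.1  # 1 m3/ha spread over 1 ha = 0.1 mm depth


def mm_to_m3ha(x: float) -> float:
    """Convert a water depth in mm to a volume per hectare in m3/ha."""
    return x * 10.0


def m3ha_to_mm(x: float) -> float:
    """Convert a volume per hectare in m3/ha to a depth in mm."""
    return x / 10.0


@dataclass
class SeasonWater:
    """Water-budget terms for one growing season (all depths in mm).

    ``runoff``, ``drainage`` and ``groundwater`` may be ``None`` to mean
    "not measured"; the simplified budget ignores them and the full budget
    refuses to proceed without them.
    """

    year: str
    irrigation_mm: float
    precip_mm: float
    delta_storage_mm: float = 0.0
    runoff_mm: float | None = field(default=0.0)
    drainage_mm: float | None = field(default=0.0)
    groundwater_mm: float | None = field(default=0.0)

    def __post_init__(self) -> None:
        if self.irrigation_mm < 0:
            raise ValueError(f"irrigation must be >= 0, got {self.irrigation_mm}")
        if self.precip_mm < 0:
            raise ValueError(f"precipitation must be >= 0, got {self.precip_mm}")

    @classmethod
    def from_m3ha(cls, year: str, irrigation_m3ha: float, precip_mm: float,
                  delta_storage_mm: float = 0.0, **kw) -> "SeasonWater":
        """Build a record with the irrigation dose given in m3/ha."""
        return cls(year, m3ha_to_mm(irrigation_m3ha), precip_mm,
                   delta_storage_mm, **kw)

    @property
    def irrigation_m3ha(self) -> float:
        return mm_to_m3ha(self.irrigation_mm)


def evapotranspiration(w: SeasonWater, simplified: bool = True) -> float:
    """Seasonal crop water consumption (mm) by the water-balance method.

    With ``simplified=True`` runoff, drainage and groundwater recharge are
    dropped: ``ET = I + Pr - dW``.  A non-positive result is physically
    inconsistent; it is returned as-is but logged as a warning so that the
    offending season record can be inspected.
    """
    for name in ("irrigation_mm", "precip_mm", "delta_storage_mm"):
        v = getattr(w, name)
        if v is None or not math.isfinite(v):
            raise IncompleteBudgetError(f"{name} missing or non-finite for year {w.year}")
    if simplified:
        et = w.irrigation_mm + w.precip_mm - w.delta_storage_mm
    else:
        extras = {"runoff_mm": w.runoff_mm, "drainage_mm": w.drainage_mm,
                  "groundwater_mm": w.groundwater_mm}
        missing = [k for k, v in extras.items() if v is None or not math.isfinite(v)]
        if missing:
            raise IncompleteBudgetError(
                f"full water budget for year {w.year} missing terms: {', '.join(missing)}")
        et = (w.irrigation_mm + w.precip_mm + w.groundwater_mm
              - w.drainage_mm - w.runoff_mm - w.delta_storage_mm)
    if et <= 0:
        logger.warning("non-positive ET (%.2f mm) for year %s: budget terms "
                       "are inconsistent", et, w.year)
    return et


def total_water_input(w: SeasonWater) -> float:
    """Irrigation plus effective precipitation (mm); independent of storage."""
    for name in ("irrigation_mm", "precip_mm"):
        v = getattr(w, name)
        if v is None or not math.isfinite(v):
            raise IncompleteBudgetError(f"{name} missing or non-finite for year {w.year}")
    return w.irrigation_mm + w.precip_mm


def effective_precipitation(events_mm, threshold_mm: float = 0.0) -> float:
    """Sum precipitation events, ignoring events below ``threshold_mm``.

    The default threshold of 0 reproduces the raw growth-period total; a
    positive threshold applies the common agronomic convention that very
    small events evaporate before infiltrating.
    """
    if threshold_mm < 0:
        raise ValueError("threshold must be >= 0")
    return float(sum(e for e in events_mm if e >= threshold_mm and e > 0))
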