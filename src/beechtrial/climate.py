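"""Climate-of-origin summaries and aridity indices from monthly normals.

Each provenance origin is characterized by 12 monthly mean temperatures (°C)
and 12 monthly precipitation sums (mm).  From these the module derives the
mean annual temperature (MAT), mean annual precipitation (MAP), early
growing-season precipitation April–June (MSP), the forest aridity index (FAI)
and Ellenberg's climate quotient (EQ).  The global aridity index (GAI) is a
database product and is only ever passed through, never computed.

FAI = 100 · T_Jul–Aug / (P_May–Jul + P_Jul–Aug): the mean July–August
temperature over the sum of May-to-July and July-to-August precipitation, so
July rain — falling in the period of peak evaporative demand — counts twice.
EQ = T_Jul / MAP × 1000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MonthlyClimate",
    "ClimateIndices",
    "climate_summaries",
    "forest_aridity_index",
    "ellenberg_quotient",
    "climate_indices",
]


@dataclass
class MonthlyClimate:
    """Monthly climate normals for one provenance origin.

    ``tmean_c`` and ``prec_mm`` are indexed January..December (length 12).
    """

    provenance: str
    tmean_c: np.ndarray
    prec_mm: np.ndarray
    gai: float | None = None

    def __post_init__(self):
        self.tmean_c = np.asarray(self.tmean_c, dtype=float)
        self.prec_mm = np.asarray(self.prec_mm, dtype=float)
        if self.tmean_c.shape != (12,) or self.prec_mm.shape != (12,):
            raise ValueError(
                f"{self.provenance}: need exactly 12 monthly values for T and P"
            )
        if np.any(~np.isfinite(self.tmean_c)) or np.any(~np.isfinite(self.prec_mm)):
            raise ValueError(f"{self.provenance}: non-finite monthly values")
        if np.any(self.prec_mm < 0):
            raise ValueError(f"{self.provenance}: negative precipitation")


@dataclass
class ClimateIndices:
    """Per-provenance climate covariates (the Table-1-style column set)."""

    provenance: str
    mat_c: float
    map_mm: float
    msp_mm: float
    eq: float
    fai: float
    gai: float | None = None


def climate_summaries(mc: MonthlyClimate) -> tuple[float, float, float]:
    """(MAT, MAP, MSP): annual mean temperature, annual and April–June rain."""
    mat = float(np.mean(mc.tmean_c))
    map_ = float(np.sum(mc.prec_mm))
    msp = float(np.sum(mc.prec_mm[3:6]))  # April, May, June
    return mat, map_, msp


def forest_aridity_index(mc: MonthlyClimate, *, interval_mean: bool = True) -> float:
    """Forest aridity index with double-weighted July precipitation.

    ``interval_mean=True`` (default) uses the arithmetic mean of the July and
    August monthly temperatures for T_Jul–Aug; ``False`` uses July alone.
    """
    t_jul, t_aug = mc.tmean_c[6], mc.tmean_c[7]
    t_summer = (t_jul + t_aug) / 2.0 if interval_mean else t_jul
    p_may_jul = float(np.sum(mc.prec_mm[4:7]))  # May, June, July
    p_jul_aug = float(np.sum(mc.prec_mm[6:8]))  # July, August
    denom = p_may_jul + p_jul_aug
    if denom <= 0:
        raise ValueError(f"{mc.provenance}: zero summer precipitation, FAI undefined")
    return 100.0 * t_summer / denom


def ellenberg_quotient(t_jul_c: float, map_mm: float) -> float:
    """Ellenberg climate quotient EQ = T_Jul / MAP × 1000."""
    if map_mm <= 0:
        raise ValueError("annual precipitation must be positive")
    return t_jul_c / map_mm * 1000.0


def climate_indices(mc: MonthlyClimate, **fai_kwargs) -> ClimateIndices:
    """All per-provenance indices in one pass (GAI echoed unchanged)."""
    mat, map_, msp = climate_summaries(mc)
    return ClimateIndices(
        provenance=mc.provenance,
        mat_c=mat,
        map_mm=map_,
        msp_mm=msp,
        eq=ellenberg_quotient(float(mc.tmean_c[6]), map_),
        fai=forest_aridity_index(mc, **fai_kwargs),
        gai=mc.gai,
    )
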