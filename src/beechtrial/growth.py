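"""Allometric growth traits: timber volume, aboveground biomass, increments.

All equations are beech-specific empirical allometries operating on diameter
at breast height (DBH, cm) and tree height (m).  The stem is treated as a
breast-height cylinder corrected by Bergel's form factor; aboveground biomass
follows a two-predictor power law.  Increments divide by elapsed time:
aboveground biomass increment (ABI, kg yr⁻¹) over the life of the stand since
planting, basal area increment (BAI, cm² yr⁻¹) between two inventories.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date

__all__ = [
    "TreeInventory",
    "GrowthTraits",
    "form_factor",
    "timber_volume",
    "aboveground_biomass",
    "basal_area_cm2",
    "growth_increments",
    "DEFAULT_STAND_AGE_YR",
]

logger = logging.getLogger(__name__)

#: Default elapsed time planting → final inventory (years): a 1995-established
#: stand surveyed in August 2014.
DEFAULT_STAND_AGE_YR = 19.0

# Bergel's beech form-factor coefficients.  The D² term is 4.2e-6 (a printed
# exponent of +6 in circulation is a typo: it would give f ~ 1e8 for any tree,
# while 1e-6 reproduces realistic beech form factors near 0.5).
_FF_C0 = 0.4039
_FF_CH = 0.0017335
_FF_CHINV = 1.1267
_FF_CD3 = 118.188
_FF_CD2 = 4.2e-6


def form_factor(dbh_cm: float, height_m: float) -> float:
    """Bergel form factor f converting a breast-height cylinder to stem volume.

    ``f = 0.4039 + 0.0017335·H + 1.1267/H − 118.188/D³ + 4.2e-6·D²``.
    Raises when D is so small that the −118.188/D³ term drives f ≤ 0 (outside
    the calibrated domain).
    """
    if dbh_cm <= 0 or height_m <= 0:
        raise ValueError("DBH and height must be positive")
    f = (
        _FF_C0
        + _FF_CH * height_m
        + _FF_CHINV / height_m
        - _FF_CD3 / dbh_cm**3
        + _FF_CD2 * dbh_cm**2
    )
    if f <= 0:
        raise ValueError(
            f"form factor non-positive (f={f:.4g}) for DBH={dbh_cm} cm, "
            f"H={height_m} m; tree outside the allometry's domain"
        )
    return f


def timber_volume(dbh_cm: float, height_m: float) -> float:
    """Standing timber volume V (m³): π ((D/100)/2)² · H · f."""
    f = form_factor(dbh_cm, height_m)
    return math.pi * (dbh_cm / 100.0 / 2.0) ** 2 * height_m * f


def aboveground_biomass(dbh_cm: float, height_m: float) -> float:
    """Aboveground biomass AGB (kg) = 0.00523 · D^2.12 · H^0.655."""
    if dbh_cm <= 0 or height_m <= 0:
        raise ValueError("DBH and height must be positive")
    return 0.00523 * dbh_cm**2.12 * height_m**0.655


def basal_area_cm2(dbh_cm: float) -> float:
    """Stem basal area (cm²) at breast height."""
    if dbh_cm <= 0:
        raise ValueError("DBH must be positive")
    return math.pi * (dbh_cm / 2.0) ** 2


@dataclass(frozen=True)
class TreeInventory:
    """One inventory record for one tree."""

    tree_id: str
    provenance: str
    block: str
    dbh_cm: float
    height_m: float
    survey_date: date

    def __post_init__(self):
        if self.dbh_cm <= 0 or self.height_m <= 0:
            raise ValueError(f"{self.tree_id}: DBH and height must be positive")


@dataclass
class GrowthTraits:
    """Derived growth traits for one tree."""

    tree_id: str
    form_factor: float
    volume_m3: float
    agb_kg: float
    abi_kg_yr: float | None  # needs stand age
    bai_cm2_yr: float | None  # needs two surveys


def growth_increments(
    surveys: list[TreeInventory],
    stand_age_yr: float = DEFAULT_STAND_AGE_YR,
) -> GrowthTraits:
    """Growth traits from a tree's inventory time series.

    ABI divides the final-survey AGB by the elapsed years since planting
    (sapling starting biomass treated as negligible).  BAI uses the first and
    last surveys only: ``(BA_last − BA_first) / Δyears`` with Δyears taken as
    exact day counts / 365.25.  A single survey yields ABI but no BAI.
    """
    if not surveys:
        raise ValueError("at least one survey required")
    ordered = sorted(surveys, key=lambda s: s.survey_date)
    dates = [s.survey_date for s in ordered]
    if len(set(dates)) != len(dates):
        raise ValueError("duplicate survey dates")
    final = ordered[-1]

    ff = form_factor(final.dbh_cm, final.height_m)
    vol = timber_volume(final.dbh_cm, final.height_m)
    agb = aboveground_biomass(final.dbh_cm, final.height_m)
    abi = agb / stand_age_yr if stand_age_yr > 0 else None

    bai = None
    if len(ordered) >= 2:
        first = ordered[0]
        dyears = (final.survey_date - first.survey_date).days / 365.25
        dba = basal_area_cm2(final.dbh_cm) - basal_area_cm2(first.dbh_cm)
        if dba < 0:
            logger.warning(
                "%s: DBH shrank between surveys; BAI negative", final.tree_id
            )
        bai = dba / dyears

    return GrowthTraits(
        tree_id=final.tree_id,
        form_factor=ff,
        volume_m3=vol,
        agb_kg=agb,
        abi_kg_yr=abi,
        bai_cm2_yr=bai,
    )
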