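"""Vessel-based and foliar trait derivation from branch cross-sections.

Vessels are recorded as major/minor radii (``a``, ``b``, μm) measured on
transverse sections; each pair is collapsed into an idealized lumen diameter
``D`` that preserves the lumen's hydraulic behaviour.  Population-level traits
follow: vessel density (VD, n mm⁻²), the lumen-to-sapwood area ratio (%), the
hydraulically weighted diameter D_h = ΣD⁵/ΣD⁴ (μm), and the Hagen–Poiseuille
theoretical conductivities, normalized either by sapwood area (KS_theo) or by
the distal leaf area the branch supplies (KL_theo).

Unit policy: radii are carried in μm and areas in mm² (the reporting units of
branch-level wood anatomy); conversion to SI happens only inside the
conductivity computation, where the Hagen–Poiseuille equation requires metres.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Dynamic viscosity of water at 20 °C, MPa s.
ETA_WATER_20C = 1.002e-9
#: Density of water at 20 °C, kg m⁻³.
RHO_WATER_20C = 998.2

__all__ = [
    "ETA_WATER_20C",
    "RHO_WATER_20C",
    "VesselRecord",
    "CrossSectionSample",
    "AnatomyTraits",
    "FoliarTraits",
    "ellipse_diameter",
    "hydraulic_diameter",
    "vessel_lumen_area",
    "sapwood_from_cross_section",
    "theoretical_conductivity",
    "cross_section_traits",
    "foliar_traits",
]


def ellipse_diameter(a: float, b: float) -> float:
    """Idealized lumen diameter (μm) of an elliptical vessel.

    ``D = ((32 (ab)^3) / (a^2 + b^2))^(1/4)`` with ``a`` the major and ``b``
    the minor radius in μm.  For a circle (``a == b``) this reduces to the
    ordinary diameter ``2a``.  The idealized diameter is the diameter of the
    circular capillary with the same laminar (Poiseuille) conductance as the
    elliptical one, so D decreases as the lumen flattens at constant size.

    Inputs with ``a < b`` are swapped with a warning: particle-analysis tools
    do not guarantee axis ordering.
    """
    if a <= 0 or b <= 0:
        raise ValueError(f"vessel radii must be positive, got a={a}, b={b}")
    if a < b:
        logger.warning("major radius a=%g < minor radius b=%g; swapping", a, b)
        a, b = b, a
    return (32.0 * (a * b) ** 3 / (a * a + b * b)) ** 0.25


def hydraulic_diameter(diameters: Sequence[float]) -> float:
    """Hydraulically weighted vessel diameter D_h = ΣD⁵/ΣD⁴ (μm).

    D_h weights each vessel by its contribution to total conductance (∝ D⁴),
    so D_h ≥ mean(D) always, with equality only for a uniform population.
    """
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise ValueError("hydraulic_diameter requires at least one vessel")
    if np.any(d <= 0):
        raise ValueError("vessel diameters must be positive")
    d4 = d**4
    return float(np.sum(d4 * d) / np.sum(d4))


def vessel_lumen_area(diameters: Sequence[float]) -> float:
    """Cumulative lumen area (μm²) as Σ π(D/2)² over idealized diameters."""
    d = np.asarray(diameters, dtype=float)
    return float(np.sum(np.pi * (d / 2.0) ** 2))


# Sapwood-area regression for beech branch segments: A_xylem = c0 + c1 * A_cross,
# both in mm².  Positivity requires A_cross > -c0/c1 ≈ 4.825 mm².
_SAPWOOD_INTERCEPT = -3.715
_SAPWOOD_SLOPE = 0.770


def sapwood_from_cross_section(a_cross_mm2: float) -> float:
    """Sapwood area (mm², pith and bark excluded) from full cross-section area.

    Uses the published beech branch-segment regression
    ``A_xylem = -3.715 + 0.770 A_cross``.  Raises for cross-sections at or
    below the positivity root (≈ 4.825 mm²), where the regression leaves the
    calibrated domain.
    """
    root = -_SAPWOOD_INTERCEPT / _SAPWOOD_SLOPE
    if a_cross_mm2 <= root:
        raise ValueError(
            f"A_cross={a_cross_mm2:g} mm² is at or below the positivity "
            f"threshold {root:.4g} mm² of the sapwood regression"
        )
    return _SAPWOOD_INTERCEPT + _SAPWOOD_SLOPE * a_cross_mm2


def theoretical_conductivity(diameters_um: Sequence[float], area_m2: float) -> float:
    """Hagen–Poiseuille conductivity (kg m⁻¹ MPa⁻¹ s⁻¹) of a vessel population.

    ``K = ((π ΣD⁴ / 128 η) ρ) / A`` with D in metres, η = 1.002e-9 MPa s and
    ρ = 998.2 kg m⁻³ (water at 20 °C).  ``area_m2`` is the normalizing area in
    m²: sapwood area for KS_theo, cumulative leaf area for KL_theo.
    """
    if area_m2 <= 0:
        raise ValueError("normalizing area must be positive")
    d_m = np.asarray(diameters_um, dtype=float) * 1e-6
    sum_d4 = float(np.sum(d_m**4))
    return (np.pi * sum_d4 / (128.0 * ETA_WATER_20C)) * RHO_WATER_20C / area_m2


@dataclass(frozen=True)
class VesselRecord:
    """One vessel: major radius ``a``, minor radius ``b`` (μm)."""

    a: float
    b: float

    @property
    def diameter(self) -> float:
        return ellipse_diameter(self.a, self.b)


@dataclass
class CrossSectionSample:
    """One branch cross-section with its vessels and branch-level metadata.

    ``a_xylem_mm2`` may be omitted; it is then regressed from ``a_cross_mm2``.
    ``leaf_area_m2`` (cumulative distal leaf area A_L) is needed only for the
    leaf-specific conductivity.
    """

    branch_id: str
    vessels: list[VesselRecord] = field(default_factory=list)
    a_cross_mm2: float | None = None
    a_xylem_mm2: float | None = None
    branch_age_yr: int | None = None
    leaf_area_m2: float | None = None

    def xylem_area_mm2(self) -> float:
        if self.a_xylem_mm2 is not None:
            if self.a_xylem_mm2 <= 0:
                raise ValueError(f"{self.branch_id}: A_xylem must be positive")
            if self.a_cross_mm2 is not None and self.a_xylem_mm2 > self.a_cross_mm2:
                raise ValueError(f"{self.branch_id}: A_xylem exceeds A_cross")
            return self.a_xylem_mm2
        if self.a_cross_mm2 is None:
            raise ValueError(f"{self.branch_id}: neither A_xylem nor A_cross given")
        return sapwood_from_cross_section(self.a_cross_mm2)


@dataclass
class AnatomyTraits:
    """Derived per-branch wood-anatomy traits (reporting units of the field)."""

    branch_id: str
    n_vessels: int
    d_mean_um: float
    d_hyd_um: float
    vessel_density_mm2: float  # n mm⁻²
    lumen_fraction_pct: float  # A_lumen : A_xylem, %
    ks_theo: float  # kg m⁻¹ MPa⁻¹ s⁻¹
    kl_theo: float | None  # kg m⁻¹ MPa⁻¹ s⁻¹, None when A_L unknown
    a_growth_mm2_yr: float | None  # A_xylem / branch age


def cross_section_traits(
    sample: CrossSectionSample, *, lumen_area: str = "idealized"
) -> AnatomyTraits:
    """Derive all vessel-population traits for one branch cross-section.

    ``lumen_area`` chooses how a single vessel's lumen area is computed:
    ``"idealized"`` uses π(D/2)² from the idealized diameter (default),
    ``"ellipse"`` uses the true ellipse area πab.  The two differ only for
    eccentric vessels.
    """
    if not sample.vessels:
        raise ValueError(f"{sample.branch_id}: no vessels in sample")
    if lumen_area not in ("idealized", "ellipse"):
        raise ValueError(f"unknown lumen_area mode {lumen_area!r}")

    diameters = np.array([v.diameter for v in sample.vessels])
    a_xylem_mm2 = sample.xylem_area_mm2()
    a_xylem_um2 = a_xylem_mm2 * 1e6

    if lumen_area == "idealized":
        lumen_um2 = vessel_lumen_area(diameters)
    else:
        lumen_um2 = float(
            sum(math.pi * v.a * v.b for v in sample.vessels)
        )

    ks = theoretical_conductivity(diameters, a_xylem_mm2 * 1e-6)
    kl = None
    if sample.leaf_area_m2 is not None:
        if sample.leaf_area_m2 <= 0:
            raise ValueError(f"{sample.branch_id}: leaf area must be positive")
        kl = theoretical_conductivity(diameters, sample.leaf_area_m2)

    a_growth = None
    if sample.branch_age_yr is not None:
        if sample.branch_age_yr < 1:
            raise ValueError(f"{sample.branch_id}: branch age must be ≥ 1 yr")
        a_growth = a_xylem_mm2 / sample.branch_age_yr

    return AnatomyTraits(
        branch_id=sample.branch_id,
        n_vessels=len(sample.vessels),
        d_mean_um=float(np.mean(diameters)),
        d_hyd_um=hydraulic_diameter(diameters),
        vessel_density_mm2=len(sample.vessels) / a_xylem_mm2,
        lumen_fraction_pct=lumen_um2 / a_xylem_um2 * 100.0,
        ks_theo=ks,
        kl_theo=kl,
        a_growth_mm2_yr=a_growth,
    )


@dataclass
class FoliarTraits:
    """Leaf morphology plus pass-through foliar chemistry."""

    a_leaf_cm2: float | None  # mean single-leaf area
    sla_cm2_g: float | None  # specific leaf area
    huber_e4: float | None  # A_S : A_L in 10⁻⁴ m² m⁻²
    chemistry: dict[str, float] = field(default_factory=dict)


def foliar_traits(
    total_leaf_area_cm2: float,
    leaf_dry_mass_g: float,
    n_leaves: int,
    a_sapwood_m2: float | None = None,
    a_leaf_total_m2: float | None = None,
    chemistry: dict[str, float] | None = None,
) -> FoliarTraits:
    """Mean leaf size, SLA and Huber value; chemistry columns pass through.

    SLA = total leaf area / dry mass (cm² g⁻¹), missing when the dry mass is
    zero.  The Huber value A_S : A_L is reported in the conventional
    10⁻⁴ m² m⁻² units.
    """
    if n_leaves < 1:
        raise ValueError("n_leaves must be ≥ 1")
    if total_leaf_area_cm2 < 0 or leaf_dry_mass_g < 0:
        raise ValueError("areas and masses must be non-negative")

    a_leaf = total_leaf_area_cm2 / n_leaves
    sla = total_leaf_area_cm2 / leaf_dry_mass_g if leaf_dry_mass_g > 0 else None

    huber = None
    if a_sapwood_m2 is not None and a_leaf_total_m2 is not None:
        if a_leaf_total_m2 <= 0:
            raise ValueError("cumulative leaf area must be positive")
        huber = (a_sapwood_m2 / a_leaf_total_m2) / 1e-4

    return FoliarTraits(
        a_leaf_cm2=a_leaf,
        sla_cm2_g=sla,
        huber_e4=huber,
        chemistry=dict(chemistry or {}),
    )
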