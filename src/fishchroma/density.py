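"""Crowding-density estimation from sea-cage geometry.

During crowding the cage is lifted so the school occupies the pyramidal
bottom section.  The school volume is taken as a cone/pyramid,
V = area * depth / 3 (the formula is identical for a right cone and a
square pyramid), with depth derived from the observed surface area by
geometric similarity to the full pyramid.  Density is biomass over volume
in kg/m^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "CageGeometry",
    "DensityEstimate",
    "cone_volume",
    "depth_from_similarity",
    "packing_density",
    "estimate_density",
]

# The experimental cage: 5 x 5 x 5 m box over a pyramidal bottom, total
# volume 149.17 m^3.  The pyramid depth is not stated; it is back-derived as
# depth = 3 * (149.17 - 5*5*5) / 5^2 = 2.9004 m.
BOX_SIDE = 5.0
BOX_DEPTH = 5.0
TOTAL_VOLUME = 149.17
PYRAMID_DEPTH = 3.0 * (TOTAL_VOLUME - BOX_SIDE**2 * BOX_DEPTH) / BOX_SIDE**2


@dataclass
class CageGeometry:
    """Sea-cage dimensions; the invariant total = box + pyramid is enforced."""

    box_side: float = BOX_SIDE
    box_depth: float = BOX_DEPTH
    pyramid_depth: float = PYRAMID_DEPTH
    total_volume: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        derived = (
            self.box_side**2 * self.box_depth
            + self.box_side**2 * self.pyramid_depth / 3.0
        )
        if self.total_volume is None:
            self.total_volume = derived
        elif not math.isclose(self.total_volume, derived, rel_tol=1e-3):
            raise ValueError(
                f"total_volume {self.total_volume} inconsistent with dimensions ({derived:.4f})"
            )


@dataclass
class DensityEstimate:
    school_area: float  # m^2
    school_depth: float  # m
    volume: float  # m^3
    biomass: float  # kg
    density: float  # kg/m^3

    def to_dict(self):
        return {k: float(v) for k, v in self.__dict__.items()}


def cone_volume(area: float, depth: float) -> float:
    """V = area * depth / 3 (right cone or pyramid of any base shape)."""
    if area < 0 or depth < 0:
        raise ValueError("area and depth must be non-negative")
    return area * depth / 3.0


def depth_from_similarity(area: float, geometry: CageGeometry | None = None) -> float:
    """School depth for a given surface area, by similar-shape scaling.

    The crowded school is treated as a shrunk copy of the full pyramid:
    linear scale k = sqrt(area / base_area), depth = k * pyramid_depth.
    """
    geometry = geometry or CageGeometry()
    base = geometry.box_side**2
    if not 0.0 < area <= base:
        raise ValueError(f"area must be in (0, {base}] m^2")
    k = math.sqrt(area / base)
    return k * geometry.pyramid_depth


def packing_density(biomass: float, volume: float) -> float:
    """Crowding density in kg/m^3."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    if biomass < 0:
        raise ValueError("biomass must be non-negative")
    return biomass / volume


def estimate_density(school_area: float, biomass: float | None = None,
                     n_fish: int | None = None, mean_weight_kg: float | None = None,
                     geometry: CageGeometry | None = None) -> DensityEstimate:
    """Full density estimate from school surface area and biomass.

    Biomass may be given directly (kg) or as n_fish * mean_weight_kg.
    """
    geometry = geometry or CageGeometry()
    if biomass is None:
        if n_fish is None or mean_weight_kg is None:
            raise ValueError("give biomass, or n_fish and mean_weight_kg")
        biomass = n_fish * mean_weight_kg
    depth = depth_from_similarity(school_area, geometry)
    vol = cone_volume(school_area, depth)
    if vol > geometry.total_volume:
        raise ValueError("estimated school volume exceeds total cage volume")
    return DensityEstimate(
        school_area=school_area,
        school_depth=depth,
        volume=vol,
        biomass=biomass,
        density=packing_density(biomass, vol),
    )
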