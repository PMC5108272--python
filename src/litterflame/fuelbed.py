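"""Fuelbed trait calculus: tissue density, packing density, packing ratio.

Litterbed packing controls aeration and hence flammability. Two packing
measures are used: packing density (air-dry fuel mass per litterbed volume,
g/cm³) and packing ratio (total litter particle volume per litterbed volume,
dimensionless, usually reported as %). Particle volume is reconstructed from
air-dry mass, moisture content and tissue density:

    particle_volume = air_dry_mass * (1 - moisture_content) / tissue_density

For mixtures, component particle volumes are summed before dividing by the
ring volume (additive volumes; nonadditive flammability is interpreted
downstream, not baked into the trait calculus).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from .geometry import BurnGeometry, ring_volume

LITTER_TYPES = ("short_needle", "long_needle", "broad_leaf", "branch", "moss")


@dataclass
class SpeciesTraits:
    """Measured litter traits for one species.

    Particle size is the product length × width × height (cm³) of a litter
    particle; tissue density is oven-dry mass per saturated-displacement
    volume (g/cm³); moisture content is water mass per air-dry mass.
    Moss litter has no defined particle size (``None``).
    """

    species_code: str
    particle_length: Optional[float]
    particle_width: Optional[float]
    particle_height: Optional[float]
    tissue_density: float
    moisture_content: float
    litter_type: str
    half_ring_air_dry_mass: float

    def __post_init__(self) -> None:
        if self.litter_type not in LITTER_TYPES:
            raise ValueError(f"unknown litter type {self.litter_type!r}")
        if self.tissue_density <= 0:
            raise ValueError("tissue density must be positive")
        if not (0 <= self.moisture_content < 1):
            raise ValueError("moisture content must be in [0, 1)")
        dims = (self.particle_length, self.particle_width, self.particle_height)
        if self.litter_type != "moss" and any(d is None or d <= 0 for d in dims):
            raise ValueError(f"{self.species_code}: particle dimensions must be positive")

    @property
    def particle_size(self) -> Optional[float]:
        """Particle 3-D size L·W·H in cm³ (None for moss)."""
        if self.particle_length is None:
            return None
        return self.particle_length * self.particle_width * self.particle_height


@dataclass
class FuelbedSpec:
    """Derived packing description of one assembled litterbed."""

    total_air_dry_mass: float  # g
    packing_density: float  # g/cm³
    packing_ratio: float  # fraction
    ring_volume: float  # cm³


def tissue_density(oven_dry_mass: float, displacement_volume: float) -> float:
    """Litter tissue density: oven-dry mass / water-displacement volume, g/cm³."""
    if displacement_volume <= 0:
        raise ValueError("displacement volume must be positive")
    if oven_dry_mass <= 0:
        raise ValueError("oven-dry mass must be positive")
    return oven_dry_mass / displacement_volume


def packing_density(total_air_dry_mass: float, geometry: BurnGeometry = BurnGeometry()) -> float:
    """Air-dry fuel mass per litterbed volume, g/cm³."""
    if total_air_dry_mass < 0:
        raise ValueError("mass must be >= 0")
    return total_air_dry_mass / ring_volume(geometry)


def particle_volume(air_dry_mass: float, moisture_content: float, density: float) -> float:
    """Oven-dry-equivalent particle volume of one component, cm³."""
    if density <= 0:
        raise ValueError("tissue density must be positive")
    if not (0 <= moisture_content < 1):
        raise ValueError("moisture content must be in [0, 1)")
    return air_dry_mass * (1 - moisture_content) / density


def packing_ratio(
    total_air_dry_mass: float,
    moisture_content: float,
    density: float,
    geometry: BurnGeometry = BurnGeometry(),
) -> float:
    """Total particle volume / litterbed volume (fraction) for one component.

    Values >= 1 are physically impossible for a real bed; they are returned
    with a warning rather than raised, since they can arise from measurement
    error in the inputs.
    """
    pr = particle_volume(total_air_dry_mass, moisture_content, density) / ring_volume(geometry)
    if pr >= 1:
        warnings.warn(f"non-physical packing ratio {pr:.3f} >= 1", stacklevel=2)
    return pr


def mixture_packing_ratio(
    masses: Sequence[float],
    moisture_contents: Sequence[float],
    densities: Sequence[float],
    geometry: BurnGeometry = BurnGeometry(),
) -> float:
    """Packing ratio of a multi-component bed: particle volumes are additive."""
    if not (len(masses) == len(moisture_contents) == len(densities)):
        raise ValueError("component sequences must have equal length")
    vol = sum(particle_volume(m, mc, d) for m, mc, d in zip(masses, moisture_contents, densities))
    pr = vol / ring_volume(geometry)
    if pr >= 1:
        warnings.warn(f"non-physical packing ratio {pr:.3f} >= 1", stacklevel=2)
    return pr


def fuelbed_spec(
    masses: Sequence[float],
    moisture_contents: Sequence[float],
    densities: Sequence[float],
    geometry: BurnGeometry = BurnGeometry(),
) -> FuelbedSpec:
    """Full packing description of a mono- or two-species bed."""
    total = float(sum(masses))
    return FuelbedSpec(
        total_air_dry_mass=total,
        packing_density=packing_density(total, geometry),
        packing_ratio=mixture_packing_ratio(masses, moisture_contents, densities, geometry),
        ring_volume=ring_volume(geometry),
    )
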