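"""Burn-ring geometry.

The laboratory fuelbed is a steel mesh ring holding the litter layer; six
thermocouples record temperature, one at the center and five equally spaced
on a circle partway to the rim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class BurnGeometry:
    """Dimensions of the standardized burn ring and its sensor array.

    Parameters
    ----------
    ring_diameter : float
        Inner diameter of the mesh ring in cm.
    ring_depth : float
        Depth of the litter layer in cm.
    sensor_radius : float
        Radial distance of the outer thermocouples from the center, cm.
    n_outer_sensors : int
        Number of outer thermocouples (evenly spaced on the circle).
    sensor_height_above_bed : float
        Height of the sensor tips above the fuelbed surface, cm
        (informational; not used in any computation).
    """

    ring_diameter: float = 25.0
    ring_depth: float = 3.0
    sensor_radius: float = 6.25
    n_outer_sensors: int = 5
    sensor_height_above_bed: float = 1.0

    def __post_init__(self) -> None:
        if self.ring_diameter <= 0 or self.ring_depth <= 0:
            raise ValueError("ring dimensions must be positive")
        if self.sensor_radius <= 0:
            raise ValueError("sensor_radius must be positive")
        if self.sensor_radius >= self.ring_diameter / 2:
            raise ValueError("sensor_radius must be inside the ring")
        if self.n_outer_sensors < 1:
            raise ValueError("need at least one outer sensor")

    @property
    def ring_volume(self) -> float:
        """Litterbed volume pi * r^2 * depth, in cm^3."""
        return math.pi * (self.ring_diameter / 2.0) ** 2 * self.ring_depth


def ring_volume(geometry: BurnGeometry) -> float:
    """Volume of the burn ring in cm^3."""
    return geometry.ring_volume
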