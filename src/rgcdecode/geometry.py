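"""Back-of-envelope retinal geometry for the flashed-target experiments.

Pinhole-eye estimates of how much retina the behavioural target covers and
how many photoreceptors and ganglion cells it engages.  Defaults describe
the archer-fish setup: a 4.5 cm target viewed from 30 cm by a 4 mm eye,
6 µm photoreceptors, 4,500 ganglion cells/mm² with ~100 µm receptive-field
radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "EyeGeometry", "retinal_image_size", "photoreceptors_stimulated",
    "ganglion_cells_covering",
]


@dataclass(frozen=True)
class EyeGeometry:
    """Viewing geometry and retinal cell parameters (mm / µm / cells/mm²)."""

    target_size: float = 45.0  # mm
    viewing_distance: float = 300.0  # mm
    eye_diameter: float = 4.0  # mm
    photoreceptor_diameter: float = 6.0  # µm
    ganglion_density: float = 4500.0  # cells/mm²
    rf_radius: float = 100.0  # µm

    def __post_init__(self) -> None:
        for name in (
            "target_size", "viewing_distance", "eye_diameter",
            "photoreceptor_diameter", "ganglion_density", "rf_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def retinal_image_size(g: EyeGeometry) -> float:
    """Retinal image diameter (mm) under pinhole projection.

    target_size × eye_diameter / viewing_distance; the default geometry
    gives 0.60 mm.
    """
    if g.viewing_distance == 0:
        raise ValueError("viewing distance must be nonzero")
    return g.target_size * g.eye_diameter / g.viewing_distance


def photoreceptors_stimulated(
    image_diameter: float, rc_diameter: float, packing: str = "square"
) -> float:
    """Photoreceptors under a retinal image disc.

    ``image_diameter`` in mm, ``rc_diameter`` (receptor diameter) in µm.
    Square packing divides the disc area by d² (default — a hexagonal/
    square mosaic footprint); circular packing by πd²/4.
    """
    if image_diameter <= 0 or rc_diameter <= 0:
        raise ValueError("sizes must be positive")
    area_um2 = math.pi * (image_diameter * 1000.0 / 2.0) ** 2
    if packing == "square":
        per = rc_diameter**2
    elif packing == "circular":
        per = math.pi * rc_diameter**2 / 4.0
    else:
        raise ValueError(f"unknown packing {packing!r}")
    return area_um2 / per


def ganglion_cells_covering(
    image_diameter: float,
    density: float = 4500.0,
    rf_radius: float = 100.0,
    mode: str = "centres_inside",
) -> float:
    """Ganglion cells engaged by the retinal image.

    ``centres_inside`` counts cells whose receptive-field centres fall
    inside the image disc (density × π r²); ``partial_overlap`` also counts
    cells whose fields merely touch it (radius grown by ``rf_radius``).
    """
    if image_diameter <= 0 or density < 0 or rf_radius < 0:
        raise ValueError("invalid geometry inputs")
    r_mm = image_diameter / 2.0
    if mode == "partial_overlap":
        r_mm += rf_radius / 1000.0
    elif mode != "centres_inside":
        raise ValueError(f"unknown mode {mode!r}")
    return density * math.pi * r_mm**2
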