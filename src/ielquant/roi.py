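"""Epithelial region-of-interest polygons.

The epithelium of an imaged organoid cross-section is an annular region:
an outer boundary enclosing the organoid minus the central lumen, which is
excluded from all area denominators. ROIs are exchanged as GeoJSON polygons
(coordinates in micrometres) because manually drawn regions must survive a
round trip through external tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon, mapping, shape


@dataclass
class RegionOfInterest:
    """Epithelial polygon with lumen hole(s), vertices in micrometres.

    Parameters
    ----------
    outer : (N, 2) array of the outer boundary vertices.
    holes : list of (M, 2) arrays, each a lumen polygon strictly inside
        the outer boundary and pairwise disjoint.
    """

    outer: np.ndarray
    holes: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.outer = np.asarray(self.outer, dtype=float)
        self.holes = [np.asarray(h, dtype=float) for h in self.holes]
        if self.outer.ndim != 2 or self.outer.shape[1] != 2 or len(self.outer) < 3:
            raise ValueError("outer boundary must be an (N>=3, 2) vertex array")
        poly = self.polygon
        if not poly.is_valid:
            raise ValueError("ROI polygon is invalid (self-intersecting or malformed)")
        if poly.area <= 0:
            raise ValueError("ROI must have positive area")
        shell = Polygon(self.outer)
        for h in self.holes:
            if not shell.contains(Polygon(h)):
                raise ValueError("every lumen hole must lie strictly inside the outer boundary")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.outer, holes=[h for h in self.holes])

    @property
    def area_um2(self) -> float:
        """Epithelial area: outer area minus lumen hole areas."""
        return float(self.polygon.area)

    # -- GeoJSON exchange ---------------------------------------------------

    def to_geojson(self) -> dict:
        return {
            "type": "Feature",
            "properties": {"units": "um"},
            "geometry": mapping(self.polygon),
        }

    @classmethod
    def from_geojson(cls, obj: dict) -> "RegionOfInterest":
        geom = obj.get("geometry", obj)
        poly = shape(geom)
        if poly.geom_type != "Polygon":
            raise ValueError(f"expected a Polygon geometry, got {poly.geom_type}")
        outer = np.asarray(poly.exterior.coords)[:-1]
        holes = [np.asarray(ring.coords)[:-1] for ring in poly.interiors]
        return cls(outer=outer, holes=holes)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh)

    @classmethod
    def read(cls, path) -> "RegionOfInterest":
        with open(path) as fh:
            return cls.from_geojson(json.load(fh))


def annulus_roi(
    center_um: tuple[float, float],
    outer_radius_um: float,
    lumen_radius_um: float = 0.0,
    n_vertices: int = 128,
) -> RegionOfInterest:
    """Polygonal approximation of an annular epithelium ROI.

    ``lumen_radius_um = 0`` yields a full disk (no hole).
    """
    if not outer_radius_um > lumen_radius_um >= 0:
        raise ValueError("require outer_radius_um > lumen_radius_um >= 0")
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    cx, cy = center_um
    outer = np.column_stack(
        [cx + outer_radius_um * np.cos(theta), cy + outer_radius_um * np.sin(theta)]
    )
    holes = []
    if lumen_radius_um > 0:
        holes.append(
            np.column_stack(
                [cx + lumen_radius_um * np.cos(theta), cy + lumen_radius_um * np.sin(theta)]
            )
        )
    return RegionOfInterest(outer=outer, holes=holes)
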