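"""Observation windows for planar point patterns.

A :class:`Window` is a simple polygon, with vertices in micrometres, that
bounds the region of retina over which cells were mapped.  All mosaic
statistics are computed relative to a window: the window's area sets the mean
density, and matched random null models are generated inside the same window
as the observed cells so that density matching is well defined.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, shape, mapping

from .errors import GeometryError

__all__ = ["Window"]

UM2_PER_MM2 = 1e6


class Window:
    """A simple (non-self-intersecting) polygonal observation region.

    Parameters
    ----------
    boundary
        Polygon vertices in micrometres as an ``(N, 2)`` array-like, or a
        shapely :class:`~shapely.geometry.Polygon`.  The ring is closed
        implicitly.

    Raises
    ------
    GeometryError
        If the polygon is self-intersecting, degenerate or has zero area.
    """

    def __init__(self, boundary: Sequence | Polygon):
        if isinstance(boundary, Polygon):
            poly = boundary
        else:
            arr = np.asarray(boundary, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
                raise GeometryError("window boundary must be an (N>=3, 2) vertex array")
            poly = Polygon(arr)
        if not poly.is_valid:
            raise GeometryError(f"invalid window polygon: {shapely.is_valid_reason(poly)}")
        if poly.is_empty or poly.area <= 0:
            raise GeometryError("window polygon has zero area")
        self.polygon: Polygon = poly

    # -- geometry ---------------------------------------------------------

    @property
    def area_um2(self) -> float:
        return float(self.polygon.area)

    @property
    def area_mm2(self) -> float:
        """Window area in mm^2 (vertices are stored in um)."""
        return float(self.polygon.area) / UM2_PER_MM2

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) in um."""
        return self.polygon.bounds

    def contains_points(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points strictly inside the window (boundary excluded)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.size == 0:
            return np.zeros(0, dtype=bool)
        return shapely.contains_xy(self.polygon, pts[:, 0], pts[:, 1])

    # -- constructors ------------------------------------------------------

    @classmethod
    def rectangle(cls, width_um: float, height_um: float,
                  origin: tuple[float, float] = (0.0, 0.0)) -> "Window":
        x0, y0 = origin
        return cls([(x0, y0), (x0 + width_um, y0),
                    (x0 + width_um, y0 + height_um), (x0, y0 + height_um)])

    @classmethod
    def disc(cls, radius_um: float, center: tuple[float, float] = (0.0, 0.0),
             n_vertices: int = 256) -> "Window":
        theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
        cx, cy = center
        return cls(np.column_stack([cx + radius_um * np.cos(theta),
                                    cy + radius_um * np.sin(theta)]))

    @classmethod
    def half_disc(cls, radius_um: float, center: tuple[float, float] = (0.0, 0.0),
                  n_vertices: int = 128) -> "Window":
        """Upper half-disc: a dorsal-hemisphere-like region above the
        naso-temporal line through ``center``."""
        theta = np.linspace(0, np.pi, n_vertices)
        cx, cy = center
        arc = np.column_stack([cx + radius_um * np.cos(theta),
                               cy + radius_um * np.sin(theta)])
        return cls(arc)

    # -- serialization -----------------------------------------------------

    def to_geojson(self) -> dict:
        """GeoJSON Polygon with coordinates in um."""
        return mapping(self.polygon)

    def save_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh)

    @classmethod
    def from_geojson(cls, obj: dict) -> "Window":
        geom = shape(obj.get("geometry", obj) if obj.get("type") == "Feature" else obj)
        if not isinstance(geom, Polygon):
            raise GeometryError(f"expected a GeoJSON Polygon, got {geom.geom_type}")
        return cls(geom)

    @classmethod
    def load_geojson(cls, path) -> "Window":
        with open(path) as fh:
            return cls.from_geojson(json.load(fh))

    def __repr__(self) -> str:  # pragma: no cover
        return f"Window(area={self.area_mm2:.3f} mm^2, vertices={len(self.polygon.exterior.coords) - 1})"
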