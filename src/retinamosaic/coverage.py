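"""Coverage factors and whole-retina density mapping.

The coverage factor of a mosaic is the average number of dendritic fields
overlapping any retinal point: CF = density x pi (d/2)^2, with the cell
density in cells/mm^2 and the mean dendritic-field diameter d in um.  A CF
of ~2 means roughly two dendritic (or receptive) fields cover each point —
the hallmark of a territorial, seamlessly tiling RGC subtype.

Density mapping follows the whole-mount convention: the retina is oriented
with +y dorsal, split through the optic nerve head along the naso-temporal
axis into dorsal and ventral hemispheres, profiled in 100 um dorso-ventral
bins, and sampled locally in 1 mm^2 regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box

from .errors import GeometryError, ParameterError
from .morphology import equivalent_diameter
from .patterns import PointPattern
from .window import Window

__all__ = ["RetinaGeometry", "CoverageResult", "DensityProfile",
           "coverage_factor", "field_diameter", "hemisphere_counts",
           "local_density", "dv_density_profile", "subtract_population",
           "square_region"]

UM2_PER_MM2 = 1e6


@dataclass
class RetinaGeometry:
    """Orientation metadata of a flat-mounted retina.

    ``optic_nerve`` is the optic nerve head position (um); ``dorsal_axis``
    is a unit vector pointing dorsal (+y by convention).  The naso-temporal
    split line runs through the optic nerve perpendicular to the dorsal
    axis.
    """

    optic_nerve: tuple[float, float] = (0.0, 0.0)
    dorsal_axis: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        ax = np.asarray(self.dorsal_axis, float)
        norm = np.linalg.norm(ax)
        if norm == 0:
            raise ParameterError("dorsal_axis must be non-zero")
        self.dorsal_axis = tuple(ax / norm)
        self.optic_nerve = tuple(map(float, self.optic_nerve))

    def projections(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of each point from the split line, + = dorsal."""
        rel = np.atleast_2d(points) - np.asarray(self.optic_nerve)
        return rel @ np.asarray(self.dorsal_axis)


@dataclass
class CoverageResult:
    density: float          # cells/mm^2
    field_diameter: float   # um
    coverage_factor: float  # dimensionless

    def to_dict(self) -> dict:
        return {"density_per_mm2": self.density,
                "field_diameter_um": self.field_diameter,
                "coverage_factor": self.coverage_factor}


@dataclass
class DensityProfile:
    """Counts and densities in dorso-ventral bins along the dorsal axis."""

    bin_edges: np.ndarray       # um, projection onto dorsal axis
    counts: np.ndarray
    strip_areas_mm2: np.ndarray
    density_per_mm2: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_lo_um": self.bin_edges[:-1],
                             "bin_hi_um": self.bin_edges[1:],
                             "count": self.counts,
                             "density_per_mm2": self.density_per_mm2})


# ---------------------------------------------------------------------------


def coverage_factor(density_per_mm2: float, field_diameter_um: float) -> CoverageResult:
    """CF = density x pi (d/2)^2 with the diameter converted to mm.

    Linear in density and quadratic in diameter.
    """
    if density_per_mm2 < 0:
        raise ParameterError("density must be >= 0")
    if field_diameter_um <= 0:
        raise ParameterError("field_diameter must be > 0")
    radius_mm = field_diameter_um / 2.0 / 1000.0
    cf = density_per_mm2 * np.pi * radius_mm ** 2
    return CoverageResult(density_per_mm2, field_diameter_um, float(cf))


def field_diameter(field_outline: Polygon | np.ndarray) -> float:
    """Equivalent-circle diameter of a dendritic-field outline (um).

    The diameter of the circle whose area equals the convex hull of the
    outline — the package's estimator for the reported mean field diameter.
    """
    if isinstance(field_outline, Polygon):
        poly = field_outline
    else:
        arr = np.asarray(field_outline, float)
        if arr.ndim != 2 or len(arr) < 3:
            raise GeometryError("field outline needs >= 3 vertices")
        poly = Polygon(arr)
    hull = poly.convex_hull
    if hull.area <= 0:
        raise GeometryError("degenerate field outline (zero hull area)")
    return 2.0 * float(np.sqrt(hull.area / np.pi))


def hemisphere_counts(pattern: PointPattern,
                      geometry: RetinaGeometry) -> tuple[int, int]:
    """(dorsal, ventral) cell counts after the naso-temporal split.

    Points exactly on the split line are assigned dorsal (fixed tie rule).
    """
    if pattern.n == 0:
        return (0, 0)
    proj = geometry.projections(pattern.points)
    dorsal = int(np.sum(proj >= 0))
    return dorsal, pattern.n - dorsal


def square_region(center: tuple[float, float], side_um: float = 1000.0) -> Polygon:
    """An axis-aligned square (default 1 mm^2) for local density sampling."""
    cx, cy = center
    h = side_um / 2.0
    return box(cx - h, cy - h, cx + h, cy + h)


def local_density(pattern: PointPattern, region: Polygon) -> float:
    """Cells per mm^2 inside a sampling region (e.g. a 1 mm^2 square).

    The region must lie inside the observation window.
    """
    if not pattern.window.polygon.contains(region):
        raise GeometryError("sampling region extends outside the window")
    if pattern.n == 0:
        return 0.0
    inside = shapely.contains_xy(region, pattern.points[:, 0], pattern.points[:, 1])
    return float(inside.sum()) / (region.area / UM2_PER_MM2)


def dv_density_profile(pattern: PointPattern, geometry: RetinaGeometry,
                       bin_um: float = 100.0) -> DensityProfile:
    """Dorso-ventral density profile in fixed bins along the dorsal axis.

    Counts are binned by each cell's projection onto the dorsal axis over
    the window's full dorso-ventral extent (so the counts always sum to n);
    densities divide each bin count by the area of the window strip it spans.
    """
    if bin_um <= 0:
        raise ParameterError("bin size must be > 0")
    verts = np.asarray(pattern.window.polygon.exterior.coords)
    vproj = geometry.projections(verts)
    lo, hi = float(vproj.min()), float(vproj.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_um - 1e-9)))
    edges = lo + bin_um * np.arange(n_bins + 1)
    if pattern.n:
        proj = geometry.projections(pattern.points)
        counts, _ = np.histogram(proj, bins=edges)
    else:
        counts = np.zeros(n_bins, dtype=int)
    # strip areas: window intersected with each band perpendicular to the axis
    u = np.asarray(geometry.dorsal_axis)
    v = np.array([-u[1], u[0]])
    on = np.asarray(geometry.optic_nerve)
    big = 2 * max(abs(lo), abs(hi), pattern.window.polygon.length) + bin_um
    areas = np.empty(n_bins)
    for k in range(n_bins):
        a, b = edges[k], edges[k + 1]
        strip = Polygon([on + u * a - v * big, on + u * b - v * big,
                         on + u * b + v * big, on + u * a + v * big])
        areas[k] = pattern.window.polygon.intersection(strip).area / UM2_PER_MM2
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(areas > 0, counts / areas, 0.0)
    return DensityProfile(edges, counts, areas, dens)


def subtract_population(pattern_all: PointPattern, pattern_sub: PointPattern,
                        match_radius: float) -> PointPattern:
    """Remove from ``pattern_all`` the cells matched by ``pattern_sub``.

    Each subtraction point claims its nearest unclaimed point of
    ``pattern_all`` within ``match_radius`` (nearest-match tie rule).
    Subtraction points with no candidate raise a warning and are reported in
    the result's ``meta['unmatched']``.  Used to ask whether removing a
    dorsal subpopulation equalises the dorso-ventral distribution.
    """
    if match_radius <= 0:
        raise ParameterError("match_radius must be > 0")
    if pattern_sub.n == 0:
        return PointPattern(pattern_all.points.copy(), pattern_all.window,
                            None if pattern_all.labels is None else pattern_all.labels.copy(),
                            dict(pattern_all.meta))
    from scipy.spatial import cKDTree
    tree = cKDTree(pattern_all.points)
    claimed = np.zeros(pattern_all.n, dtype=bool)
    unmatched = []
    for i, p in enumerate(pattern_sub.points):
        cand = tree.query_ball_point(p, match_radius)
        cand = [c for c in cand if not claimed[c]]
        if not cand:
            unmatched.append(i)
            continue
        d = np.linalg.norm(pattern_all.points[cand] - p, axis=1)
        claimed[cand[int(np.argmin(d))]] = True
    if unmatched:
        warnings.warn(f"{len(unmatched)} subtraction point(s) had no match within "
                      f"{match_radius} um", stacklevel=2)
    keep = ~claimed
    labels = pattern_all.labels[keep] if pattern_all.labels is not None else None
    meta = dict(pattern_all.meta)
    meta.update(n_removed=int(claimed.sum()), unmatched=unmatched)
    return PointPattern(pattern_all.points[keep], pattern_all.window, labels, meta)
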