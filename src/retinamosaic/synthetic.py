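"""Synthetic inputs with known ground truth.

This module generates every kind of input the analysis consumes:

* planar soma patterns in an arbitrary window — uniform random (binomial),
  hard-core random with a fixed soma-size exclusion, and regular "dmin"
  mosaics with a per-cell exclusion drawn from a truncated normal — the three
  spatial regimes against which mosaic statistics are validated;
* small branched neuron trees with a controlled dendritic-field radius, for
  Sholl analysis and morphometrics;
* grayscale images with polygon ROIs of known mean intensity over a known
  background, for fluorescence-ratio quantification.

All randomness flows from one explicit integer seed per call; there is no
global random state.  Identical spec + seed reproduces coordinates
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import Polygon

from .errors import GeometryError, PackingError, ParameterError
from .morphology import Morphology
from .patterns import PointPattern
from .window import Window

__all__ = ["MosaicSpec", "gen_uniform", "gen_hardcore", "gen_dmin_mosaic",
           "gen_morphology", "gen_fluor_image", "save_tiff"]

# dart-throwing gives up after this many in-window candidates per requested point
MAX_ATTEMPTS_PER_POINT = 1000


@dataclass
class MosaicSpec:
    """Declarative description of a point-process draw (used by the CLI)."""

    process: str  # "uniform" | "hardcore" | "dmin_mosaic"
    n_points: int
    hardcore_diameter: float = 14.0
    dmin_mean: float = 0.0
    dmin_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.process not in ("uniform", "hardcore", "dmin_mosaic"):
            raise ParameterError(f"unknown process {self.process!r}")
        if self.n_points < 0:
            raise ParameterError("n_points must be >= 0")
        if self.hardcore_diameter < 0:
            raise ParameterError("hardcore_diameter must be >= 0")
        if self.process == "dmin_mosaic" and not (self.dmin_mean > self.dmin_sd >= 0):
            raise ParameterError("dmin_mosaic requires dmin_mean > dmin_sd >= 0")

    def realize(self, window: Window) -> PointPattern:
        if self.process == "uniform":
            return gen_uniform(window, self.n_points, self.seed)
        if self.process == "hardcore":
            return gen_hardcore(window, self.n_points, self.hardcore_diameter, self.seed)
        return gen_dmin_mosaic(window, self.n_points, self.dmin_mean,
                               self.dmin_sd, self.seed)


# ---------------------------------------------------------------------------
# point patterns


def _propose_in_window(window: Window, rng: np.random.Generator) -> np.ndarray:
    """One uniform point inside the window, by rejection from the bbox."""
    minx, miny, maxx, maxy = window.bounds
    while True:
        p = rng.uniform((minx, miny), (maxx, maxy))
        if window.contains_points(p[None, :])[0]:
            return p


def gen_uniform(window: Window, n: int, seed: int) -> PointPattern:
    """n i.i.d. uniform points over the window (binomial process).

    Sampling rejects bounding-box draws that fall outside the polygon, so the
    accepted points are exactly uniform over the window area.
    """
    if n < 0:
        raise ParameterError("n must be >= 0")
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = window.bounds
    chunks = []
    got = 0
    while got < n:
        m = max(2 * (n - got), 64)
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(m, 2))
        keep = window.contains_points(cand)
        acc = cand[keep]
        chunks.append(acc)
        got += len(acc)
    pts = np.concatenate(chunks)[:n] if chunks else np.empty((0, 2))
    return PointPattern(pts, window,
                        meta={"process": "uniform", "n": n, "seed": seed})


def _dart_throw(window: Window, n: int, draw_exclusion: Callable, rng,
                max_attempts: int) -> np.ndarray:
    """Sequential dart throwing with a per-candidate exclusion radius.

    Each candidate is uniform over the window and is rejected if any already
    accepted point lies closer than the candidate's own drawn exclusion
    distance.  Raises PackingError when the attempt budget is exhausted —
    never silently returns fewer points.
    """
    accepted = np.empty((n, 2))
    n_acc = 0
    attempts = 0
    while n_acc < n:
        if attempts >= max_attempts:
            raise PackingError(
                f"placed {n_acc}/{n} points after {attempts} candidates; "
                "packing too dense for dart throwing")
        p = _propose_in_window(window, rng)
        attempts += 1
        excl = draw_exclusion(rng)
        if n_acc:
            d2 = np.min(np.sum((accepted[:n_acc] - p) ** 2, axis=1))
            if d2 < excl * excl:
                continue
        accepted[n_acc] = p
        n_acc += 1
    return accepted


def gen_hardcore(window: Window, n: int, diameter: float = 14.0,
                 seed: int = 0, max_attempts: int | None = None) -> PointPattern:
    """Hard-core random pattern: uniform darts with a fixed exclusion.

    Emulates a random arrangement of somas of the given diameter (no two
    cell centres closer than one soma diameter), the standard null model for
    testing mosaic regularity at matched density.

    Raises ParameterError when the requested packing exceeds half the window
    area (dart throwing would stall), and PackingError if the attempt budget
    (``1000 * n`` by default) runs out.
    """
    if n < 0:
        raise ParameterError("n must be >= 0")
    if diameter < 0:
        raise ParameterError("diameter must be >= 0")
    if n * np.pi * (diameter / 2.0) ** 2 >= 0.5 * window.area_um2:
        raise ParameterError(
            "infeasible packing: n * soma disc area exceeds half the window")
    rng = np.random.default_rng(seed)
    pts = _dart_throw(window, n, lambda _rng: diameter, rng,
                      max_attempts or MAX_ATTEMPTS_PER_POINT * max(n, 1))
    return PointPattern(pts, window,
                        meta={"process": "hardcore", "n": n,
                              "hardcore_diameter": diameter, "seed": seed})


def gen_dmin_mosaic(window: Window, n: int, dmin_mean: float, dmin_sd: float,
                    seed: int = 0, max_attempts: int | None = None) -> PointPattern:
    """Regular mosaic via the dmin rule: per-cell exclusion ~ Normal(mean, sd).

    Each candidate draws its own minimum spacing from a normal distribution
    floored at zero and is rejected if it falls closer than that to any
    accepted cell.  With ``dmin_sd == 0`` this reduces exactly to
    :func:`gen_hardcore` with ``diameter = dmin_mean`` (the same candidate
    stream is consumed, so the coordinates are identical).
    """
    if not (dmin_mean > dmin_sd >= 0):
        raise ParameterError("requires dmin_mean > dmin_sd >= 0")
    if n < 0:
        raise ParameterError("n must be >= 0")
    if n * np.pi * (dmin_mean / 2.0) ** 2 >= 0.55 * window.area_um2:
        raise ParameterError("infeasible density for dmin mosaic")
    rng = np.random.default_rng(seed)
    if dmin_sd == 0:
        draw = lambda _rng: dmin_mean  # noqa: E731 - keep rng stream identical to hardcore
    else:
        draw = lambda _rng: max(0.0, _rng.normal(dmin_mean, dmin_sd))  # noqa: E731
    pts = _dart_throw(window, n, draw, rng,
                      max_attempts or MAX_ATTEMPTS_PER_POINT * max(n, 1))
    return PointPattern(pts, window,
                        meta={"process": "dmin_mosaic", "n": n, "dmin_mean": dmin_mean,
                              "dmin_sd": dmin_sd, "seed": seed})


# ---------------------------------------------------------------------------
# morphologies


#: Radial extent that makes the *measured* (convex-hull equivalent-circle)
#: field diameter of generated trees average ~324 um: the hull of a
#: finite-tip arbor underfills its enclosing circle by ~6%, so emulating a
#: population with a 324 um mean measured diameter needs a slightly larger
#: radial extent than 162 um.
M1_FIELD_RADIUS_UM = 172.0


def gen_morphology(n_primary: int, branch_prob: float = 0.18,
                   field_radius: float = 162.0, seed: int = 0,
                   step_um: float = 15.0, jitter_rad: float = 0.15,
                   soma_radius: float = 6.0) -> Morphology:
    """Grow a small M1-like dendritic tree with a known field radius.

    ``n_primary`` dendrites leave the soma at evenly spaced (jittered)
    angles.  Each tip carries an angular offset from the radial direction
    and marches outward in fixed steps — the segment direction is the
    radial direction at the tip plus the offset plus jitter — so every
    branch terminates after ~``field_radius / step_um`` steps.  At each step
    a tip bifurcates with probability ``branch_prob`` (offsets split apart).
    A tip's final node is clipped onto the circle of ``field_radius``, so
    the arbor's radial extent equals the requested field radius by
    construction and its convex hull approaches the enclosing disc as tips
    accumulate.
    """
    if n_primary < 1:
        raise ParameterError("n_primary must be >= 1")
    if not (0 <= branch_prob < 1):
        raise ParameterError("branch_prob must be in [0, 1)")
    if field_radius <= 0 or step_um <= 0:
        raise ParameterError("field_radius and step_um must be > 0")
    rng = np.random.default_rng(seed)
    ids = [1]
    types = [1]          # soma
    xyz = [[0.0, 0.0, 0.0]]
    radii = [soma_radius]
    parents = [-1]
    next_id = 2
    base = rng.uniform(0, 2 * np.pi)
    # active tips: (parent_id, angular offset from the radial direction)
    # a primary's first step leaves the soma at its assigned angle
    tips: list[tuple[int, float, float]] = [
        (1, rng.normal(0, jitter_rad),
         base + 2 * np.pi * k / n_primary + rng.normal(0, jitter_rad))
        for k in range(n_primary)]
    max_offset = 1.0  # rad; keeps growth outward-bound
    while tips:
        parent_id, offset, first_ang = tips.pop(0)
        px, py, _ = xyz[parent_id - 1]  # ids are assigned 1..n in order
        if px == 0.0 and py == 0.0:
            ang = first_ang
        else:
            ang = np.arctan2(py, px) + offset + rng.normal(0, jitter_rad)
        nx, ny = px + step_um * np.cos(ang), py + step_um * np.sin(ang)
        r = float(np.hypot(nx, ny))
        terminal = r >= field_radius
        if terminal:
            nx, ny = nx * field_radius / r, ny * field_radius / r
        ids.append(next_id)
        types.append(3)  # basal dendrite code
        xyz.append([nx, ny, 0.0])
        radii.append(0.5)
        parents.append(parent_id)
        node = next_id
        next_id += 1
        if not terminal:
            if rng.random() < branch_prob:
                split = rng.uniform(0.3, 0.6)
                for sgn in (-1.0, 1.0):
                    off = float(np.clip(offset + sgn * split, -max_offset, max_offset))
                    tips.append((node, off, ang))
            else:
                tips.append((node, offset, ang))
    return Morphology(np.array(ids), np.array(types), np.array(xyz),
                      np.array(radii), np.array(parents))


# ---------------------------------------------------------------------------
# fluorescence images


def gen_fluor_image(shape: tuple[int, int], pixel_size: float,
                    rois: Sequence[Polygon], intensities: Sequence[float],
                    background: float, noise_sd: float = 0.0,
                    seed: int = 0) -> np.ndarray:
    """Grayscale image with known ROI means over a known background.

    ROI polygons are in um; a pixel belongs to an ROI if its centre lies
    inside the polygon (the same rule the quantification uses).  Gaussian
    noise of the given SD is added and the image clipped to the valid 16-bit
    range.  Returns a float64 array (use :func:`save_tiff` for 16-bit TIFF).
    """
    if len(rois) != len(intensities):
        raise ParameterError("rois and intensities must have equal length")
    h, w = shape
    img = np.full((h, w), float(background))
    xs = (np.arange(w) + 0.5) * pixel_size
    ys = (np.arange(h) + 0.5) * pixel_size
    xx, yy = np.meshgrid(xs, ys)
    width_um, height_um = w * pixel_size, h * pixel_size
    for poly, inten in zip(rois, intensities):
        minx, miny, maxx, maxy = poly.bounds
        if minx < 0 or miny < 0 or maxx > width_um or maxy > height_um:
            raise GeometryError("ROI extends outside the image")
        mask = shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(h, w)
        img[mask] = float(inten)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 65535.0)


def save_tiff(image: np.ndarray, path) -> None:
    """Write a single-channel 16-bit TIFF (values rounded and clipped)."""
    tifffile.imwrite(path, np.clip(np.round(image), 0, 65535).astype(np.uint16))
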