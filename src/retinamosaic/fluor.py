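"""ROI-based normalized fluorescence (F/Fo) and cross-section profiles.

Axonal innervation of a brain region is quantified as the mean pixel
intensity inside a region-of-interest polygon divided by the mean intensity
of a user-supplied background region of the same slice (F/Fo).  A region is
called densely innervated when F/Fo exceeds 1.5 (strict inequality).

Innervation *patterns* across a structure are profiled by sampling intensity
along a thin rectangular mask (30 um wide, 650-750 um long) transecting the
structure: intensity is averaged across the mask width at stations every
0.75 um along its axis (bilinear interpolation), then stations are averaged
into 6 um bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
import tifffile
from scipy.ndimage import map_coordinates
from shapely.geometry import Polygon

from .errors import GeometryError, ParameterError, RetinaMosaicError

__all__ = ["FluorMeasurement", "CrossSectionProfile", "roi_mean",
           "f_over_fo", "cross_section_profile", "innervation_call",
           "load_tiff"]

INNERVATION_THRESHOLD = 1.5


@dataclass
class FluorMeasurement:
    """F/Fo measurement for one region."""

    roi_mean: float
    background_mean: float
    f_over_fo: float
    innervated: bool
    threshold: float = INNERVATION_THRESHOLD

    def to_dict(self) -> dict:
        return {"roi_mean": self.roi_mean, "background_mean": self.background_mean,
                "f_over_fo": self.f_over_fo, "innervated": self.innervated,
                "threshold": self.threshold}


@dataclass
class CrossSectionProfile:
    """Binned intensity along a rectangular mask axis."""

    bin_centers_um: np.ndarray
    values: np.ndarray
    station_values: np.ndarray
    sample_step_um: float
    bin_um: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"pos_um": self.bin_centers_um,
                             "mean_intensity": self.values})


def load_tiff(path) -> np.ndarray:
    """Read a single-channel TIFF as float64."""
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise GeometryError(f"expected a single-channel 2-D image, got shape {img.shape}")
    return img.astype(float)


def _check_inside_image(poly: Polygon, shape: tuple[int, int], pixel_size: float,
                        what: str) -> None:
    h, w = shape
    minx, miny, maxx, maxy = poly.bounds
    if minx < 0 or miny < 0 or maxx > w * pixel_size or maxy > h * pixel_size:
        raise GeometryError(f"{what} extends outside the image")


def roi_mean(image: np.ndarray, roi: Polygon, pixel_size: float = 1.0) -> float:
    """Mean intensity of pixels whose centres fall inside the polygon."""
    _check_inside_image(roi, image.shape, pixel_size, "ROI")
    h, w = image.shape
    # restrict the center test to the ROI's bounding box
    minx, miny, maxx, maxy = roi.bounds
    c0 = max(0, int(minx / pixel_size) - 1)
    c1 = min(w, int(np.ceil(maxx / pixel_size)) + 1)
    r0 = max(0, int(miny / pixel_size) - 1)
    r1 = min(h, int(np.ceil(maxy / pixel_size)) + 1)
    xs = (np.arange(c0, c1) + 0.5) * pixel_size
    ys = (np.arange(r0, r1) + 0.5) * pixel_size
    xx, yy = np.meshgrid(xs, ys)
    mask = shapely.contains_xy(roi, xx.ravel(), yy.ravel()).reshape(xx.shape)
    if not mask.any():
        raise GeometryError("ROI contains no pixel centres")
    return float(image[r0:r1, c0:c1][mask].mean())


def f_over_fo(image: np.ndarray, roi: Polygon, background_roi: Polygon,
              pixel_size: float = 1.0,
              threshold: float = INNERVATION_THRESHOLD) -> FluorMeasurement:
    """Normalized fluorescence: mean(roi) / mean(background).

    Both polygons are in um; pixels belong to a polygon when their centre is
    inside it.  Invariant under multiplying the whole image by any k > 0.
    """
    fm = roi_mean(image, roi, pixel_size)
    fo = roi_mean(image, background_roi, pixel_size)
    if fo <= 0:
        raise RetinaMosaicError(
            f"background mean is {fo}; F/Fo undefined (check the background ROI)")
    ratio = fm / fo
    return FluorMeasurement(fm, fo, ratio, ratio > threshold, threshold)


def innervation_call(m: FluorMeasurement,
                     threshold: float = INNERVATION_THRESHOLD) -> bool:
    """Dense-innervation call: strictly F/Fo > threshold."""
    return m.f_over_fo > threshold


def cross_section_profile(image: np.ndarray, pixel_size: float,
                          mask_origin: tuple[float, float],
                          mask_axis: tuple[float, float],
                          length_um: float, width_um: float = 30.0,
                          sample_step_um: float = 0.75,
                          bin_um: float = 6.0) -> CrossSectionProfile:
    """Mean intensity along a rectangular mask, binned along its axis.

    ``mask_origin`` (um) is the start of the mask centre-line and
    ``mask_axis`` its direction.  At each station (every ``sample_step_um``
    along the axis) intensity is averaged across the mask width by bilinear
    interpolation; stations are then averaged in groups of
    ``bin_um / sample_step_um`` into bins.  Bin centres are reported in um
    from the origin.  Trailing stations that do not fill a whole bin are
    dropped from the binned values (a 650 um mask holds 866 stations and
    108 full 6 um bins); ``station_values`` always carries every station.
    """
    if length_um <= 0 or width_um <= 0 or sample_step_um <= 0 or bin_um <= 0:
        raise ParameterError("length, width, sample_step and bin must be > 0")
    per_bin = bin_um / sample_step_um
    if abs(per_bin - round(per_bin)) > 1e-9:
        raise ParameterError("bin must be a multiple of sample_step")
    per_bin = int(round(per_bin))
    n_stations = int(np.floor(length_um / sample_step_um + 1e-9))
    if n_stations < per_bin:
        raise ParameterError("mask too short for a single bin")
    u = np.asarray(mask_axis, float)
    nu = np.linalg.norm(u)
    if nu == 0:
        raise ParameterError("mask_axis must be non-zero")
    u = u / nu
    v = np.array([-u[1], u[0]])
    origin = np.asarray(mask_origin, float)
    # geometric mask bounds check
    corners = [origin - v * width_um / 2, origin + v * width_um / 2,
               origin + u * length_um - v * width_um / 2,
               origin + u * length_um + v * width_um / 2]
    _check_inside_image(Polygon(corners).convex_hull, image.shape, pixel_size, "mask")
    s = (np.arange(n_stations) + 0.5) * sample_step_um
    n_w = max(2, int(round(width_um / sample_step_um)))
    t = (np.arange(n_w) + 0.5) / n_w * width_um - width_um / 2
    # sample grid (n_stations, n_w, 2) in um
    pts = (origin[None, None, :] + s[:, None, None] * u[None, None, :]
           + t[None, :, None] * v[None, None, :])
    cols = pts[..., 0] / pixel_size - 0.5
    rows = pts[..., 1] / pixel_size - 0.5
    samples = map_coordinates(image, [rows.ravel(), cols.ravel()],
                              order=1, mode="nearest").reshape(rows.shape)
    station_values = samples.mean(axis=1)
    n_full = (n_stations // per_bin) * per_bin
    values = station_values[:n_full].reshape(-1, per_bin).mean(axis=1)
    centers = (np.arange(len(values)) + 0.5) * bin_um
    return CrossSectionProfile(centers, values, station_values,
                               sample_step_um, bin_um)
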