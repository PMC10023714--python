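"""Planar point patterns: the universal container for soma coordinates.

A :class:`PointPattern` pairs an ``(N, 2)`` array of cell positions (um) with
the :class:`~retinamosaic.window.Window` they were observed in, optional
per-cell labels, and free-form provenance metadata (generator spec, seed,
retina id).  Patterns round-trip to CSV with the header ``x_um,y_um,label``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import GeometryError
from .window import Window

__all__ = ["PointPattern", "DUPLICATE_TOL_UM"]

# Two somas closer than this are considered the same marked cell.
DUPLICATE_TOL_UM = 0.01


@dataclass
class PointPattern:
    """Cell coordinates inside an explicit observation window.

    Invariants enforced at construction: every point lies strictly inside the
    window, and no two points coincide within ``DUPLICATE_TOL_UM``.
    """

    points: np.ndarray
    window: Window
    labels: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.points = pts
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(pts):
                raise ValueError("labels length must match number of points")
        if len(pts):
            inside = self.window.contains_points(pts)
            if not inside.all():
                bad = np.flatnonzero(~inside)[:5]
                raise GeometryError(
                    f"{(~inside).sum()} point(s) outside window, first indices {bad.tolist()}")
            if len(pts) > 1:
                dup = cKDTree(pts).query_pairs(DUPLICATE_TOL_UM)
                if dup:
                    i, j = sorted(dup)[0]
                    raise GeometryError(
                        f"duplicate points within {DUPLICATE_TOL_UM} um (indices {i}, {j})")

    # -- basic properties --------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def intensity_per_mm2(self) -> float:
        """Mean density n / window area, in cells/mm^2."""
        return self.n / self.window.area_mm2

    def subset(self, mask: np.ndarray) -> "PointPattern":
        labels = self.labels[mask] if self.labels is not None else None
        return PointPattern(self.points[mask], self.window, labels, dict(self.meta))

    # -- serialization -----------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"x_um": self.points[:, 0], "y_um": self.points[:, 1]})
        df["label"] = self.labels if self.labels is not None else ""
        return df

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, window: Window, **meta) -> "PointPattern":
        df = pd.read_csv(path)
        for col in ("x_um", "y_um"):
            if col not in df.columns:
                raise ValueError(f"point CSV must have column {col!r}")
        labels = None
        if "label" in df.columns and df["label"].notna().any():
            labels = df["label"].fillna("").to_numpy()
        return cls(df[["x_um", "y_um"]].to_numpy(float), window, labels, meta)
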