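"""Neuron morphologies, Sholl analysis and tree morphometrics.

Morphologies are rooted trees in SWC semantics: each node has an id, a type
code, 3-D position (um), a radius (um) and a parent id (-1 for the root,
which is taken to be the soma).  Sholl analysis counts intersections of the
dendritic arbor with concentric circles centred on the soma; because retinal
whole-mounts are analysed en face, segments are projected to the (x, y) plane
before intersecting.

Crossings are computed by exact segment-circle intersection (roots of a
quadratic in the segment parameter), not by sampling.  Tie rules: a node
lying exactly on a circle counts once, and a tangent segment counts once.  At
radius zero the crossing count is defined as the number of primary dendrites
leaving the soma.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import MultiPoint

from .errors import ParameterError, SWCParseError

__all__ = ["Morphology", "ShollResult", "read_swc", "write_swc",
           "sholl_crossings", "morphometrics", "equivalent_diameter"]


def equivalent_diameter(points_xy: np.ndarray) -> float:
    """Diameter of the circle whose area equals the convex hull of the points.

    Returns 0.0 for degenerate (collinear or < 3 point) inputs.
    """
    pts = np.asarray(points_xy, dtype=float)
    if len(pts) < 3:
        return 0.0
    hull_area = MultiPoint(pts).convex_hull.area
    return 2.0 * float(np.sqrt(hull_area / np.pi))


@dataclass
class Morphology:
    """A rooted neuron tree with SWC node semantics.

    ``ids``, ``types``, ``radii`` and ``parents`` are parallel arrays;
    ``xyz`` is ``(N, 3)`` in um.  Exactly one node has parent -1 (the soma /
    root); every parent id must reference an existing node and the graph must
    be a single connected tree.
    """

    ids: np.ndarray
    types: np.ndarray
    xyz: np.ndarray
    radii: np.ndarray
    parents: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=int)
        self.types = np.asarray(self.types, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float)
        self.parents = np.asarray(self.parents, dtype=int)
        n = len(self.ids)
        if not (len(self.types) == len(self.xyz) == len(self.radii) == len(self.parents) == n):
            raise ValueError("morphology arrays must be parallel")
        if len(np.unique(self.ids)) != n:
            raise SWCParseError("duplicate node ids")
        roots = np.flatnonzero(self.parents == -1)
        if len(roots) != 1:
            raise SWCParseError(f"expected exactly one root (parent -1), found {len(roots)}")
        self._root_idx = int(roots[0])
        id_to_idx = {int(i): k for k, i in enumerate(self.ids)}
        self._id_to_idx = id_to_idx
        parent_idx = np.full(n, -1, dtype=int)
        for k in range(n):
            p = int(self.parents[k])
            if p == -1:
                continue
            if p not in id_to_idx:
                raise SWCParseError(f"node {int(self.ids[k])} references missing parent {p}")
            parent_idx[k] = id_to_idx[p]
        self._parent_idx = parent_idx
        # connectivity: walking parent links from every node must reach the root
        # (guards against cycles among non-root nodes)
        reach = np.zeros(n, dtype=bool)
        reach[self._root_idx] = True
        for k in range(n):
            path = []
            j = k
            while not reach[j]:
                path.append(j)
                j = parent_idx[j]
                if j == -1 or len(path) > n:
                    raise SWCParseError(f"node {int(self.ids[k])} is disconnected or in a cycle")
            reach[path] = True

    # -- tree structure ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def root(self) -> int:
        """Index (not id) of the root/soma node."""
        return self._root_idx

    @property
    def parent_index(self) -> np.ndarray:
        """Parent of each node as an array index (-1 for the root)."""
        return self._parent_idx

    def children_index(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for k, p in enumerate(self._parent_idx):
            if p >= 0:
                ch[p].append(k)
        return ch

    def edges(self) -> np.ndarray:
        """(E, 2) array of (parent_idx, child_idx) pairs."""
        child = np.flatnonzero(self._parent_idx >= 0)
        return np.column_stack([self._parent_idx[child], child])

    @property
    def soma_xy(self) -> np.ndarray:
        return self.xyz[self._root_idx, :2]


@dataclass
class ShollResult:
    """Sholl profile plus scalar morphometrics of one tree."""

    radii: np.ndarray
    crossings: np.ndarray
    n_branches: int
    n_junctions: int
    n_endpoints: int
    soma_diameter: float
    field_diameter: float

    def to_dict(self) -> dict:
        return {
            "n_branches": self.n_branches,
            "n_junctions": self.n_junctions,
            "n_endpoints": self.n_endpoints,
            "soma_diameter_um": self.soma_diameter,
            "field_diameter_um": self.field_diameter,
        }


# ---------------------------------------------------------------------------
# SWC i/o


def read_swc(source) -> Morphology:
    """Read a 7-column whitespace-delimited SWC file or stream.

    Lines starting with ``#`` are comments.  Raises
    :class:`~retinamosaic.errors.SWCParseError` with a line number for
    malformed lines, orphan nodes or multiple roots.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    ids, types, xyz, radii, parents = [], [], [], [], []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 7:
            raise SWCParseError(f"expected 7 columns, got {len(fields)}", line=lineno)
        try:
            ids.append(int(fields[0]))
            types.append(int(fields[1]))
            xyz.append([float(fields[2]), float(fields[3]), float(fields[4])])
            radii.append(float(fields[5]))
            parents.append(int(fields[6]))
        except ValueError as exc:
            raise SWCParseError(str(exc), line=lineno) from exc
    if not ids:
        raise SWCParseError("empty SWC file")
    return Morphology(np.array(ids), np.array(types), np.array(xyz),
                      np.array(radii), np.array(parents))


def write_swc(morph: Morphology, target) -> None:
    """Write standard 7-column SWC."""
    buf = io.StringIO()
    buf.write("# id type x y z radius parent\n")
    for k in range(morph.n_nodes):
        x, y, z = morph.xyz[k]
        buf.write(f"{int(morph.ids[k])} {int(morph.types[k])} "
                  f"{x:.4f} {y:.4f} {z:.4f} {morph.radii[k]:.4f} {int(morph.parents[k])}\n")
    if hasattr(target, "write"):
        target.write(buf.getvalue())
    else:
        with open(target, "w") as fh:
            fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Sholl analysis


def _circle_crossings_at(morph: Morphology, r: float, rel_xy: np.ndarray,
                         edges: np.ndarray) -> int:
    """Exact count of segment-circle intersections at radius r.

    Intersections at a segment's start point (t == 0) are not counted: they
    belong to the parent segment (where they occur at t == 1), so a shared
    node exactly on the circle counts once.  A tangent double root counts
    once.
    """
    p0 = rel_xy[edges[:, 0]]
    p1 = rel_xy[edges[:, 1]]
    d = p1 - p0
    a = np.einsum("ij,ij->i", d, d)
    b = 2.0 * np.einsum("ij,ij->i", p0, d)
    c = np.einsum("ij,ij->i", p0, p0) - r * r
    count = 0
    eps = 1e-9
    with np.errstate(invalid="ignore", divide="ignore"):
        disc = b * b - 4.0 * a * c
        ok = (a > 0) & (disc >= 0)
        sq = np.sqrt(np.where(ok, disc, 0.0))
        t1 = (-b - sq) / (2.0 * a)
        t2 = (-b + sq) / (2.0 * a)
    tangent = ok & (disc < eps * np.maximum(a, 1.0) ** 2)
    in1 = ok & (t1 > eps) & (t1 <= 1.0 + eps)
    in2 = ok & (t2 > eps) & (t2 <= 1.0 + eps) & ~tangent
    count = int(in1.sum() + in2.sum())
    return count


def sholl_crossings(morph: Morphology, r_max: float = 400.0,
                    step: float = 10.0) -> ShollResult:
    """Sholl profile: dendritic crossings of circles centred on the soma.

    Radii run 0, step, 2*step, ... up to ``r_max`` inclusive.  Crossings at
    radius 0 equal the number of primary dendrites.  The returned result also
    carries the tree's morphometrics (see :func:`morphometrics`).
    """
    if step <= 0:
        raise ParameterError("step must be > 0")
    if r_max < step:
        raise ParameterError("r_max must be >= step")
    radii = np.arange(0.0, r_max + step / 2, step)
    rel = morph.xyz[:, :2] - morph.soma_xy
    edges = morph.edges()
    counts = np.zeros(len(radii), dtype=int)
    n_primary = len(morph.children_index()[morph.root])
    for i, r in enumerate(radii):
        counts[i] = n_primary if r == 0 else _circle_crossings_at(morph, r, rel, edges)
    base = morphometrics(morph)
    return ShollResult(radii, counts, base.n_branches, base.n_junctions,
                       base.n_endpoints, base.soma_diameter, base.field_diameter)


def morphometrics(morph: Morphology) -> ShollResult:
    """Branch/junction/endpoint counts plus soma and dendritic-field diameters.

    * junctions: nodes with >= 2 children
    * endpoints: leaves (soma excluded)
    * branches: maximal unbranched paths, i.e. one per child of the root or of
      a junction
    * soma diameter: twice the root-node radius
    * field diameter: equivalent-circle diameter of the convex hull of the
      dendritic (non-root) node positions, projected en face
    """
    children = morph.children_index()
    root = morph.root
    n_junctions = sum(1 for k, ch in enumerate(children) if k != root and len(ch) >= 2)
    n_endpoints = sum(1 for k, ch in enumerate(children) if k != root and len(ch) == 0)
    n_branches = len(children[root]) + sum(
        len(ch) for k, ch in enumerate(children) if k != root and len(ch) >= 2)
    dendrite_xy = np.delete(morph.xyz[:, :2], root, axis=0)
    field_d = equivalent_diameter(dendrite_xy)
    return ShollResult(np.array([]), np.array([], dtype=int), n_branches,
                       n_junctions, n_endpoints,
                       2.0 * float(morph.radii[root]), field_d)
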