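"""In-plane packing analysis: plane intersections, 2D Voronoi, RDF.

Voronoi tessellation needs all key points in one plane, which thermal
motion normal to the eigenplane spoils for any single atom or the COM.
The key point used instead is the intersection of each molecule's
long-axis line (through the C3 and C13 anchors) with the crystallite
eigenplane; the intersections are then rotated into the z = 0 frame by
the single rigid rotation taking the plane normal to +z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, Voronoi

from quasicryst.eigenplane import Eigenplane
from quasicryst.model_io import SimulationBox

logger = logging.getLogger(__name__)

_Z = np.array([0.0, 0.0, 1.0])


def plane_line_intersection(c3: np.ndarray, c13: np.ndarray,
                            plane: Eigenplane,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Intersection of the line through two anchor atoms with a plane.

    The line is parametrized as P(l) = C3 + l * (C13 - C3); substituting
    into a*x + b*y + c*z = d gives
    l = (d - a*C3x - b*C3y - c*C3z) / (a*dx + b*dy + c*dz).
    Returns (points, l); the points satisfy the plane equation.
    Raises for lines (numerically) parallel to the plane.
    """
    c3 = np.atleast_2d(np.asarray(c3, float))
    c13 = np.atleast_2d(np.asarray(c13, float))
    delta = c13 - c3
    denom = delta @ plane.normal
    if np.any(np.abs(denom) < 1e-12):
        raise ValueError("molecule long axis lies in the plane; no intersection")
    l = (plane.d - c3 @ plane.normal) / denom
    points = c3 + l[:, None] * delta
    if c3.shape[0] == 1:
        return points[0], float(l[0])
    return points, l


def rotation_to_plane_frame(plane: Eigenplane) -> np.ndarray:
    """Proper rotation taking the plane normal to +z (axis-angle form).

    The rotation axis is (n x z)/|n x z| and the angle phi = arccos(n.z);
    with q = cos(phi), s = sin(phi), p = 1 - q and axis components
    (x, y, z) the matrix is

        [[x*x*p + q,  x*y*p - z*s,  x*z*p + y*s],
         [y*x*p + z*s, y*y*p + q,   y*z*p - x*s],
         [z*x*p - y*s, z*y*p + x*s, z*z*p + q ]]

    For n = +-z the rotation degenerates to the identity / a half turn
    about x.
    """
    n = plane.normal
    axis = np.cross(n, _Z)
    s = float(np.linalg.norm(axis))
    q = float(np.clip(n @ _Z, -1.0, 1.0))
    if s < 1e-15:
        if q > 0:
            return np.eye(3)
        return np.diag([1.0, -1.0, -1.0])  # half turn about x
    x, y, z = axis / s
    p = 1.0 - q
    return np.array([
        [x * x * p + q, x * y * p - z * s, x * z * p + y * s],
        [y * x * p + z * s, y * y * p + q, y * z * p - x * s],
        [z * x * p - y * s, z * y * p + x * s, z * z * p + q],
    ])


def to_plane_2d(points3d: np.ndarray, plane: Eigenplane) -> np.ndarray:
    """Rotate in-plane points to the z = 0 frame and drop the constant z."""
    R = rotation_to_plane_frame(plane)
    rotated = np.atleast_2d(points3d) @ R.T
    return rotated[:, :2]


@dataclass
class VoronoiCell:
    """Per-molecule Voronoi observables in the plane frame."""

    molecule_id: int
    area: float
    neighbor_ids: np.ndarray
    neighbor_distances: np.ndarray
    is_boundary: bool


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def voronoi_tessellate(points2d: np.ndarray,
                       molecule_ids: np.ndarray | None = None,
                       min_edge: float = 1e-9) -> list[VoronoiCell]:
    """2D Voronoi tessellation of in-plane key points.

    Neighbors are cells sharing a Voronoi edge longer than ``min_edge``
    (zero-length edges from cocircular degeneracies, e.g. square
    lattices, do not create neighbor pairs).  Cells that are unbounded
    or have a vertex outside the convex hull of the input points are
    flagged as boundary and should be excluded from area statistics;
    crystallites are finite, so edge cells have no meaningful area.
    Neighbor distances are Euclidean between generating points.
    """
    pts = np.asarray(points2d, float)
    if len(pts) < 4:
        raise ValueError("need at least 4 points for a 2D tessellation")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ValueError("points are collinear")
    ids = (np.arange(len(pts)) if molecule_ids is None
           else np.asarray(molecule_ids, int))
    vor = Voronoi(pts)
    hull = Delaunay(pts)

    neighbors: list[set[int]] = [set() for _ in range(len(pts))]
    for (i, j), ridge in zip(vor.ridge_points, vor.ridge_vertices):
        if -1 in ridge:
            neighbors[i].add(j)
            neighbors[j].add(i)  # infinite ridge: both cells are boundary
            continue
        edge = vor.vertices[ridge[0]] - vor.vertices[ridge[1]]
        if np.linalg.norm(edge) > min_edge:
            neighbors[i].add(j)
            neighbors[j].add(i)

    cells = []
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        unbounded = -1 in region or len(region) == 0
        if unbounded:
            area, boundary = np.nan, True
        else:
            verts = vor.vertices[region]
            boundary = bool(np.any(hull.find_simplex(verts) < 0))
            # order vertices by angle about the generator for the shoelace
            ang = np.arctan2(verts[:, 1] - pts[i, 1], verts[:, 0] - pts[i, 0])
            area = _polygon_area(verts[np.argsort(ang)])
        nb = np.array(sorted(neighbors[i]), dtype=int)
        dist = np.linalg.norm(pts[nb] - pts[i], axis=1)
        cells.append(VoronoiCell(molecule_id=int(ids[i]), area=float(area),
                                 neighbor_ids=ids[nb], neighbor_distances=dist,
                                 is_boundary=boundary))
    return cells


def neighbor_distance_histogram(cells_per_frame: list[list[VoronoiCell]],
                                bin_width: float = 0.005,
                                r_max: float | None = None,
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of interior-cell nearest-neighbor distances.

    Distances are pooled per frame over interior (non-boundary) cells
    and each frame contributes unit total weight; frames are then
    averaged.  Returns (bin_centers, weights).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    per_frame = []
    for cells in cells_per_frame:
        d = np.concatenate([c.neighbor_distances for c in cells
                            if not c.is_boundary] or [np.empty(0)])
        per_frame.append(d)
    if all(d.size == 0 for d in per_frame):
        logger.warning("no interior cells: empty neighbor-distance histogram")
        return np.empty(0), np.empty(0)
    if r_max is None:
        r_max = max(d.max() for d in per_frame if d.size) * 1.05
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    weights = np.zeros(len(edges) - 1)
    n_frames = 0
    for d in per_frame:
        if d.size == 0:
            continue
        h, _ = np.histogram(d, bins=edges)
        weights += h / d.size
        n_frames += 1
    weights /= max(n_frames, 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, weights


@dataclass
class RdfProfile:
    """Radial distribution function g(r) between molecular COMs."""

    bin_centers: np.ndarray
    g: np.ndarray
    bin_width: float
    r_max: float
    n_frames: int


def com_rdf(com_points_per_frame: list[np.ndarray], box: SimulationBox,
            bin_width: float = 0.01, r_max: float | None = None) -> RdfProfile:
    """COM-COM pair correlation in an orthorhombic periodic box.

    Pair distances use the minimum-image convention; counts are
    normalized by the ideal-gas expectation at the selection's number
    density in the box volume and averaged over frames.  ``r_max``
    defaults to 0.45 * the smallest box edge and may not exceed half of
    it (minimum-image validity).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    L = box.lengths
    if r_max is None:
        r_max = 0.45 * float(L.min())
    if r_max > 0.5 * float(L.min()):
        raise ValueError("r_max exceeds half the smallest box edge")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    volume = float(np.prod(L))
    g_acc = np.zeros(len(edges) - 1)
    n_frames = 0
    for pts in com_points_per_frame:
        pts = np.asarray(pts, float)
        n = len(pts)
        if n < 2:
            continue
        delta = pts[:, None, :] - pts[None, :, :]
        delta -= np.round(delta / L) * L
        dist = np.linalg.norm(delta, axis=2)
        iu = np.triu_indices(n, k=1)
        h, _ = np.histogram(dist[iu], bins=edges)
        # n*(n-1)/2 pairs; ideal count per pair-shell = shell_vol * (n-1)/(2V) * n
        ideal = shell_vol * n * (n - 1) / (2.0 * volume)
        g_acc += h / ideal
        n_frames += 1
    if n_frames == 0:
        raise ValueError("no frame contained at least two points")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RdfProfile(bin_centers=centers, g=g_acc / n_frames,
                      bin_width=bin_width, r_max=r_max, n_frames=n_frames)
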