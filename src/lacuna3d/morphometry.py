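"""Per-component morphometry: volume, Feret diameters, aspect ratio.

For each labeled component we report

* ``volume_um3`` — voxel count times voxel volume (voxel counting, so the
  sum over components equals the total void volume exactly);
* ``max_feret_um`` — the maximum caliper (Feret) diameter: the largest
  pairwise distance over the component's point cloud;
* ``min_orth_feret_um`` — the minimum caliper width measured in the plane
  orthogonal to the achieved maximum-Feret direction (rotating-calipers
  minimum width of the projected 2D hull);
* ``aspect_ratio`` — psi_A = min_orth_feret / max_feret, in (0, 1].

Geometry is computed on the component's *cell-corner* point cloud: every
surface voxel contributes the 8 corners of its voxel cell (in physical um),
so calipers measure the extent of the occupied cells, not of their centers,
and a single voxel has nonzero extent.  Degenerate projected widths are
guarded to one voxel edge so psi_A stays strictly positive.

An alternative reading of the minimum Feret — the global minimum caliper
over all 3D directions, not restricted to the orthogonal plane — is
available via :func:`min_feret_3d` and the ``min_feret_mode`` pipeline
option; the mode used is recorded in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .errors import NumericError
from .labeling import STRUCTURE_6, LabelMap

_CORNER_OFFSETS = np.array(
    [[dz, dy, dx] for dz in (0, 1) for dy in (0, 1) for dx in (0, 1)], dtype=np.int64
)


@dataclass
class LacunaRecord:
    """Morphometrics of one segmented object (one label)."""

    label: int
    voxel_count: int
    volume_um3: float
    centroid_um: tuple[float, float, float]
    max_feret_um: float
    min_orth_feret_um: float
    aspect_ratio: float


def _corner_cloud(voxels: np.ndarray, spacing) -> np.ndarray:
    """Unique cell-corner coordinates (um) of the given voxel indices.

    Voxel ``(i, j, k)`` occupies the cell ``[i, i+1] x [j, j+1] x [k, k+1]``
    in index units; its center is at ``(i+0.5, j+0.5, k+0.5) * spacing``.
    """
    corners = (voxels[:, None, :] + _CORNER_OFFSETS[None, :, :]).reshape(-1, 3)
    corners = np.unique(corners, axis=0)
    return corners * np.asarray(spacing, dtype=np.float64)


def component_points(labelmap: LabelMap, label_id: int) -> np.ndarray:
    """Cell-corner point cloud (um) of a component's surface voxels.

    Interior voxels are dropped first (their corners cannot be hull
    vertices), which leaves caliper measures unchanged.
    """
    if not 1 <= label_id <= labelmap.n_labels:
        raise NumericError(f"label {label_id} outside 1..{labelmap.n_labels}")
    mask = labelmap.data == label_id
    voxels = _surface_voxels(mask)
    return _corner_cloud(voxels, labelmap.spacing)


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Indices of mask voxels with at least one 6-neighbor outside the mask
    (array borders count as outside)."""
    if not mask.any():
        raise NumericError("empty component")
    eroded = ndimage.binary_erosion(mask, structure=STRUCTURE_6, border_value=0)
    surface = mask & ~eroded
    return np.argwhere(surface)


def _hull_vertices(points: np.ndarray) -> np.ndarray:
    """Convex hull vertices; falls back to the full set for degenerate
    (coplanar/collinear) clouds, which Qhull rejects."""
    if len(points) >= 4:
        try:
            return points[ConvexHull(points).vertices]
        except QhullError:
            pass
    return points


def max_feret(points: np.ndarray) -> float:
    """Maximum Feret diameter: largest pairwise distance of the cloud."""
    d, _, _ = _max_feret_pair(points)
    return d


def _max_feret_pair(points: np.ndarray) -> tuple[float, np.ndarray, tuple[int, int]]:
    """Max pairwise distance over hull vertices, with the achieving unit
    direction.  Ties are broken toward the lexicographically smallest vertex
    pair (hull vertices sorted), so the axis is deterministic."""
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) == 0:
        raise NumericError("max_feret needs a nonempty (n, 3) point set")
    if len(points) == 1:
        return 0.0, np.array([0.0, 0.0, 1.0]), (0, 0)
    hull = _hull_vertices(points)
    hull = np.unique(hull, axis=0)  # lexicographic sort -> deterministic ties
    diff = hull[:, None, :] - hull[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    dmax2 = d2.max()
    if dmax2 == 0.0:
        return 0.0, np.array([0.0, 0.0, 1.0]), (0, 0)
    i, j = np.argwhere(d2 == dmax2)[0]  # first in row-major = smallest (i, j)
    axis = hull[j] - hull[i]
    d = float(np.sqrt(dmax2))
    return d, axis / np.linalg.norm(axis), (int(i), int(j))


def brute_force_max_feret(points: np.ndarray) -> float:
    """O(n^2) oracle over *all* point pairs (no hull)."""
    points = np.asarray(points, dtype=np.float64)
    if len(points) == 0:
        raise NumericError("empty point set")
    diff = points[:, None, :] - points[None, :, :]
    return float(np.sqrt(np.einsum("ijk,ijk->ij", diff, diff).max()))


def _orthonormal_plane(axis: np.ndarray) -> np.ndarray:
    """Deterministic orthonormal basis (2, 3) of the plane orthogonal to
    ``axis``."""
    axis = axis / np.linalg.norm(axis)
    e = np.zeros(3)
    e[int(np.argmin(np.abs(axis)))] = 1.0
    u = np.cross(axis, e)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return np.stack([u, v])


def _min_width_2d(pts2: np.ndarray) -> float:
    """Minimum directional width of a 2D point cloud (rotating calipers:
    the minimum width of a convex polygon is attained with one edge flush)."""
    pts2 = np.unique(pts2, axis=0)
    if len(pts2) < 3:
        if len(pts2) < 2:
            return 0.0
        return 0.0  # two points: zero width orthogonal to their segment
    try:
        hull = ConvexHull(pts2)
    except QhullError:
        return 0.0  # collinear cloud
    verts = pts2[hull.vertices]  # counter-clockwise order
    edges = np.roll(verts, -1, axis=0) - verts
    lengths = np.linalg.norm(edges, axis=1)
    good = lengths > 0
    normals = np.stack([-edges[:, 1], edges[:, 0]], axis=1)[good] / lengths[good, None]
    # width for each edge direction = max distance of any vertex from the edge line
    proj = normals @ verts.T  # (n_edges, n_verts)
    widths = proj.max(axis=1) - proj.min(axis=1)
    return float(widths.min())


def min_orth_feret(points: np.ndarray, max_axis: np.ndarray, guard: float = 0.0) -> float:
    """Minimum caliper width in the plane orthogonal to the max-Feret axis.

    Degenerate (collinear or single-point) projections return ``guard``
    (the pipeline passes one voxel edge length) instead of zero.
    """
    points = np.asarray(points, dtype=np.float64)
    if len(points) == 0:
        raise NumericError("min_orth_feret needs a nonempty point set")
    basis = _orthonormal_plane(np.asarray(max_axis, dtype=np.float64))
    pts2 = points @ basis.T
    return max(_min_width_2d(pts2), float(guard))


def min_feret_3d(points: np.ndarray, n_dirs: int = 2000) -> float:
    """Global minimum caliper width over 3D directions (Fibonacci-sphere
    scan).  Alternative min-Feret reading; approximate to the angular grid."""
    points = np.asarray(points, dtype=np.float64)
    if len(points) == 0:
        raise NumericError("empty point set")
    hull = _hull_vertices(points)
    i = np.arange(n_dirs)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (i + 0.5) * (2.0 / n_dirs)
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    dirs = np.stack([z, r * np.sin(phi), r * np.cos(phi)], axis=1)
    proj = dirs @ hull.T
    widths = proj.max(axis=1) - proj.min(axis=1)
    return float(widths.min())


def measure_points(
    points: np.ndarray, guard: float = 0.0, min_feret_mode: str = "orthogonal"
) -> tuple[float, float, float]:
    """(max_feret, min_feret, aspect_ratio) of a corner cloud."""
    dmax, axis, _ = _max_feret_pair(points)
    if dmax == 0.0:
        dmax = max(guard, np.finfo(float).tiny)
    if min_feret_mode == "orthogonal":
        dmin = min_orth_feret(points, axis, guard=guard)
    elif min_feret_mode == "global3d":
        dmin = max(min_feret_3d(points), guard)
    else:
        raise NumericError(f"unknown min_feret_mode: {min_feret_mode!r}")
    ar = min(1.0, dmin / dmax) if dmax > 0 else 1.0
    ar = max(ar, np.finfo(float).tiny)  # psi_A in (0, 1]
    return float(dmax), float(dmin), float(ar)


def measure_component(
    labelmap: LabelMap, label_id: int, min_feret_mode: str = "orthogonal"
) -> LacunaRecord:
    """Full morphometric record for one label."""
    if not 1 <= label_id <= labelmap.n_labels:
        raise NumericError(f"label {label_id} outside 1..{labelmap.n_labels}")
    mask = labelmap.data == label_id
    return _measure_mask(mask, label_id, labelmap.spacing, min_feret_mode, origin=(0, 0, 0))


def _measure_mask(mask, label_id, spacing, min_feret_mode, origin) -> LacunaRecord:
    spacing = np.asarray(spacing, dtype=np.float64)
    voxels = np.argwhere(mask)
    if voxels.size == 0:
        raise NumericError(f"label {label_id} has no voxels")
    origin = np.asarray(origin, dtype=np.int64)
    count = int(len(voxels))
    vv = float(spacing.prod())
    centroid = ((voxels + origin) + 0.5).mean(axis=0) * spacing
    surface = _surface_voxels(mask) + origin
    points = _corner_cloud(surface, spacing)
    guard = float(spacing.min())
    dmax, dmin, ar = measure_points(points, guard=guard, min_feret_mode=min_feret_mode)
    return LacunaRecord(
        label=int(label_id),
        voxel_count=count,
        volume_um3=count * vv,
        centroid_um=tuple(float(c) for c in centroid),
        max_feret_um=dmax,
        min_orth_feret_um=dmin,
        aspect_ratio=ar,
    )


def measure_all(
    labelmap: LabelMap,
    label_ids=None,
    min_feret_mode: str = "orthogonal",
) -> list[LacunaRecord]:
    """Measure many labels efficiently (bounding-box local crops).

    ``label_ids`` restricts measurement to a subset (e.g. labels already
    inside the analysis volume window); default is all labels.
    """
    objects = ndimage.find_objects(labelmap.data)
    if label_ids is None:
        label_ids = range(1, labelmap.n_labels + 1)
    records = []
    for lid in label_ids:
        lid = int(lid)
        if not 1 <= lid <= labelmap.n_labels:
            raise NumericError(f"label {lid} outside 1..{labelmap.n_labels}")
        sl = objects[lid - 1]
        if sl is None:
            raise NumericError(f"label {lid} has no voxels")
        local = labelmap.data[sl] == lid
        origin = tuple(s.start for s in sl)
        records.append(
            _measure_mask(local, lid, labelmap.spacing, min_feret_mode, origin=origin)
        )
    return records
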