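"""Surface reconstruction accuracy metrics.

Three metrics compare a recovered mesh against a reference surface (e.g. a
registered 3D scan represented as a point cloud):

* *surface distance*: each mesh vertex is projected onto the plane through
  its three nearest reference points; the projection vector gives both the
  scalar distance and its per-axis (x, y, z) decomposition, where x/y are
  parallel to the image plane and z to the optical axis;
* *HD95*: the 95th-percentile symmetric Hausdorff distance between two
  point sets;
* *Cauchy edge strain*: per-edge relative length change ``(L - L0) / L0``
  against the initial mesh, a rigid-motion-invariant deformation map.

A thin ICP wrapper registers reference scans into camera coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .meshcore import TriangleMesh

__all__ = [
    "SurfaceDistanceReport",
    "surface_distance",
    "hd95",
    "cauchy_edge_strain",
    "register_icp",
]


@dataclass
class SurfaceDistanceReport:
    """Per-vertex plane-projection distances and their axis decomposition.

    ``components[i]`` is the projection vector ``V0 - P0`` (mm) of vertex i;
    ``distance[i]`` is its norm.  Summaries (max/mean/std, overall and per
    axis) are recomputed from the per-vertex table on demand; per-axis
    statistics are taken on the magnitudes, matching how stereo depth error
    is conventionally reported.
    """

    distance: np.ndarray      # (N,)
    components: np.ndarray    # (N, 3) signed

    def summary(self) -> dict:
        mag = np.abs(self.components)
        out = {
            "all": {"max": float(self.distance.max()),
                    "mean": float(self.distance.mean()),
                    "std": float(self.distance.std())},
        }
        for k, axis in enumerate("xyz"):
            out[axis] = {"max": float(mag[:, k].max()),
                         "mean": float(mag[:, k].mean()),
                         "std": float(mag[:, k].std())}
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "vertex": np.arange(len(self.distance)),
            "distance": self.distance,
            "dx": self.components[:, 0],
            "dy": self.components[:, 1],
            "dz": self.components[:, 2],
        })


def _plane_projection(v0: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Project v0 onto plane(a, b, c); returns (projection, normal) or None
    if the triple is collinear."""
    n = np.cross(b - a, c - a)
    norm = np.linalg.norm(n)
    if norm < 1e-12 * max(np.linalg.norm(b - a), np.linalg.norm(c - a), 1e-300):
        return None
    n = n / norm
    return v0 - np.dot(v0 - a, n) * n


def surface_distance(
    mesh: TriangleMesh | np.ndarray,
    reference_points: np.ndarray,
) -> SurfaceDistanceReport:
    """Three-point plane-projection distance from mesh vertices to a scan.

    For every vertex the three closest reference points span a local plane;
    the vertex's distance is to its orthogonal projection on that plane.
    Collinear triples fall back to the next nearest point until a proper
    plane is found.

    Raises
    ------
    ValueError
        For fewer than 3 reference points.
    """
    vertices = mesh.vertices if isinstance(mesh, TriangleMesh) else np.asarray(mesh, float)
    reference_points = np.asarray(reference_points, dtype=np.float64)
    if len(reference_points) < 3:
        raise ValueError("need at least 3 reference points")
    tree = cKDTree(reference_points)
    k_max = min(len(reference_points), 12)
    _, nn_all = tree.query(vertices, k=k_max)
    nn_all = np.atleast_2d(nn_all)

    # vectorized common case: the 3 nearest points span a proper plane
    a = reference_points[nn_all[:, 0]]
    b = reference_points[nn_all[:, 1]]
    c = reference_points[nn_all[:, 2]]
    n = np.cross(b - a, c - a)
    norms = np.linalg.norm(n, axis=1)
    scale = np.maximum(np.linalg.norm(b - a, axis=1), np.linalg.norm(c - a, axis=1))
    ok = norms >= 1e-12 * np.maximum(scale, 1e-300)
    unit = n / np.where(ok, norms, 1.0)[:, None]
    components = ((vertices - a) * unit).sum(axis=1)[:, None] * unit
    # collinear triples: replace the third point by ever-farther neighbours
    for i in np.flatnonzero(~ok):
        nn = nn_all[i]
        proj = None
        for extra in range(3, len(nn)):
            proj = _plane_projection(vertices[i], reference_points[nn[0]],
                                     reference_points[nn[1]],
                                     reference_points[nn[extra]])
            if proj is not None:
                break
        if proj is None:
            raise ValueError(f"reference points around vertex {i} are collinear")
        components[i] = vertices[i] - proj
    distance = np.linalg.norm(components, axis=1)
    return SurfaceDistanceReport(distance=distance, components=components)


def hd95(points_a: np.ndarray, points_b: np.ndarray, directed: bool = False) -> float:
    """95th-percentile Hausdorff distance (mm) between two point sets.

    Symmetric by default: the maximum of the two directed 95th percentiles
    (linear interpolation).  With ``directed=True`` only a -> b is used.
    """
    points_a = np.asarray(points_a, dtype=np.float64)
    points_b = np.asarray(points_b, dtype=np.float64)
    if len(points_a) == 0 or len(points_b) == 0:
        raise ValueError("point sets must be non-empty")
    d_ab = cKDTree(points_b).query(points_a)[0]
    ab = float(np.percentile(d_ab, 95, method="linear"))
    if directed:
        return ab
    d_ba = cKDTree(points_a).query(points_b)[0]
    ba = float(np.percentile(d_ba, 95, method="linear"))
    return max(ab, ba)


def cauchy_edge_strain(mesh_t: TriangleMesh, mesh_0: TriangleMesh) -> np.ndarray:
    """Per-edge Cauchy strain ``(L - L0) / L0`` against the initial mesh.

    Requires identical connectivity; rigid motion of ``mesh_t`` leaves the
    strains unchanged since only edge lengths enter.
    """
    if mesh_t.n_vertices != mesh_0.n_vertices or not np.array_equal(mesh_t.faces, mesh_0.faces):
        raise ValueError("meshes must share connectivity")
    e = mesh_0.edges
    l0 = np.linalg.norm(mesh_0.vertices[e[:, 0]] - mesh_0.vertices[e[:, 1]], axis=1)
    if (l0 == 0).any():
        raise ValueError("initial mesh contains zero-length edges")
    lt = np.linalg.norm(mesh_t.vertices[e[:, 0]] - mesh_t.vertices[e[:, 1]], axis=1)
    return (lt - l0) / l0


def register_icp(
    moving_points: np.ndarray,
    fixed_points: np.ndarray,
    init: np.ndarray | None = None,
    threshold: float = 1e-7,
    max_iterations: int = 50,
) -> tuple[np.ndarray, float, bool]:
    """Rigid point-to-point ICP; returns (4x4 transform, RMS residual, ok).

    ``ok`` is False when the final RMS residual exceeds ten times the median
    nearest-neighbour spacing of the fixed set (likely divergence).
    """
    import trimesh.registration

    moving_points = np.asarray(moving_points, dtype=np.float64)
    fixed_points = np.asarray(fixed_points, dtype=np.float64)
    matrix, _, cost = trimesh.registration.icp(
        moving_points, fixed_points,
        initial=np.eye(4) if init is None else init,
        threshold=threshold, max_iterations=max_iterations, scale=False,
    )
    rms = float(cost)
    d, _ = cKDTree(fixed_points).query(fixed_points, k=2)
    ok = rms <= 10.0 * max(float(np.median(d[:, 1])), 1e-9)
    return np.asarray(matrix), rms, ok
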