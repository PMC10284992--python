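"""Triangle mesh container, edge connectivity, and differential-coordinate operators.

The deformation recovery pipeline represents the tissue surface as a triangle
mesh in the left-camera frame (x right, y down, z along the optical axis;
units mm, z increasing with depth).  Two sparse operators are built from the
mesh connectivity and reused for every frame:

* the *differential edge matrix* ``E`` (one row per edge, +1 on the smaller
  vertex index, -1 on the larger), whose product with the vertex coordinate
  matrix yields per-edge difference vectors ("delta coordinates"); and
* the combinatorial graph Laplacian ``L = D - A``, used as the classical
  baseline smoothness operator.  ``L == E.T @ E`` holds exactly.

Both operators are derived from the *initial* mesh and kept fixed over the
whole sequence; only vertex positions are updated frame to frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay

__all__ = [
    "TriangleMesh",
    "DifferentialEdgeSystem",
    "MeshError",
    "MeshIOError",
    "build_edges",
    "build_differential_edge_matrix",
    "build_laplacian_matrix",
    "compute_delta_coordinates",
    "initialize_mesh_from_points",
    "load_mesh",
    "save_mesh",
]


class MeshError(ValueError):
    """Invalid mesh topology or geometry."""


class MeshIOError(IOError):
    """Mesh file could not be parsed or written."""


def build_edges(faces: np.ndarray) -> np.ndarray:
    """Extract the unique undirected edge list of a triangle list.

    Parameters
    ----------
    faces : (F, 3) int array
        Triangles as vertex index triples.

    Returns
    -------
    (N_edge, 2) int array
        Each undirected edge exactly once as ``(j, k)`` with ``j < k``,
        rows sorted lexicographically.  Deterministic and invariant under
        permutation of the face list.

    Raises
    ------
    MeshError
        If any face repeats a vertex (degenerate triangle).
    """
    faces = np.asarray(faces, dtype=np.int64)
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise MeshError(f"faces must be (F, 3), got {faces.shape}")
    degenerate = (
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 0] == faces[:, 2])
        | (faces[:, 1] == faces[:, 2])
    )
    if degenerate.any():
        bad = int(np.flatnonzero(degenerate)[0])
        raise MeshError(f"degenerate face at index {bad}: {faces[bad].tolist()}")
    pairs = faces[:, [0, 1, 0, 2, 1, 2]].reshape(-1, 2)
    pairs = np.sort(pairs, axis=1)
    return np.unique(pairs, axis=0)


@dataclass
class TriangleMesh:
    """Triangle surface mesh in left-camera coordinates (mm).

    Attributes
    ----------
    vertices : (N, 3) float array
        Vertex positions.
    faces : (F, 3) int array
        0-based triangle vertex indices.

    The unique edge list and connected-component labelling are computed
    lazily from the face list and cached.  Disconnected meshes are legal
    (each component is reported) but most pipeline stages expect a single
    component.
    """

    vertices: np.ndarray
    faces: np.ndarray
    _edges: np.ndarray | None = field(default=None, repr=False, compare=False)
    _labels: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError(f"vertices must be (N, 3), got {self.vertices.shape}")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshError("face index out of range [0, N)")
        build_edges(self.faces)  # validates degeneracy eagerly

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def edges(self) -> np.ndarray:
        if self._edges is None:
            self._edges = build_edges(self.faces)
        return self._edges

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric boolean vertex adjacency matrix."""
        e = self.edges
        n = self.n_vertices
        data = np.ones(len(e), dtype=bool)
        a = sp.coo_matrix((data, (e[:, 0], e[:, 1])), shape=(n, n))
        return (a + a.T).tocsr()

    def component_labels(self) -> np.ndarray:
        """Connected-component label of every vertex in the edge graph."""
        if self._labels is None:
            _, self._labels = connected_components(self.adjacency(), directed=False)
        return self._labels

    @property
    def n_components(self) -> int:
        return int(self.component_labels().max()) + 1 if self.n_vertices else 0

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        """Copy of this mesh with replaced vertex positions (same connectivity)."""
        m = TriangleMesh(np.asarray(vertices, dtype=np.float64), self.faces)
        m._edges = self._edges
        m._labels = self._labels
        return m

    def mean_edge_length(self) -> float:
        e = self.edges
        d = self.vertices[e[:, 0]] - self.vertices[e[:, 1]]
        return float(np.linalg.norm(d, axis=1).mean())


def build_differential_edge_matrix(edges: np.ndarray, n_vertices: int) -> sp.csr_matrix:
    """Signed edge-incidence matrix: row i of edge (j, k) has +1 at j, -1 at k.

    Every row has exactly two non-zeros summing to zero, so constant vertex
    fields (rigid translations applied per coordinate) are annihilated.
    ``rank(E) = N - (#connected components)``.
    """
    edges = np.asarray(edges, dtype=np.int64)
    if edges.size and (edges.min() < 0 or edges.max() >= n_vertices):
        raise MeshError("edge index out of range [0, N)")
    m = len(edges)
    rows = np.repeat(np.arange(m), 2)
    cols = edges.reshape(-1)
    data = np.tile([1.0, -1.0], m)
    return sp.csr_matrix((data, (rows, cols)), shape=(m, n_vertices))


def build_laplacian_matrix(edges: np.ndarray, n_vertices: int) -> sp.csr_matrix:
    """Uniform-weight graph Laplacian L = D - A; equals ``E.T @ E`` exactly."""
    e = build_differential_edge_matrix(edges, n_vertices)
    return (e.T @ e).tocsr()


def compute_delta_coordinates(E: sp.spmatrix, c0: np.ndarray) -> np.ndarray:
    """Delta (differential) coordinates of the initial mesh: ``E @ C0``.

    Computed once from the initial vertex positions and held fixed for the
    whole sequence: the smoothness term pulls each frame's edge difference
    vectors back toward these reference values.
    """
    c0 = np.asarray(c0, dtype=np.float64)
    if c0.ndim != 2 or c0.shape[0] != E.shape[1]:
        raise MeshError(
            f"C0 shape {c0.shape} incompatible with E shape {tuple(E.shape)}"
        )
    return np.asarray(E @ c0)


def initialize_mesh_from_points(
    points: np.ndarray,
    max_edge_factor: float = 3.0,
    min_points: int = 100,
) -> TriangleMesh:
    """Build a surface mesh from a reconstructed 3D point cloud.

    The points are projected onto their PCA plane (camera-facing surfaces are
    height fields over that plane), triangulated by 2D Delaunay, and hull
    triangles whose longest edge exceeds ``max_edge_factor`` times the median
    nearest-neighbour spacing are dropped so the mesh follows the point
    support instead of its convex hull.  Only the largest connected component
    is kept.  The input points themselves become the mesh vertices, so the
    mesh interpolates the reconstruction.

    Raises
    ------
    MeshError
        For fewer than ``min_points`` input points or a degenerate
        (collinear) configuration.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 3:
        raise MeshError(f"points must be (N, 3), got {points.shape}")
    if len(points) < min_points:
        raise MeshError(f"need at least {min_points} points, got {len(points)}")
    centred = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] < 1e-12 * s[0]:
        raise MeshError("points are collinear; cannot estimate a surface plane")
    uv = centred @ vt[:2].T
    tri = Delaunay(uv)
    faces = tri.simplices.astype(np.int64)

    # spacing scale from a subsample (median NN distance in the plane)
    from scipy.spatial import cKDTree

    tree = cKDTree(uv)
    d, _ = tree.query(uv, k=2)
    spacing = float(np.median(d[:, 1]))
    edge_vecs = uv[faces] - uv[np.roll(faces, 1, axis=1)]
    longest = np.linalg.norm(edge_vecs, axis=2).max(axis=1)
    faces = faces[longest <= max_edge_factor * spacing]
    if len(faces) == 0:
        raise MeshError("no triangles survive the edge-length crop")

    mesh = TriangleMesh(points, faces)
    if mesh.n_components > 1:
        labels = mesh.component_labels()
        keep = np.bincount(labels).argmax()
        mask = labels == keep
        remap = -np.ones(mesh.n_vertices, dtype=np.int64)
        remap[mask] = np.arange(mask.sum())
        faces = remap[faces]
        faces = faces[(faces >= 0).all(axis=1)]
        mesh = TriangleMesh(points[mask], faces)
    return mesh


def load_mesh(path) -> TriangleMesh:
    """Load a PLY or OBJ mesh; indices are converted to 0-based internally."""
    import trimesh

    try:
        tm = trimesh.load_mesh(str(path), process=False, maintain_order=True)
    except Exception as exc:  # trimesh raises a zoo of exception types
        raise MeshIOError(f"cannot parse mesh file {path}: {exc}") from exc
    if not hasattr(tm, "faces") or tm.faces is None or len(tm.faces) == 0:
        raise MeshIOError(f"file {path} contains no triangle faces")
    return TriangleMesh(np.asarray(tm.vertices, dtype=np.float64),
                        np.asarray(tm.faces, dtype=np.int64))


def save_mesh(mesh: TriangleMesh, path) -> None:
    """Write a mesh as PLY or OBJ (by extension); vertices kept in mm."""
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    try:
        tm.export(str(path))
    except Exception as exc:
        raise MeshIOError(f"cannot write mesh file {path}: {exc}") from exc


def load_point_cloud(path) -> np.ndarray:
    """Load a PLY/OBJ point cloud (vertices only) as an (N, 3) array."""
    import trimesh

    try:
        obj = trimesh.load(str(path), process=False, maintain_order=True)
    except Exception as exc:
        raise MeshIOError(f"cannot parse point file {path}: {exc}") from exc
    return np.asarray(obj.vertices, dtype=np.float64)


def save_point_cloud(points: np.ndarray, path) -> None:
    import trimesh

    trimesh.PointCloud(np.asarray(points, dtype=np.float64)).export(str(path))


@dataclass
class DifferentialEdgeSystem:
    """Smoothness operator bundle: E, its delta coordinates, and the weight.

    ``delta`` is computed from the initial mesh and immutable across frames.
    ``alpha`` is the smoothness weight (dimensionless); values between 1 and
    2 balance the dynamic and smoothness residuals at mm scale.
    """

    E: sp.csr_matrix
    delta: np.ndarray
    alpha: float

    @classmethod
    def from_mesh(cls, mesh: TriangleMesh, alpha: float = 1.5) -> "DifferentialEdgeSystem":
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        E = build_differential_edge_matrix(mesh.edges, mesh.n_vertices)
        return cls(E=E, delta=compute_delta_coordinates(E, mesh.vertices), alpha=float(alpha))
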