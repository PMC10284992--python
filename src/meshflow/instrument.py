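"""Instrument (surgical tool) tracking and occlusion constraints.

The tool is described by a coarse binary mask in the left image, propagated
frame to frame by forward-warping along the optical flow.  Mesh vertices
whose projection lands on the mask are *occluded*: their scene flow belongs
to the tool, not the tissue, so they carry no dynamic-term rows.  Instead
each occluded vertex receives a one-sided depth bound: the recovered tissue
surface must stay at least as deep as the tool above it, ``z >= p_z + delta``
with ``p_z`` the depth of the nearest reconstructed instrument point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .meshcore import TriangleMesh
from .sceneflow import StereoCalibration, triangulate

__all__ = [
    "OcclusionConstraintSet",
    "propagate_mask",
    "detect_occluded_vertices",
    "compute_depth_bounds",
    "instrument_points_from_disparity",
]


@dataclass
class OcclusionConstraintSet:
    """Depth bounds for occluded vertices.

    indices : unique occluded vertex indices.
    p_z : per-occluded-vertex depth bound (mm), same length as indices.
    delta : non-negative safety margin (mm); the constraint applied to the
        z coordinate is ``z >= p_z + delta``.
    """

    indices: np.ndarray
    p_z: np.ndarray
    delta: float = 0.0

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.p_z = np.asarray(self.p_z, dtype=np.float64)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("occluded vertex indices must be unique")
        if self.p_z.shape != self.indices.shape:
            raise ValueError("p_z must align with indices")
        if not np.isfinite(self.p_z).all():
            raise ValueError("p_z bounds must be finite")
        if self.delta < 0:
            raise ValueError("delta margin must be non-negative")

    @property
    def n(self) -> int:
        return len(self.indices)

    @classmethod
    def empty(cls) -> "OcclusionConstraintSet":
        return cls(np.empty(0, dtype=np.int64), np.empty(0))

    def lower_bounds(self, n_vertices: int) -> np.ndarray:
        """Dense (N,) lower-bound vector, -inf where unconstrained."""
        lb = np.full(n_vertices, -np.inf)
        lb[self.indices] = self.p_z + self.delta
        return lb


def propagate_mask(mask: np.ndarray, flow: np.ndarray) -> np.ndarray:
    """Forward-warp a binary mask along optical flow; close small holes.

    Masked pixels move to their rounded flow endpoints; pixels warped out of
    the frame are dropped.  A single 3x3 binary closing fills the
    one-pixel holes left by the scatter.
    """
    mask = np.asarray(mask, dtype=bool)
    flow = np.asarray(flow, dtype=np.float64)
    if flow.shape[:2] != mask.shape or flow.ndim != 3 or flow.shape[2] != 2:
        raise ValueError("mask and flow dimensions do not match")
    h, w = mask.shape
    rows, cols = np.nonzero(mask)
    tc = np.rint(cols + flow[rows, cols, 0]).astype(np.int64)
    tr = np.rint(rows + flow[rows, cols, 1]).astype(np.int64)
    keep = (tc >= 0) & (tc < w) & (tr >= 0) & (tr < h)
    out = np.zeros_like(mask)
    out[tr[keep], tc[keep]] = True

    from skimage.morphology import closing, footprint_rectangle

    return closing(out, footprint_rectangle((3, 3))).astype(bool)


def detect_occluded_vertices(
    mesh: TriangleMesh,
    mask: np.ndarray,
    calib: StereoCalibration,
) -> np.ndarray:
    """Indices of vertices whose image projection lies on a mask pixel.

    Projections are rounded to the nearest pixel; vertices projecting
    outside the image are not occluded.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    pix = calib.project(mesh.vertices)
    u = np.rint(pix[:, 0]).astype(np.int64)
    v = np.rint(pix[:, 1]).astype(np.int64)
    inside = (u >= 0) & (u < w) & (v >= 0) & (v < h)
    occluded = np.zeros(mesh.n_vertices, dtype=bool)
    occluded[inside] = mask[v[inside], u[inside]]
    return np.flatnonzero(occluded)


def compute_depth_bounds(
    occluded: np.ndarray,
    instrument_points: np.ndarray,
    mesh_prev: TriangleMesh,
    delta: float = 0.0,
) -> OcclusionConstraintSet:
    """Per-occluded-vertex depth bound from the instrument point cloud.

    ``p_z`` is the z coordinate of the instrument point nearest (Euclidean,
    3D) to the vertex's previous-frame position.
    """
    occluded = np.asarray(occluded, dtype=np.int64)
    if occluded.size == 0:
        return OcclusionConstraintSet.empty()
    instrument_points = np.asarray(instrument_points, dtype=np.float64)
    if instrument_points.size == 0:
        raise ValueError("occluded vertices present but instrument point set is empty")
    tree = cKDTree(instrument_points)
    _, nn = tree.query(mesh_prev.vertices[occluded])
    return OcclusionConstraintSet(occluded, instrument_points[nn, 2], delta=delta)


def instrument_points_from_disparity(
    mask: np.ndarray,
    disparity: np.ndarray,
    calib: StereoCalibration,
) -> np.ndarray:
    """Triangulate the masked pixels with valid disparity into 3D points."""
    mask = np.asarray(mask, dtype=bool)
    disparity = np.asarray(disparity, dtype=np.float64)
    if disparity.shape != mask.shape:
        raise ValueError("mask and disparity dimensions do not match")
    rows, cols = np.nonzero(mask & np.isfinite(disparity) & (disparity > 0))
    return triangulate(cols.astype(float), rows.astype(float),
                       disparity[rows, cols], calib)
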