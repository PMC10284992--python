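"""Scene flow: per-vertex 3D displacement fields between adjacent frames.

Scene flow is composed with the classical two-step construction: rectified
stereo disparity gives each vertex's 3D position at frame t, 2D optical flow
transports its left-image projection to frame t+1, and the disparity there
gives the new 3D position.  The displacement ``F_s = X_{t+1} - X_t`` (mm) is
attached to each mesh vertex together with a status flag; only VALID vectors
drive the mesh update, everything else (off-image, invalid samples, tool
pixels, strain outliers) is excluded from the dynamic term.

The estimation of disparity and flow themselves is out of scope: fields are
consumed precomputed (files or the synthetic renderer).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .meshcore import TriangleMesh

__all__ = [
    "FlowStatus",
    "StereoCalibration",
    "FrameObservation",
    "SceneFlowField",
    "triangulate",
    "compose_scene_flow",
    "ingest_scene_flow",
]


class FlowStatus(enum.IntEnum):
    """Per-vertex scene-flow validity."""

    VALID = 0
    VACANT = 1          # off-image projection or invalid disparity/flow sample
    INSTRUMENT = 2      # projection inside the tracked tool mask
    STRAIN_OUTLIER = 3  # rejected by the strain filter


@dataclass(frozen=True)
class StereoCalibration:
    """Rectified stereo geometry: focal length f (px), principal point
    (cx, cy) (px), and baseline b (mm).  Epipolar lines are row-aligned, so
    depth follows from horizontal disparity alone: ``z = f * b / d``."""

    f: float
    cx: float
    cy: float
    b: float

    def __post_init__(self):
        if self.f <= 0 or self.b <= 0:
            raise ValueError("focal length and baseline must be positive")

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project (N, 3) camera-frame points (mm) to left-image pixels (u, v)."""
        points = np.asarray(points, dtype=np.float64)
        z = points[..., 2]
        u = self.cx + self.f * points[..., 0] / z
        v = self.cy + self.f * points[..., 1] / z
        return np.stack([u, v], axis=-1)

    def disparity_of_depth(self, z: np.ndarray) -> np.ndarray:
        return self.f * self.b / np.asarray(z, dtype=np.float64)

    @classmethod
    def from_yaml(cls, path) -> "StereoCalibration":
        from .fileio import read_calibration_yaml

        d = read_calibration_yaml(path)
        return cls(f=float(d["f"]), cx=float(d["cx"]), cy=float(d["cy"]), b=float(d["b"]))


def triangulate(u, v, d, calib: StereoCalibration) -> np.ndarray:
    """Rectified-stereo triangulation of pixel (u, v) with disparity d (px).

    ``z = f b / d``; ``x = (u - cx) z / f``; ``y = (v - cy) z / f`` (mm).
    Non-positive disparities yield NaN points (invalid).
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(d > 0, calib.f * calib.b / d, np.nan)
    x = (u - calib.cx) * z / calib.f
    y = (v - calib.cy) * z / calib.f
    return np.stack([x, y, z], axis=-1)


@dataclass
class FrameObservation:
    """Image-domain observations for one frame pair (t -> t+1).

    disparity_t / disparity_t1 : (H, W) float, NaN or <=0 where invalid.
    flow : (H, W, 2) float, left_t -> left_{t+1} pixel displacement (u, v).
    mask_t / mask_t1 : optional (H, W) bool instrument masks.
    """

    disparity_t: np.ndarray
    disparity_t1: np.ndarray
    flow: np.ndarray
    mask_t: np.ndarray | None = None
    mask_t1: np.ndarray | None = None

    def __post_init__(self):
        shape = self.disparity_t.shape
        if self.disparity_t1.shape != shape or self.flow.shape[:2] != shape:
            raise ValueError("disparity and flow fields must share image dimensions")
        if self.flow.ndim != 3 or self.flow.shape[2] != 2:
            raise ValueError("flow must be (H, W, 2)")
        for m in (self.mask_t, self.mask_t1):
            if m is not None and m.shape != shape:
                raise ValueError("mask dimensions must match disparity")


@dataclass
class SceneFlowField:
    """Per-vertex 3D displacement vectors with validity status.

    ``vectors`` is (N, 3) mm; ``status`` is (N,) of :class:`FlowStatus`.
    Non-VALID vectors are preserved for diagnostics but never consumed by
    the dynamic term.
    """

    vectors: np.ndarray
    status: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        self.status = np.asarray(self.status, dtype=np.int8)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != 3:
            raise ValueError(f"vectors must be (N, 3), got {self.vectors.shape}")
        if self.status.shape != (len(self.vectors),):
            raise ValueError("status length must match number of vectors")

    @property
    def n(self) -> int:
        return len(self.vectors)

    @property
    def valid_mask(self) -> np.ndarray:
        return self.status == FlowStatus.VALID

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def copy(self) -> "SceneFlowField":
        return SceneFlowField(self.vectors.copy(), self.status.copy())


def ingest_scene_flow(vectors: np.ndarray, status=None) -> SceneFlowField:
    """Validate and wrap precomputed per-vertex flow vectors.

    Non-finite vectors are forced to VACANT regardless of the given status.
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim != 2 or vectors.shape[1] != 3:
        raise ValueError(f"vectors must be (N, 3), got {vectors.shape}")
    n = len(vectors)
    if status is None:
        status = np.full(n, FlowStatus.VALID, dtype=np.int8)
    else:
        status = np.asarray(status, dtype=np.int8)
        if status.shape != (n,):
            raise ValueError(f"status length {status.shape} != number of vectors {n}")
        status = status.copy()
    bad = ~np.isfinite(vectors).all(axis=1)
    status[bad] = FlowStatus.VACANT
    return SceneFlowField(vectors, status)


def _bilinear(field: np.ndarray, u: np.ndarray, v: np.ndarray):
    """Bilinearly sample ``field`` at (u, v); pixel centers at integers.

    Returns (values, ok): ok requires the sample inside the image and all
    four neighbouring pixels finite (and > 0 for disparity handled by the
    caller via NaN-marking).  Conservative: one bad neighbour invalidates
    the sample so values never smear across occlusion boundaries.
    """
    h, w = field.shape[:2]
    u0 = np.floor(u).astype(np.int64)
    v0 = np.floor(v).astype(np.int64)
    inside = (u0 >= 0) & (v0 >= 0) & (u0 + 1 <= w - 1) & (v0 + 1 <= h - 1)
    u0c = np.clip(u0, 0, w - 2)
    v0c = np.clip(v0, 0, h - 2)
    fu = u - u0c
    fv = v - v0c
    q00 = field[v0c, u0c]
    q01 = field[v0c, u0c + 1]
    q10 = field[v0c + 1, u0c]
    q11 = field[v0c + 1, u0c + 1]
    if field.ndim == 3:
        fu = fu[..., None]
        fv = fv[..., None]
    val = (q00 * (1 - fu) * (1 - fv) + q01 * fu * (1 - fv)
           + q10 * (1 - fu) * fv + q11 * fu * fv)
    finite = np.isfinite(q00) & np.isfinite(q01) & np.isfinite(q10) & np.isfinite(q11)
    if field.ndim == 3:
        finite = finite.all(axis=-1)
    return val, inside & finite


def compose_scene_flow(
    mesh_prev: TriangleMesh,
    obs: FrameObservation,
    calib: StereoCalibration,
) -> SceneFlowField:
    """Compose per-vertex scene flow from disparity + optical flow fields.

    For each vertex of the previous-frame mesh: project into the left image
    at t, sample disparity_t to get the 3D anchor, follow the sampled flow
    to the corresponding pixel at t+1, sample disparity_t1 to get the moved
    3D point; the difference is the vertex's scene flow.  A vertex becomes
    VACANT when its projection or flow endpoint leaves the image or any
    sampled field is invalid at the sampling location.
    """
    dt = np.where(np.asarray(obs.disparity_t, dtype=np.float64) > 0,
                  obs.disparity_t, np.nan)
    dt1 = np.where(np.asarray(obs.disparity_t1, dtype=np.float64) > 0,
                   obs.disparity_t1, np.nan)

    pix = calib.project(mesh_prev.vertices)
    u, v = pix[:, 0], pix[:, 1]

    d0, ok0 = _bilinear(dt, u, v)
    fl, okf = _bilinear(np.asarray(obs.flow, dtype=np.float64), u, v)
    u1 = u + fl[:, 0]
    v1 = v + fl[:, 1]
    d1, ok1 = _bilinear(dt1, u1, v1)

    ok = ok0 & okf & ok1
    x0 = triangulate(u, v, d0, calib)
    x1 = triangulate(u1, v1, d1, calib)
    vectors = x1 - x0
    vectors[~ok] = 0.0

    status = np.where(ok, FlowStatus.VALID, FlowStatus.VACANT).astype(np.int8)
    return SceneFlowField(vectors, status)
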