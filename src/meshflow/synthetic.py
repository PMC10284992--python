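"""Synthetic deformation scenarios with exact ground truth.

Emulates the phantom experiment the method is designed for: a smooth tissue
surface (rectangular grid mesh with gentle sinusoidal relief, since real
tissue is never planar) indented by a forceps tip — a Gaussian depth bump
growing linearly over the sequence — observed through noisy per-vertex
scene flow.  The observations are corrupted the way a real two-step
stereo/optical-flow pipeline corrupts them:

* isotropic Gaussian noise on every flow vector;
* a fraction of vertices *replaced* by gross outlier vectors of fixed
  magnitude and random direction (stereo/flow mismatches);
* a rod-shaped occluder (tool shaft) strictly nearer the camera than the
  surface; vertices under its image footprint observe the tool's motion
  instead of the tissue's;
* vacancies at the mesh margins (features leaving the image).

Everything is seeded and bit-reproducible; ground-truth meshes share the
connectivity of the initial mesh across all frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .meshcore import TriangleMesh
from .meshopt import FrameInput
from .sceneflow import FlowStatus, FrameObservation, SceneFlowField, StereoCalibration

__all__ = ["SyntheticScenario", "SyntheticSequence", "generate_sequence",
           "render_observations", "default_calibration"]


@dataclass(frozen=True)
class SyntheticScenario:
    """Scenario parameters (lengths in mm, camera frame, z = depth).

    The default scenario is a 60 x 60 vertex grid at 1 mm spacing sitting
    about 100 mm from the camera, indented up to 5 mm (Gaussian profile,
    sigma 8 mm) over 10 frames, with 0.1 mm flow noise, 10% gross outliers
    of 10 mm magnitude, and a ~10% tool-shaft occluder — small enough for
    seconds-scale tests while exercising every pipeline stage.
    """

    nx: int = 60
    ny: int = 60
    spacing: float = 1.0
    z0: float = 100.0
    relief_amplitude: float = 1.0
    relief_wavelength: float = 25.0
    indent_center: tuple[float, float] = (3.0, -2.0)
    indent_sigma: float = 8.0
    max_depth: float = 5.0
    n_frames: int = 10
    sigma_n: float = 0.1
    p_out: float = 0.1
    m_out: float = 10.0
    occluder: bool = True
    occluder_width: float = 5.0
    occluder_angle_deg: float = 60.0
    occluder_offset: float = 6.0
    occluder_clearance: float = 20.0
    occluder_drift: float = 0.3
    vacant_margin: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("vertex spacing must be positive")
        if self.indent_sigma <= 0:
            raise ValueError("indentation sigma must be positive")
        if not 0 <= self.p_out <= 1:
            raise ValueError("outlier rate must be in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


def default_calibration() -> StereoCalibration:
    """Camera that frames the default scenario: f=500 px, 320x240 image,
    baseline 5.2 mm (a typical stereo-laparoscope baseline)."""
    return StereoCalibration(f=500.0, cx=160.0, cy=120.0, b=5.2)


DEFAULT_IMAGE_SHAPE = (240, 320)


def _grid_mesh(s: SyntheticScenario) -> TriangleMesh:
    x = (np.arange(s.nx) - (s.nx - 1) / 2) * s.spacing
    y = (np.arange(s.ny) - (s.ny - 1) / 2) * s.spacing
    xx, yy = np.meshgrid(x, y, indexing="xy")
    zz = _base_depth(s, xx, yy)
    vertices = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    idx = np.arange(s.nx * s.ny).reshape(s.ny, s.nx)
    v00 = idx[:-1, :-1].ravel()
    v01 = idx[:-1, 1:].ravel()
    v10 = idx[1:, :-1].ravel()
    v11 = idx[1:, 1:].ravel()
    faces = np.concatenate([
        np.column_stack([v00, v01, v11]),
        np.column_stack([v00, v11, v10]),
    ])
    return TriangleMesh(vertices, faces)


def _base_depth(s: SyntheticScenario, x, y):
    k = 2 * np.pi / s.relief_wavelength
    return s.z0 - s.relief_amplitude * np.sin(k * x) * np.sin(k * y)


def _indent_depth(s: SyntheticScenario, t: int, x, y):
    """Indentation depth d_t * gaussian at frame t (0-based; frame 0 flat)."""
    if s.n_frames == 1:
        d_t = 0.0
    else:
        d_t = s.max_depth * t / (s.n_frames - 1)
    cx, cy = s.indent_center
    r2 = (x - cx) ** 2 + (y - cy) ** 2
    return d_t * np.exp(-r2 / (2 * s.indent_sigma**2))


def surface_depth(s: SyntheticScenario, t: int, x, y):
    """Analytic surface depth z(x, y) at frame t (indentation presses +z)."""
    return _base_depth(s, x, y) + _indent_depth(s, t, x, y)


def _occluder_geometry(s: SyntheticScenario, t: int):
    """Stripe axis direction, normal, and a point on the axis at frame t."""
    th = np.deg2rad(s.occluder_angle_deg)
    d = np.array([np.cos(th), np.sin(th)])
    n = np.array([-np.sin(th), np.cos(th)])
    p0 = np.asarray(s.indent_center) + s.occluder_offset * n + t * s.occluder_drift * d
    return d, n, p0


def _occluder_footprint(s: SyntheticScenario, t: int, xy: np.ndarray) -> np.ndarray:
    if not s.occluder:
        return np.zeros(len(xy), dtype=bool)
    _, n, p0 = _occluder_geometry(s, t)
    signed = (xy - p0) @ n
    return np.abs(signed) < s.occluder_width / 2


def _occluder_points(s: SyntheticScenario, t: int, mesh: TriangleMesh,
                     footprint: np.ndarray) -> np.ndarray:
    pts = mesh.vertices[footprint].copy()
    pts[:, 2] = surface_depth(s, t, pts[:, 0], pts[:, 1]) - s.occluder_clearance
    return pts


def _rasterize_footprint(points_3d: np.ndarray, calib: StereoCalibration,
                         shape=DEFAULT_IMAGE_SHAPE, pad: int = 3) -> np.ndarray:
    """Paint squares around the projections of the occluder points."""
    mask = np.zeros(shape, dtype=bool)
    if len(points_3d) == 0:
        return mask
    pix = np.rint(calib.project(points_3d)).astype(np.int64)
    h, w = shape
    for du in range(-pad, pad + 1):
        for dv in range(-pad, pad + 1):
            u = pix[:, 0] + du
            v = pix[:, 1] + dv
            ok = (u >= 0) & (u < w) & (v >= 0) & (v < h)
            mask[v[ok], u[ok]] = True
    return mask


def _margin_mask(s: SyntheticScenario) -> np.ndarray:
    """Vertices within ``vacant_margin`` rings of the grid boundary."""
    m = np.zeros((s.ny, s.nx), dtype=bool)
    k = s.vacant_margin
    if k > 0:
        m[:k, :] = m[-k:, :] = True
        m[:, :k] = m[:, -k:] = True
    return m.ravel()


@dataclass
class SyntheticSequence:
    """Generated scenario: ground truth plus observed frame inputs.

    ``true_vertices[t]`` are the exact vertex positions at frame t;
    ``frames[t-1]`` holds the observed (noisy, contaminated) scene flow for
    the step t-1 -> t together with the tool mask and tool points;
    ``outlier_indices[t-1]`` records which vertices were replaced by gross
    outliers (ground truth for filter evaluation).
    """

    scenario: SyntheticScenario
    mesh0: TriangleMesh
    true_vertices: list[np.ndarray]
    frames: list[FrameInput]
    masks: list[np.ndarray]
    footprints: list[np.ndarray]
    outlier_indices: list[np.ndarray]
    calib: StereoCalibration = field(default_factory=default_calibration)

    @property
    def n_steps(self) -> int:
        return len(self.frames)


def generate_sequence(scenario: SyntheticScenario,
                      calib: StereoCalibration | None = None) -> SyntheticSequence:
    """Generate ground truth meshes and corrupted scene-flow observations."""
    s = scenario
    calib = calib or default_calibration()
    rng = np.random.default_rng(s.seed)
    mesh0 = _grid_mesh(s)
    xy = mesh0.vertices[:, :2]
    n = mesh0.n_vertices
    margin = _margin_mask(s)

    true_vertices = []
    for t in range(s.n_frames):
        v = mesh0.vertices.copy()
        v[:, 2] = surface_depth(s, t, v[:, 0], v[:, 1])
        true_vertices.append(v)

    frames, masks, footprints, outliers = [], [], [], []
    for t in range(1, s.n_frames):
        step = true_vertices[t] - true_vertices[t - 1]
        vectors = step + rng.normal(0.0, s.sigma_n, size=(n, 3))

        footprint = _occluder_footprint(s, t, xy)
        # gross outliers: replaced vectors, injected away from tool & margins
        eligible = np.flatnonzero(~footprint & ~margin)
        n_out = int(round(s.p_out * len(eligible)))
        out_idx = rng.choice(eligible, size=n_out, replace=False) if n_out else \
            np.empty(0, dtype=np.int64)
        if n_out:
            dirs = rng.normal(size=(n_out, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            vectors[out_idx] = s.m_out * dirs

        # tool-contaminated vectors: the occluder's own motion
        if footprint.any():
            d, _, _ = _occluder_geometry(s, t)
            tool_step = np.array([s.occluder_drift * d[0], s.occluder_drift * d[1], 0.0])
            vectors[footprint] = tool_step + rng.normal(0.0, s.sigma_n,
                                                        size=(int(footprint.sum()), 3))

        status = np.full(n, FlowStatus.VALID, dtype=np.int8)
        status[margin] = FlowStatus.VACANT

        tool_pts = _occluder_points(s, t, mesh0.with_vertices(true_vertices[t]),
                                    footprint) if footprint.any() else np.empty((0, 3))
        mask = _rasterize_footprint(tool_pts, calib)

        frames.append(FrameInput(
            flow=SceneFlowField(vectors, status),
            instrument_vertex_mask=footprint.copy(),
            instrument_points=tool_pts,
        ))
        masks.append(mask)
        footprints.append(footprint)
        outliers.append(np.sort(out_idx))

    return SyntheticSequence(
        scenario=s, mesh0=mesh0, true_vertices=true_vertices, frames=frames,
        masks=masks, footprints=footprints, outlier_indices=outliers, calib=calib,
    )


def render_observations(
    scenario: SyntheticScenario,
    t: int,
    calib: StereoCalibration | None = None,
    shape=DEFAULT_IMAGE_SHAPE,
    disparity_quant: float = 1.0 / 16.0,
) -> FrameObservation:
    """Render image-domain observations for the step t -> t+1.

    Disparity maps follow from the analytic surface depth along each pixel
    ray (fixed-point iteration on ``z = S(x(z), y(z))``), quantized to
    ``disparity_quant`` pixels; the optical flow transports each pixel's
    material surface point to its projection at t+1 (the deformation is
    depth-only, so material (x, y) is preserved).  Pixels whose ray misses
    the surface extent are invalid (NaN / zero flow).

    Raises
    ------
    ValueError
        If the surface lies entirely outside the image frustum.
    """
    s = scenario
    if not 0 <= t < s.n_frames - 1:
        raise ValueError(f"step index {t} outside [0, {s.n_frames - 1})")
    calib = calib or default_calibration()
    h, w = shape
    u, v = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    ru = (u - calib.cx) / calib.f
    rv = (v - calib.cy) / calib.f

    def solve_surface(frame_idx):
        z = np.full((h, w), s.z0)
        for _ in range(30):
            z = surface_depth(s, frame_idx, ru * z, rv * z)
        return ru * z, rv * z, z

    x_t, y_t, z_t = solve_surface(t)
    half_x = (s.nx - 1) / 2 * s.spacing
    half_y = (s.ny - 1) / 2 * s.spacing
    inside = (np.abs(x_t) <= half_x) & (np.abs(y_t) <= half_y)
    if not inside.any():
        raise ValueError("surface lies outside the image frustum")

    def quantize(d):
        return np.round(d / disparity_quant) * disparity_quant

    disp_t = np.where(inside, quantize(calib.disparity_of_depth(z_t)), np.nan)

    # frame t+1 depth sampled on its own pixel grid (for disparity_t1)
    x1g, y1g, z1g = solve_surface(t + 1)
    inside1 = (np.abs(x1g) <= half_x) & (np.abs(y1g) <= half_y)
    disp_t1 = np.where(inside1, quantize(calib.disparity_of_depth(z1g)), np.nan)

    # flow: material point (x_t, y_t) keeps its (x, y); depth changes
    z_next = surface_depth(s, t + 1, x_t, y_t)
    u1 = calib.cx + calib.f * x_t / z_next
    v1 = calib.cy + calib.f * y_t / z_next
    flow = np.stack([u1 - u, v1 - v], axis=-1)
    flow[~inside] = 0.0

    mask = None
    if s.occluder:
        foot_xy = _occluder_footprint(s, t + 1, np.column_stack([x_t[inside], y_t[inside]]))
        pts = np.column_stack([x_t[inside][foot_xy], y_t[inside][foot_xy],
                               z_t[inside][foot_xy] - s.occluder_clearance])
        mask = _rasterize_footprint(pts, calib, shape=shape, pad=1)

    return FrameObservation(disparity_t=disp_t, disparity_t1=disp_t1,
                            flow=flow, mask_t1=mask)
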