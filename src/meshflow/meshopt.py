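"""Per-frame mesh optimization: dynamic + smoothness terms under depth bounds.

Each frame the new vertex positions ``C`` (N x 3, mm) solve the stacked
linear system

    [ I~      ]       [ C*        ]
    [ alpha S ] C  =  [ alpha D_S ]

in the least-squares sense, where

* the *dynamic term* ``I~ C = C*`` anchors every vertex with a surviving
  (filtered) scene-flow vector to its flow-updated position
  ``C* = I~ C_p + F_s`` (one selector row per valid vertex);
* the *smoothness term* ``S C = D_S`` pulls the mesh's differential
  coordinates back toward those of the initial mesh.  ``S`` is the
  differential edge matrix ``E`` (two non-zeros per row) by default, or the
  graph Laplacian ``L = E^T E`` as the classical baseline; ``D_S = S C_0``
  is fixed over the whole sequence.

The x and y columns are unconstrained sparse least-squares solves.  The z
column additionally satisfies the instrument constraint: occluded vertices
must stay at least as deep as the tool above them, ``z_i >= p_z,i + delta``.
This bound-constrained problem is solved exactly with a primal active-set
method on the normal equations (the objective is strictly convex whenever
every connected component of the mesh contains at least one valid vertex).

:class:`MeshDeformationModel` wraps the per-frame solve in a fit interface:
``fit_frame`` returns a :class:`FrameFit` results object with the estimated
positions, residual norms and constraint diagnostics, and ``run_sequence``
drives a whole observation sequence, carrying the estimate forward as the
next frame's ``C_p``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .instrument import OcclusionConstraintSet, compute_depth_bounds
from .meshcore import (
    TriangleMesh,
    build_differential_edge_matrix,
    build_laplacian_matrix,
    compute_delta_coordinates,
)
from .sceneflow import FlowStatus, SceneFlowField
from .strainfilter import FilterConfig, filter_scene_flow

__all__ = [
    "MeshOptimizationProblem",
    "build_dynamic_term",
    "solve_frame",
    "solve_bounded_least_squares",
    "MeshDeformationModel",
    "FrameFit",
    "SequenceResult",
    "FrameInput",
    "naive_update",
    "SolverError",
]


class SolverError(RuntimeError):
    """The per-frame linear system could not be solved."""


def build_dynamic_term(
    c_prev: np.ndarray,
    flow: SceneFlowField,
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Selector matrix and target positions for the valid vertices.

    Rows are ordered by ascending vertex index; row r selects valid vertex
    ``i_r`` (single +1 entry) and targets ``C_p[i_r] + F_s[i_r]``.

    Raises
    ------
    SolverError
        If no vertex is valid (the frame cannot constrain any position).
    """
    c_prev = np.asarray(c_prev, dtype=np.float64)
    valid = np.flatnonzero(flow.valid_mask)
    if valid.size == 0:
        raise SolverError("no valid scene-flow vertices: dynamic term is empty")
    n = len(c_prev)
    sel = sp.csr_matrix(
        (np.ones(valid.size), (np.arange(valid.size), valid)),
        shape=(valid.size, n),
    )
    c_star = c_prev[valid] + flow.vectors[valid]
    return sel, c_star


@dataclass
class MeshOptimizationProblem:
    """One frame's assembled optimization problem.

    Attributes mirror the stacked system: the selector ``I_tilde`` with its
    targets ``c_star``, the smoothness operator ``S`` with delta
    coordinates ``delta`` and weight ``alpha``, the previous positions
    ``c_prev``, the occlusion constraint set, and the vertex component
    labels of the mesh graph (frozen components are carried at ``c_prev``).
    """

    I_tilde: sp.csr_matrix
    c_star: np.ndarray
    S: sp.csr_matrix
    delta: np.ndarray
    alpha: float
    c_prev: np.ndarray
    occlusion: OcclusionConstraintSet = field(default_factory=OcclusionConstraintSet.empty)
    component_labels: np.ndarray | None = None


def solve_bounded_least_squares(
    A: sp.spmatrix,
    b: np.ndarray,
    lower: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> np.ndarray:
    """Exact solution of ``min ||A x - b||^2`` subject to ``x >= lower``.

    Primal active-set method on the normal equations ``H = A^T A``:
    violated bounds are clamped, the free subsystem is re-solved with a
    sparse LU factorization, and bounds whose Lagrange multiplier
    ``(H x - g)_i`` turns negative are released one at a time.  Terminates
    finitely for strictly convex problems; falls back to
    :func:`scipy.optimize.lsq_linear` if the iteration cap is hit.
    Entries of ``lower`` may be ``-inf`` (unconstrained).
    """
    H = (A.T @ A).tocsc()
    g = A.T @ b
    n = H.shape[0]
    bounded = np.isfinite(lower)

    def solve_free(active: np.ndarray) -> np.ndarray:
        x = np.empty(n)
        x[active] = lower[active]
        free = ~active
        if free.any():
            Hff = H[free][:, free]
            rhs = g[free] - H[free][:, active] @ lower[active]
            try:
                x[free] = spla.splu(Hff.tocsc()).solve(rhs)
            except RuntimeError as exc:
                raise SolverError(f"singular free subsystem: {exc}") from exc
        return x

    x = solve_free(np.zeros(n, dtype=bool))
    active = bounded & (x < lower - tol)
    if not active.any():
        return x

    for _ in range(max_iter):
        x = solve_free(active)
        violated = bounded & ~active & (x < lower - tol)
        if violated.any():
            active |= violated
            continue
        lam = (H @ x - g)[active]
        if (lam >= -tol).all():
            return np.maximum(x, np.where(bounded, lower, -np.inf))
        release = np.flatnonzero(active)[np.argmin(lam)]
        active[release] = False

    from scipy.optimize import lsq_linear  # cycling guard; rarely reached

    res = lsq_linear(A.tocsc(), b, bounds=(lower, np.full(n, np.inf)),
                     method="trf", tol=1e-14)
    return np.maximum(res.x, np.where(bounded, lower, -np.inf))


def solve_frame(problem: MeshOptimizationProblem) -> np.ndarray:
    """Solve one frame's constrained least-squares problem for all vertices.

    x and y columns are unconstrained least squares; the z column respects
    the occlusion depth bounds.  Connected components without any valid
    vertex are frozen at their previous positions (the smoothness term
    alone would leave them determined only up to a translation).
    """
    n = problem.I_tilde.shape[1]
    c_prev = np.asarray(problem.c_prev, dtype=np.float64)
    valid_cols = np.unique(problem.I_tilde.indices)
    if valid_cols.size == 0:
        raise SolverError("empty dynamic term")

    labels = problem.component_labels
    if labels is None:
        labels = np.zeros(n, dtype=np.int64)
    live_components = np.unique(labels[valid_cols])
    active_vertices = np.isin(labels, live_components)

    # restrict columns to live components; smoothness rows never straddle
    # components, so rows touching only active vertices are kept intact
    col_map = -np.ones(n, dtype=np.int64)
    col_map[active_vertices] = np.arange(active_vertices.sum())
    S = problem.S.tocsr()
    row_live = np.ones(S.shape[0], dtype=bool)
    if not active_vertices.all():
        frozen = (S[:, ~active_vertices] != 0).sum(axis=1)
        row_live = np.asarray(frozen).ravel() == 0
    S_r = S[row_live][:, active_vertices]
    delta_r = problem.delta[row_live]
    I_r = problem.I_tilde[:, active_vertices]

    A = sp.vstack([I_r, problem.alpha * S_r]).tocsc()
    H = (A.T @ A).tocsc()
    try:
        lu = spla.splu(H)
    except RuntimeError as exc:
        dead = np.setdiff1d(np.unique(labels), live_components)
        raise SolverError(
            f"stacked system is rank deficient (components without valid "
            f"vertices: {dead.tolist()}): {exc}"
        ) from exc

    out = c_prev.copy()
    for col in (0, 1):
        b = np.concatenate([problem.c_star[:, col],
                            problem.alpha * delta_r[:, col]])
        out[active_vertices, col] = lu.solve(A.T @ b)

    bz = np.concatenate([problem.c_star[:, 2], problem.alpha * delta_r[:, 2]])
    lb_full = problem.occlusion.lower_bounds(n)
    lb = lb_full[active_vertices]
    if not np.isfinite(lb).any():
        out[active_vertices, 2] = lu.solve(A.T @ bz)
    else:
        z = lu.solve(A.T @ bz)
        if (z >= lb).all():
            out[active_vertices, 2] = z
        else:
            out[active_vertices, 2] = solve_bounded_least_squares(A, bz, lb)
    return out


def naive_update(c_prev: np.ndarray, flow: SceneFlowField) -> np.ndarray:
    """Direct raw scene-flow update (the failure-mode baseline).

    Every vertex with an observed vector (anything but VACANT) moves by its
    raw scene flow, outliers and tool motion included; VACANT vertices stay.
    """
    c_prev = np.asarray(c_prev, dtype=np.float64)
    observed = flow.status != FlowStatus.VACANT
    out = c_prev.copy()
    out[observed] += flow.vectors[observed]
    return out


@dataclass
class FrameInput:
    """Vertex-level observations for one frame step.

    flow : raw (unfiltered) per-vertex scene flow.
    instrument_vertex_mask : optional per-vertex bool, True where the
        vertex's projection falls inside the tool mask.
    instrument_points : optional (M, 3) reconstructed tool points (mm) used
        for the depth bounds.
    """

    flow: SceneFlowField
    instrument_vertex_mask: np.ndarray | None = None
    instrument_points: np.ndarray | None = None


@dataclass
class FrameFit:
    """Result of one frame's fit."""

    positions: np.ndarray
    flow: SceneFlowField            # post-filter statuses
    occlusion: OcclusionConstraintSet
    n_valid: int
    dynamic_residual: float         # ||I~ C - C*||_F (mm)
    smoothness_residual: float      # ||S C - D_S||_F (mm)
    n_active_bounds: int
    skipped: bool = False

    def summary(self) -> str:
        lines = [
            "Frame fit summary",
            "-----------------",
            f"valid vertices       : {self.n_valid} / {self.flow.n}",
            f"occluded vertices    : {self.occlusion.n}",
            f"active depth bounds  : {self.n_active_bounds}",
            f"dynamic residual     : {self.dynamic_residual:.6g} mm",
            f"smoothness residual  : {self.smoothness_residual:.6g} mm",
        ]
        if self.skipped:
            lines.append("frame skipped: previous mesh carried forward")
        return "\n".join(lines)


class MeshDeformationModel:
    """Deformation recovery model bound to an initial mesh.

    Parameters
    ----------
    initial_mesh : TriangleMesh
        Mesh of the undeformed surface; its connectivity defines the
        smoothness operator and its positions the reference delta
        coordinates, both fixed for the model's lifetime.
    alpha : float
        Smoothness weight (default 1.5; useful range about 1-2 for the
        edge operator at mm scale).
    smoothness : {"edge", "laplacian"}
        Differential edge matrix (default) or graph Laplacian baseline.
    delta_margin : float
        Safety margin added to the occlusion depth bounds (mm).
    filter_config : FilterConfig
        Strain-filter parameters.
    """

    def __init__(
        self,
        initial_mesh: TriangleMesh,
        alpha: float = 1.5,
        smoothness: str = "edge",
        delta_margin: float = 0.0,
        filter_config: FilterConfig | None = None,
    ):
        if smoothness not in ("edge", "laplacian"):
            raise ValueError("smoothness must be 'edge' or 'laplacian'")
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        self.initial_mesh = initial_mesh
        self.alpha = float(alpha)
        self.smoothness = smoothness
        self.delta_margin = float(delta_margin)
        self.filter_config = filter_config or FilterConfig()
        edges = initial_mesh.edges
        n = initial_mesh.n_vertices
        if smoothness == "edge":
            self.S = build_differential_edge_matrix(edges, n)
        else:
            self.S = build_laplacian_matrix(edges, n)
        self.delta = compute_delta_coordinates(self.S, initial_mesh.vertices)
        self.component_labels = initial_mesh.component_labels()

    def build_problem(
        self,
        c_prev: np.ndarray,
        flow: SceneFlowField,
        occlusion: OcclusionConstraintSet | None = None,
    ) -> MeshOptimizationProblem:
        I_tilde, c_star = build_dynamic_term(c_prev, flow)
        return MeshOptimizationProblem(
            I_tilde=I_tilde,
            c_star=c_star,
            S=self.S,
            delta=self.delta,
            alpha=self.alpha,
            c_prev=np.asarray(c_prev, dtype=np.float64),
            occlusion=occlusion or OcclusionConstraintSet.empty(),
            component_labels=self.component_labels,
        )

    def fit_frame(
        self,
        c_prev: np.ndarray,
        frame: FrameInput,
        apply_filter: bool = True,
        apply_constraint: bool = True,
    ) -> FrameFit:
        """Filter the frame's flow, assemble constraints, and solve."""
        mesh_prev = self.initial_mesh.with_vertices(c_prev)
        if apply_filter:
            flow, _ = filter_scene_flow(
                mesh_prev, frame.flow, frame.instrument_vertex_mask,
                self.filter_config,
            )
        else:
            flow = frame.flow

        occlusion = OcclusionConstraintSet.empty()
        if apply_constraint and frame.instrument_vertex_mask is not None \
                and frame.instrument_points is not None:
            occluded = np.flatnonzero(np.asarray(frame.instrument_vertex_mask, bool))
            if occluded.size:
                occlusion = compute_depth_bounds(
                    occluded, frame.instrument_points, mesh_prev,
                    delta=self.delta_margin,
                )

        problem = self.build_problem(c_prev, flow, occlusion)
        positions = solve_frame(problem)

        dyn = float(np.linalg.norm(problem.I_tilde @ positions - problem.c_star))
        smo = float(np.linalg.norm(self.S @ positions - self.delta))
        lb = occlusion.lower_bounds(len(positions))
        n_active = int(np.sum(np.isfinite(lb) & (positions[:, 2] <= lb + 1e-9)))
        return FrameFit(
            positions=positions,
            flow=flow,
            occlusion=occlusion,
            n_valid=flow.n_valid,
            dynamic_residual=dyn,
            smoothness_residual=smo,
            n_active_bounds=n_active,
        )

    def run_sequence(
        self,
        frames: list[FrameInput],
        apply_filter: bool = True,
        apply_constraint: bool = True,
        raw_update: bool = False,
    ) -> "SequenceResult":
        """Recover the whole sequence; frame 0 is the initial mesh.

        Any frame whose solve fails is skipped: the previous mesh is
        carried forward and the frame recorded in ``skipped``.  With
        ``raw_update`` the optimization is bypassed entirely and vertices
        move by their raw scene flow (the failure-mode baseline).
        """
        meshes = [self.initial_mesh]
        fits: list[FrameFit | None] = [None]
        skipped: list[int] = []
        c_prev = self.initial_mesh.vertices
        for t, frame in enumerate(frames, start=1):
            if raw_update:
                c_prev = naive_update(c_prev, frame.flow)
                meshes.append(self.initial_mesh.with_vertices(c_prev))
                fits.append(None)
                continue
            try:
                fit = self.fit_frame(c_prev, frame, apply_filter, apply_constraint)
            except SolverError:
                skipped.append(t)
                fit = FrameFit(
                    positions=c_prev.copy(), flow=frame.flow,
                    occlusion=OcclusionConstraintSet.empty(),
                    n_valid=0, dynamic_residual=np.nan,
                    smoothness_residual=np.nan, n_active_bounds=0, skipped=True,
                )
            c_prev = fit.positions
            meshes.append(self.initial_mesh.with_vertices(c_prev))
            fits.append(fit)
        return SequenceResult(model=self, meshes=meshes, fits=fits, skipped=skipped)


@dataclass
class SequenceResult:
    """Recovered sequence: per-frame meshes and fit diagnostics."""

    model: MeshDeformationModel
    meshes: list[TriangleMesh]
    fits: list[FrameFit | None]
    skipped: list[int]

    @property
    def n_frames(self) -> int:
        return len(self.meshes)

    def frame_stats(self) -> list[dict]:
        stats = []
        for t, fit in enumerate(self.fits):
            if fit is None:
                stats.append({"frame": t, "n_valid": None, "n_occluded": None,
                              "dynamic_residual": None, "smoothness_residual": None,
                              "skipped": t in self.skipped})
            else:
                stats.append({
                    "frame": t,
                    "n_valid": fit.n_valid,
                    "n_occluded": fit.occlusion.n,
                    "dynamic_residual": fit.dynamic_residual,
                    "smoothness_residual": fit.smoothness_residual,
                    "n_active_bounds": fit.n_active_bounds,
                    "skipped": fit.skipped,
                })
        return stats

    def summary(self) -> str:
        lines = [
            "Deformation recovery summary",
            "============================",
            f"frames               : {self.n_frames} (incl. initial)",
            f"vertices             : {self.model.initial_mesh.n_vertices}",
            f"smoothness operator  : {self.model.smoothness} (alpha={self.model.alpha})",
            f"skipped frames       : {self.skipped or 'none'}",
            "",
            f"{'frame':>5} {'valid':>7} {'occl':>6} {'dyn res (mm)':>13} {'smooth res (mm)':>16}",
        ]
        for s in self.frame_stats()[1:]:
            if s["n_valid"] is None:
                lines.append(f"{s['frame']:>5} {'-':>7} {'-':>6} {'-':>13} {'-':>16}")
            else:
                lines.append(
                    f"{s['frame']:>5} {s['n_valid']:>7} {s['n_occluded']:>6} "
                    f"{s['dynamic_residual']:>13.4f} {s['smoothness_residual']:>16.4f}"
                )
        return "\n".join(lines)
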