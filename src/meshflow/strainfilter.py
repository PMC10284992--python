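"""Strain-based scene-flow outlier filtering.

The filter rests on a consistency hypothesis: scene flow within a small
surface patch should be nearly uniform, because tissue deforms smoothly at
the scale of a few mesh edges.  A vector that cannot be explained by a
smooth local displacement field implies an implausibly large local strain
and is rejected, whatever its physical cause (specular mismatch, occlusion
boundary, tracking failure).

Per vertex the filter estimates the spatial displacement gradient
``G = d(u, v, w)/d(x, y, z)`` by vertex-wise least squares (VWLS): each
displacement component is fitted with an affine model over the vertex's
k-ring neighbourhood.  The infinitesimal strain tensor is the symmetric
part ``eps = (G + G^T) / 2``; its eigenvalues are the principal strains and
the outlier score is built from the maximal absolute principal strain
``eps_max``, thresholded at ``eps_t`` (default 1, i.e. 100% strain).

Two practical refinements make the score usable on camera-facing surfaces:

* The affine fit is solved minimum-norm via truncated SVD.  Surface
  neighbourhoods are nearly coplanar, so the derivative along the surface
  normal is ill-determined; truncation leaves it at zero instead of
  amplifying observation noise without bound.  Only neighbourhoods that do
  not even span a plane (collinear) or have too few usable neighbours are
  UNDETERMINED.
* A fitted gradient has, by symmetry, zero leverage for the centre vertex's
  own vector: an isolated gross outlier at the centre leaves its own OLS
  gradient untouched.  The outlier score therefore adds a *deviation
  strain* ``|f_i - median(f_neighbours)| / h`` — the smallest gradient
  magnitude any displacement field needs in order to reconcile the
  vertex's own vector with its neighbours over the local edge length
  ``h``.  The componentwise median makes the reference robust to
  contaminated neighbours, and vertices whose deviation strain already
  exceeds the threshold are excluded from other vertices' fits so one
  gross vector cannot poison a whole neighbourhood.  For exact affine
  fields both refinements vanish and the fit reproduces the gradient to
  machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .meshcore import TriangleMesh
from .sceneflow import FlowStatus, SceneFlowField

__all__ = [
    "FilterConfig",
    "StrainTensor",
    "StrainField",
    "estimate_gradient_vwls",
    "strain_from_gradient",
    "filter_scene_flow",
    "ring_neighborhoods",
]


@dataclass(frozen=True)
class FilterConfig:
    """Strain filter parameters.

    eps_t : outlier threshold on the strain score (dimensionless, default 1.0).
    ring : neighbourhood ring order k (default 2).
    min_neighbors : minimum usable neighbours for a determined fit (default 6).
    svd_rcond : relative singular-value cutoff for the truncated-SVD affine
        fit (default 0.1).  The derivative along a singular direction of the
        neighbourhood (in practice the surface normal) is estimated only
        when the neighbourhood's extent along it is at least this fraction
        of its largest extent; below that the direction's derivative is
        left at zero.  The cutoff bounds the noise amplification of the
        fit: a direction with relative extent r turns observation noise
        sigma into derivative noise of order sigma / (r * patch size).
    """

    eps_t: float = 1.0
    ring: int = 2
    min_neighbors: int = 6
    svd_rcond: float = 0.1

    def __post_init__(self):
        if self.eps_t <= 0:
            raise ValueError("eps_t must be positive")
        if self.ring < 1:
            raise ValueError("ring order must be >= 1")


@dataclass(frozen=True)
class StrainTensor:
    """Strain at one vertex: tensor, sorted principal strains, eps_max."""

    eps: np.ndarray              # symmetric 3x3
    principal: np.ndarray        # eigenvalues, descending
    eps_max: float               # max absolute principal strain


@dataclass
class StrainField:
    """Per-vertex gradients and strain summaries over a mesh."""

    gradients: np.ndarray        # (N, 3, 3), NaN where undetermined
    eps_max: np.ndarray          # (N,), NaN where undetermined
    deviation: np.ndarray        # (N,), deviation strain |f - median| / h
    score: np.ndarray = field(default=None)  # eps_max + deviation

    def __post_init__(self):
        if self.score is None:
            self.score = self.eps_max + self.deviation

    @property
    def undetermined(self) -> np.ndarray:
        return ~np.isfinite(self.eps_max)


def ring_neighborhoods(mesh: TriangleMesh, ring: int) -> list[np.ndarray]:
    """k-ring neighbour index lists (excluding the vertex itself)."""
    a = mesh.adjacency().astype(bool)
    reach = a.copy()
    hop = a
    for _ in range(ring - 1):
        hop = (hop @ a).astype(bool)
        reach = (reach + hop).astype(bool)
    reach = sp.csr_matrix(reach)
    reach.setdiag(False)
    reach.eliminate_zeros()
    return [reach.indices[reach.indptr[i]:reach.indptr[i + 1]]
            for i in range(mesh.n_vertices)]


def _affine_fit(positions: np.ndarray, values: np.ndarray, rcond: float):
    """Minimum-norm OLS affine fit of a vector field over scattered points.

    Fits ``value(p) ~ G (p - mean) + c`` per component and returns the 3x3
    gradient G, the fitted values at the input points, and the design rank
    (of the centred positions).  Returns ``None`` if the points are
    collinear (cannot span a plane).
    """
    if len(positions) < 3:
        return None
    centred = positions - positions.mean(axis=0)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[0] == 0 or s[1] < 1e-8 * s[0]:  # collinear: cannot even span a plane
        return None
    rank = max(2, int((s >= rcond * s[0]).sum()))
    vals = values - values.mean(axis=0)
    # G^T = pinv(centred) @ vals restricted to the kept singular directions
    inv_s = np.zeros_like(s)
    inv_s[:rank] = 1.0 / s[:rank]
    gt = vt.T * inv_s @ (u.T @ vals)
    grad = gt.T  # rows are d(component)/d(x, y, z)
    fitted = centred @ gt + values.mean(axis=0)
    return grad, fitted, rank


def estimate_gradient_vwls(
    vertex: int,
    mesh: TriangleMesh,
    flow: SceneFlowField,
    config: FilterConfig = FilterConfig(),
    neighborhoods: list[np.ndarray] | None = None,
) -> np.ndarray | None:
    """VWLS displacement gradient at one vertex, or ``None`` if undetermined.

    The vertex and its k-ring neighbours with usable status (not VACANT or
    INSTRUMENT) contribute; each displacement component is fitted with an
    affine model over the previous-frame positions by ordinary least
    squares.  The 3x3 gradient has rows ``(d comp/dx, d comp/dy, d comp/dz)``.
    Undetermined when fewer than ``min_neighbors`` neighbours are usable or
    the neighbourhood is collinear.
    """
    if neighborhoods is None:
        neighborhoods = ring_neighborhoods(mesh, config.ring)
    usable = (flow.status != FlowStatus.VACANT) & (flow.status != FlowStatus.INSTRUMENT)
    nbrs = neighborhoods[vertex]
    nbrs = nbrs[usable[nbrs]]
    if len(nbrs) < config.min_neighbors:
        return None
    idx = np.concatenate([[vertex], nbrs]) if usable[vertex] else nbrs
    fit = _affine_fit(mesh.vertices[idx], flow.vectors[idx], config.svd_rcond)
    if fit is None:
        return None
    return fit[0]


def strain_from_gradient(grad: np.ndarray) -> StrainTensor:
    """Infinitesimal strain from a displacement gradient.

    ``eps = (G + G^T) / 2``; principal strains are its eigenvalues sorted
    descending; ``eps_max`` is the maximal absolute principal strain.  The
    antisymmetric part of G (infinitesimal rotation) does not contribute.
    """
    grad = np.asarray(grad, dtype=np.float64)
    if grad.shape != (3, 3) or not np.isfinite(grad).all():
        raise ValueError("gradient must be a finite 3x3 matrix")
    eps = 0.5 * (grad + grad.T)
    evals = np.linalg.eigvalsh(eps)[::-1]
    return StrainTensor(eps=eps, principal=evals, eps_max=float(np.abs(evals).max()))


def compute_strain_field(
    mesh: TriangleMesh,
    flow: SceneFlowField,
    config: FilterConfig = FilterConfig(),
    neighborhoods: list[np.ndarray] | None = None,
) -> StrainField:
    """Strain field over all usable vertices with the robust outlier score.

    Pipeline per usable vertex i:
    1. deviation strain: distance of f_i from the componentwise median of
       its usable k-ring neighbours, divided by the mean 1-ring edge length;
    2. provisional outliers (deviation > eps_t) are excluded from all fits;
    3. truncated-SVD affine fit over the remaining neighbourhood gives the
       gradient and eps_max;
    4. score = eps_max + deviation strain.
    """
    n = mesh.n_vertices
    if neighborhoods is None:
        neighborhoods = ring_neighborhoods(mesh, config.ring)
    usable = (flow.status != FlowStatus.VACANT) & (flow.status != FlowStatus.INSTRUMENT)

    # local length scale: mean distance to usable 1-ring neighbours
    one_ring = neighborhoods if config.ring == 1 else ring_neighborhoods(mesh, 1)
    vectors = flow.vectors
    verts = mesh.vertices

    deviation = np.zeros(n)
    for i in range(n):
        if not usable[i]:
            continue
        nb = one_ring[i]
        nb_all = neighborhoods[i]
        nb_u = nb_all[usable[nb_all]]
        nb1 = nb[usable[nb]]
        if len(nb_u) < 1 or len(nb1) < 1:
            deviation[i] = np.inf
            continue
        h = np.linalg.norm(verts[nb1] - verts[i], axis=1).mean()
        med = np.median(vectors[nb_u], axis=0)
        deviation[i] = np.linalg.norm(vectors[i] - med) / h

    provisional = usable & (deviation > config.eps_t)
    fit_ok = usable & ~provisional

    gradients = np.full((n, 3, 3), np.nan)
    eps_max = np.full(n, np.nan)
    for i in range(n):
        if not usable[i]:
            continue
        nb = neighborhoods[i]
        nb = nb[fit_ok[nb]]
        if len(nb) < config.min_neighbors:
            continue
        idx = np.concatenate([[i], nb]) if fit_ok[i] else nb
        fit = _affine_fit(verts[idx], vectors[idx], config.svd_rcond)
        if fit is None:
            continue
        gradients[i] = fit[0]
        eps_max[i] = strain_from_gradient(fit[0]).eps_max

    return StrainField(gradients=gradients, eps_max=eps_max, deviation=deviation)


def filter_scene_flow(
    mesh: TriangleMesh,
    flow: SceneFlowField,
    instrument_vertex_mask: np.ndarray | None = None,
    config: FilterConfig = FilterConfig(),
) -> tuple[SceneFlowField, StrainField]:
    """Filter a scene-flow field; returns the refiltered field and strains.

    Rule order (earlier rules take precedence):
    1. VACANT vertices stay VACANT;
    2. vertices whose projection lies inside the instrument mask (given
       here as a per-vertex boolean) become INSTRUMENT;
    3. remaining vertices with strain score > eps_t, or with an
       undetermined gradient, become STRAIN_OUTLIER;
    4. everything else is VALID.

    Vectors are never modified, only statuses.  The function is a pure
    function of the vectors and the VACANT/INSTRUMENT partition, so
    re-running it on its own output changes nothing (idempotent):
    previously assigned STRAIN_OUTLIER statuses are re-derived, not
    accumulated.
    """
    status = flow.status.copy()
    status[status == FlowStatus.STRAIN_OUTLIER] = FlowStatus.VALID  # re-judge
    if instrument_vertex_mask is not None:
        instrument_vertex_mask = np.asarray(instrument_vertex_mask, dtype=bool)
        inside = instrument_vertex_mask & (status != FlowStatus.VACANT)
        status[inside] = FlowStatus.INSTRUMENT
        status[~instrument_vertex_mask & (status == FlowStatus.INSTRUMENT)] = FlowStatus.VALID

    work = SceneFlowField(flow.vectors, status)
    strains = compute_strain_field(mesh, work, config)

    judged = status == FlowStatus.VALID
    outlier = judged & (~np.isfinite(strains.score) | (strains.score > config.eps_t))
    status[outlier] = FlowStatus.STRAIN_OUTLIER
    return SceneFlowField(flow.vectors.copy(), status), strains


def filter_report(flow: SceneFlowField, strains: StrainField):
    """Per-vertex filter diagnostics as a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame({
        "vertex": np.arange(flow.n),
        "status": [FlowStatus(s).name for s in flow.status],
        "eps_max": strains.eps_max,
        "deviation_strain": strains.deviation,
        "score": strains.score,
    })
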