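"""Surface registration: coarse landmark initialization and trimmed ICP.

The ICP variant is point-to-point against the *vertices* of the target
cloud (the segmented scalp / scan meshes used here are dense enough that
point-to-plane buys little). Each iteration matches every source point to
its nearest target vertex with a k-d tree, discards a fixed fraction of the
worst correspondences (and any beyond an optional distance gate), refits a
full Kabsch transform on the retained pairs, and stops when the retained
RMS changes by less than the tolerance.

The reported ``rms`` — the root-mean-square of retained correspondence
distances at the final pose — is this toolbox's operationalization of the
"ICP fitting error" that users should inspect: experience puts a good face
fit below 2 mm and a good helmet fit below 0.8 mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .containers import PointCloud
from .errors import InputError, RegistrationError
from .geometry import RigidTransform, _as_points, kabsch_align

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IcpParams:
    """Trimmed-ICP tuning parameters.

    Parameters
    ----------
    max_iterations : int
        Iteration cap (default 100).
    convergence_tol : float
        Stop when the retained-pair RMS changes by less than this (mm).
    trim_fraction : float in [0, 0.5)
        Fraction of the worst correspondences discarded each iteration.
    max_pair_distance : float or None
        Optional hard gate (mm) on correspondence distance.
    """

    max_iterations: int = 100
    convergence_tol: float = 1e-4
    trim_fraction: float = 0.1
    max_pair_distance: float | None = None

    def __post_init__(self):
        if self.max_iterations < 1:
            raise InputError("max_iterations must be >= 1")
        if not (self.convergence_tol > 0):
            raise InputError("convergence_tol must be > 0")
        if not (0.0 <= self.trim_fraction < 0.5):
            raise InputError("trim_fraction must lie in [0, 0.5)")
        if self.max_pair_distance is not None and not (self.max_pair_distance > 0):
            raise InputError("max_pair_distance must be > 0 when set")


@dataclass
class IcpResult:
    """Converged transform plus fit diagnostics."""

    transform: RigidTransform
    rms: float
    iterations: int
    converged: bool
    rms_history: list[float] = field(default_factory=list)


@dataclass
class RegionSelection:
    """Vertex indices into a PointCloud (a scriptable stand-in for GUI picking)."""

    indices: np.ndarray
    description: str = ""

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.int64).ravel()
        if idx.size == 0:
            raise InputError("region selection is empty")
        if len(np.unique(idx)) != len(idx):
            raise InputError("region selection contains duplicate indices")
        if idx.min() < 0:
            raise InputError("region selection contains negative indices")
        self.indices = idx

    def __len__(self):
        return len(self.indices)


def coarse_match(pairs_source, pairs_target) -> RigidTransform:
    """Rigid transform from at least four user-picked corresponding points.

    Delegates to the Kabsch alignment; the fiducial registration error of
    the picked pairs is logged as the coarse-match quality.
    """
    src = _as_points(pairs_source, "pairs_source")
    tgt = _as_points(pairs_target, "pairs_target")
    if len(src) < 4 or len(tgt) < 4:
        raise InputError(
            f"coarse matching requires at least four point pairs, got {len(src)}"
        )
    xform, fre = kabsch_align(src, tgt)
    logger.info("coarse match over %d pairs: FRE = %.4f mm", len(src), fre)
    return xform


def pair_fre(t: RigidTransform, pairs_source, pairs_target) -> float:
    """RMS residual (mm) of point pairs under a given transform."""
    src = _as_points(pairs_source, "pairs_source")
    tgt = _as_points(pairs_target, "pairs_target")
    resid = t.apply(src) - tgt
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


def crop_region(cloud: PointCloud, selection: RegionSelection) -> PointCloud:
    """Sub-cloud of the selected vertices (colours kept, faces dropped)."""
    if selection.indices.max() >= len(cloud):
        raise InputError(
            f"region index {selection.indices.max()} out of range for "
            f"cloud of {len(cloud)} vertices"
        )
    colors = None if cloud.colors is None else cloud.colors[selection.indices]
    return PointCloud(cloud.vertices[selection.indices], colors=colors)


def select_by_sphere(cloud: PointCloud, center, radius: float,
                     description: str = "") -> RegionSelection:
    """Indices of vertices within ``radius`` mm of ``center``."""
    if not (radius > 0):
        raise InputError("radius must be > 0")
    c = _as_points(center, "center", allow_single=True)[0]
    idx = cKDTree(cloud.vertices).query_ball_point(c, radius)
    idx = np.sort(np.asarray(idx, dtype=np.int64))
    if idx.size == 0:
        raise InputError("sphere selection matched no vertices")
    return RegionSelection(idx, description or f"sphere r={radius:g} mm")


def icp_register(source: PointCloud, target: PointCloud,
                 init: RigidTransform | None = None,
                 params: IcpParams | None = None) -> IcpResult:
    """Trimmed point-to-point ICP of ``source`` onto ``target`` vertices.

    ``init`` seeds the first correspondence search; the returned transform
    is cumulative (maps original source coordinates into the target frame).
    Raises :class:`RegistrationError` when fewer than three correspondences
    survive trimming/gating in any iteration.
    """
    params = params or IcpParams()
    if init is None:
        init = RigidTransform.identity()
    src = source.vertices
    tgt = target.vertices
    if len(src) < 3 or len(tgt) < 3:
        raise InputError("both clouds need at least 3 vertices for ICP")
    tree = cKDTree(tgt)
    xform = init
    history: list[float] = []
    converged = False
    iterations = 0
    prev_rms: float | None = None
    for iterations in range(1, params.max_iterations + 1):
        moved = xform.apply(src)
        dist, nn = tree.query(moved)
        if params.max_pair_distance is not None:
            valid = dist <= params.max_pair_distance
        else:
            valid = np.ones(len(src), dtype=bool)
        n_valid = int(valid.sum())
        n_keep = n_valid - int(np.floor(params.trim_fraction * n_valid))
        if n_keep < 3:
            raise RegistrationError(
                f"ICP retained only {n_keep} correspondences "
                f"(of {len(src)} source points) at iteration {iterations}"
            )
        vidx = np.flatnonzero(valid)
        order = np.argsort(dist[vidx], kind="stable")[:n_keep]
        keep = vidx[order]
        rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        history.append(rms)
        xform, _ = kabsch_align(src[keep], tgt[nn[keep]])
        xform = xform.retag(source=init.source, target=init.target)
        if prev_rms is not None and abs(prev_rms - rms) < params.convergence_tol:
            converged = True
            break
        prev_rms = rms
    # report the residual at the *final* pose
    final_rms = _retained_rms(xform, src, tree, params)
    logger.info("ICP finished after %d iterations (converged=%s): rms = %.4f mm",
                iterations, converged, final_rms)
    return IcpResult(xform, final_rms, iterations, converged, history)


def _retained_rms(xform: RigidTransform, src: np.ndarray, tree: cKDTree,
                  params: IcpParams) -> float:
    dist, _ = tree.query(xform.apply(src))
    if params.max_pair_distance is not None:
        dist = dist[dist <= params.max_pair_distance]
    if dist.size == 0:
        raise RegistrationError("no correspondences within max_pair_distance at final pose")
    n_keep = max(3, len(dist) - int(np.floor(params.trim_fraction * len(dist))))
    kept = np.sort(dist, kind="stable")[:n_keep]
    return float(np.sqrt(np.mean(kept**2)))
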