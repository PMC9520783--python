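"""Helmet reference-marker extraction from coloured scans.

Structured-light scanners return per-vertex RGB; the helmet's painted
reference markers are isolated by thresholding in HSV space (the default
window targets green paint: H 0.2–0.66, S 0.3–1, V 0.16–1 on a 0–1 scale),
grouped into spatial clusters, and matched to the designed reference points
by exhaustive assignment search.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from matplotlib.colors import rgb_to_hsv as _mpl_rgb_to_hsv
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .containers import PointCloud
from .errors import AmbiguityError, InputError, MarkerCountError
from .geometry import RigidTransform, _as_points, kabsch_align
from .registration import RegionSelection
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class HsvRange:
    """Closed box in HSV space; all bounds on a 0–1 scale.

    The hue interval must not wrap around 0/1 — callers split a wrapping
    window (e.g. red) into two ranges.
    """

    h_min: float
    h_max: float
    s_min: float = 0.0
    s_max: float = 1.0
    v_min: float = 0.0
    v_max: float = 1.0

    def __post_init__(self):
        for lo, hi, name in ((self.h_min, self.h_max, "h"),
                             (self.s_min, self.s_max, "s"),
                             (self.v_min, self.v_max, "v")):
            if not (0.0 <= lo <= hi <= 1.0):
                raise InputError(f"invalid HSV bounds: {name} in [{lo}, {hi}]")

    def contains(self, hsv: np.ndarray) -> np.ndarray:
        hsv = np.asarray(hsv, dtype=float)
        return ((hsv[:, 0] >= self.h_min) & (hsv[:, 0] <= self.h_max)
                & (hsv[:, 1] >= self.s_min) & (hsv[:, 1] <= self.s_max)
                & (hsv[:, 2] >= self.v_min) & (hsv[:, 2] <= self.v_max))


#: Default window for green helmet markers.
GREEN_MARKER_WINDOW = HsvRange(0.2, 0.66, 0.3, 1.0, 0.16, 1.0)


@dataclass
class MarkerSet:
    """Detected marker centroids (mm) with per-cluster member counts."""

    centroids: np.ndarray
    member_counts: np.ndarray
    frame: str | None = None

    def __post_init__(self):
        self.centroids = _as_points(self.centroids, "centroids")
        self.member_counts = np.asarray(self.member_counts, dtype=int)
        if len(self.member_counts) != len(self.centroids):
            raise InputError("centroid/count length mismatch")

    def __len__(self):
        return len(self.centroids)


def rgb_to_hsv(rgb) -> np.ndarray:
    """Convert (N, 3) RGB in [0, 255] to HSV in [0, 1] (hexagonal model)."""
    arr = np.asarray(rgb, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise InputError(f"rgb must be (N, 3), got {arr.shape}")
    if np.any(arr < 0) or np.any(arr > 255):
        raise InputError("rgb values must lie in [0, 255]")
    return _mpl_rgb_to_hsv(arr / 255.0)


def select_by_hsv(cloud: PointCloud, window: HsvRange) -> RegionSelection:
    """Indices of vertices whose colour lies inside the HSV window."""
    if cloud.colors is None:
        raise InputError("cloud has no per-vertex colours; cannot select by HSV")
    mask = window.contains(rgb_to_hsv(cloud.colors))
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise InputError("HSV window selected no vertices")
    return RegionSelection(idx, description="hsv selection")


def cluster_markers(cloud: PointCloud, selection: RegionSelection,
                    linkage_radius: float = 10.0, min_cluster_size: int = 5,
                    expected_k: int | None = None,
                    frame: str | None = None) -> MarkerSet:
    """Group selected vertices into marker clusters and take centroids.

    Clusters are the connected components of the "within ``linkage_radius``"
    adjacency graph (single linkage); components smaller than
    ``min_cluster_size`` are dropped as paint specks/noise. When
    ``expected_k`` is given, a differing surviving count raises
    :class:`MarkerCountError` with diagnostic counts. Centroids are returned
    in lexicographic coordinate order, so the result is independent of
    vertex ordering.
    """
    if selection.indices.max() >= len(cloud):
        raise InputError("selection indices out of range")
    pts = cloud.vertices[selection.indices]
    pairs = cKDTree(pts).query_pairs(linkage_radius, output_type="ndarray")
    n = len(pts)
    adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    centroids = []
    counts = []
    for c in range(n_comp):
        members = labels == c
        size = int(members.sum())
        if size >= min_cluster_size:
            centroids.append(pts[members].mean(axis=0))
            counts.append(size)
    if expected_k is not None and len(centroids) != expected_k:
        raise MarkerCountError(
            f"expected {expected_k} markers but found {len(centroids)} "
            f"clusters of sizes {sorted(counts, reverse=True)} "
            f"({n_comp} raw components, min_cluster_size={min_cluster_size})"
        )
    if not centroids:
        raise MarkerCountError("no marker cluster survived min_cluster_size")
    centroids = np.asarray(centroids)
    counts = np.asarray(counts)
    order = np.lexsort(centroids.T[::-1])
    return MarkerSet(centroids[order], counts[order], frame=frame)


def match_markers(designed, detected: MarkerSet, *,
                  ambiguity_factor: float = 2.0):
    """Assign detected marker centroids to designed reference points.

    All K! assignments are scored by Kabsch FRE and the best is returned as
    ``(permutation, transform, fre)`` where ``detected.centroids[permutation]``
    corresponds row-wise to ``designed`` and ``transform`` maps designed
    coordinates into the detected frame. If the runner-up assignment scores
    within ``ambiguity_factor`` of the best (near-symmetric marker layouts,
    e.g. an equilateral triangle), an :class:`AmbiguityError` is raised.
    """
    des = _as_points(designed, "designed")
    k = len(des)
    if len(detected) != k:
        raise InputError(
            f"designed has {k} points but detected set has {len(detected)}"
        )
    if not (3 <= k <= 8):
        raise InputError(
            f"marker matching supports 3..8 markers (exhaustive search), got {k}"
        )
    best = None
    runner_up_fre = np.inf
    for perm in itertools.permutations(range(k)):
        xform, fre = kabsch_align(des, detected.centroids[list(perm)])
        if best is None or fre < best[2]:
            if best is not None:
                runner_up_fre = min(runner_up_fre, best[2])
            best = (perm, xform, fre)
        else:
            runner_up_fre = min(runner_up_fre, fre)
    perm, xform, fre = best
    if runner_up_fre < ambiguity_factor * max(fre, 1e-9):
        raise AmbiguityError(
            f"marker correspondence ambiguous: best FRE {fre:.6f} mm vs "
            f"runner-up {runner_up_fre:.6f} mm (factor < {ambiguity_factor})"
        )
    return perm, xform, fre
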