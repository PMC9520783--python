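"""In-memory containers passed between pipeline stages.

Coordinates are always millimetres. Containers are deliberately thin: a
:class:`PointCloud` is vertices with optional per-vertex colour and optional
triangle faces; a :class:`SensorArray` is labelled sensor positions with one
(radial) or more (e.g. tri-axis) unit orientation vectors per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import InputError
from .geometry import FiducialSet, RigidTransform, _as_points, compose


@dataclass
class PointCloud:
    """Vertices (mm) with optional RGB colours in [0, 255] and triangle faces."""

    vertices: np.ndarray
    colors: np.ndarray | None = None
    faces: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = _as_points(self.vertices, "vertices")
        if len(self.vertices) < 1:
            raise InputError("point cloud must contain at least one vertex")
        if self.colors is not None:
            c = np.asarray(self.colors)
            if c.shape != self.vertices.shape:
                raise InputError(
                    f"colors shape {c.shape} does not match vertices {self.vertices.shape}"
                )
            if np.any(c < 0) or np.any(c > 255):
                raise InputError("colors must lie in [0, 255]")
            self.colors = c.astype(np.uint8)
        if self.faces is not None:
            f = np.asarray(self.faces)
            if f.size == 0:
                self.faces = None
            else:
                if f.ndim != 2 or f.shape[1] != 3:
                    raise InputError(f"faces must be (M, 3), got {f.shape}")
                if f.min() < 0 or f.max() >= len(self.vertices):
                    raise InputError("face indices out of range")
                self.faces = f.astype(np.int64)

    def __len__(self):
        return len(self.vertices)

    @property
    def has_colors(self) -> bool:
        return self.colors is not None

    def transformed(self, t: RigidTransform) -> "PointCloud":
        """Same cloud with vertices mapped rigidly (colours/faces carried)."""
        return PointCloud(t.apply(self.vertices),
                          None if self.colors is None else self.colors.copy(),
                          None if self.faces is None else self.faces.copy())


@dataclass
class LabelledPoints:
    """Ordered labelled points (e.g. designed helmet reference markers)."""

    labels: list[str]
    points: np.ndarray

    def __post_init__(self):
        self.points = _as_points(self.points, "points")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != len(self.points):
            raise InputError("label/point count mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise InputError("labels must be unique")

    def __len__(self):
        return len(self.labels)

    def subset(self, labels: list[str]) -> "LabelledPoints":
        idx = []
        for lab in labels:
            if lab not in self.labels:
                raise InputError(f"unknown label {lab!r}")
            idx.append(self.labels.index(lab))
        return LabelledPoints(list(labels), self.points[idx])


@dataclass
class SensorArray:
    """Per-channel label, position (mm) and K ≥ 1 unit orientation vectors.

    K = 1 is the usual radial single-axis OPM; K = 3 covers tri-axis
    sensors. The first orientation row is taken as the slot-radial axis.
    """

    labels: list[str]
    positions: np.ndarray
    orientations: np.ndarray  # (N, K, 3)

    def __post_init__(self):
        self.positions = _as_points(self.positions, "sensor positions")
        ori = np.asarray(self.orientations, dtype=float)
        if ori.ndim == 2:
            ori = ori[:, None, :]
        if ori.ndim != 3 or ori.shape[2] != 3 or ori.shape[0] != len(self.positions):
            raise InputError(f"orientations must be (N, K, 3), got {ori.shape}")
        if not np.all(np.isfinite(ori)):
            raise InputError("orientations contain non-finite values")
        norms = np.linalg.norm(ori, axis=2)
        if np.any(norms < 1e-6):
            raise InputError("orientation vectors must have non-zero norm")
        self.orientations = ori / norms[:, :, None]
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != len(self.positions):
            raise InputError("label/position count mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise InputError("channel labels must be unique")

    def __len__(self):
        return len(self.labels)

    @property
    def n_axes(self) -> int:
        return self.orientations.shape[1]

    def transformed(self, t: RigidTransform) -> "SensorArray":
        """Positions mapped by R·p + t; orientations rotated only."""
        n, k, _ = self.orientations.shape
        ori = t.apply_directions(self.orientations.reshape(n * k, 3)).reshape(n, k, 3)
        return SensorArray(list(self.labels), t.apply(self.positions), ori)

    def subset(self, labels: list[str]) -> "SensorArray":
        idx = []
        for lab in labels:
            if lab not in self.labels:
                raise InputError(f"unknown channel label {lab!r}")
            idx.append(self.labels.index(lab))
        return SensorArray(list(labels), self.positions[idx], self.orientations[idx])


@dataclass
class DigitizedPoints:
    """Stylus-digitizer output: fiducials, scalp points, helmet reference points."""

    fiducials: FiducialSet
    scalp_points: np.ndarray
    helmet_ref_points: LabelledPoints

    def __post_init__(self):
        self.scalp_points = _as_points(self.scalp_points, "scalp points")
        for lab in ("nasion", "lpa", "rpa"):
            if lab not in self.fiducials.labels:
                raise InputError(f"digitized fiducials missing {lab!r}")


@dataclass
class CoregResult:
    """Final co-registration output plus per-stage fit quality.

    ``fre_transform1`` is the RMS fiducial registration error of the
    device→head alignment; ``icp_rms_transform1`` is only set for the laser
    workflow (designed-helmet-to-scan ICP); ``icp_rms_transform2`` is the
    head→MRI surface ICP residual.
    """

    transform_device_to_head: RigidTransform
    transform_head_to_mri: RigidTransform
    sensors_mri: SensorArray
    fre_transform1: float
    icp_rms_transform2: float
    icp_rms_transform1: float | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("fre_transform1", "icp_rms_transform2"):
            v = getattr(self, name)
            if v is None or v < 0:
                raise InputError(f"{name} must be a non-negative number, got {v}")
        if self.icp_rms_transform1 is not None and self.icp_rms_transform1 < 0:
            raise InputError("icp_rms_transform1 must be non-negative")

    @property
    def transform_device_to_mri(self) -> RigidTransform:
        return compose(self.transform_head_to_mri, self.transform_device_to_head)
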