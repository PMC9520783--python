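"""Rigid-body mathematics for MEG/MRI co-registration.

All coordinates are in millimetres. A :class:`RigidTransform` is a proper
rigid motion ``p ↦ R·p + t`` (rotation ``R`` orthonormal with det +1, no
scaling, no reflection) optionally tagged with the coordinate frames it maps
between. The co-registration workflows compose two such transforms:
*transform 1* (MEG-Device → MEG-Head) and *transform 2* (MEG-Head → MRI).

The head coordinate frame follows the common MEG convention built from the
three anatomical fiducials: origin at the midpoint of the pre-auricular
points, +X through the nasion, +Y toward the left pre-auricular point
(up to the small out-of-plane component of the nasion), +Z up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, FrameError, InputError

#: Recognised coordinate-frame tags.
FRAMES = ("device", "digitizer", "scan", "head", "mri")

_ORTHO_TOL = 1e-8


def _as_points(arr, name: str = "points", allow_single: bool = False) -> np.ndarray:
    """Coerce to a float (N, 3) array, rejecting non-finite values."""
    pts = np.asarray(arr, dtype=float)
    if allow_single and pts.shape == (3,):
        pts = pts[None, :]
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InputError(f"{name} must be an (N, 3) array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise InputError(f"{name} contain non-finite coordinates")
    return pts


def _check_frame_tag(tag):
    if tag is not None and tag not in FRAMES:
        raise FrameError(f"unknown frame tag {tag!r}; expected one of {FRAMES}")


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p ↦ rotation·p + translation`` (millimetres).

    Parameters
    ----------
    rotation : (3, 3) array
        Orthonormal matrix with determinant +1.
    translation : (3,) array
        Translation in mm.
    source, target : str, optional
        Frame tags (one of :data:`FRAMES`); used to catch frame mix-ups
        when composing transforms.
    """

    rotation: np.ndarray
    translation: np.ndarray
    source: str | None = None
    target: str | None = None

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise InputError(f"rotation must be 3x3, got {R.shape}")
        if not (np.all(np.isfinite(R)) and np.all(np.isfinite(t))):
            raise InputError("transform contains non-finite values")
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
            raise InputError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise InputError("rotation matrix is a reflection (det = -1)")
        _check_frame_tag(self.source)
        _check_frame_tag(self.target)
        R.flags.writeable = False
        t.flags.writeable = False
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls, source=None, target=None) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), source=source, target=target)

    @classmethod
    def from_matrix(cls, mat, source=None, target=None) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix."""
        mat = np.asarray(mat, dtype=float)
        if mat.shape != (4, 4):
            raise InputError(f"expected a 4x4 matrix, got {mat.shape}")
        return cls(mat[:3, :3], mat[:3, 3], source=source, target=target)

    # -- representation ----------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        mat = np.eye(4)
        mat[:3, :3] = self.rotation
        mat[:3, 3] = self.translation
        return mat

    def retag(self, source=None, target=None) -> "RigidTransform":
        return RigidTransform(self.rotation, self.translation, source=source, target=target)

    # -- actions -----------------------------------------------------------
    def apply(self, points) -> np.ndarray:
        """Map (N, 3) points (or a single 3-vector) by ``R·p + t``."""
        pts = np.asarray(points, dtype=float)
        single = pts.shape == (3,)
        pts = _as_points(pts, "points", allow_single=True)
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out

    def apply_directions(self, dirs) -> np.ndarray:
        """Rotate unit direction vectors; translation is not applied.

        Rows are renormalized to exactly unit length. Rows whose norm is
        below 1e-6 raise :class:`InputError`.
        """
        d = np.asarray(dirs, dtype=float)
        single = d.shape == (3,)
        d = _as_points(d, "directions", allow_single=True)
        norms = np.linalg.norm(d, axis=1)
        if np.any(norms < 1e-6):
            raise InputError("direction vectors must have non-zero norm")
        out = (d / norms[:, None]) @ self.rotation.T
        # rotation is orthonormal so norms are preserved to machine precision;
        # renormalize anyway so downstream invariants hold exactly
        out /= np.linalg.norm(out, axis=1)[:, None]
        return out[0] if single else out

    def inverse(self) -> "RigidTransform":
        """Inverse motion; frame tags are swapped."""
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation,
                              source=self.target, target=self.source)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)


def compose(t2: RigidTransform, t1: RigidTransform) -> RigidTransform:
    """Transform equivalent to applying ``t1`` first, then ``t2``.

    Frame tags propagate (``t1.source → t2.target``); if both inner tags are
    set they must agree.
    """
    if t1.target is not None and t2.source is not None and t1.target != t2.source:
        raise FrameError(
            f"cannot compose: first transform targets frame {t1.target!r} "
            f"but second expects {t2.source!r}"
        )
    return RigidTransform(
        t2.rotation @ t1.rotation,
        t2.rotation @ t1.translation + t2.translation,
        source=t1.source,
        target=t2.target,
    )


def invert(t: RigidTransform) -> RigidTransform:
    """Functional alias for :meth:`RigidTransform.inverse`."""
    return t.inverse()


def apply_to_points(t: RigidTransform, pts) -> np.ndarray:
    return t.apply(pts)


def apply_to_directions(t: RigidTransform, dirs) -> np.ndarray:
    return t.apply_directions(dirs)


def kabsch_align(source, target, *, source_frame=None, target_frame=None):
    """Least-squares rigid alignment of corresponding point sets (Kabsch).

    Finds the proper rigid transform minimizing ``Σ‖R·sᵢ + t − tᵢ‖²`` via
    SVD of the cross-covariance of the centred point sets, with the
    determinant sign corrected so the result is never a reflection.

    Parameters
    ----------
    source, target : (N, 3) arrays, N ≥ 3
        Row i of ``source`` corresponds to row i of ``target``.

    Returns
    -------
    transform : RigidTransform
    fre : float
        Fiducial registration error — RMS residual (mm) after alignment.
    """
    s = _as_points(source, "source")
    t = _as_points(target, "target")
    if s.shape != t.shape:
        raise InputError(f"source/target shape mismatch: {s.shape} vs {t.shape}")
    if len(s) < 3:
        raise InputError(f"need at least 3 point pairs, got {len(s)}")
    cs = s.mean(axis=0)
    ct = t.mean(axis=0)
    S = s - cs
    sv = np.linalg.svd(S, compute_uv=False)
    # rank < 2 means collinear or coincident points: the in-plane rotation
    # about the degenerate axis is unconstrained
    if sv[0] <= 0 or sv[1] < 1e-6 * sv[0]:
        raise DegenerateGeometryError(
            "source points are collinear or coincident; alignment is underdetermined"
        )
    H = S.T @ (t - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    trans = ct - R @ cs
    xform = RigidTransform(R, trans, source=source_frame, target=target_frame)
    resid = s @ R.T + trans - t
    fre = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return xform, fre


def build_head_frame(nasion, lpa, rpa, *, source_frame=None) -> RigidTransform:
    """Transform from the input frame into the fiducial-based head frame.

    Convention: origin at the midpoint of LPA/RPA; +X the unit vector toward
    the nasion; +Z = X × unit(LPA − origin) (up); +Y = Z × X (leftward). By
    construction the nasion lands on the +X axis and the LPA has positive Y
    and zero Z.
    """
    nas = _as_points(nasion, "nasion", allow_single=True)[0]
    l = _as_points(lpa, "lpa", allow_single=True)[0]
    r = _as_points(rpa, "rpa", allow_single=True)[0]
    origin = 0.5 * (l + r)
    x = nas - origin
    ear = l - origin
    scale = max(np.linalg.norm(x), np.linalg.norm(ear))
    z = np.cross(x, ear)
    if scale <= 0 or np.linalg.norm(z) < 1e-9 * scale**2:
        raise DegenerateGeometryError("fiducials are collinear or coincident")
    x = x / np.linalg.norm(x)
    z = z / np.linalg.norm(z)
    y = np.cross(z, x)
    R = np.vstack([x, y, z])  # rows are head-frame axes in input coordinates
    return RigidTransform(R, -R @ origin, source=source_frame, target="head")


def rotation_angle(R) -> float:
    """Geodesic angle (radians) of a rotation matrix; distance from identity."""
    R = np.asarray(R, dtype=float)
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def random_rotation(rng: np.random.Generator, max_angle: float = np.pi) -> np.ndarray:
    """Rotation by a uniform angle in [0, max_angle] about a uniform axis."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_angle)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def random_rigid_transform(rng: np.random.Generator, max_angle: float = np.pi,
                           max_translation: float = 200.0,
                           source=None, target=None) -> RigidTransform:
    """Seeded random rigid motion (uniform axis/angle, translation in a ball)."""
    R = random_rotation(rng, max_angle)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    t = direction * rng.uniform(0.0, max_translation)
    return RigidTransform(R, t, source=source, target=target)


@dataclass
class FiducialSet:
    """Labelled anatomical or marker points in a tagged frame."""

    labels: list[str]
    points: np.ndarray
    frame: str | None = None

    def __post_init__(self):
        self.points = _as_points(self.points, "fiducial points")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != len(self.points):
            raise InputError("label/point count mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise InputError("fiducial labels must be unique")
        _check_frame_tag(self.frame)

    def __len__(self):
        return len(self.labels)

    def get(self, label: str) -> np.ndarray:
        try:
            return self.points[self.labels.index(label)]
        except ValueError:
            raise InputError(f"no fiducial labelled {label!r}") from None
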