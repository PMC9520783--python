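"""Synthetic head/helmet phantom with known ground-truth transforms.

The phantom emulates every input of the co-registration workflows with no
external data: an ellipsoidal scalp with a raised nose (the asymmetry that
makes face registration and the head frame well-posed), a helmet surface
offset outward from the scalp carrying sensor slots with inward radial
orientations, painted reference-marker patches, and per-device simulated
measurements (stylus digitization, coloured structured-light scan,
colourless laser scan) each in its own randomly-posed frame.

All continuous surfaces are realized once on a nested icosphere lattice:
the designed-helmet mesh lives on the coarse lattice, the scalp mesh and
simulated scans on the one-step-finer lattice whose vertex set contains the
coarse vertices exactly. Every modality therefore samples the *same*
surface realization, so noiseless pipelines recover the ground truth to
numerical precision and added Gaussian noise is the only error source. (The
methods note discusses what this idealization does and does not emulate.)

All randomness flows from explicit integer seeds; equal seeds give
bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .containers import DigitizedPoints, LabelledPoints, PointCloud, SensorArray
from .errors import InputError
from .geometry import FiducialSet, RigidTransform, random_rigid_transform
from .registration import RegionSelection

# Fixed anatomy of the phantom face, as unit directions in the head frame
# (+X nasion, +Y left, +Z up).
_NOSE_AXIS = np.array([1.0, 0.0, -0.25]) / np.linalg.norm([1.0, 0.0, -0.25])

def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)

# Secondary facial relief (direction, amplitude mm, angular sigma rad). The
# left/right asymmetry breaks the rotational symmetry of the lone nose bump
# about its own axis, which would otherwise leave face ICP free to spin.
_FACE_FEATURES = (
    (_unit([0.85, 0.4, 0.4]), 10.0, 0.15),    # left brow
    (_unit([0.85, -0.4, 0.4]), 6.0, 0.15),    # right brow
    (_unit([0.75, 0.15, -0.6]), 8.0, 0.15),   # chin, slightly off-midline
)
_FACE_HALF_ANGLE = np.deg2rad(45.0)        # scanned face patch
_HELMET_RIM_ANGLE = np.deg2rad(110.0)      # helmet extends this far from +Z
_HELMET_FACE_CLEARANCE = np.deg2rad(50.0)  # helmet stays this far from the nose axis
_MARKER_MARGIN = np.deg2rad(60.0)          # markers keep clear of the helmet rim
_PICK_DIRS = {
    "front": np.array([1.0, 0.0, 0.25]),
    "left": np.array([0.8, 0.55, -0.3]),
    "right": np.array([0.8, -0.55, -0.3]),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, sampling and noise conditions of the synthetic phantom.

    Lengths in mm. ``subdivisions`` sets the coarse icosphere lattice
    (designed helmet); scans and the scalp mesh use one subdivision more.
    The per-modality noise levels are the default digitization/scan
    perturbations applied by the simulators.
    """

    scalp_semiaxes: tuple[float, float, float] = (90.0, 70.0, 100.0)
    nose_amplitude: float = 25.0
    nose_sigma: float = 0.28  # radians, angular width of the nose bump
    helmet_standoff: float = 6.0
    sensor_standoff: float = 2.5  # vapor-cell center above the helmet surface
    n_sensors: int = 85
    n_markers: int = 4
    marker_patch_radius: float = 5.0
    subdivisions: int = 4
    sigma_fastrak: float = 0.5
    sigma_structured_light: float = 0.3
    sigma_laser: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if any(a <= 0 for a in self.scalp_semiaxes):
            raise InputError("scalp semi-axes must be positive")
        for name in ("helmet_standoff", "marker_patch_radius", "nose_sigma"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.n_sensors < 1:
            raise InputError("n_sensors must be >= 1")
        if not (3 <= self.n_markers <= 8):
            raise InputError("n_markers must lie in 3..8")


@dataclass
class PhantomTruth:
    """Ground truth the generator knows and the pipelines must recover."""

    t1: RigidTransform                 # device -> head
    t2: RigidTransform                 # head -> mri
    sensors_head: SensorArray
    sensors_mri: SensorArray
    marker_refs_head: np.ndarray       # (K, 3) marker reference points, head frame


@dataclass
class Phantom:
    """A generated phantom: workflow inputs plus ground truth and lattice data."""

    spec: PhantomSpec
    scalp_head: PointCloud             # scalp mesh in the head frame
    mri_scalp: PointCloud              # same mesh in the MRI frame
    designed_helmet: PointCloud        # helmet mesh in the device frame
    sensors_device: SensorArray
    designed_refs: LabelledPoints      # marker reference points, device frame
    fiducials_head: FiducialSet
    mri_fiducials: FiducialSet
    truth: PhantomTruth
    # lattice internals used by the measurement simulators
    dirs5: np.ndarray = field(repr=False, default=None)
    dirs6: np.ndarray = field(repr=False, default=None)
    scalp5: np.ndarray = field(repr=False, default=None)
    helmet5: np.ndarray = field(repr=False, default=None)
    face_mask5: np.ndarray = field(repr=False, default=None)
    helmet_mask5: np.ndarray = field(repr=False, default=None)
    lower_mask5: np.ndarray = field(repr=False, default=None)
    helmet_row4: np.ndarray = field(repr=False, default=None)  # dirs4 idx -> helmet-mesh row
    patch_members5: list = field(repr=False, default=None)     # per marker: dirs5 indices


# --------------------------------------------------------------------------
# analytic surfaces
# --------------------------------------------------------------------------

def _ellipsoid_point(u: np.ndarray, semiaxes) -> np.ndarray:
    return u * np.asarray(semiaxes)


def _ellipsoid_normal(u: np.ndarray, semiaxes) -> np.ndarray:
    n = u / np.asarray(semiaxes)
    return n / np.linalg.norm(n, axis=-1, keepdims=True)


def _nose_bump(u: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    theta = np.arccos(np.clip(u @ _NOSE_AXIS, -1.0, 1.0))
    bump = spec.nose_amplitude * np.exp(-0.5 * (theta / spec.nose_sigma) ** 2)
    for axis, amp, sigma in _FACE_FEATURES:
        th = np.arccos(np.clip(u @ axis, -1.0, 1.0))
        bump = bump + amp * np.exp(-0.5 * (th / sigma) ** 2)
    return bump


def scalp_surface(u, spec: PhantomSpec) -> np.ndarray:
    """Scalp point for unit direction(s) ``u``: ellipsoid plus nose bump."""
    u = np.atleast_2d(np.asarray(u, dtype=float))
    p = _ellipsoid_point(u, spec.scalp_semiaxes)
    n = _ellipsoid_normal(u, spec.scalp_semiaxes)
    return p + _nose_bump(u, spec)[:, None] * n


def helmet_surface(u, spec: PhantomSpec) -> np.ndarray:
    """Helmet inner-shell point: scalp surface offset outward along the normal."""
    u = np.atleast_2d(np.asarray(u, dtype=float))
    n = _ellipsoid_normal(u, spec.scalp_semiaxes)
    return scalp_surface(u, spec) + spec.helmet_standoff * n


def _angle_from(u: np.ndarray, axis: np.ndarray) -> np.ndarray:
    return np.arccos(np.clip(u @ axis, -1.0, 1.0))


def _face_mask(u: np.ndarray) -> np.ndarray:
    return _angle_from(u, _NOSE_AXIS) < _FACE_HALF_ANGLE


def _helmet_mask(u: np.ndarray, margin: float = 0.0) -> np.ndarray:
    return ((_angle_from(u, np.array([0.0, 0.0, 1.0])) < _HELMET_RIM_ANGLE - margin)
            & (_angle_from(u, _NOSE_AXIS) > _HELMET_FACE_CLEARANCE + margin))


def _farthest_point_subset(points: np.ndarray, k: int, start: int) -> np.ndarray:
    """Greedy farthest-point selection of k indices, deterministic given start."""
    chosen = [start]
    d = np.linalg.norm(points - points[start], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    return np.asarray(chosen)


def _nested_lattices(seed_rotation: np.ndarray, subdivisions: int):
    """Helmet, scan and MRI icosphere direction lattices, each nesting the last.

    The designed helmet lives on the coarse lattice, scans one subdivision
    finer, the MRI scalp mesh one finer still (segmented MRI surfaces are
    denser than optical scans). Midpoint subdivision keeps every coarse
    vertex, so the vertex sets nest exactly.
    """
    base = trimesh.creation.icosphere(subdivisions=subdivisions)
    v4 = np.asarray(base.vertices, dtype=float)
    f4 = np.asarray(base.faces)
    v5, f5 = trimesh.remesh.subdivide(v4, f4)
    v5 = v5 / np.linalg.norm(v5, axis=1, keepdims=True)
    v5[: len(v4)] = v4  # guarantee exact nesting
    v6, f6 = trimesh.remesh.subdivide(v5, f5)
    v6 = v6 / np.linalg.norm(v6, axis=1, keepdims=True)
    v6[: len(v5)] = v5
    rot = seed_rotation.T
    return v4 @ rot, f4, v5 @ rot, np.asarray(f5), v6 @ rot, np.asarray(f6)


# --------------------------------------------------------------------------
# phantom construction
# --------------------------------------------------------------------------

def make_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Generate the phantom for ``spec`` (deterministic in ``spec.seed``)."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)

    lattice_rot = random_rigid_transform(rng).rotation
    dirs4, faces4, dirs5, faces5, dirs6, faces6 = _nested_lattices(
        lattice_rot, spec.subdivisions)

    t1 = random_rigid_transform(rng, max_angle=np.deg2rad(15), max_translation=15,
                                source="device", target="head")
    t2 = random_rigid_transform(rng, max_angle=np.deg2rad(20), max_translation=30,
                                source="head", target="mri")
    inv_t1 = t1.inverse()

    scalp5 = scalp_surface(dirs5, spec)
    helmet5 = helmet_surface(dirs5, spec)
    face_mask5 = _face_mask(dirs5)
    helmet_mask5 = _helmet_mask(dirs5)
    lower_mask5 = _angle_from(dirs5, np.array([0.0, 0.0, 1.0])) > _HELMET_RIM_ANGLE
    helmet_mask4 = _helmet_mask(dirs4)

    scalp6 = scalp_surface(dirs6, spec)
    scalp_head = PointCloud(scalp6, faces=faces6)
    mri_scalp = PointCloud(t2.apply(scalp6), faces=faces6.copy())

    # designed helmet mesh: coarse-lattice vertices inside the helmet region
    hidx4 = np.flatnonzero(helmet_mask4)
    helmet_row4 = np.full(len(dirs4), -1, dtype=np.int64)
    helmet_row4[hidx4] = np.arange(len(hidx4))
    helmet_faces4 = faces4[helmet_mask4[faces4].all(axis=1)]
    helmet_mesh_head = helmet_surface(dirs4[hidx4], spec)
    designed_helmet = PointCloud(inv_t1.apply(helmet_mesh_head),
                                 faces=helmet_row4[helmet_faces4])

    # markers: well-spread interior helmet directions on the coarse lattice
    marker_cand = np.flatnonzero(_helmet_mask(dirs4)
                                 & (_angle_from(dirs4, _NOSE_AXIS) > _MARKER_MARGIN)
                                 & (_angle_from(dirs4, np.array([0., 0., 1.]))
                                    < _HELMET_RIM_ANGLE - np.deg2rad(10)))
    start = int(rng.integers(len(marker_cand)))
    marker_idx4 = marker_cand[_farthest_point_subset(dirs4[marker_cand],
                                                     spec.n_markers, start)]
    marker_centers = helmet_surface(dirs4[marker_idx4], spec)

    # painted patch = fine-lattice helmet samples within the patch radius;
    # the reference point is the centroid of the (noiseless) patch
    patch_members5 = []
    refs = []
    for c in marker_centers:
        members = np.flatnonzero(helmet_mask5
                                 & (np.linalg.norm(helmet5 - c, axis=1)
                                    <= spec.marker_patch_radius))
        if len(members) < 5:
            raise InputError("marker patch has too few scan samples; "
                             "increase marker_patch_radius or mesh density")
        patch_members5.append(members)
        refs.append(helmet5[members].mean(axis=0))
    marker_refs_head = np.asarray(refs)
    designed_refs = LabelledPoints(
        [f"REF{i + 1}" for i in range(spec.n_markers)],
        inv_t1.apply(marker_refs_head),
    )

    # sensors: spread over the coarse helmet lattice
    sensor_cand = hidx4
    if len(sensor_cand) < spec.n_sensors:
        raise InputError("helmet lattice too coarse for requested n_sensors")
    start = int(rng.integers(len(sensor_cand)))
    sensor_idx4 = sensor_cand[_farthest_point_subset(dirs4[sensor_cand],
                                                     spec.n_sensors, start)]
    su = dirs4[sensor_idx4]
    normals = _ellipsoid_normal(su, spec.scalp_semiaxes)
    positions_head = helmet_surface(su, spec) + spec.sensor_standoff * normals
    orientations_head = -normals[:, None, :]  # inward radial axis (toward scalp)
    labels = [f"CH{i + 1:03d}" for i in range(spec.n_sensors)]
    sensors_head = SensorArray(labels, positions_head, orientations_head)
    sensors_device = sensors_head.transformed(inv_t1)
    sensors_mri = sensors_head.transformed(t2)

    fid_dirs = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, -1.0, 0.0]])
    fid_pts = scalp_surface(fid_dirs, spec)
    fiducials_head = FiducialSet(["nasion", "lpa", "rpa"], fid_pts, frame="head")
    mri_fiducials = FiducialSet(["nasion", "lpa", "rpa"], t2.apply(fid_pts),
                                frame="mri")

    return Phantom(
        spec=spec, scalp_head=scalp_head, mri_scalp=mri_scalp,
        designed_helmet=designed_helmet, sensors_device=sensors_device,
        designed_refs=designed_refs, fiducials_head=fiducials_head,
        mri_fiducials=mri_fiducials,
        truth=PhantomTruth(t1=t1, t2=t2, sensors_head=sensors_head,
                           sensors_mri=sensors_mri,
                           marker_refs_head=marker_refs_head),
        dirs5=dirs5, dirs6=dirs6, scalp5=scalp5, helmet5=helmet5,
        face_mask5=face_mask5,
        helmet_mask5=helmet_mask5, lower_mask5=lower_mask5,
        helmet_row4=helmet_row4, patch_members5=patch_members5,
    )


# --------------------------------------------------------------------------
# simulated measurements
# --------------------------------------------------------------------------

def simulate_fastrak(phantom: Phantom, noise_sigma: float | None = None,
                     n_scalp_points: int = 200, seed: int = 0) -> DigitizedPoints:
    """Simulate a stylus digitization session.

    Fiducials, a sample of reachable scalp points (face and below-helmet
    band, drawn from the scalp-mesh vertex set) and the helmet reference
    points, all expressed in a random transmitter frame and perturbed by
    isotropic Gaussian noise of ``noise_sigma`` mm (default: the phantom
    spec's Fastrak noise level).
    """
    spec = phantom.spec
    sigma = spec.sigma_fastrak if noise_sigma is None else noise_sigma
    if n_scalp_points < 3:
        raise InputError("n_scalp_points must be >= 3")
    rng = np.random.default_rng(seed)
    dig = random_rigid_transform(rng, max_angle=np.deg2rad(45), max_translation=250,
                                 source="head", target="digitizer")
    reachable = np.flatnonzero(phantom.face_mask5 | phantom.lower_mask5)
    if n_scalp_points > len(reachable):
        raise InputError(f"at most {len(reachable)} reachable scalp points available")
    idx = rng.choice(reachable, size=n_scalp_points, replace=False)
    noise = lambda shape: rng.normal(scale=sigma, size=shape) if sigma > 0 else 0.0
    fid_pts = dig.apply(phantom.fiducials_head.points) + noise((3, 3))
    scalp = dig.apply(phantom.scalp5[idx]) + noise((n_scalp_points, 3))
    refs = dig.apply(phantom.truth.marker_refs_head) + noise(
        (len(phantom.truth.marker_refs_head), 3))
    return DigitizedPoints(
        FiducialSet(["nasion", "lpa", "rpa"], fid_pts, frame="digitizer"),
        scalp,
        LabelledPoints(list(phantom.designed_refs.labels), refs),
    )


_SKIN_RGB = np.array([205, 170, 140])
_MARKER_RGB = np.array([0, 255, 0])


@dataclass
class ScanSim:
    """A simulated optical scan plus the bookkeeping tests/pipelines need."""

    cloud: PointCloud
    head_to_scan: RigidTransform
    part: np.ndarray            # 0 = face (scalp surface), 1 = helmet surface
    lattice_index: np.ndarray   # per scan point: row into phantom.dirs5
    marker_mask: np.ndarray
    face_region: RegionSelection
    helmet_region: RegionSelection
    face_picks: np.ndarray      # (3, 3): front / left-cheek / right-cheek, scan frame

    def _spread(self, candidates: np.ndarray, k: int) -> np.ndarray:
        start = int(np.argmin(np.linalg.norm(
            self.cloud.vertices[candidates] - self.face_picks[0], axis=1)))
        return candidates[_farthest_point_subset(self.cloud.vertices[candidates],
                                                 k, start)]

    def face_pairs(self, phantom: Phantom, k: int = 4):
        """k corresponding landmark pairs (scan frame, MRI frame) on the face."""
        cand = np.flatnonzero(self.part == 0)
        chosen = self._spread(cand, k)
        src = self.cloud.vertices[chosen]
        tgt = phantom.mri_scalp.vertices[self.lattice_index[chosen]]
        return src, tgt

    def helmet_pairs(self, phantom: Phantom, k: int = 4):
        """k corresponding pairs (designed helmet device frame, scan frame)."""
        row = np.full(len(phantom.dirs5), -1, dtype=np.int64)
        n4 = len(phantom.helmet_row4)
        row[:n4] = phantom.helmet_row4
        cand = np.flatnonzero((self.part == 1) & (row[self.lattice_index] >= 0))
        chosen = self._spread(cand, k)
        src = phantom.designed_helmet.vertices[row[self.lattice_index[chosen]]]
        tgt = self.cloud.vertices[chosen]
        return src, tgt


def simulate_scan(phantom: Phantom, colored: bool, noise_sigma: float | None = None,
                  density: float | None = None, seed: int = 0) -> ScanSim:
    """Simulate an optical scan of the subject wearing the helmet.

    The scan covers the visible face (scalp surface) and the helmet outer
    region, sampled on the fine lattice, expressed in a random scanner
    frame and perturbed by isotropic Gaussian noise. When ``colored``,
    marker patches are painted pure green and everything else skin/grey
    tones chosen so the default green HSV window selects exactly the
    markers. ``density`` (points/mm²) optionally thins the sampling below
    the lattice density (marker patches are always kept intact); the
    default keeps the full lattice (≈0.1 points/mm²).

    Default noise: the phantom spec's structured-light sigma when
    ``colored``, else its laser sigma.
    """
    spec = phantom.spec
    if noise_sigma is None:
        noise_sigma = spec.sigma_structured_light if colored else spec.sigma_laser
    rng = np.random.default_rng(seed)
    scan_t = random_rigid_transform(rng, max_angle=np.deg2rad(30), max_translation=200,
                                    source="head", target="scan")

    face_idx = np.flatnonzero(phantom.face_mask5)
    helm_idx = np.flatnonzero(phantom.helmet_mask5)
    lattice_index = np.concatenate([face_idx, helm_idx])
    part = np.concatenate([np.zeros(len(face_idx), dtype=int),
                           np.ones(len(helm_idx), dtype=int)])
    verts_head = np.vstack([phantom.scalp5[face_idx], phantom.helmet5[helm_idx]])

    patch_set = np.zeros(len(phantom.dirs5), dtype=bool)
    for members in phantom.patch_members5:
        patch_set[members] = True
    marker_mask = patch_set[lattice_index] & (part == 1)

    if density is not None:
        if density <= 0:
            raise InputError("density must be positive")
        area = float(trimesh.Trimesh(phantom.scalp_head.vertices,
                                     phantom.scalp_head.faces, process=False).area)
        full_density = len(phantom.dirs5) / area
        frac = min(1.0, density / full_density)
        keep = (rng.random(len(verts_head)) < frac) | marker_mask
        verts_head = verts_head[keep]
        lattice_index = lattice_index[keep]
        part = part[keep]
        marker_mask = marker_mask[keep]

    verts = scan_t.apply(verts_head)
    if noise_sigma > 0:
        verts = verts + rng.normal(scale=noise_sigma, size=verts.shape)

    colors = None
    if colored:
        colors = np.empty((len(verts), 3), dtype=np.uint8)
        skin = np.clip(_SKIN_RGB + rng.integers(-10, 11, size=(len(verts), 3)),
                       0, 255)
        grey = rng.integers(190, 216, size=len(verts))
        helmet_rgb = np.stack([grey, grey, grey], axis=1)  # achromatic: S = 0
        colors[part == 0] = skin[part == 0]
        colors[part == 1] = helmet_rgb[part == 1]
        colors[marker_mask] = _MARKER_RGB

    cloud = PointCloud(verts, colors=colors)
    picks = []
    for key in ("front", "left", "right"):
        d = _PICK_DIRS[key] / np.linalg.norm(_PICK_DIRS[key])
        target = scan_t.apply(scalp_surface(d, spec)[0])
        face_verts = verts[part == 0]
        picks.append(face_verts[np.argmin(np.linalg.norm(face_verts - target, axis=1))])
    return ScanSim(
        cloud=cloud, head_to_scan=scan_t, part=part, lattice_index=lattice_index,
        marker_mask=marker_mask,
        face_region=RegionSelection(np.flatnonzero(part == 0), "face area"),
        helmet_region=RegionSelection(np.flatnonzero(part == 1), "helmet area"),
        face_picks=np.asarray(picks),
    )
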