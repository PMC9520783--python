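"""The three device co-registration workflows, depth adjustment, reporting.

Each workflow produces the same two-stage result: *transform 1* maps sensor
geometry from the helmet-design (MEG-Device) frame into a head-anchored
frame, *transform 2* maps that head frame onto the MRI, and their
composition carries the sensor array into MRI coordinates.

* Fastrak (electromagnetic stylus): head frame from digitized anatomical
  fiducials; transform 1 from labelled helmet reference points; transform 2
  from surface ICP of digitized scalp points onto the segmented MRI scalp.
* Structured-light scanner: head frame from three picked face points;
  transform 1 from HSV-extracted marker centroids matched to the designed
  reference points; transform 2 from coarse landmark pairs + face-region ICP.
* Laser scanner (colourless, high accuracy): transform 1 from coarse pairs
  + ICP of the designed helmet mesh onto the scanned helmet; transform 2 as
  for the structured-light scanner.

Depth adjustment moves each selected sensor along its slot-radial axis by
``depth = l − t − h`` (sensor height − helmet thickness − exposed height),
the offset between the actually-inserted vapor-cell center and its design
position.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import (CoregResult, DigitizedPoints, LabelledPoints, PointCloud,
                         SensorArray)
from .errors import InputError
from .geometry import FiducialSet, RigidTransform, build_head_frame, compose, kabsch_align
from .markers import HsvRange, cluster_markers, match_markers, select_by_hsv
from .registration import (IcpParams, RegionSelection, coarse_match, crop_region,
                           icp_register, pair_fre)

logger = logging.getLogger(__name__)

#: Empirical quality bounds on the ICP fitting error (mm); exceeding them
#: usually means poor scan/digitization quality rather than a bad algorithm.
FACE_RMS_WARN_MM = 2.0
HELMET_RMS_WARN_MM = 0.8


# --------------------------------------------------------------------------
# Depth adjustment
# --------------------------------------------------------------------------

@dataclass
class DepthSpec:
    """Per-channel insertion depth (mm).

    Depth may be given directly or derived from the measured triple
    ``(l, t, h)`` as ``depth = l − t − h`` with ``l`` the sensor height,
    ``t`` the helmet thickness and ``h`` the height of sensor left exposed
    outside the helmet. Flush insertion (``h = l − t``) gives depth 0.
    """

    depths: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for lab, d in self.depths.items():
            if not np.isfinite(d):
                raise InputError(f"non-finite depth for channel {lab!r}")

    @staticmethod
    def depth_from_lth(l: float, t: float, h: float) -> float:
        if not (l > 0):
            raise InputError(f"sensor height l must be > 0, got {l}")
        if t < 0 or h < 0:
            raise InputError("helmet thickness t and exposed height h must be >= 0")
        return l - t - h

    @classmethod
    def from_lth(cls, triples: dict[str, tuple[float, float, float]]) -> "DepthSpec":
        return cls({lab: cls.depth_from_lth(*lth) for lab, lth in triples.items()})

    @classmethod
    def from_table(cls, df) -> "DepthSpec":
        """Build from a table with columns ``label,depth`` or ``label,l,t,h``."""
        cols = set(df.columns)
        if "depth" in cols:
            return cls({str(r["label"]): float(r["depth"]) for _, r in df.iterrows()})
        if {"l", "t", "h"} <= cols:
            return cls.from_lth({str(r["label"]): (float(r["l"]), float(r["t"]),
                                                   float(r["h"]))
                                 for _, r in df.iterrows()})
        raise InputError("depth table needs columns label,depth or label,l,t,h")

    def get(self, label: str) -> float:
        if label not in self.depths:
            raise InputError(f"no depth recorded for channel {label!r}")
        return self.depths[label]


@dataclass
class ChannelSelection:
    """Subset of sensor-channel labels actually used in the measurement."""

    labels: list[str]

    def __post_init__(self):
        self.labels = [str(l) for l in self.labels]
        if not self.labels:
            raise InputError("channel selection is empty")
        if len(set(self.labels)) != len(self.labels):
            raise InputError("channel selection contains duplicates")


def apply_depth(sensors: SensorArray, selection: ChannelSelection,
                depths: DepthSpec, flip_direction: bool = False) -> SensorArray:
    """Keep only the selected channels and push each along its radial axis.

    The stored orientations are taken to point inward (helmet → scalp), so
    positive depth — a sensor inserted deeper than its design position —
    moves the vapor-cell center toward the scalp. ``flip_direction``
    reverses that convention for arrays stored with outward normals.
    Orientations are unchanged.
    """
    sub = sensors.subset(selection.labels)
    d = np.array([depths.get(lab) for lab in sub.labels])
    if np.any(np.abs(d) > 50.0):
        warnings.warn(
            f"implausible sensor depth(s) |d| > 50 mm: "
            f"{dict((lab, float(v)) for lab, v in zip(sub.labels, d) if abs(v) > 50)}",
            stacklevel=2,
        )
    sign = -1.0 if flip_direction else 1.0
    radial = sub.orientations[:, 0, :]
    return SensorArray(sub.labels, sub.positions + sign * d[:, None] * radial,
                       sub.orientations)


# --------------------------------------------------------------------------
# Workflows
# --------------------------------------------------------------------------

def _finish(sensors: SensorArray, t1: RigidTransform, t2: RigidTransform,
            fre1: float, rms2: float, rms1: float | None,
            metadata: dict) -> CoregResult:
    total = compose(t2, t1)
    return CoregResult(
        transform_device_to_head=t1,
        transform_head_to_mri=t2,
        sensors_mri=sensors.transformed(total),
        fre_transform1=fre1,
        icp_rms_transform2=rms2,
        icp_rms_transform1=rms1,
        metadata=metadata,
    )


def run_fastrak(sensors: SensorArray, designed_refs: LabelledPoints,
                digitized: DigitizedPoints, mri_scalp: PointCloud,
                params: IcpParams | None = None,
                mri_fiducials: FiducialSet | None = None) -> CoregResult:
    """Stylus-digitizer workflow.

    The head frame is built from the digitized nasion/LPA/RPA and all
    digitized points are re-expressed in it. Transform 1 aligns the designed
    helmet reference points to the digitized ones (matched by label);
    transform 2 registers the digitized scalp points onto the MRI scalp by
    trimmed ICP, seeded by a fiducial pre-alignment when MRI fiducials are
    supplied (otherwise the head and MRI frames are assumed roughly aligned).
    """
    params = params or IcpParams()
    fid = digitized.fiducials
    head_t = build_head_frame(fid.get("nasion"), fid.get("lpa"), fid.get("rpa"),
                              source_frame=fid.frame)
    common = [lab for lab in designed_refs.labels
              if lab in digitized.helmet_ref_points.labels]
    if len(common) < 3:
        raise InputError(
            f"need at least 3 helmet reference labels shared between the design "
            f"and the digitization, got {len(common)}: {common}"
        )
    refs_head = head_t.apply(digitized.helmet_ref_points.subset(common).points)
    t1, fre1 = kabsch_align(designed_refs.subset(common).points, refs_head,
                            source_frame="device", target_frame="head")
    scalp_head = head_t.apply(digitized.scalp_points)
    if mri_fiducials is not None:
        fids_head = head_t.apply(np.array([fid.get(l) for l in ("nasion", "lpa", "rpa")]))
        fids_mri = np.array([mri_fiducials.get(l) for l in ("nasion", "lpa", "rpa")])
        init, _ = kabsch_align(fids_head, fids_mri,
                               source_frame="head", target_frame="mri")
    else:
        init = RigidTransform.identity(source="head", target="mri")
    icp = icp_register(PointCloud(scalp_head), mri_scalp, init, params)
    meta = {"device": "fastrak", "icp_params": vars(params) | {},
            "icp_iterations_transform2": icp.iterations,
            "n_scalp_points": len(scalp_head), "ref_labels": common}
    return _finish(sensors, t1, icp.transform, fre1, icp.rms, None, meta)


def run_structured_light(sensors: SensorArray, designed_refs: LabelledPoints,
                         scan: PointCloud, face_picks, hsv: HsvRange,
                         coarse_pairs: tuple, face_region: RegionSelection,
                         mri_scalp: PointCloud,
                         params: IcpParams | None = None,
                         linkage_radius: float = 10.0,
                         min_cluster_size: int = 5) -> CoregResult:
    """Coloured-scan workflow.

    ``face_picks`` are three points on the scanned face, in the fixed order
    (nose-bridge/front, left cheek, right cheek), which define the head
    frame. ``coarse_pairs = (scan_points, mri_points)`` are ≥4 user-picked
    landmark pairs (scan frame / MRI frame) seeding the face ICP;
    ``face_region`` selects the face vertices of the scan used by the ICP.
    """
    params = params or IcpParams()
    if scan.colors is None:
        raise InputError("structured-light workflow requires a coloured scan")
    picks = np.asarray(face_picks, dtype=float)
    if picks.shape != (3, 3):
        raise InputError(f"face_picks must be three 3D points, got {picks.shape}")
    head_t = build_head_frame(picks[0], picks[1], picks[2], source_frame="scan")
    scan_head = scan.transformed(head_t)

    selection = select_by_hsv(scan_head, hsv)
    detected = cluster_markers(scan_head, selection, linkage_radius,
                               min_cluster_size, expected_k=len(designed_refs),
                               frame="head")
    _, t1, fre1 = match_markers(designed_refs.points, detected)
    t1 = t1.retag(source="device", target="head")

    pairs_scan, pairs_mri = coarse_pairs
    init = coarse_match(head_t.apply(pairs_scan), pairs_mri).retag(
        source="head", target="mri")
    face = crop_region(scan_head, face_region)
    icp = icp_register(face, mri_scalp, init, params)
    meta = {"device": "structured-light", "icp_params": vars(params) | {},
            "icp_iterations_transform2": icp.iterations,
            "hsv_window": vars(hsv) | {},
            "marker_cluster_sizes": detected.member_counts.tolist(),
            "n_face_points": len(face)}
    return _finish(sensors, t1, icp.transform, fre1, icp.rms, None, meta)


def run_laser(sensors: SensorArray, designed_helmet: PointCloud,
              scan: PointCloud, face_picks, helmet_pairs: tuple,
              helmet_region: RegionSelection, face_pairs: tuple,
              face_region: RegionSelection, mri_scalp: PointCloud,
              params: IcpParams | None = None) -> CoregResult:
    """Colourless high-accuracy scan workflow.

    Transform 1 registers the designed helmet mesh onto the scanned helmet
    (coarse pairs, then ICP); its residual is reported as
    ``icp_rms_transform1`` so the user can check the helmet match quality.
    Transform 2 is the same face-region ICP as in the structured-light
    workflow. ``helmet_pairs = (device_points, scan_points)`` and
    ``face_pairs = (scan_points, mri_points)``, each with ≥4 pairs.
    """
    params = params or IcpParams()
    picks = np.asarray(face_picks, dtype=float)
    if picks.shape != (3, 3):
        raise InputError(f"face_picks must be three 3D points, got {picks.shape}")
    head_t = build_head_frame(picks[0], picks[1], picks[2], source_frame="scan")
    scan_head = scan.transformed(head_t)

    hp_device, hp_scan = helmet_pairs
    hp_head = head_t.apply(hp_scan)
    coarse1 = coarse_match(hp_device, hp_head).retag(source="device", target="head")
    fre1 = pair_fre(coarse1, hp_device, hp_head)
    helmet_crop = crop_region(scan_head, helmet_region)
    icp1 = icp_register(designed_helmet, helmet_crop, coarse1, params)

    fp_scan, fp_mri = face_pairs
    coarse2 = coarse_match(head_t.apply(fp_scan), fp_mri).retag(
        source="head", target="mri")
    face = crop_region(scan_head, face_region)
    icp2 = icp_register(face, mri_scalp, coarse2, params)
    meta = {"device": "laser", "icp_params": vars(params) | {},
            "icp_iterations_transform1": icp1.iterations,
            "icp_iterations_transform2": icp2.iterations,
            "n_helmet_points": len(helmet_crop), "n_face_points": len(face)}
    return _finish(sensors, icp1.transform, icp2.transform, fre1,
                   icp2.rms, icp1.rms, meta)


# --------------------------------------------------------------------------
# Reporting
# --------------------------------------------------------------------------

def report(result: CoregResult) -> str:
    """Human-readable fit summary with quality warnings.

    A WARNING line is emitted when the face ICP residual exceeds 2 mm or
    the helmet ICP residual exceeds 0.8 mm — empirical bounds beyond which
    the scanned or digitized data quality should be checked.
    """
    meta = result.metadata
    lines = [f"device: {meta.get('device', 'unknown')}",
             f"transform 1 FRE: {result.fre_transform1:.4f} mm"]
    if result.icp_rms_transform1 is not None:
        lines.append(f"transform 1 ICP rms (helmet): {result.icp_rms_transform1:.4f} mm"
                     f" [{meta.get('icp_iterations_transform1', '?')} iterations]")
    lines.append(f"transform 2 ICP rms (face/scalp): {result.icp_rms_transform2:.4f} mm"
                 f" [{meta.get('icp_iterations_transform2', '?')} iterations]")
    lines.append(f"channels in MRI frame: {len(result.sensors_mri)}")
    if result.icp_rms_transform2 > FACE_RMS_WARN_MM:
        lines.append(
            f"WARNING: face ICP error {result.icp_rms_transform2:.2f} mm exceeds "
            f"{FACE_RMS_WARN_MM:g} mm — check the scanned/digitized data quality"
        )
    if result.icp_rms_transform1 is not None and result.icp_rms_transform1 > HELMET_RMS_WARN_MM:
        lines.append(
            f"WARNING: helmet ICP error {result.icp_rms_transform1:.2f} mm exceeds "
            f"{HELMET_RMS_WARN_MM:g} mm — check the scanned data quality"
        )
    text = "\n".join(lines)
    for line in lines:
        if line.startswith("WARNING"):
            logger.warning(line)
    return text
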