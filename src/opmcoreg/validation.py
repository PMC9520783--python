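"""Seeded registration benchmarks on the synthetic phantom.

These routines reproduce, at desk scale, the two quality figures users are
told to watch: the face-surface ICP fitting error (good fits stay below
2 mm) and the designed-helmet-to-scan ICP fitting error (below 0.8 mm).
Each trial generates a fresh phantom, simulates the relevant scan, and
registers with the default trimmed ICP, reporting the final retained-pair
RMS in mm.
"""

from __future__ import annotations

import numpy as np

from .geometry import RigidTransform, compose, random_rigid_transform, rotation_angle
from .phantom import Phantom, PhantomSpec, make_phantom, simulate_scan
from .registration import IcpParams, RegionSelection, coarse_match, crop_region, icp_register


def perturbed(t: RigidTransform, rng: np.random.Generator,
              max_angle_deg: float = 5.0, max_translation: float = 5.0,
              about=(0.0, 0.0, 0.0)) -> RigidTransform:
    """Compose ``t`` with a bounded random wobble rotating about ``about``.

    Rotating about a point near the registered surface keeps the initial
    pose displacement of that surface within roughly the stated bounds
    (a rotation about a distant origin would displace it far more).
    """
    about = np.asarray(about, dtype=float)
    wobble = random_rigid_transform(rng, max_angle=np.deg2rad(max_angle_deg),
                                    max_translation=max_translation)
    centered = RigidTransform(wobble.rotation,
                              about - wobble.rotation @ about + wobble.translation)
    return compose(centered, t.retag(source=None, target=None)).retag(
        source=t.source, target=t.target)


def face_icp_trial(seed: int, noise_sigma: float = 0.5,
                   init_angle_deg: float = 5.0, init_translation: float = 5.0,
                   params: IcpParams | None = None) -> dict:
    """One face-registration trial: noisy face scan onto the noiseless scalp mesh.

    The scan's face region (≈1500 points at the default sampling) is
    expressed in the head frame, the initialization is displaced from the
    ground-truth head→MRI transform by up to ``init_angle_deg`` /
    ``init_translation``, and trimmed ICP runs against the phantom scalp
    mesh in the MRI frame. Returns the final RMS plus recovery errors.
    """
    params = params or IcpParams()
    rng = np.random.default_rng(seed + 7919)
    ph = make_phantom(PhantomSpec(seed=seed))
    scan = simulate_scan(ph, colored=False, noise_sigma=noise_sigma, seed=seed)
    face_head = crop_region(scan.cloud.transformed(scan.head_to_scan.inverse()),
                            scan.face_region)
    face_centroid_mri = ph.truth.t2.apply(face_head.vertices).mean(axis=0)
    init = perturbed(ph.truth.t2, rng, init_angle_deg, init_translation,
                     about=face_centroid_mri)
    res = icp_register(face_head, ph.mri_scalp, init, params)
    err = compose(res.transform.retag(source=None, target=None),
                  ph.truth.t2.inverse().retag(source=None, target=None))
    sensor_pts = ph.truth.sensors_mri.positions
    sensor_err = np.linalg.norm(err.apply(sensor_pts) - sensor_pts, axis=1)
    return {
        "rms": res.rms,
        "n_points": len(face_head),
        "iterations": res.iterations,
        "rotation_error_deg": np.rad2deg(rotation_angle(err.rotation)),
        "translation_error_mm": float(np.linalg.norm(err.translation)),
        "sensor_position_error_mm": float(sensor_err.mean()),
    }


def helmet_icp_trial(seed: int, noise_sigma: float = 0.1, n_pairs: int = 4,
                     params: IcpParams | None = None) -> dict:
    """One helmet-registration trial: designed helmet onto a noisy laser scan.

    A colourless scan of the helmet is simulated, the registration is
    seeded by a coarse match over ``n_pairs`` labelled pairs, and trimmed
    ICP registers the designed helmet mesh onto the cropped helmet region
    of the scan (both in the head frame).
    """
    params = params or IcpParams()
    ph = make_phantom(PhantomSpec(seed=seed))
    scan = simulate_scan(ph, colored=False, noise_sigma=noise_sigma, seed=seed)
    scan_head = scan.cloud.transformed(scan.head_to_scan.inverse())
    helmet_crop = crop_region(scan_head, scan.helmet_region)
    src_dev, tgt_scan = scan.helmet_pairs(ph, k=n_pairs)
    init = coarse_match(src_dev, scan.head_to_scan.inverse().apply(tgt_scan))
    res = icp_register(ph.designed_helmet, helmet_crop, init, params)
    err = compose(res.transform.retag(source=None, target=None),
                  ph.truth.t1.inverse().retag(source=None, target=None))
    return {
        "rms": res.rms,
        "n_points": len(ph.designed_helmet),
        "iterations": res.iterations,
        "rotation_error_deg": np.rad2deg(rotation_angle(err.rotation)),
        "translation_error_mm": float(np.linalg.norm(err.translation)),
    }


def mean_face_icp_rms(seeds) -> tuple[float, int]:
    """Mean face-ICP RMS (mm) over trial seeds, plus the mean problem size."""
    trials = [face_icp_trial(int(s)) for s in seeds]
    return (float(np.mean([t["rms"] for t in trials])),
            int(np.mean([t["n_points"] for t in trials])))


def mean_helmet_icp_rms(seeds) -> tuple[float, int]:
    """Mean helmet-ICP RMS (mm) over trial seeds, plus the mean problem size."""
    trials = [helmet_icp_trial(int(s)) for s in seeds]
    return (float(np.mean([t["rms"] for t in trials])),
            int(np.mean([t["n_points"] for t in trials])))
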