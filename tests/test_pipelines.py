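"""Device workflows end-to-end on the synthetic phantom, depth, reporting."""

import numpy as np
import pytest

from opmcoreg import (ChannelSelection, DepthSpec, GREEN_MARKER_WINDOW, InputError,
                      LabelledPoints, PointCloud, SensorArray, apply_depth,
                      make_phantom, PhantomSpec, report, run_fastrak, run_laser,
                      run_structured_light, simulate_fastrak, simulate_scan)
from opmcoreg.containers import CoregResult, DigitizedPoints
from opmcoreg.geometry import FiducialSet, RigidTransform, random_rigid_transform


def sensor_errors(result, phantom):
    truth = phantom.truth.sensors_mri
    pos = np.linalg.norm(result.sensors_mri.positions - truth.positions, axis=1)
    dots = np.clip(np.sum(result.sensors_mri.orientations * truth.orientations,
                          axis=2), -1.0, 1.0)
    return pos, np.arccos(dots)


class TestFastrak:
    def test_noiseless_recovery_is_exact(self, phantom):
        dig = simulate_fastrak(phantom, noise_sigma=0.0, seed=5)
        res = run_fastrak(phantom.sensors_device, phantom.designed_refs, dig,
                          phantom.mri_scalp, mri_fiducials=phantom.mri_fiducials)
        pos, _ = sensor_errors(res, phantom)
        assert pos.max() < 1e-6
        # chord length between unit vectors ~ angle in radians for small angles
        # (arccos cannot resolve angles this small in float64)
        chord = np.linalg.norm(res.sensors_mri.orientations
                               - phantom.truth.sensors_mri.orientations, axis=2)
        assert chord.max() < 1e-8
        assert res.fre_transform1 < 1e-9
        assert res.icp_rms_transform1 is None

    def test_noisy_recovery_within_bounds(self):
        """Digitization noise of 0.5 mm keeps mean sensor errors < 2 mm / 1 deg."""
        pos_means, ang_means = [], []
        for seed in range(1, 6):
            ph = make_phantom(PhantomSpec(seed=seed))
            dig = simulate_fastrak(ph, noise_sigma=0.5, seed=100 + seed)
            res = run_fastrak(ph.sensors_device, ph.designed_refs, dig,
                              ph.mri_scalp, mri_fiducials=ph.mri_fiducials)
            pos, ang = sensor_errors(res, ph)
            pos_means.append(pos.mean())
            ang_means.append(np.rad2deg(ang).mean())
        assert np.mean(pos_means) < 2.0
        assert np.mean(ang_means) < 1.0

    def test_missing_helmet_refs_rejected(self, phantom):
        dig = simulate_fastrak(phantom, noise_sigma=0.0, seed=5)
        broken = DigitizedPoints(
            dig.fiducials, dig.scalp_points,
            LabelledPoints(["OTHER1", "OTHER2", "OTHER3"],
                           dig.helmet_ref_points.points[:3]))
        with pytest.raises(InputError, match="at least 3"):
            run_fastrak(phantom.sensors_device, phantom.designed_refs, broken,
                        phantom.mri_scalp)


class TestStructuredLight:
    def test_noiseless_recovery(self, phantom, clean_scan):
        res = run_structured_light(
            phantom.sensors_device, phantom.designed_refs, clean_scan.cloud,
            clean_scan.face_picks, GREEN_MARKER_WINDOW,
            clean_scan.face_pairs(phantom), clean_scan.face_region,
            phantom.mri_scalp)
        pos, ang = sensor_errors(res, phantom)
        assert pos.max() < 1e-3
        assert np.rad2deg(ang).max() < 0.01
        assert res.metadata["device"] == "structured-light"

    def test_noisy_recovery(self):
        pos_means = []
        for seed in range(1, 4):
            ph = make_phantom(PhantomSpec(seed=seed))
            scan = simulate_scan(ph, colored=True, noise_sigma=0.3, seed=30 + seed)
            res = run_structured_light(
                ph.sensors_device, ph.designed_refs, scan.cloud, scan.face_picks,
                GREEN_MARKER_WINDOW, scan.face_pairs(ph), scan.face_region,
                ph.mri_scalp)
            pos, _ = sensor_errors(res, ph)
            pos_means.append(pos.mean())
        assert np.mean(pos_means) < 2.5

    def test_colourless_scan_rejected(self, phantom):
        scan = simulate_scan(phantom, colored=False, noise_sigma=0.0, seed=7)
        with pytest.raises(InputError, match="colour"):
            run_structured_light(
                phantom.sensors_device, phantom.designed_refs, scan.cloud,
                scan.face_picks, GREEN_MARKER_WINDOW, scan.face_pairs(phantom),
                scan.face_region, phantom.mri_scalp)


class TestLaser:
    def test_noiseless_recovery(self, phantom, clean_scan):
        res = run_laser(
            phantom.sensors_device, phantom.designed_helmet, clean_scan.cloud,
            clean_scan.face_picks, clean_scan.helmet_pairs(phantom),
            clean_scan.helmet_region, clean_scan.face_pairs(phantom),
            clean_scan.face_region, phantom.mri_scalp)
        pos, ang = sensor_errors(res, phantom)
        assert pos.max() < 0.05
        assert res.icp_rms_transform1 is not None
        assert res.icp_rms_transform1 < 1e-9  # exact surface overlap

    def test_noisy_helmet_rms_stays_below_bound(self):
        rmss = []
        for seed in range(1, 4):
            ph = make_phantom(PhantomSpec(seed=seed))
            scan = simulate_scan(ph, colored=False, noise_sigma=0.1, seed=40 + seed)
            res = run_laser(
                ph.sensors_device, ph.designed_helmet, scan.cloud, scan.face_picks,
                scan.helmet_pairs(ph), scan.helmet_region, scan.face_pairs(ph),
                scan.face_region, ph.mri_scalp)
            rmss.append(res.icp_rms_transform1)
        assert np.mean(rmss) < 0.8

    def test_three_helmet_pairs_rejected(self, phantom, clean_scan):
        src, tgt = clean_scan.helmet_pairs(phantom, k=4)
        with pytest.raises(InputError, match="four"):
            run_laser(phantom.sensors_device, phantom.designed_helmet,
                      clean_scan.cloud, clean_scan.face_picks,
                      (src[:3], tgt[:3]), clean_scan.helmet_region,
                      clean_scan.face_pairs(phantom), clean_scan.face_region,
                      phantom.mri_scalp)


class TestEquivariance:
    def test_moving_the_mri_moves_sensors_identically(self, phantom, rng):
        """Rigidly moving the MRI scalp and fiducials by Q moves the recovered
        sensors by exactly Q (noiseless phantom)."""
        dig = simulate_fastrak(phantom, noise_sigma=0.0, seed=5)
        q = random_rigid_transform(rng)
        res0 = run_fastrak(phantom.sensors_device, phantom.designed_refs, dig,
                           phantom.mri_scalp, mri_fiducials=phantom.mri_fiducials)
        moved_fids = FiducialSet(phantom.mri_fiducials.labels,
                                 q.apply(phantom.mri_fiducials.points), frame="mri")
        res1 = run_fastrak(phantom.sensors_device, phantom.designed_refs, dig,
                           phantom.mri_scalp.transformed(q),
                           mri_fiducials=moved_fids)
        assert np.allclose(res1.sensors_mri.positions,
                           q.apply(res0.sensors_mri.positions), atol=1e-6)

    def test_triaxis_orientations_rotate_together(self, phantom):
        """A K=3 array keeps its orthonormal triads to 1e-9 through the pipeline."""
        base = phantom.sensors_device
        n = len(base)
        triads = np.zeros((n, 3, 3))
        triads[:, 0] = base.orientations[:, 0]
        helper = np.where(np.abs(triads[:, 0, 2:3]) < 0.9,
                          np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]))
        second = np.cross(triads[:, 0], helper)
        triads[:, 1] = second / np.linalg.norm(second, axis=1, keepdims=True)
        triads[:, 2] = np.cross(triads[:, 0], triads[:, 1])
        tri = SensorArray(base.labels, base.positions, triads)
        dig = simulate_fastrak(phantom, noise_sigma=0.0, seed=5)
        res = run_fastrak(tri, phantom.designed_refs, dig, phantom.mri_scalp,
                          mri_fiducials=phantom.mri_fiducials)
        o = res.sensors_mri.orientations
        gram = np.einsum("nij,nkj->nik", o, o)
        assert np.allclose(gram, np.eye(3), atol=1e-9)


class TestDepth:
    @pytest.mark.parametrize("l,t,h,expected", [
        (14.5, 3.0, 8.5, 3.0),
        (14.5, 3.0, 11.5, 0.0),   # flush insertion: h = l - t
        (20.0, 0.0, 5.0, 15.0),
        (10.0, 2.5, 7.5, 0.0),
        (12.0, 4.0, 9.0, -1.0),   # sensor sitting proud of the slot
    ])
    def test_depth_formula(self, l, t, h, expected):
        assert DepthSpec.depth_from_lth(l, t, h) == pytest.approx(expected,
                                                                  abs=1e-12)

    def test_positive_depth_moves_along_radial_axis(self):
        sensors = SensorArray(["A", "B"], [[0.0, 0, 10.0], [5.0, 0, 10.0]],
                              [[[0.0, 0, -1.0]], [[0.0, 0, -1.0]]])
        out = apply_depth(sensors, ChannelSelection(["A", "B"]),
                          DepthSpec.from_lth({"A": (14.5, 3.0, 8.5),
                                              "B": (14.5, 3.0, 11.5)}))
        assert np.allclose(out.positions[0], [0, 0, 7.0])   # moved 3 mm inward
        assert np.allclose(out.positions[1], [5, 0, 10.0])  # flush: no-op
        assert np.allclose(out.orientations, sensors.orientations)

    def test_selection_subsets_channels(self, phantom):
        sel = ChannelSelection(phantom.sensors_device.labels[:10])
        depths = DepthSpec({lab: 1.0 for lab in sel.labels})
        out = apply_depth(phantom.sensors_device, sel, depths)
        assert out.labels == sel.labels and len(out) == 10

    def test_flip_direction(self):
        sensors = SensorArray(["A"], [[0.0, 0, 0]], [[[0.0, 0, 1.0]]])
        sel = ChannelSelection(["A"])
        d = DepthSpec({"A": 2.0})
        assert np.allclose(apply_depth(sensors, sel, d).positions[0], [0, 0, 2.0])
        assert np.allclose(
            apply_depth(sensors, sel, d, flip_direction=True).positions[0],
            [0, 0, -2.0])

    def test_commutes_with_rigid_transform(self, phantom, rng):
        sel = ChannelSelection(phantom.sensors_device.labels)
        depths = DepthSpec({lab: float(d) for lab, d in
                            zip(sel.labels, rng.uniform(-3, 6, len(sel.labels)))})
        q = random_rigid_transform(rng)
        a = apply_depth(phantom.sensors_device, sel, depths).transformed(q)
        b = apply_depth(phantom.sensors_device.transformed(q), sel, depths)
        assert np.allclose(a.positions, b.positions, atol=1e-9)

    def test_unknown_label_and_implausible_depth(self, phantom):
        with pytest.raises(InputError):
            apply_depth(phantom.sensors_device, ChannelSelection(["NOPE"]),
                        DepthSpec({"NOPE": 1.0}))
        sel = ChannelSelection(phantom.sensors_device.labels[:1])
        with pytest.warns(UserWarning, match="implausible"):
            apply_depth(phantom.sensors_device, sel,
                        DepthSpec({sel.labels[0]: 60.0}))

    def test_lth_validation(self):
        with pytest.raises(InputError):
            DepthSpec.depth_from_lth(0.0, 1.0, 1.0)
        with pytest.raises(InputError):
            DepthSpec.depth_from_lth(10.0, -1.0, 1.0)


class TestReport:
    def make_result(self, face_rms, helmet_rms=None):
        sensors = SensorArray(["A"], [[0.0, 0, 0]], [[[0.0, 0, 1.0]]])
        return CoregResult(RigidTransform.identity(), RigidTransform.identity(),
                           sensors, fre_transform1=0.5,
                           icp_rms_transform2=face_rms,
                           icp_rms_transform1=helmet_rms,
                           metadata={"device": "laser"})

    def test_good_fit_has_no_warning(self):
        assert "WARNING" not in report(self.make_result(1.2))

    def test_face_rms_above_2mm_warns(self):
        text = report(self.make_result(2.5))
        assert "WARNING" in text and "2.50 mm" in text

    def test_helmet_rms_above_08mm_warns(self):
        text = report(self.make_result(1.0, helmet_rms=0.9))
        assert "WARNING" in text and "0.90 mm" in text
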