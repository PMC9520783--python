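"""File formats: PLY round trips, sensor/digitization tables, result export."""

import json

import numpy as np
import pytest

from opmcoreg import (FormatError, InputError, PointCloud, RigidTransform, SensorArray,
                      read_coreg_metadata, read_digitized_points, read_ply,
                      read_sensor_table, write_coreg_result, write_ply,
                      write_sensor_table)
from opmcoreg.containers import CoregResult
from opmcoreg.geometry import random_rigid_transform


def make_cloud(rng, n=20, colors=False, faces=False):
    v = rng.uniform(-50, 50, size=(n, 3))
    c = rng.integers(0, 256, size=(n, 3)) if colors else None
    f = np.array([[0, 1, 2], [1, 2, 3]]) if faces else None
    return PointCloud(v, colors=c, faces=f)


class TestPly:
    @pytest.mark.parametrize("binary", [False, True])
    @pytest.mark.parametrize("colors,faces", [(False, False), (True, False),
                                              (False, True), (True, True)])
    def test_round_trip(self, tmp_path, rng, binary, colors, faces):
        cloud = make_cloud(rng, colors=colors, faces=faces)
        path = tmp_path / "c.ply"
        write_ply(cloud, path, binary=binary)
        back = read_ply(path)
        assert np.allclose(back.vertices, cloud.vertices, atol=1e-4)  # float32
        assert back.has_colors == colors
        if colors:
            assert np.array_equal(back.colors, cloud.colors)
        if faces:
            assert np.array_equal(back.faces, cloud.faces)
        else:
            assert back.faces is None

    def test_colorless_cloud_omits_color_properties(self, tmp_path, rng):
        path = tmp_path / "c.ply"
        write_ply(make_cloud(rng), path)
        header = path.read_bytes().split(b"end_header")[0].decode()
        assert "red" not in header and "face" not in header

    def test_ascii_fixture_with_colors(self, tmp_path):
        path = tmp_path / "c.ply"
        path.write_text(
            "ply\nformat ascii 1.0\nelement vertex 3\n"
            "property float x\nproperty float y\nproperty float z\n"
            "property uchar red\nproperty uchar green\nproperty uchar blue\n"
            "end_header\n0 0 0 255 0 0\n1 0 0 0 255 0\n0 1 0 10 20 30\n")
        cloud = read_ply(path)
        assert len(cloud) == 3 and cloud.has_colors
        assert np.array_equal(cloud.colors[2], [10, 20, 30])
        assert cloud.colors.min() >= 0 and cloud.colors.max() <= 255

    def test_big_endian_rejected(self, tmp_path):
        path = tmp_path / "be.ply"
        path.write_bytes(b"ply\nformat binary_big_endian 1.0\nelement vertex 1\n"
                         b"property float x\nproperty float y\nproperty float z\n"
                         b"end_header\n" + b"\x00" * 12)
        with pytest.raises(FormatError, match="big_endian"):
            read_ply(path)

    def test_missing_xyz_rejected(self, tmp_path):
        path = tmp_path / "bad.ply"
        path.write_text("ply\nformat ascii 1.0\nelement vertex 1\n"
                        "property float x\nproperty float y\nend_header\n0 0\n")
        with pytest.raises(FormatError, match="x/y/z"):
            read_ply(path)

    def test_unknown_property_warns_and_is_ignored(self, tmp_path, caplog):
        path = tmp_path / "extra.ply"
        path.write_text(
            "ply\nformat ascii 1.0\nelement vertex 2\n"
            "property float x\nproperty float y\nproperty float z\n"
            "property float quality\nend_header\n1 2 3 0.5\n4 5 6 0.6\n")
        with caplog.at_level("WARNING"):
            cloud = read_ply(path)
        assert "quality" in caplog.text
        assert np.allclose(cloud.vertices, [[1, 2, 3], [4, 5, 6]])

    def test_nan_coordinates_rejected(self, tmp_path):
        path = tmp_path / "nan.ply"
        path.write_text("ply\nformat ascii 1.0\nelement vertex 1\n"
                        "property float x\nproperty float y\nproperty float z\n"
                        "end_header\nnan 0 0\n")
        with pytest.raises(FormatError, match="NaN"):
            read_ply(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(InputError):
            read_ply(tmp_path / "nope.ply")


class TestSensorTable:
    def test_radial_round_trip(self, tmp_path, rng):
        ori = rng.normal(size=(2, 1, 3))
        sensors = SensorArray(["A1", "A2"], rng.normal(size=(2, 3)), ori)
        path = tmp_path / "s.csv"
        write_sensor_table(sensors, path)
        back = read_sensor_table(path)
        assert back.labels == ["A1", "A2"] and back.n_axes == 1
        assert np.allclose(back.positions, sensors.positions, atol=1e-9)
        assert np.allclose(back.orientations, sensors.orientations, atol=1e-9)

    def test_triaxis_inferred_from_columns(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("label,px,py,pz,ox1,oy1,oz1,ox2,oy2,oz2,ox3,oy3,oz3\n"
                        "A,0,0,0,1,0,0,0,1,0,0,0,1\n"
                        "B,1,1,1,0,0,1,1,0,0,0,1,0\n")
        sensors = read_sensor_table(path)
        assert sensors.n_axes == 3 and len(sensors) == 2

    def test_slightly_off_norms_renormalized_exactly(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("label,px,py,pz,ox1,oy1,oz1\nA,0,0,0,0.999,0,0\n")
        sensors = read_sensor_table(path)
        assert np.linalg.norm(sensors.orientations[0, 0]) == pytest.approx(1.0,
                                                                           abs=1e-15)

    def test_badly_off_norm_warns(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("label,px,py,pz,ox1,oy1,oz1\nA,0,0,0,0.5,0,0\n")
        with pytest.warns(UserWarning, match="renormalizing"):
            read_sensor_table(path)

    def test_zero_norm_rejected(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("label,px,py,pz,ox1,oy1,oz1\nA,0,0,0,0,0,0\n")
        with pytest.raises(InputError):
            read_sensor_table(path)

    def test_nan_rejected(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("label,px,py,pz,ox1,oy1,oz1\nA,nan,0,0,1,0,0\n")
        with pytest.raises(FormatError):
            read_sensor_table(path)


def write_head_points(path, rows):
    path.write_text("label,x,y,z\n" + "\n".join(rows) + "\n")


class TestDigitizedPoints:
    FIDS = ["nasion,100,0,0", "LPA,0,75,0", "rpa,0,-75,0"]

    def test_fiducials_and_scalp_split(self, tmp_path):
        scalp = [f"S{i},{i},0,50" for i in range(40)]
        write_head_points(tmp_path / "head.csv", self.FIDS + scalp)
        write_head_points(tmp_path / "refs.csv", ["R1,0,0,120", "R2,50,0,110",
                                                  "R3,-50,0,110"])
        dig = read_digitized_points(tmp_path / "head.csv", tmp_path / "refs.csv")
        assert len(dig.scalp_points) == 40
        assert dig.fiducials.labels == ["nasion", "lpa", "rpa"]  # case-insensitive
        assert dig.helmet_ref_points.labels == ["R1", "R2", "R3"]

    def test_missing_fiducial_rejected(self, tmp_path):
        write_head_points(tmp_path / "head.csv",
                          [self.FIDS[0], self.FIDS[2]] + ["S1,0,0,50"] * 1)
        write_head_points(tmp_path / "refs.csv", ["R1,0,0,120"])
        with pytest.raises(InputError, match="lpa"):
            read_digitized_points(tmp_path / "head.csv", tmp_path / "refs.csv")

    def test_duplicate_fiducial_rejected(self, tmp_path):
        write_head_points(tmp_path / "head.csv", self.FIDS + ["NASION,99,0,0"])
        write_head_points(tmp_path / "refs.csv", ["R1,0,0,120"])
        with pytest.raises(InputError, match="duplicate"):
            read_digitized_points(tmp_path / "head.csv", tmp_path / "refs.csv")

    def test_few_scalp_points_warn(self, tmp_path):
        write_head_points(tmp_path / "head.csv", self.FIDS + ["S1,0,0,50"])
        write_head_points(tmp_path / "refs.csv", ["R1,0,0,120"])
        with pytest.warns(UserWarning, match="recommended"):
            read_digitized_points(tmp_path / "head.csv", tmp_path / "refs.csv")


class TestCoregResult:
    def make_result(self, rng):
        t1 = random_rigid_transform(rng, source="device", target="head")
        t2 = random_rigid_transform(rng, source="head", target="mri")
        sensors = SensorArray(["A"], [[1.0, 2.0, 3.0]], [[[0.0, 0.0, 1.0]]])
        return CoregResult(t1, t2, sensors, fre_transform1=0.1234567,
                           icp_rms_transform2=0.7654321,
                           metadata={"device": "fastrak"})

    def test_sidecar_round_trip(self, tmp_path, rng):
        result = self.make_result(rng)
        write_coreg_result(result, tmp_path / "out")
        meta = read_coreg_metadata(tmp_path / "out")
        for key, t in (("transform_device_to_head", result.transform_device_to_head),
                       ("transform_head_to_mri", result.transform_head_to_mri)):
            assert np.allclose(meta[key].rotation, t.rotation, atol=1e-12)
            assert np.allclose(meta[key].translation, t.translation, atol=1e-12)
        assert meta["fre_transform1_mm"] == pytest.approx(0.1234567, abs=1e-9)
        assert meta["icp_rms_transform1_mm"] is None
        assert meta["metadata"]["device"] == "fastrak"

    def test_error_fields_keep_precision(self, tmp_path, rng):
        result = self.make_result(rng)
        write_coreg_result(result, tmp_path / "out")
        raw = json.loads((tmp_path / "out" / "coreg_metadata.json").read_text())
        assert abs(raw["icp_rms_transform2_mm"] - 0.7654321) < 1e-7

    def test_sensor_table_round_trips(self, tmp_path, rng):
        result = self.make_result(rng)
        paths = write_coreg_result(result, tmp_path / "out")
        back = read_sensor_table(paths["sensors"])
        assert np.allclose(back.positions, result.sensors_mri.positions, atol=1e-9)

    def test_negative_error_rejected(self, rng):
        sensors = SensorArray(["A"], [[0.0, 0, 0]], [[[0.0, 0, 1.0]]])
        with pytest.raises(InputError):
            CoregResult(RigidTransform.identity(), RigidTransform.identity(),
                        sensors, fre_transform1=-1.0, icp_rms_transform2=0.0)
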