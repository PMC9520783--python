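"""Readers and writers for the co-registration inputs and outputs.

Surfaces and scans travel as PLY (ASCII or binary little-endian); tabular
data (sensors, digitized points, landmark pairs, depths) travels as
delimited text with a header row, with an optional ``.xlsx`` path accepted
wherever a table is read. The final result is a sensor table in the MRI
frame plus a JSON sidecar holding both transforms as 4x4 homogeneous
matrices and the fit-error metrics.
"""

from __future__ import annotations

import datetime
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .containers import CoregResult, DigitizedPoints, LabelledPoints, PointCloud, SensorArray
from .errors import FormatError, InputError
from .geometry import FiducialSet, RigidTransform

logger = logging.getLogger(__name__)

_KNOWN_VERTEX_PROPS = {"x", "y", "z", "red", "green", "blue"}
_RESERVED_FIDUCIALS = ("nasion", "lpa", "rpa")


# --------------------------------------------------------------------------
# PLY
# --------------------------------------------------------------------------

def _parse_ply_header(path: Path):
    """Light header scan: dialect check plus declared vertex properties."""
    lines = []
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise FormatError(f"{path}: not a PLY file (missing 'ply' magic)")
        while True:
            raw = fh.readline()
            if not raw:
                raise FormatError(f"{path}: truncated PLY header")
            line = raw.decode("ascii", errors="replace").strip()
            lines.append(line)
            if line == "end_header":
                break
    fmt = next((l.split() for l in lines if l.startswith("format")), None)
    if fmt is None:
        raise FormatError(f"{path}: PLY header missing format line")
    if fmt[1] == "binary_big_endian":
        raise FormatError(
            f"{path}: binary_big_endian PLY is not supported; "
            "convert to ASCII or binary little-endian"
        )
    if fmt[1] not in ("ascii", "binary_little_endian"):
        raise FormatError(f"{path}: unknown PLY format {fmt[1]!r}")
    vertex_props: list[str] = []
    in_vertex = False
    has_faces = False
    for line in lines:
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if tok[1] == "face":
                has_faces = True
        elif tok[0] == "property" and in_vertex:
            vertex_props.append(tok[-1])
    if not {"x", "y", "z"} <= set(vertex_props):
        raise FormatError(f"{path}: PLY vertex element lacks x/y/z properties")
    unknown = [p for p in vertex_props if p not in _KNOWN_VERTEX_PROPS]
    if unknown:
        logger.warning("%s: ignoring unknown vertex properties %s", path, unknown)
    return vertex_props, has_faces


def read_ply(path) -> PointCloud:
    """Read an ASCII or binary-little-endian PLY file into a PointCloud.

    Vertex colours are returned only when the file declares per-vertex
    red/green/blue; unknown vertex properties are ignored with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    props, _ = _parse_ply_header(path)
    try:
        mesh = trimesh.load(str(path), file_type="ply", process=False)
    except Exception as exc:  # malformed/truncated body
        raise FormatError(f"{path}: failed to parse PLY body ({exc})") from exc
    vertices = np.asarray(mesh.vertices, dtype=float)
    if vertices.size == 0:
        raise FormatError(f"{path}: PLY file contains no vertices")
    if not np.all(np.isfinite(vertices)):
        raise FormatError(f"{path}: vertex coordinates contain NaN/Inf")
    colors = None
    if {"red", "green", "blue"} <= set(props):
        if isinstance(mesh, trimesh.PointCloud):
            colors = np.asarray(mesh.colors)[:, :3]
        else:
            colors = np.asarray(mesh.visual.vertex_colors)[:, :3]
    faces = None
    if isinstance(mesh, trimesh.Trimesh) and len(mesh.faces):
        faces = np.asarray(mesh.faces, dtype=np.int64)
    return PointCloud(vertices, colors=colors, faces=faces)


def write_ply(cloud: PointCloud, path, binary: bool = False) -> None:
    """Write a PointCloud as standard PLY (ASCII or binary little-endian).

    Vertices are stored as float32 (the conventional PLY precision);
    colours, when present, as uchar red/green/blue.
    """
    path = Path(path)
    n = len(cloud)
    header = ["ply",
              f"format {'binary_little_endian' if binary else 'ascii'} 1.0",
              f"element vertex {n}",
              "property float x", "property float y", "property float z"]
    if cloud.has_colors:
        header += ["property uchar red", "property uchar green", "property uchar blue"]
    if cloud.faces is not None:
        header += [f"element face {len(cloud.faces)}",
                   "property list uchar int vertex_indices"]
    header.append("end_header")

    verts = cloud.vertices.astype("<f4")
    try:
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            if binary:
                if cloud.has_colors:
                    rec = np.empty(n, dtype=[("v", "<f4", (3,)), ("c", "u1", (3,))])
                    rec["v"] = verts
                    rec["c"] = cloud.colors
                else:
                    rec = verts
                fh.write(rec.tobytes())
                if cloud.faces is not None:
                    frec = np.empty(len(cloud.faces),
                                    dtype=[("n", "u1"), ("i", "<i4", (3,))])
                    frec["n"] = 3
                    frec["i"] = cloud.faces.astype("<i4")
                    fh.write(frec.tobytes())
            else:
                for i in range(n):
                    row = " ".join(repr(float(x)) for x in verts[i])
                    if cloud.has_colors:
                        row += " " + " ".join(str(int(c)) for c in cloud.colors[i])
                    fh.write((row + "\n").encode("ascii"))
                if cloud.faces is not None:
                    for f in cloud.faces:
                        fh.write(f"3 {f[0]} {f[1]} {f[2]}\n".encode("ascii"))
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc


# --------------------------------------------------------------------------
# Tables
# --------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        if path.suffix.lower() in (".xlsx", ".xls"):
            df = pd.read_excel(path)
        else:
            df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: failed to parse table ({exc})") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def _table_points(df: pd.DataFrame, cols, path) -> np.ndarray:
    for c in cols:
        if c not in df.columns:
            raise FormatError(f"{path}: missing required column {c!r}")
    pts = df[list(cols)].to_numpy(dtype=float)
    if not np.all(np.isfinite(pts)):
        raise FormatError(f"{path}: table contains NaN/Inf coordinates")
    return pts


def read_sensor_table(path) -> SensorArray:
    """Read a sensor table: ``label,px,py,pz,ox1,oy1,oz1[,ox2,...]``.

    The number of orientation triplets K is inferred from the columns;
    orientation rows are renormalized to unit length (a warning is emitted
    when a norm deviates from 1 by more than 0.05 before renormalization).
    """
    df = _read_table(path)
    if "label" not in df.columns:
        raise FormatError(f"{path}: sensor table missing 'label' column")
    positions = _table_points(df, ("px", "py", "pz"), path)
    k = 1
    while {f"ox{k + 1}", f"oy{k + 1}", f"oz{k + 1}"} <= set(df.columns):
        k += 1
    if not {"ox1", "oy1", "oz1"} <= set(df.columns):
        raise FormatError(f"{path}: sensor table missing ox1/oy1/oz1 columns")
    ori = np.stack(
        [_table_points(df, (f"ox{i}", f"oy{i}", f"oz{i}"), path) for i in range(1, k + 1)],
        axis=1,
    )
    norms = np.linalg.norm(ori, axis=2)
    if np.any(norms < 1e-6):
        raise InputError(f"{path}: orientation with (near-)zero norm")
    if np.any(np.abs(norms - 1.0) > 0.05):
        warnings.warn(
            f"{path}: orientation norms deviate from 1 by more than 0.05; renormalizing",
            stacklevel=2,
        )
    return SensorArray(df["label"].astype(str).tolist(), positions, ori)


def write_sensor_table(sensors: SensorArray, path) -> None:
    """Write a sensor table readable by :func:`read_sensor_table`."""
    data = {"label": sensors.labels}
    for j, c in enumerate(("px", "py", "pz")):
        data[c] = sensors.positions[:, j]
    for i in range(sensors.n_axes):
        for j, c in enumerate((f"ox{i + 1}", f"oy{i + 1}", f"oz{i + 1}")):
            data[c] = sensors.orientations[:, i, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")


def read_labelled_points(path) -> LabelledPoints:
    """Read a ``label,x,y,z`` table (designed refs, landmark picks, ...)."""
    df = _read_table(path)
    if "label" not in df.columns:
        raise FormatError(f"{path}: missing 'label' column")
    return LabelledPoints(df["label"].astype(str).tolist(),
                          _table_points(df, ("x", "y", "z"), path))


def read_digitized_points(head_path, helmet_ref_path) -> DigitizedPoints:
    """Read stylus-digitized head points and helmet reference points.

    In the head-point table, rows labelled nasion/lpa/rpa (case-insensitive)
    become the anatomical fiducials; every other row is a scalp point. The
    helmet table rows become labelled reference points in file order.
    """
    head = read_labelled_points(head_path)
    fid_idx: dict[str, int] = {}
    scalp = []
    for i, lab in enumerate(head.labels):
        key = lab.strip().lower()
        if key in _RESERVED_FIDUCIALS:
            if key in fid_idx:
                raise InputError(f"{head_path}: duplicate fiducial label {lab!r}")
            fid_idx[key] = i
        else:
            scalp.append(i)
    missing = [f for f in _RESERVED_FIDUCIALS if f not in fid_idx]
    if missing:
        raise InputError(f"{head_path}: missing fiducial row(s) {missing}")
    if len(scalp) < 20:
        warnings.warn(
            f"{head_path}: only {len(scalp)} scalp points; at least 20 are "
            "recommended for a stable surface ICP",
            stacklevel=2,
        )
    fiducials = FiducialSet(
        list(_RESERVED_FIDUCIALS),
        head.points[[fid_idx[f] for f in _RESERVED_FIDUCIALS]],
        frame="digitizer",
    )
    refs = read_labelled_points(helmet_ref_path)
    return DigitizedPoints(fiducials, head.points[scalp], refs)


# --------------------------------------------------------------------------
# Result export
# --------------------------------------------------------------------------

def write_coreg_result(result: CoregResult, out_dir) -> dict[str, Path]:
    """Write a CoregResult to ``out_dir``.

    Produces ``sensors_mri.csv`` (same schema as :func:`read_sensor_table`)
    and ``coreg_metadata.json`` with both transforms as 4x4 homogeneous
    matrices, the error metrics, the device tag and run parameters.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sensor_path = out_dir / "sensors_mri.csv"
    meta_path = out_dir / "coreg_metadata.json"
    write_sensor_table(result.sensors_mri, sensor_path)
    meta = {
        "transform_device_to_head": result.transform_device_to_head.matrix.tolist(),
        "transform_head_to_mri": result.transform_head_to_mri.matrix.tolist(),
        "fre_transform1_mm": result.fre_transform1,
        "icp_rms_transform1_mm": result.icp_rms_transform1,
        "icp_rms_transform2_mm": result.icp_rms_transform2,
        "metadata": result.metadata,
        "units": "mm",
        "written": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2)
    return {"sensors": sensor_path, "metadata": meta_path}


def read_coreg_metadata(out_dir) -> dict:
    """Read back the JSON sidecar; transforms are reconstructed."""
    path = Path(out_dir) / "coreg_metadata.json"
    if not path.exists():
        raise InputError(f"no such file: {path}")
    with open(path) as fh:
        meta = json.load(fh)
    meta["transform_device_to_head"] = RigidTransform.from_matrix(
        np.array(meta["transform_device_to_head"]), source="device", target="head")
    meta["transform_head_to_mri"] = RigidTransform.from_matrix(
        np.array(meta["transform_head_to_mri"]), source="head", target="mri")
    return meta
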