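"""File formats: ASCII PLY and OBJ meshes, labelled-cloud PLY/CSV, landmark
and correspondence CSVs, JSON transforms/results.

PLY is the primary carrier (it supports per-vertex integer labels); CSV is
provided wherever a human-auditable table is useful. Floats are written with
17 significant digits so write→read round-trips are exact.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .cloud import LabeledPointCloud
from .errors import FormatError, SchemaError
from .mesh import TriangleMesh
from .stereo import StereoCorrespondence
from .transforms import RigidTransform
from .tre import FrameLandmarks

_F = "%.17g"

_PLY_TYPES = {
    "char": int, "uchar": int, "short": int, "ushort": int, "int": int,
    "uint": int, "int8": int, "uint8": int, "int16": int, "uint16": int,
    "int32": int, "uint32": int,
    "float": float, "double": float, "float32": float, "float64": float,
}


# -- PLY ---------------------------------------------------------------------

def _parse_ply(path):
    """Parse an ASCII PLY into {element: {property: column array}} (+ face lists)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise FormatError("not a PLY file (missing 'ply' magic)", path, 1)
    elements = []  # (name, count, [(prop_name, kind, is_list)])
    i = 1
    in_header = True
    while i < len(lines):
        tok = lines[i].strip().split()
        i += 1
        if not tok or tok[0] == "comment":
            continue
        if tok[0] == "format":
            if tok[1] != "ascii":
                raise FormatError("only ASCII PLY is supported", path, i)
        elif tok[0] == "element":
            elements.append((tok[1], int(tok[2]), []))
        elif tok[0] == "property":
            if not elements:
                raise FormatError("property before any element", path, i)
            if tok[1] == "list":
                elements[-1][2].append((tok[4], _PLY_TYPES[tok[3]], True))
            else:
                elements[-1][2].append((tok[2], _PLY_TYPES[tok[1]], False))
        elif tok[0] == "end_header":
            in_header = False
            break
        else:
            raise FormatError(f"unknown header keyword {tok[0]!r}", path, i)
    if in_header:
        raise FormatError("unterminated PLY header", path, i)

    data: dict = {}
    for name, count, props in elements:
        cols: dict = {p: [] for p, _, _ in props}
        for row in range(count):
            if i >= len(lines):
                raise FormatError(f"unexpected EOF in element {name!r}", path, i)
            vals = lines[i].split()
            i += 1
            pos = 0
            try:
                for pname, kind, is_list in props:
                    if is_list:
                        n = int(vals[pos])
                        cols[pname].append([kind(v) for v in vals[pos + 1 : pos + 1 + n]])
                        pos += 1 + n
                    else:
                        cols[pname].append(kind(vals[pos]))
                        pos += 1
            except (ValueError, IndexError) as e:
                raise FormatError(f"malformed {name!r} row: {e}", path, i) from e
        data[name] = cols
    return data


def write_ply_mesh(mesh: TriangleMesh, path) -> None:
    path = Path(path)
    with path.open("w") as f:
        f.write("ply\nformat ascii 1.0\ncomment units mm, right-handed\n")
        f.write(f"element vertex {len(mesh.vertices)}\n")
        f.write("property double x\nproperty double y\nproperty double z\n")
        f.write(f"element face {mesh.n_faces}\n")
        f.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            f.write(f"{_F % v[0]} {_F % v[1]} {_F % v[2]}\n")
        for tri in mesh.faces:
            f.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")


def read_ply_mesh(path) -> TriangleMesh:
    data = _parse_ply(path)
    if "vertex" not in data or "face" not in data:
        raise FormatError("PLY mesh needs 'vertex' and 'face' elements", path)
    vc = data["vertex"]
    verts = np.column_stack([vc["x"], vc["y"], vc["z"]]).astype(float)
    fkey = "vertex_indices" if "vertex_indices" in data["face"] else "vertex_index"
    faces_raw = data["face"][fkey]
    if any(len(t) != 3 for t in faces_raw):
        raise FormatError("only triangle faces are supported", path)
    return TriangleMesh(verts, np.array(faces_raw, dtype=np.int64))


def write_ply_cloud(cloud: LabeledPointCloud, path) -> None:
    path = Path(path)
    with path.open("w") as f:
        f.write("ply\nformat ascii 1.0\ncomment units mm; label 0 = liver\n")
        f.write(f"element vertex {len(cloud)}\n")
        f.write("property double x\nproperty double y\nproperty double z\n")
        f.write("property int label\nproperty int patch_id\nend_header\n")
        for p, lab, pid in zip(cloud.points, cloud.labels, cloud.source_patch_id):
            f.write(f"{_F % p[0]} {_F % p[1]} {_F % p[2]} {lab} {pid}\n")


def read_ply_cloud(path) -> LabeledPointCloud:
    data = _parse_ply(path)
    if "vertex" not in data:
        raise FormatError("PLY cloud needs a 'vertex' element", path)
    vc = data["vertex"]
    pts = np.column_stack([vc["x"], vc["y"], vc["z"]]).astype(float)
    labels = np.asarray(vc.get("label", np.zeros(len(pts))), dtype=np.int64)
    pid = np.asarray(vc.get("patch_id", np.zeros(len(pts))), dtype=np.int64)
    return LabeledPointCloud(pts, labels, pid)


# -- OBJ ---------------------------------------------------------------------

def write_obj_mesh(mesh: TriangleMesh, path) -> None:
    path = Path(path)
    with path.open("w") as f:
        for v in mesh.vertices:
            f.write(f"v {_F % v[0]} {_F % v[1]} {_F % v[2]}\n")
        for tri in mesh.faces:
            f.write(f"f {tri[0] + 1} {tri[1] + 1} {tri[2] + 1}\n")


def read_obj_mesh(path) -> TriangleMesh:
    path = Path(path)
    verts, faces = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        tok = line.split()
        if not tok or tok[0].startswith("#"):
            continue
        try:
            if tok[0] == "v":
                verts.append([float(x) for x in tok[1:4]])
            elif tok[0] == "f":
                idx = [int(t.split("/")[0]) - 1 for t in tok[1:]]
                if len(idx) != 3:
                    raise FormatError("only triangle faces are supported", path, lineno)
                faces.append(idx)
        except (ValueError, IndexError) as e:
            raise FormatError(f"malformed OBJ line: {e}", path, lineno) from e
    if not verts or not faces:
        raise FormatError("OBJ file has no usable geometry", path)
    return TriangleMesh(np.array(verts), np.array(faces, dtype=np.int64))


# -- dispatchers -------------------------------------------------------------

def read_mesh(path) -> TriangleMesh:
    """Load a PLY or OBJ triangle mesh; warns when the mesh is not watertight."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".ply":
        mesh = read_ply_mesh(path)
    elif suffix == ".obj":
        mesh = read_obj_mesh(path)
    else:
        raise FormatError(f"unsupported mesh format {suffix!r} (use .ply or .obj)", path)
    if not mesh.is_watertight:
        warnings.warn(f"mesh {path.name} is not watertight", stacklevel=2)
    return mesh


def write_mesh(mesh: TriangleMesh, path) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".ply":
        write_ply_mesh(mesh, path)
    elif suffix == ".obj":
        write_obj_mesh(mesh, path)
    else:
        raise FormatError(f"unsupported mesh format {suffix!r} (use .ply or .obj)", path)


def read_cloud(path) -> LabeledPointCloud:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        return read_ply_cloud(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, float_precision="round_trip")
        for col in ("x", "y", "z"):
            if col not in df.columns:
                raise SchemaError(f"cloud CSV missing column {col!r}")
        labels = df["label"].to_numpy() if "label" in df.columns else np.zeros(len(df))
        pid = df["patch_id"].to_numpy() if "patch_id" in df.columns else None
        return LabeledPointCloud(df[["x", "y", "z"]].to_numpy(float),
                                 labels.astype(np.int64), pid)
    raise FormatError(f"unsupported cloud format {path.suffix!r}", path)


def write_cloud(cloud: LabeledPointCloud, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        write_ply_cloud(cloud, path)
    elif path.suffix.lower() == ".csv":
        pd.DataFrame(
            {
                "x": cloud.points[:, 0], "y": cloud.points[:, 1], "z": cloud.points[:, 2],
                "label": cloud.labels, "patch_id": cloud.source_patch_id,
            }
        ).to_csv(path, index=False, float_format=_F)
    else:
        raise FormatError(f"unsupported cloud format {path.suffix!r}", path)


# -- CSV tables --------------------------------------------------------------

def read_landmarks_csv(path) -> dict:
    """Model landmark table: columns name,x,y,z (mx,my,mz also accepted)."""
    df = pd.read_csv(path, float_precision="round_trip")
    cols = ("x", "y", "z") if "x" in df.columns else ("mx", "my", "mz")
    if "name" not in df.columns or any(c not in df.columns for c in cols):
        raise SchemaError("landmark CSV needs columns name,x,y,z")
    return {
        str(r["name"]): np.array([r[cols[0]], r[cols[1]], r[cols[2]]], dtype=float)
        for _, r in df.iterrows()
    }


def write_landmarks_csv(landmarks: dict, path) -> None:
    pd.DataFrame(
        [{"name": k, "x": v[0], "y": v[1], "z": v[2]} for k, v in landmarks.items()]
    ).to_csv(path, index=False, float_format=_F)


def read_patient_frames_csv(path) -> list:
    """Per-frame patient landmarks: columns frame_id,name,px,py,pz."""
    df = pd.read_csv(path, float_precision="round_trip")
    needed = ["frame_id", "name", "px", "py", "pz"]
    if any(c not in df.columns for c in needed):
        raise SchemaError("frame CSV needs columns frame_id,name,px,py,pz")
    frames = []
    for fid, grp in df.groupby("frame_id", sort=True):
        pts = {
            str(r["name"]): np.array([r["px"], r["py"], r["pz"]], dtype=float)
            for _, r in grp.iterrows()
        }
        frames.append(FrameLandmarks(int(fid), pts))
    return frames


def write_patient_frames_csv(frames, path) -> None:
    rows = [
        {"frame_id": f.frame_id, "name": k, "px": v[0], "py": v[1], "pz": v[2]}
        for f in frames
        for k, v in f.points.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_F)


def read_correspondences_csv(path) -> list:
    """Stereo correspondences: columns ul,vl,ur,vr,label."""
    df = pd.read_csv(path, float_precision="round_trip")
    needed = ["ul", "vl", "ur", "vr"]
    if any(c not in df.columns for c in needed):
        raise SchemaError("correspondence CSV needs columns ul,vl,ur,vr[,label]")
    labels = df["label"] if "label" in df.columns else np.zeros(len(df), dtype=int)
    return [
        StereoCorrespondence((r.ul, r.vl), (r.ur, r.vr), int(lab))
        for r, lab in zip(df.itertuples(), labels)
    ]


def write_correspondences_csv(correspondences, path) -> None:
    pd.DataFrame(
        [
            {"ul": c.pixel_left[0], "vl": c.pixel_left[1],
             "ur": c.pixel_right[0], "vr": c.pixel_right[1], "label": c.label}
            for c in correspondences
        ]
    ).to_csv(path, index=False, float_format=_F)


# -- JSON --------------------------------------------------------------------

def read_json(path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"invalid JSON: {e.msg}", path, e.lineno) from e


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_transform_json(path) -> RigidTransform:
    return RigidTransform.from_dict(read_json(path))


def write_transform_json(T: RigidTransform, path) -> None:
    write_json(T.to_dict(), path)
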