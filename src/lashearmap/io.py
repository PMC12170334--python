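"""File I/O for meshes, fields, waveforms, point clouds and templates.

Formats are inferred from the extension: ``.vtk`` (legacy ASCII PolyData),
``.vtp`` (XML PolyData, ascii), ``.stl``/``.ply`` (via trimesh), ``.csv``
(waveforms, clouds, vertex tables) and ``.json`` (templates, manifests).
Vertex labels travel as an integer point-data array named ``region_label``;
additional per-vertex scalars as named float arrays.  STL carries no point
data, so fields are dropped with a warning on write.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd
import trimesh

from .mesh import SurfaceMesh
from .waveform import VelocityWaveform


class FormatError(ValueError):
    pass


class SchemaError(FormatError):
    pass


# ----------------------------------------------------------------------
# VTK legacy ASCII PolyData
def _write_vtk(path: Path, mesh: SurfaceMesh, point_data: dict | None):
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nlashearmap surface\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {mesh.n_vertices} double\n")
        np.savetxt(f, mesh.vertices, fmt="%.17g")
        f.write(f"POLYGONS {mesh.n_triangles} {4 * mesh.n_triangles}\n")
        np.savetxt(
            f,
            np.column_stack([np.full(mesh.n_triangles, 3), mesh.triangles]),
            fmt="%d",
        )
        f.write(f"POINT_DATA {mesh.n_vertices}\n")
        f.write("SCALARS region_label int 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, mesh.vertex_labels, fmt="%d")
        if point_data:
            f.write(f"FIELD wall_fields {len(point_data)}\n")
            for name, vals in point_data.items():
                f.write(f"{name} 1 {mesh.n_vertices} double\n")
                np.savetxt(f, np.asarray(vals, dtype=float), fmt="%.17g")


def _read_vtk(path: Path):
    tokens = []
    with open(path) as f:
        lines = f.readlines()
    if not lines or not lines[0].startswith("# vtk"):
        raise FormatError(f"{path}: not a VTK legacy file (bad header line 1)")
    i = 0
    n_pts = n_poly = None
    verts = faces = labels = None
    point_data: dict[str, np.ndarray] = {}

    def grab(count, start):
        vals = []
        j = start
        while len(vals) < count:
            if j >= len(lines):
                raise FormatError(f"{path}: truncated near line {j}")
            vals.extend(lines[j].split())
            j += 1
        return vals, j

    while i < len(lines):
        parts = lines[i].split()
        if not parts:
            i += 1
            continue
        key = parts[0].upper()
        if key == "POINTS":
            n_pts = int(parts[1])
            vals, i = grab(3 * n_pts, i + 1)
            verts = np.array(vals, dtype=float).reshape(n_pts, 3)
        elif key == "POLYGONS":
            n_poly = int(parts[1])
            total = int(parts[2])
            vals, i = grab(total, i + 1)
            arr = np.array(vals, dtype=np.int64)
            faces = []
            j = 0
            while j < len(arr):
                k = arr[j]
                if k != 3:
                    raise FormatError(f"{path}: non-triangle polygon of size {k}")
                faces.append(arr[j + 1 : j + 4])
                j += k + 1
            faces = np.array(faces)
        elif key == "SCALARS":
            name = parts[1]
            i += 2  # skip LOOKUP_TABLE
            vals, i = grab(n_pts, i)
            arr = np.array(vals, dtype=float)
            if name == "region_label":
                labels = arr.astype(np.int64)
            else:
                point_data[name] = arr
        elif key == "FIELD":
            n_arrays = int(parts[2])
            i += 1
            for _ in range(n_arrays):
                name, _, cnt, _ = lines[i].split()
                vals, i = grab(int(cnt), i + 1)
                point_data[name] = np.array(vals, dtype=float)
        else:
            i += 1
    if verts is None or faces is None:
        raise FormatError(f"{path}: missing POINTS or POLYGONS section")
    return SurfaceMesh(verts, faces, labels), point_data


# ----------------------------------------------------------------------
# XML VTP (ascii)
def _write_vtp(path: Path, mesh: SurfaceMesh, point_data: dict | None):
    root = ET.Element("VTKFile", type="PolyData", version="0.1", byte_order="LittleEndian")
    pd_el = ET.SubElement(root, "PolyData")
    piece = ET.SubElement(
        pd_el,
        "Piece",
        NumberOfPoints=str(mesh.n_vertices),
        NumberOfPolys=str(mesh.n_triangles),
    )
    pts = ET.SubElement(piece, "Points")
    da = ET.SubElement(
        pts, "DataArray", type="Float64", NumberOfComponents="3", format="ascii"
    )
    da.text = " ".join(f"{v:.17g}" for v in mesh.vertices.ravel())
    pdata = ET.SubElement(piece, "PointData")
    lab = ET.SubElement(
        pdata, "DataArray", type="Int64", Name="region_label", format="ascii"
    )
    lab.text = " ".join(map(str, mesh.vertex_labels))
    for name, vals in (point_data or {}).items():
        el = ET.SubElement(pdata, "DataArray", type="Float64", Name=name, format="ascii")
        el.text = " ".join(f"{v:.17g}" for v in np.asarray(vals, dtype=float))
    polys = ET.SubElement(piece, "Polys")
    conn = ET.SubElement(polys, "DataArray", type="Int64", Name="connectivity", format="ascii")
    conn.text = " ".join(map(str, mesh.triangles.ravel()))
    offs = ET.SubElement(polys, "DataArray", type="Int64", Name="offsets", format="ascii")
    offs.text = " ".join(map(str, 3 * (np.arange(mesh.n_triangles) + 1)))
    ET.ElementTree(root).write(path)


def _read_vtp(path: Path):
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as e:
        raise FormatError(f"{path}: malformed XML ({e})") from e
    piece = root.find(".//Piece")
    pts = piece.find("Points/DataArray")
    verts = np.fromstring(pts.text, sep=" ").reshape(-1, 3)
    conn = None
    for da in piece.find("Polys"):
        if da.get("Name") == "connectivity":
            conn = np.fromstring(da.text, sep=" ", dtype=np.int64)
    faces = conn.reshape(-1, 3)
    labels = None
    point_data = {}
    pdata = piece.find("PointData")
    if pdata is not None:
        for da in pdata:
            name = da.get("Name")
            arr = np.fromstring(da.text, sep=" ")
            if name == "region_label":
                labels = arr.astype(np.int64)
            else:
                point_data[name] = arr
    return SurfaceMesh(verts, faces, labels), point_data


# ----------------------------------------------------------------------
# ----------------------------------------------------------------------
# ascii PLY with region_label and scalar vertex properties
def _write_ply(path: Path, mesh: SurfaceMesh, point_data: dict | None):
    names = list((point_data or {}).keys())
    with open(path, "w") as f:
        f.write("ply\nformat ascii 1.0\ncomment lashearmap surface\n")
        f.write(f"element vertex {mesh.n_vertices}\n")
        f.write("property double x\nproperty double y\nproperty double z\n")
        f.write("property int region_label\n")
        for name in names:
            f.write(f"property double {name}\n")
        f.write(f"element face {mesh.n_triangles}\n")
        f.write("property list uchar int vertex_indices\nend_header\n")
        cols = [mesh.vertices, mesh.vertex_labels[:, None].astype(float)]
        cols += [np.asarray(point_data[n], dtype=float)[:, None] for n in names]
        body = np.concatenate(cols, axis=1)
        for row in body:
            f.write(
                " ".join(f"{v:.17g}" for v in row[:3])
                + f" {int(row[3])} "
                + " ".join(f"{v:.17g}" for v in row[4:])
                + "\n"
            )
        for tri in mesh.triangles:
            f.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")


def _read_ply(path: Path):
    with open(path) as f:
        lines = f.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise FormatError(f"{path}: not a PLY file (bad magic, line 1)")
    n_vert = n_face = 0
    props = []
    element = None
    i = 1
    for i, line in enumerate(lines[1:], start=1):
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "format" and parts[1] != "ascii":
            raise FormatError(f"{path}: only ascii PLY supported here")
        if parts[0] == "element":
            element = parts[1]
            if element == "vertex":
                n_vert = int(parts[2])
            elif element == "face":
                n_face = int(parts[2])
        elif parts[0] == "property" and element == "vertex" and parts[1] != "list":
            props.append(parts[2])
        elif parts[0] == "end_header":
            break
    data = np.array(
        [lines[j].split() for j in range(i + 1, i + 1 + n_vert)], dtype=float
    )
    if data.shape[1] != len(props):
        raise FormatError(f"{path}: vertex row width {data.shape[1]} != header {len(props)}")
    cols = dict(zip(props, data.T))
    verts = np.column_stack([cols["x"], cols["y"], cols["z"]])
    labels = cols.pop("region_label", None)
    faces = []
    for j in range(i + 1 + n_vert, i + 1 + n_vert + n_face):
        row = lines[j].split()
        if int(row[0]) != 3:
            raise FormatError(f"{path}: non-triangle face at line {j + 1}")
        faces.append([int(x) for x in row[1:4]])
    point_data = {
        k: v for k, v in cols.items() if k not in ("x", "y", "z")
    }
    return (
        SurfaceMesh(
            verts, np.array(faces), None if labels is None else labels.astype(np.int64)
        ),
        point_data,
    )


def write_mesh(path, mesh: SurfaceMesh, point_data: dict | None = None) -> None:
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".vtk":
        _write_vtk(path, mesh, point_data)
    elif ext == ".vtp":
        _write_vtp(path, mesh, point_data)
    elif ext == ".ply":
        _write_ply(path, mesh, point_data)
    elif ext == ".stl":
        if point_data or mesh.vertex_labels.any():
            warnings.warn("STL carries no point data; labels/fields dropped", stacklevel=2)
        mesh.to_trimesh().export(path)
    else:
        raise FormatError(f"unsupported mesh extension {ext!r}")


def read_mesh(path):
    """Read a mesh; returns (SurfaceMesh, point_data dict)."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".vtk":
        return _read_vtk(path)
    if ext == ".vtp":
        return _read_vtp(path)
    if ext == ".ply":
        return _read_ply(path)
    if ext == ".stl":
        tm = trimesh.load(path, process=False)
        return SurfaceMesh(np.array(tm.vertices), np.array(tm.faces), None), {}
    raise FormatError(f"unsupported mesh extension {ext!r}")


# ----------------------------------------------------------------------
def write_waveform_csv(path, waveform: VelocityWaveform) -> None:
    with open(path, "w") as f:
        f.write(f"# period_s={waveform.period!r}\n")
        pd.DataFrame(
            {"time_s": waveform.times, "velocity_m_per_s": waveform.velocity}
        ).to_csv(f, index=False)


def read_waveform_csv(path) -> VelocityWaveform:
    path = Path(path)
    with open(path) as f:
        first = f.readline()
    if not first.startswith("# period_s="):
        raise SchemaError(f"{path}: missing '# period_s=' header line")
    period = float(first.split("=", 1)[1])
    df = pd.read_csv(path, comment="#")
    for col in ("time_s", "velocity_m_per_s"):
        if col not in df:
            raise SchemaError(f"{path}: missing column {col!r}")
    return VelocityWaveform(df["time_s"].to_numpy(), df["velocity_m_per_s"].to_numpy(), period)


CLOUD_COLUMNS = ("x_mm", "y_mm", "z_mm", "bv_mV")


def write_cloud_csv(path, points: np.ndarray, bv: np.ndarray) -> None:
    pd.DataFrame(
        {"x_mm": points[:, 0], "y_mm": points[:, 1], "z_mm": points[:, 2], "bv_mV": bv}
    ).to_csv(path, index=False)


def read_cloud_csv(path):
    df = pd.read_csv(path)
    for col in CLOUD_COLUMNS:
        if col not in df:
            raise SchemaError(f"{path}: missing column {col!r}")
    pts = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    return pts, df["bv_mV"].to_numpy(dtype=float)
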