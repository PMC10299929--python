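"""File I/O: centerline CSV/VTP dialects, meshes, landmarks, run logs.

Centerline CSV dialect (one or more cases per file, 0-based indices,
millimetres, ordering per the pipeline convention):

    case_id,segment,index,x_mm,y_mm,z_mm,radius_mm

with ``segment`` one of AAO, AD, DAO.  VTP files are minimal ASCII VTK
XML PolyData written/read with the standard library: polylines carry the
per-point radius as a PointData array named
``MaximumInscribedSphereRadius``, one cell per segment with an Int8
CellData array ``SegmentId`` (0=AAO, 1=AD, 2=DAO) and the bifurcation
origin as FieldData.  Triangle meshes load through trimesh (STL, both
ASCII and binary) or the same minimal VTP dialect.
"""

from __future__ import annotations

import hashlib
import json
import warnings
import xml.etree.ElementTree as ET
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .centerline import ArchCenterline, Centerline
from .errors import EmptyMeshError, ParseError, SchemaError

__all__ = [
    "write_centerline_csv", "read_centerline_csv",
    "write_centerline_vtp", "read_centerline_vtp",
    "read_mesh", "write_mesh_vtp", "read_mesh_vtp",
    "read_landmarks", "write_landmarks", "LANDMARK_KEYS",
    "read_cohort_table", "write_run_log", "config_hash",
]

SEGMENT_NAMES = ("AAO", "AD", "DAO")
RADIUS_ARRAY_NAME = "MaximumInscribedSphereRadius"
LANDMARK_KEYS = ("dao_diaphragm", "ad_pa_bifurcation", "ad_medial", "aao_rpa")

_CSV_COLUMNS = ["case_id", "segment", "index", "x_mm", "y_mm", "z_mm",
                "radius_mm"]


# ---------------------------------------------------------------------------
# centerline CSV dialect
# ---------------------------------------------------------------------------


def _arch_rows(arch: ArchCenterline, case_id: str):
    rows = []
    for seg_name, seg in zip(SEGMENT_NAMES,
                             (arch.aao, arch.ad, arch.dao)):
        for i, (p, r) in enumerate(zip(seg.points, seg.radius)):
            rows.append((case_id, seg_name, i, p[0], p[1], p[2], r))
    return rows


def write_centerline_csv(path, arches, case_ids=None) -> None:
    """Write one arch or a list of arches in the CSV dialect.

    Floats are written at full round-trip precision.
    """
    if isinstance(arches, ArchCenterline):
        arches = [arches]
    if case_ids is None:
        case_ids = [f"case_{i:04d}" for i in range(len(arches))]
    rows = []
    for arch, cid in zip(arches, case_ids):
        rows.extend(_arch_rows(arch, cid))
    frame = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_centerline_csv(path, counts=None) -> dict[str, ArchCenterline]:
    """Read the CSV dialect back into {case_id: ArchCenterline}.

    Malformed rows raise :class:`ParseError` with a line number; a case
    whose per-segment counts differ from ``counts`` (when given) only
    triggers a warning offering resampling.
    """
    try:
        frame = pd.read_csv(path, dtype={"case_id": str, "segment": str})
    except Exception as exc:
        raise ParseError(f"cannot read centerline CSV {path}: {exc}")
    missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"centerline CSV is missing columns {missing}", line=1)
    bad_seg = ~frame["segment"].isin(SEGMENT_NAMES)
    if bad_seg.any():
        first = int(np.flatnonzero(bad_seg.to_numpy())[0])
        raise ParseError(
            f"unknown segment label {frame['segment'].iloc[first]!r}",
            line=first + 2)  # +1 header, +1 1-based
    numeric = frame[["x_mm", "y_mm", "z_mm", "radius_mm"]].to_numpy(dtype=float)
    nan_rows = np.isnan(numeric).any(axis=1)
    if nan_rows.any():
        first = int(np.flatnonzero(nan_rows)[0])
        raise ParseError("NaN value in centerline coordinates/radius",
                         line=first + 2)

    out: dict[str, ArchCenterline] = {}
    for cid, grp in frame.groupby("case_id", sort=False):
        segs = {}
        for seg_name in SEGMENT_NAMES:
            sub = grp[grp["segment"] == seg_name].sort_values("index")
            if len(sub) == 0:
                raise ParseError(f"case {cid} lacks segment {seg_name}")
            idx = sub["index"].to_numpy()
            if not np.array_equal(idx, np.arange(len(idx))):
                first = int(sub.index[0])
                raise ParseError(
                    f"case {cid} segment {seg_name} indices are not a "
                    "contiguous 0-based range", line=first + 2)
            pts = sub[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
            rad = sub["radius_mm"].to_numpy(dtype=float)
            segs[seg_name] = Centerline(pts, rad)
        arch = ArchCenterline(segs["AAO"], segs["AD"], segs["DAO"])
        arch.bifurcation_origin = (arch.aao.points[-1] + arch.ad.points[-1]
                                   + arch.dao.points[0]) / 3.0
        if counts is not None and arch.counts != tuple(counts):
            warnings.warn(
                f"case {cid} has counts {arch.counts}, expected "
                f"{tuple(counts)}; resample with "
                "centerline.resample_centerline if correspondence is needed",
                stacklevel=2)
        out[cid] = arch
    if not out:
        raise ParseError("centerline CSV contains no cases")
    return out


# ---------------------------------------------------------------------------
# minimal VTK XML PolyData (ASCII)
# ---------------------------------------------------------------------------


def _fmt(arr) -> str:
    return " ".join(repr(float(v)) for v in np.asarray(arr).ravel())


def _data_array(parent, name, arr, dtype, n_comp=1):
    el = ET.SubElement(parent, "DataArray",
                       type=dtype, Name=name, format="ascii",
                       NumberOfComponents=str(n_comp))
    if dtype.startswith("Float"):
        el.text = _fmt(arr)
    else:
        el.text = " ".join(str(int(v)) for v in np.asarray(arr).ravel())
    return el


def _read_array(piece, section, name=None, index=0):
    sec = piece.find(section)
    if sec is None:
        raise ParseError(f"VTP file lacks a {section} section")
    arrays = sec.findall("DataArray")
    if name is not None:
        arrays = [a for a in arrays if a.get("Name") == name]
    if len(arrays) <= index:
        raise ParseError(f"VTP {section} lacks array {name or index}")
    el = arrays[index]
    text = (el.text or "").split()
    if el.get("type", "").startswith("Float"):
        vals = np.array([float(v) for v in text])
    else:
        vals = np.array([int(v) for v in text])
    n_comp = int(el.get("NumberOfComponents", "1"))
    return vals.reshape(-1, n_comp) if n_comp > 1 else vals


def write_centerline_vtp(path, arch: ArchCenterline) -> None:
    """Write one arch as VTP polylines with the radius point array."""
    segs = (arch.aao, arch.ad, arch.dao)
    points = np.vstack([s.points for s in segs])
    radius = np.concatenate([s.radius for s in segs])
    offsets, connectivity = [], []
    start = 0
    for s in segs:
        connectivity.extend(range(start, start + s.n_points))
        start += s.n_points
        offsets.append(start)

    root = ET.Element("VTKFile", type="PolyData", version="0.1",
                      byte_order="LittleEndian")
    poly = ET.SubElement(root, "PolyData")
    fd = ET.SubElement(poly, "FieldData")
    _data_array(fd, "BifurcationOrigin", arch.bifurcation_origin, "Float64", 3)
    piece = ET.SubElement(poly, "Piece",
                          NumberOfPoints=str(len(points)),
                          NumberOfLines=str(len(segs)))
    pts_el = ET.SubElement(piece, "Points")
    _data_array(pts_el, "Points", points, "Float64", 3)
    pdata = ET.SubElement(piece, "PointData")
    _data_array(pdata, RADIUS_ARRAY_NAME, radius, "Float64", 1)
    cdata = ET.SubElement(piece, "CellData")
    _data_array(cdata, "SegmentId", np.arange(len(segs)), "Int8", 1)
    lines = ET.SubElement(piece, "Lines")
    _data_array(lines, "connectivity", connectivity, "Int64", 1)
    _data_array(lines, "offsets", offsets, "Int64", 1)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def read_centerline_vtp(path) -> ArchCenterline:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ParseError(f"invalid VTP XML: {exc}")
    poly = root.find("PolyData")
    if poly is None:
        raise ParseError("not a PolyData VTP file")
    piece = poly.find("Piece")
    points = _read_array(piece, "Points")
    radius = _read_array(piece, "PointData", RADIUS_ARRAY_NAME)
    conn = _read_array(piece, "Lines", "connectivity").astype(int)
    offs = _read_array(piece, "Lines", "offsets").astype(int)
    if len(offs) != 3:
        raise ParseError(f"expected 3 polyline cells, found {len(offs)}")
    segs = []
    start = 0
    for end in offs:
        ids = conn[start:end]
        segs.append(Centerline(points[ids], radius[ids]))
        start = end
    fd = poly.find("FieldData")
    if fd is not None:
        origin = _read_array(poly, "FieldData", "BifurcationOrigin").ravel()
    else:
        origin = (segs[0].points[-1] + segs[1].points[-1] + segs[2].points[0]) / 3.0
    return ArchCenterline(segs[0], segs[1], segs[2], origin)


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------


def read_mesh(path):
    """Load a triangulated surface (STL via trimesh, or minimal VTP)."""
    path = str(path)
    if path.lower().endswith(".vtp"):
        return read_mesh_vtp(path)
    import trimesh

    mesh = trimesh.load(path, force="mesh")
    if mesh.faces.shape[0] == 0:
        raise EmptyMeshError(f"{path} contains no triangles")
    return mesh


def write_mesh_vtp(path, mesh) -> None:
    """Write a triangle mesh as minimal ASCII VTP."""
    verts = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=int)
    root = ET.Element("VTKFile", type="PolyData", version="0.1",
                      byte_order="LittleEndian")
    poly = ET.SubElement(root, "PolyData")
    piece = ET.SubElement(poly, "Piece", NumberOfPoints=str(len(verts)),
                          NumberOfPolys=str(len(faces)))
    pts_el = ET.SubElement(piece, "Points")
    _data_array(pts_el, "Points", verts, "Float64", 3)
    polys = ET.SubElement(piece, "Polys")
    _data_array(polys, "connectivity", faces.ravel(), "Int64", 1)
    _data_array(polys, "offsets", 3 * (np.arange(len(faces)) + 1), "Int64", 1)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def read_mesh_vtp(path):
    import trimesh

    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ParseError(f"invalid VTP XML: {exc}")
    poly = root.find("PolyData")
    if poly is None:
        raise ParseError("not a PolyData VTP file")
    piece = poly.find("Piece")
    verts = _read_array(piece, "Points")
    conn = _read_array(piece, "Polys", "connectivity").astype(int)
    offs = _read_array(piece, "Polys", "offsets").astype(int)
    if len(offs) == 0:
        raise EmptyMeshError(f"{path} contains no triangles")
    if np.any(np.diff(np.concatenate([[0], offs])) != 3):
        raise ParseError("VTP mesh contains non-triangle cells")
    faces = conn.reshape(-1, 3)
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


# ---------------------------------------------------------------------------
# landmarks and cohort table
# ---------------------------------------------------------------------------


def read_landmarks(path) -> dict[str, np.ndarray]:
    """Read the 4-landmark JSON; missing keys raise SchemaError by name."""
    with open(path) as fh:
        data = json.load(fh)
    out = {}
    for key in LANDMARK_KEYS:
        if key not in data:
            raise SchemaError(f"landmarks file is missing key {key!r}")
        pt = np.asarray(data[key], dtype=float)
        if pt.shape != (3,) or not np.all(np.isfinite(pt)):
            raise SchemaError(f"landmark {key!r} must be a finite 3D point")
        out[key] = pt
    return out


def write_landmarks(path, landmarks: dict) -> None:
    data = {k: np.asarray(v, dtype=float).tolist() for k, v in landmarks.items()}
    missing = [k for k in LANDMARK_KEYS if k not in data]
    if missing:
        raise SchemaError(f"landmarks dict is missing keys {missing}")
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)


def read_cohort_table(path) -> pd.DataFrame:
    """Read the cohort CSV (case_id, label, optional GA and file paths)."""
    frame = pd.read_csv(path, dtype={"case_id": str})
    for col in ("case_id", "label"):
        if col not in frame.columns:
            raise SchemaError(f"cohort table is missing column {col!r}")
    if frame["case_id"].duplicated().any():
        dup = frame.loc[frame["case_id"].duplicated(), "case_id"].iloc[0]
        raise SchemaError(f"duplicate case_id {dup!r}")
    labels = frame["label"].to_numpy()
    if not np.isin(labels, (0, 1)).all():
        raise SchemaError("labels must be binary (0=FP, 1=CoA)")
    return frame


# ---------------------------------------------------------------------------
# run logs
# ---------------------------------------------------------------------------


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_run_log(path, command: str, config: dict, seed: int | None) -> None:
    from . import __version__

    log = {"tool": "archssm", "version": __version__, "command": command,
           "config": config, "config_hash": config_hash(config),
           "seed": seed,
           "timestamp": datetime.now(timezone.utc).isoformat()}
    with open(path, "w") as fh:
        json.dump(log, fh, indent=2, default=str)
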