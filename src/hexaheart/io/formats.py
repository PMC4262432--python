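"""Text-first file formats for meshes, trees, fields and waveforms.

All writers emit plain ASCII (HDF5 excepted) with full float64 precision
("%.17g"), so write/read round trips are bitwise lossless. Readers raise
:class:`FileFormatError` with the offending file (and, where known, line)
on malformed input instead of propagating parser internals.

Formats
-------
- VTU (XML unstructured grid, ascii): hexahedral meshes with per-element
  region labels and per-node surface tags (string labels are stored as
  integer codes plus a ``LabelTable`` attribute on the data array), and
  arbitrary scalar point/cell data (e.g. activation times).
- Legacy VTK polydata (ascii): Purkinje trees as polylines with radius,
  seed and per-node root/terminal flags.
- CSV: PMJ coupling tables (terminal id, myocardial node, area fraction)
  and multi-lead ECG traces.
- NRRD (ascii encoding): voxel occupancy masks and regular lattices of
  symmetric 3x3 tensors (6 components + validity flag on a leading axis).
- HDF5: voltage time series with units metadata.
- manifest.json: provenance record (package version, seed, configuration)
  for a directory of artifacts.

Units are µm / ms / mV throughout and are recorded in each artifact.
"""

from __future__ import annotations

import io as _io
import json
import os
import xml.etree.ElementTree as ET
from xml.sax.saxutils import quoteattr

import numpy as np

from .. import __version__
from ..ecg import EcgTrace
from ..mesh import HexMesh, VoxelMask
from ..purkinje import PMJ, PurkinjeTree
from ..tensors import TensorLattice

FLOAT_FMT = "%.17g"

UNITS = {"length": "um", "time": "ms", "voltage": "mV"}

#: symmetric tensor component order on the leading NRRD axis
SYM_COMPONENTS = ("xx", "xy", "xz", "yy", "yz", "zz")


class FileFormatError(ValueError):
    """Raised when a file cannot be parsed; message names file and cause."""


def _fail(path, message, line=None):
    where = f"{path}:{line}" if line is not None else str(path)
    raise FileFormatError(f"{where}: {message}")


def _format_floats(arr: np.ndarray) -> str:
    buf = _io.StringIO()
    np.savetxt(buf, np.atleast_2d(arr), fmt=FLOAT_FMT)
    return buf.getvalue()


def _format_ints(arr: np.ndarray) -> str:
    buf = _io.StringIO()
    np.savetxt(buf, np.atleast_2d(arr), fmt="%d")
    return buf.getvalue()


def _parse_numbers(text, path, dtype, expected, what):
    try:
        vals = np.fromstring(text, dtype=dtype, sep=" ")
    except ValueError:
        vals = None
    if vals is None or len(vals) != expected:
        got = "unparseable" if vals is None else f"{len(vals)} values"
        _fail(path, f"{what}: expected {expected} numeric values, got {got}")
    return vals


# ---------------------------------------------------------------------------
# VTU hexahedral meshes
# ---------------------------------------------------------------------------

_VTK_HEXAHEDRON = 12


def _encode_labels(labels: np.ndarray):
    """String labels -> (int32 codes, table attribute value)."""
    table, codes = np.unique(labels, return_inverse=True)
    return codes.astype(np.int32), "|".join(table.tolist())


def _label_array(name, labels):
    codes, table = _encode_labels(labels)
    return (f'<DataArray type="Int32" Name={quoteattr(name)} '
            f'format="ascii" LabelTable={quoteattr(table)}>\n'
            + _format_ints(codes.reshape(-1, 1)) + "</DataArray>\n")


def _scalar_array(name, values):
    values = np.asarray(values, dtype=float).reshape(-1, 1)
    return (f'<DataArray type="Float64" Name={quoteattr(name)} '
            f'format="ascii">\n' + _format_floats(values) + "</DataArray>\n")


def write_mesh_vtu(path, mesh: HexMesh, point_data=None, cell_data=None):
    """Write a hexahedral mesh (plus optional scalar fields) as ascii VTU.

    ``point_data`` / ``cell_data`` map names to per-node / per-element
    scalar arrays. Region labels and surface tags are always included.
    """
    n, m = mesh.n_nodes, mesh.n_elements
    parts = ['<?xml version="1.0"?>\n',
             f'<!-- units: length={UNITS["length"]} -->\n',
             '<VTKFile type="UnstructuredGrid" version="0.1" '
             'byte_order="LittleEndian">\n<UnstructuredGrid>\n',
             f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">\n']
    parts.append('<Points>\n<DataArray type="Float64" Name="Points" '
                 'NumberOfComponents="3" format="ascii">\n')
    parts.append(_format_floats(mesh.nodes))
    parts.append("</DataArray>\n</Points>\n<Cells>\n")
    parts.append('<DataArray type="Int64" Name="connectivity" '
                 'format="ascii">\n')
    parts.append(_format_ints(mesh.elements))
    parts.append('</DataArray>\n<DataArray type="Int64" Name="offsets" '
                 'format="ascii">\n')
    parts.append(_format_ints(8 * np.arange(1, m + 1).reshape(-1, 1)))
    parts.append('</DataArray>\n<DataArray type="UInt8" Name="types" '
                 'format="ascii">\n')
    parts.append(_format_ints(
        np.full((m, 1), _VTK_HEXAHEDRON, dtype=np.uint8)))
    parts.append("</DataArray>\n</Cells>\n<PointData>\n")
    parts.append(_label_array("surface_tag", mesh.surface_tags))
    for name, values in (point_data or {}).items():
        if len(values) != n:
            raise ValueError(f"point data {name!r}: expected {n} values")
        parts.append(_scalar_array(name, values))
    parts.append("</PointData>\n<CellData>\n")
    parts.append(_label_array("region_label", mesh.region_labels))
    for name, values in (cell_data or {}).items():
        if len(values) != m:
            raise ValueError(f"cell data {name!r}: expected {m} values")
        parts.append(_scalar_array(name, values))
    parts.append("</CellData>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")
    with open(path, "w") as fh:
        fh.write("".join(parts))


def _find_array(parent, name, path):
    for da in parent.iter("DataArray"):
        if da.get("Name") == name:
            return da
    _fail(path, f"missing DataArray {name!r}")


def _decode_label_array(da, count, path):
    table = da.get("LabelTable")
    if table is None:
        _fail(path, f"DataArray {da.get('Name')!r} lacks a LabelTable")
    names = np.array(table.split("|"), dtype="<U16")
    codes = _parse_numbers(da.text or "", path, np.int64, count,
                           da.get("Name"))
    if codes.size and (codes.min() < 0 or codes.max() >= len(names)):
        _fail(path, f"DataArray {da.get('Name')!r}: label code out of range")
    return names[codes]


def read_mesh_vtu(path):
    """Read a mesh written by :func:`write_mesh_vtu`.

    Returns ``(mesh, point_data, cell_data)`` where the data dicts hold any
    scalar arrays beyond the label/tag fields.
    """
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        _fail(path, f"invalid XML ({exc})", exc.position[0])
    except OSError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "VTKFile":
        _fail(path, f"not a VTKFile (root element {root.tag!r})")
    piece = root.find(".//Piece")
    if piece is None:
        _fail(path, "no <Piece> element")
    try:
        n = int(piece.get("NumberOfPoints"))
        m = int(piece.get("NumberOfCells"))
    except (TypeError, ValueError):
        _fail(path, "Piece lacks integer NumberOfPoints/NumberOfCells")
    pts = _find_array(piece.find("Points"), "Points", path)
    nodes = _parse_numbers(pts.text or "", path, float, 3 * n,
                           "Points").reshape(n, 3)
    cells = piece.find("Cells")
    if cells is None:
        _fail(path, "no <Cells> element")
    conn = _parse_numbers(_find_array(cells, "connectivity", path).text or "",
                          path, np.int64, 8 * m, "connectivity").reshape(m, 8)
    pdata_el = piece.find("PointData")
    cdata_el = piece.find("CellData")
    if pdata_el is None or cdata_el is None:
        _fail(path, "missing <PointData> or <CellData>")
    tags = _decode_label_array(_find_array(pdata_el, "surface_tag", path),
                               n, path)
    labels = _decode_label_array(_find_array(cdata_el, "region_label", path),
                                 m, path)
    try:
        mesh = HexMesh(nodes, conn, region_labels=labels, surface_tags=tags)
    except ValueError as exc:
        _fail(path, f"inconsistent mesh data: {exc}")
    point_data, cell_data = {}, {}
    for el, count, out in ((pdata_el, n, point_data),
                           (cdata_el, m, cell_data)):
        for da in el.iter("DataArray"):
            name = da.get("Name")
            if name in ("surface_tag", "region_label"):
                continue
            out[name] = _parse_numbers(da.text or "", path, float,
                                       count, name)
    return mesh, point_data, cell_data


# ---------------------------------------------------------------------------
# Legacy VTK polydata for Purkinje trees
# ---------------------------------------------------------------------------

_FLAG_ROOT = 1
_FLAG_TERMINAL = 2


def write_tree_vtk(path, tree: PurkinjeTree):
    """Write a Purkinje tree as legacy ascii VTK polydata.

    Radius and generation seed travel in the title line; root and terminal
    nodes are flagged in a ``node_flags`` point scalar (1 = root,
    2 = terminal).
    """
    p, s = tree.n_nodes, len(tree.segments)
    seed = "none" if tree.seed is None else str(tree.seed)
    flags = np.zeros(p, dtype=np.int64)
    flags[tree.root] |= _FLAG_ROOT
    flags[tree.terminals] |= _FLAG_TERMINAL
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("hexaheart purkinje tree | units=um | "
                 f"radius={FLOAT_FMT % tree.radius} | seed={seed}\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {p} double\n")
        fh.write(_format_floats(tree.nodes))
        fh.write(f"LINES {s} {3 * s}\n")
        fh.write(_format_ints(np.column_stack(
            [np.full(s, 2, dtype=np.int64), tree.segments])))
        fh.write(f"POINT_DATA {p}\nSCALARS node_flags int 1\n"
                 "LOOKUP_TABLE default\n")
        fh.write(_format_ints(flags.reshape(-1, 1)))


def read_tree_vtk(path) -> PurkinjeTree:
    """Read a tree written by :func:`write_tree_vtk`."""
    try:
        with open(path) as fh:
            lines = fh.read().splitlines()
    except OSError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
    if len(lines) < 5 or not lines[0].startswith("# vtk DataFile"):
        _fail(path, "not a legacy VTK file", 1)
    meta = {}
    for part in lines[1].split("|")[1:]:
        if "=" in part:
            key, val = part.split("=", 1)
            meta[key.strip()] = val.strip()
    try:
        radius = float(meta["radius"])
    except (KeyError, ValueError):
        _fail(path, "title line lacks a radius= entry", 2)
    seed = None if meta.get("seed", "none") == "none" else int(meta["seed"])
    if lines[2].strip() != "ASCII" or lines[3].strip() != "DATASET POLYDATA":
        _fail(path, "expected ASCII / DATASET POLYDATA header", 3)

    def section(keyword, skip=1):
        for i, line in enumerate(lines):
            if line.startswith(keyword):
                body = []
                for nxt in lines[i + skip:]:
                    if nxt[:1].isalpha() or nxt[:1] == "#":
                        break
                    body.append(nxt)
                return i, line.split(), " ".join(body)
        _fail(path, f"missing {keyword} section")

    i, toks, body = section("POINTS")
    p = int(toks[1])
    nodes = _parse_numbers(body, path, float, 3 * p, "POINTS")
    nodes = nodes.reshape(p, 3)
    i, toks, body = section("LINES")
    s = int(toks[1])
    rows = _parse_numbers(body, path, np.int64, 3 * s, "LINES").reshape(s, 3)
    if np.any(rows[:, 0] != 2):
        _fail(path, "only 2-point polylines are supported", i + 1)
    segments = rows[:, 1:]
    i, _, body = section("SCALARS node_flags", skip=2)
    flags = _parse_numbers(body, path, np.int64, p, "node_flags")
    roots = np.nonzero(flags & _FLAG_ROOT)[0]
    if len(roots) != 1:
        _fail(path, f"expected exactly one root flag, found {len(roots)}")
    terminals = np.nonzero(flags & _FLAG_TERMINAL)[0]
    try:
        return PurkinjeTree(nodes, segments, root=int(roots[0]),
                            radius=radius, terminals=terminals, seed=seed)
    except ValueError as exc:
        _fail(path, f"inconsistent tree data: {exc}")


# ---------------------------------------------------------------------------
# PMJ coupling tables (CSV)
# ---------------------------------------------------------------------------

_PMJ_COLUMNS = ("terminal_id", "myo_node_id", "area_fraction",
                "branch_area_um2", "length_um", "dir_x", "dir_y", "dir_z",
                "fallback")


def write_pmj_csv(path, pmjs, tree_area: float):
    """Write PMJ couplings, one row per (terminal, myocardial node) branch.

    ``area_fraction`` is the branch area divided by the cable
    cross-sectional area ``tree_area``; full geometric branch data is kept
    alongside so the table alone reconstructs the junctions.
    """
    import pandas as pd

    rows = []
    for pmj in pmjs:
        for node in pmj.myo_nodes:
            rows.append((pmj.terminal, int(node),
                         pmj.branch_area / tree_area, pmj.branch_area,
                         pmj.length, pmj.direction[0], pmj.direction[1],
                         pmj.direction[2], int(pmj.fallback)))
    frame = pd.DataFrame(rows, columns=list(_PMJ_COLUMNS))
    frame.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_pmj_csv(path):
    """Read a PMJ table written by :func:`write_pmj_csv` -> list of PMJ."""
    import pandas as pd

    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except (OSError, ValueError, pd.errors.ParserError) as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
    missing = [c for c in _PMJ_COLUMNS if c not in frame.columns]
    if missing:
        _fail(path, f"missing columns {missing}", 1)
    pmjs = []
    for terminal, group in frame.groupby("terminal_id", sort=True):
        first = group.iloc[0]
        try:
            pmjs.append(PMJ(
                terminal=int(terminal),
                myo_nodes=group["myo_node_id"].to_numpy(dtype=np.int64),
                branch_area=float(first["branch_area_um2"]),
                length=float(first["length_um"]),
                direction=first[["dir_x", "dir_y", "dir_z"]].to_numpy(float),
                fallback=bool(first["fallback"])))
        except (ValueError, TypeError) as exc:
            _fail(path, f"terminal {terminal}: {exc}")
    return pmjs


# ---------------------------------------------------------------------------
# NRRD voxel masks and tensor lattices
# ---------------------------------------------------------------------------


def _nrrd_header(fh, fields):
    fh.write("NRRD0004\n")
    fh.write(f"# units: {UNITS['length']}\n")
    for key, val in fields.items():
        fh.write(f"{key}: {val}\n")
    fh.write("\n")


def _vec(v):
    return "(" + ",".join(FLOAT_FMT % x for x in v) + ")"


def write_mask_nrrd(path, mask: VoxelMask):
    """Write a voxel occupancy mask as ascii NRRD (x fastest)."""
    s = mask.spacing
    with open(path, "w") as fh:
        _nrrd_header(fh, {
            "type": "uint8",
            "dimension": 3,
            "sizes": " ".join(str(k) for k in mask.occupancy.shape),
            "encoding": "ascii",
            "space dimension": 3,
            "space directions": " ".join(
                _vec(s[i] * np.eye(3)[i]) for i in range(3)),
            "space origin": _vec(mask.origin),
        })
        fh.write(_format_ints(
            mask.occupancy.astype(np.uint8).ravel(order="F").reshape(-1, 1)))


def write_tensor_nrrd(path, lattice: TensorLattice):
    """Write a symmetric-tensor lattice as ascii NRRD.

    Leading (fastest) axis holds 7 values per lattice point: the six
    symmetric components (xx, xy, xz, yy, yz, zz) followed by the validity
    flag.
    """
    t = lattice.tensors
    comps = np.stack([t[..., 0, 0], t[..., 0, 1], t[..., 0, 2],
                      t[..., 1, 1], t[..., 1, 2], t[..., 2, 2],
                      lattice.valid.astype(float)], axis=0)
    s = lattice.spacing
    with open(path, "w") as fh:
        _nrrd_header(fh, {
            "type": "double",
            "dimension": 4,
            "sizes": " ".join(str(k) for k in comps.shape),
            "encoding": "ascii",
            "kinds": "covariant-vector space space space",
            "space dimension": 3,
            "space directions": "none " + " ".join(
                _vec(s[i] * np.eye(3)[i]) for i in range(3)),
            "space origin": _vec(lattice.origin),
        })
        fh.write(_format_floats(comps.ravel(order="F").reshape(-1, 1)))


def _read_nrrd(path):
    try:
        with open(path) as fh:
            text = fh.read()
    except OSError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
    lines = text.splitlines()
    if not lines or not lines[0].startswith("NRRD"):
        _fail(path, "missing NRRD magic", 1)
    fields = {}
    body_start = None
    for i, line in enumerate(lines[1:], start=2):
        if line.strip() == "":
            body_start = i
            break
        if line.startswith("#"):
            continue
        if ":" not in line:
            _fail(path, f"malformed header line {line!r}", i)
        key, val = line.split(":", 1)
        fields[key.strip()] = val.strip()
    if body_start is None:
        _fail(path, "header not terminated by a blank line")
    for req in ("type", "dimension", "sizes", "encoding"):
        if req not in fields:
            _fail(path, f"missing required header field {req!r}")
    if fields["encoding"] != "ascii":
        _fail(path, f"unsupported encoding {fields['encoding']!r}")
    try:
        sizes = [int(k) for k in fields["sizes"].split()]
    except ValueError:
        _fail(path, f"unparseable sizes {fields['sizes']!r}")
    if len(sizes) != int(fields["dimension"]):
        _fail(path, "sizes count does not match dimension")
    data = _parse_numbers(" ".join(lines[body_start:]), path, float,
                          int(np.prod(sizes)), "NRRD data")
    return fields, sizes, data


def _parse_space(fields, path):
    vecs = []
    raw = fields.get("space directions", "")
    for tok in raw.split():
        if tok == "none":
            continue
        try:
            vecs.append([float(x) for x in tok.strip("()").split(",")])
        except ValueError:
            _fail(path, f"unparseable space direction {tok!r}")
    if len(vecs) != 3:
        _fail(path, "expected three spatial direction vectors")
    spacing = np.linalg.norm(np.asarray(vecs), axis=1)
    origin_raw = fields.get("space origin", "(0,0,0)")
    try:
        origin = np.array([float(x)
                           for x in origin_raw.strip("()").split(",")])
    except ValueError:
        _fail(path, f"unparseable space origin {origin_raw!r}")
    return spacing, origin


def read_mask_nrrd(path) -> VoxelMask:
    """Read a mask written by :func:`write_mask_nrrd`."""
    fields, sizes, data = _read_nrrd(path)
    if len(sizes) != 3:
        _fail(path, f"expected a 3D mask, got dimension {len(sizes)}")
    spacing, origin = _parse_space(fields, path)
    occ = data.reshape(sizes, order="F") != 0
    return VoxelMask(occ, spacing=spacing, origin=origin)


def read_tensor_nrrd(path) -> TensorLattice:
    """Read a tensor lattice written by :func:`write_tensor_nrrd`."""
    fields, sizes, data = _read_nrrd(path)
    if len(sizes) != 4 or sizes[0] != 7:
        _fail(path, "expected 4D data with 7 components on the first axis")
    comps = data.reshape(sizes, order="F")
    xx, xy, xz, yy, yz, zz, valid = comps
    t = np.empty(tuple(sizes[1:]) + (3, 3))
    t[..., 0, 0], t[..., 0, 1], t[..., 0, 2] = xx, xy, xz
    t[..., 1, 0], t[..., 1, 1], t[..., 1, 2] = xy, yy, yz
    t[..., 2, 0], t[..., 2, 1], t[..., 2, 2] = xz, yz, zz
    spacing, origin = _parse_space(fields, path)
    return TensorLattice(t, valid=valid != 0, spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------
# HDF5 voltage series
# ---------------------------------------------------------------------------


def write_series_h5(path, times, v_series, metadata=None):
    """Write a voltage time series (times in ms, V in mV) to HDF5."""
    import h5py

    times = np.asarray(times, dtype=float)
    v_series = np.asarray(v_series, dtype=float)
    if v_series.shape[0] != len(times):
        raise ValueError("one voltage row per sample time required")
    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=times)
        fh.create_dataset("V", data=v_series)
        fh.attrs["units_time"] = UNITS["time"]
        fh.attrs["units_voltage"] = UNITS["voltage"]
        fh.attrs["package"] = f"hexaheart {__version__}"
        for key, val in (metadata or {}).items():
            fh.attrs[key] = val


def read_series_h5(path):
    """Read a series written by :func:`write_series_h5`.

    Returns ``(times, V, metadata_dict)``.
    """
    import h5py

    try:
        with h5py.File(path, "r") as fh:
            if "times" not in fh or "V" not in fh:
                _fail(path, "missing 'times' or 'V' dataset")
            times = fh["times"][...]
            v = fh["V"][...]
            meta = {k: fh.attrs[k] for k in fh.attrs}
    except OSError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
    return times, v, meta


# ---------------------------------------------------------------------------
# ECG traces (CSV)
# ---------------------------------------------------------------------------


def write_ecg_csv(path, trace: EcgTrace):
    """Write a multi-lead trace: time_ms column plus one column per lead."""
    import pandas as pd

    frame = pd.DataFrame({"time_ms": trace.times})
    for i, label in enumerate(trace.labels):
        frame[label] = trace.signals[:, i]
    frame.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_ecg_csv(path) -> EcgTrace:
    """Read a trace written by :func:`write_ecg_csv`."""
    import pandas as pd

    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except (OSError, ValueError, pd.errors.ParserError) as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
    if "time_ms" not in frame.columns:
        _fail(path, "missing time_ms column", 1)
    labels = [c for c in frame.columns if c != "time_ms"]
    if not labels:
        _fail(path, "no lead columns", 1)
    try:
        return EcgTrace(frame["time_ms"].to_numpy(float),
                        frame[labels].to_numpy(float), tuple(labels))
    except ValueError as exc:
        _fail(path, f"inconsistent trace data: {exc}")


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.json"


def write_manifest(directory, config=None, seed=None, artifacts=None):
    """Write a provenance manifest for a directory of artifacts."""
    payload = {
        "package": "hexaheart",
        "version": __version__,
        "units": UNITS,
        "seed": seed,
        "config": config or {},
        "artifacts": sorted(artifacts or []),
    }
    path = os.path.join(directory, MANIFEST_NAME)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_manifest(directory):
    path = os.path.join(directory, MANIFEST_NAME)
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except OSError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        _fail(path, f"invalid JSON ({exc.msg})", exc.lineno)
    if payload.get("package") != "hexaheart":
        _fail(path, "not a hexaheart manifest")
    return payload
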