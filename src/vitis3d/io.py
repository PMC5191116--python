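"""File I/O: PLY point clouds, camera tracks, label sidecars.

PLY support covers the subset the pipeline exchanges: PLY 1.0, ``ascii`` and
``binary_little_endian`` dialects, a ``vertex`` element with ``x,y,z``
(float or double), optional ``red,green,blue`` (or ``r,g,b``; uchar or
float), optional ``nx,ny,nz`` and an optional integer ``label`` property.
8-bit colors are normalized to [0, 1] on load. Point order is preserved.
"""

from __future__ import annotations

import warnings
from pathlib import Path


import numpy as np

from .pointcloud import CameraTrack, PointCloud


class PlyFormatError(ValueError):
    """Malformed or unsupported PLY content."""


_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def _parse_header(fh) -> tuple[str, list[tuple[str, int, list[tuple[str, str]]]]]:
    """Parse a PLY header from a binary file handle.

    Returns (format, elements) where elements is a list of
    (name, count, [(prop_name, prop_type), ...]). List properties are
    recorded with type 'list:<count_type>:<item_type>'.
    """
    magic = fh.readline().strip()
    if magic != b"ply":
        raise PlyFormatError("not a PLY file (missing 'ply' magic)")
    fmt = None
    elements: list[tuple[str, int, list[tuple[str, str]]]] = []
    while True:
        raw = fh.readline()
        if not raw:
            raise PlyFormatError("unexpected end of file inside PLY header")
        line = raw.decode("ascii", errors="replace").strip()
        if not line or line.startswith("comment") or line.startswith("obj_info"):
            continue
        tokens = line.split()
        if tokens[0] == "format":
            if len(tokens) < 2 or tokens[1] not in ("ascii", "binary_little_endian"):
                raise PlyFormatError(f"unsupported PLY format: {line!r}")
            fmt = tokens[1]
        elif tokens[0] == "element":
            if len(tokens) != 3:
                raise PlyFormatError(f"malformed element line: {line!r}")
            try:
                count = int(tokens[2])
            except ValueError as exc:
                raise PlyFormatError(f"malformed element count: {line!r}") from exc
            elements.append((tokens[1], count, []))
        elif tokens[0] == "property":
            if not elements:
                raise PlyFormatError("property before any element in header")
            if tokens[1] == "list":
                if len(tokens) != 5:
                    raise PlyFormatError(f"malformed list property: {line!r}")
                elements[-1][2].append((tokens[4], f"list:{tokens[2]}:{tokens[3]}"))
            else:
                if len(tokens) != 3:
                    raise PlyFormatError(f"malformed property line: {line!r}")
                if tokens[1] not in _PLY_DTYPES:
                    raise PlyFormatError(f"unsupported property type: {tokens[1]}")
                elements[-1][2].append((tokens[2], tokens[1]))
        elif tokens[0] == "end_header":
            break
        else:
            raise PlyFormatError(f"unrecognized header line: {line!r}")
    if fmt is None:
        raise PlyFormatError("PLY header lacks a format line")
    return fmt, elements


def read_ply(path) -> PointCloud:
    """Read a PLY file into a :class:`PointCloud`.

    Colors are normalized to [0, 1] (integer channels divided by their type
    maximum). Missing color properties produce a cloud without colors and a
    warning; missing coordinates raise :class:`PlyFormatError`.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        fmt, elements = _parse_header(fh)
        names = [e[0] for e in elements]
        if "vertex" not in names:
            raise PlyFormatError("PLY file has no vertex element")
        vidx = names.index("vertex")
        if vidx != 0 and fmt != "ascii":
            # binary elements before vertex may hold variable-length lists;
            # skipping them is not supported
            for _, _, props in elements[:vidx]:
                if any(t.startswith("list:") for _, t in props):
                    raise PlyFormatError(
                        "binary PLY with list elements before vertex is unsupported")
        _, count, props = elements[vidx]
        if any(t.startswith("list:") for _, t in props):
            raise PlyFormatError("list properties on the vertex element are unsupported")

        if fmt == "binary_little_endian":
            for _, ecount, eprops in elements[:vidx]:
                rowsize = sum(np.dtype("<" + _PLY_DTYPES[t]).itemsize for _, t in eprops)
                fh.seek(ecount * rowsize, 1)
            dtype = np.dtype([(n, "<" + _PLY_DTYPES[t]) for n, t in props])
            data = np.frombuffer(fh.read(count * dtype.itemsize), dtype=dtype, count=count)
        else:
            rows = []
            read_rows = 0
            skip = sum(e[1] for e in elements[:vidx])
            while read_rows < skip + count:
                line = fh.readline()
                if not line:
                    raise PlyFormatError("unexpected end of ASCII PLY data")
                if not line.strip():
                    continue
                read_rows += 1
                if read_rows > skip:
                    rows.append(line.split())
            arr = np.array(rows)
            if arr.shape[1] < len(props):
                raise PlyFormatError("vertex rows have fewer columns than declared")
            dtype = np.dtype([(n, _PLY_DTYPES[t]) for n, t in props])
            data = np.zeros(count, dtype=dtype)
            for i, (n, t) in enumerate(props):
                col = arr[:, i].astype(np.float64)
                data[n] = col.astype(_PLY_DTYPES[t])

    fields = data.dtype.names
    for c in ("x", "y", "z"):
        if c not in fields:
            raise PlyFormatError("vertex element lacks x, y, z coordinate properties")
    coords = np.column_stack([data["x"], data["y"], data["z"]]).astype(np.float64)

    colors = None
    for rgb in (("red", "green", "blue"), ("r", "g", "b")):
        if all(c in fields for c in rgb):
            cols = np.column_stack([data[c] for c in rgb]).astype(np.float64)
            kind = data.dtype[rgb[0]]
            if kind.kind in "ui":
                cols /= float(np.iinfo(kind).max)
            colors = np.clip(cols, 0.0, 1.0)
            break
    if colors is None:
        warnings.warn(f"{path.name}: no color properties found; loading without colors",
                      stacklevel=2)

    normals = None
    if all(c in fields for c in ("nx", "ny", "nz")):
        normals = np.column_stack([data["nx"], data["ny"], data["nz"]]).astype(np.float64)
        norm = np.linalg.norm(normals, axis=1)
        nz = norm > 0
        normals[nz] /= norm[nz, None]
        normals[~nz] = np.nan

    labels = data["label"].astype(np.int64) if "label" in fields else None

    return PointCloud(coords=coords, colors=colors, normals=normals, labels=labels)


def write_ply(cloud: PointCloud, path, ascii_flag: bool = True) -> None:
    """Write a cloud as PLY; labels (if any) become an integer vertex property."""
    if len(cloud) == 0:
        raise ValueError("refusing to write an empty point cloud")
    path = Path(path)

    props: list[tuple[str, str, np.ndarray]] = [
        ("x", "float", cloud.coords[:, 0]),
        ("y", "float", cloud.coords[:, 1]),
        ("z", "float", cloud.coords[:, 2]),
    ]
    if cloud.colors is not None:
        rgb = np.rint(np.clip(cloud.colors, 0, 1) * 255).astype(np.uint8)
        props += [("red", "uchar", rgb[:, 0]),
                  ("green", "uchar", rgb[:, 1]),
                  ("blue", "uchar", rgb[:, 2])]
    if cloud.normals is not None:
        nrm = np.nan_to_num(cloud.normals, nan=0.0)
        props += [("nx", "float", nrm[:, 0]),
                  ("ny", "float", nrm[:, 1]),
                  ("nz", "float", nrm[:, 2])]
    if cloud.labels is not None:
        props.append(("label", "int", cloud.labels))

    header = ["ply",
              f"format {'ascii' if ascii_flag else 'binary_little_endian'} 1.0",
              f"element vertex {len(cloud)}"]
    header += [f"property {t} {n}" for n, t, _ in props]
    header.append("end_header")

    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if ascii_flag:
            cols = []
            for _, t, v in props:
                if t in ("uchar", "int"):
                    cols.append(v.astype(np.int64).astype(str))
                else:
                    cols.append(np.char.mod("%.9g", v.astype(np.float32)))
            body = "\n".join(" ".join(row) for row in zip(*cols))
            fh.write((body + "\n").encode("ascii"))
        else:
            dtype = np.dtype([(n, "<" + _PLY_DTYPES[t]) for n, t, _ in props])
            rec = np.zeros(len(cloud), dtype=dtype)
            for n, t, v in props:
                rec[n] = v
            fh.write(rec.tobytes())


def read_camera_track(path) -> CameraTrack:
    """Read a plain-text camera track: 3 numeric columns, '#' comments allowed."""
    positions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.replace(",", " ").split()
            try:
                row = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric camera row at line {lineno}") from exc
            if len(row) != 3:
                raise ValueError(f"{path}: expected 3 columns at line {lineno}, got {len(row)}")
            positions.append(row)
    if not positions:
        raise ValueError(f"{path}: camera track is empty")
    return CameraTrack(positions=np.asarray(positions))


def write_camera_track(track: CameraTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write("# camera positions: x y z (meters)\n")
        for p in track.positions:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")


def read_labels(path) -> np.ndarray:
    """Read a one-label-per-line integer sidecar file."""
    labels = np.loadtxt(path, dtype=np.int64, comments="#", ndmin=1)
    return labels


def write_labels(labels: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(labels, dtype=np.int64), fmt="%d")


def read_posteriors(path) -> np.ndarray:
    post = np.loadtxt(path, dtype=np.float64, comments="#", ndmin=2)
    return post


def write_posteriors(post: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(post, dtype=np.float64), fmt="%.9g")
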