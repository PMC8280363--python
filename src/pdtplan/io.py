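"""File formats and configuration.

Clouds round-trip through PLY (ASCII or binary little-endian, with
``nx,ny,nz`` and ``red,green,blue`` vertex properties), whitespace XYZ
(``x y z [nx ny nz] [r g b]``) and OBJ vertex lines.  Coordinates in all
files are millimetres.  Device descriptions and surface specs are flat
YAML key-value files.

PLY handling is implemented directly on numpy structured arrays: the
point-cloud flavour of PLY used here (vertices with normal and color
properties, no faces) is simple enough that a dedicated reader keeps the
normals, which mesh-oriented loaders drop for vertex-only files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .array_model import LEDArray, LEDSpec
from .cloud import PointCloud
from .phantoms import SurfaceSpec

__all__ = [
    "read_cloud",
    "write_cloud",
    "load_device",
    "save_device",
    "load_surface_spec",
    "save_surface_spec",
]

_FORMATS = {".ply": "ply", ".xyz": "xyz", ".obj": "obj", ".txt": "xyz"}


class CloudParseError(ValueError):
    """Malformed cloud file; carries the offending line number when known."""


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in {"ply", "xyz", "obj"}:
            raise ValueError(f"unsupported format {fmt!r}")
        return fmt
    try:
        return _FORMATS[path.suffix.lower()]
    except KeyError:
        raise ValueError(f"cannot infer format from suffix {path.suffix!r}") from None


def read_cloud(path, fmt: str | None = None, frame: str = "scan") -> PointCloud:
    """Load a point cloud from PLY / XYZ / OBJ."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "ply":
        return _read_ply(path, frame)
    if fmt == "xyz":
        return _read_xyz(path, frame)
    return _read_obj(path, frame)


def write_cloud(cloud: PointCloud, path, fmt: str | None = None, binary: bool = False) -> None:
    """Write a point cloud; ASCII floats use 9 significant digits."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "ply":
        _write_ply(cloud, path, binary=binary)
    elif fmt == "xyz":
        _write_xyz(cloud, path)
    else:
        _write_obj(cloud, path)


# ---------------------------------------------------------------- PLY

_PLY_TYPES = {
    "float": "<f4", "float32": "<f4", "double": "<f8", "float64": "<f8",
    "uchar": "u1", "uint8": "u1", "char": "i1", "int8": "i1",
    "short": "<i2", "ushort": "<u2", "int": "<i4", "uint": "<u4",
    "int32": "<i4", "uint32": "<u4",
}


def _read_ply(path: Path, frame: str) -> PointCloud:
    with open(path, "rb") as fh:
        line = fh.readline().strip()
        if line != b"ply":
            raise CloudParseError(f"{path}:1: not a PLY file")
        fmt = None
        n_vertex = None
        props: list[tuple[str, str]] = []
        in_vertex = False
        lineno = 1
        while True:
            raw = fh.readline()
            lineno += 1
            if not raw:
                raise CloudParseError(f"{path}:{lineno}: unexpected end of header")
            tok = raw.decode("ascii", "replace").split()
            if not tok:
                continue
            if tok[0] == "format":
                fmt = tok[1]
            elif tok[0] == "element":
                in_vertex = tok[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tok[2])
            elif tok[0] == "property" and in_vertex:
                if tok[1] == "list":
                    raise CloudParseError(f"{path}:{lineno}: list properties not supported on vertices")
                props.append((tok[2], _PLY_TYPES[tok[1]]))
            elif tok[0] == "end_header":
                break
        if fmt not in {"ascii", "binary_little_endian"}:
            raise CloudParseError(f"{path}: unsupported PLY format {fmt!r}")
        if n_vertex is None:
            raise CloudParseError(f"{path}: no vertex element")
        dtype = np.dtype(props)
        if fmt == "ascii":
            rows = []
            for i in range(n_vertex):
                raw = fh.readline()
                lineno += 1
                vals = raw.split()
                if len(vals) != len(props):
                    raise CloudParseError(f"{path}:{lineno}: expected {len(props)} values, got {len(vals)}")
                rows.append(tuple(float(v) for v in vals))
            data = np.array(rows, dtype=[(n, "f8") for n, _ in props])
        else:
            data = np.frombuffer(fh.read(dtype.itemsize * n_vertex), dtype=dtype, count=n_vertex)
    names = data.dtype.names
    for c in ("x", "y", "z"):
        if c not in names:
            raise CloudParseError(f"{path}: vertex element lacks coordinate {c!r}")
    pos = np.column_stack([data["x"], data["y"], data["z"]]).astype(float)
    normals = None
    if all(c in names for c in ("nx", "ny", "nz")):
        normals = np.column_stack([data["nx"], data["ny"], data["nz"]]).astype(float)
    colors = None
    if all(c in names for c in ("red", "green", "blue")):
        colors = np.column_stack([data["red"], data["green"], data["blue"]]).astype(float)
        if colors.max() > 1.0:  # stored as uchar 0..255
            colors = colors / 255.0
    return PointCloud(pos, normals, colors, frame=frame)


def _write_ply(cloud: PointCloud, path: Path, binary: bool) -> None:
    fields = [("x", "<f8"), ("y", "<f8"), ("z", "<f8")]
    header_props = ["property double x", "property double y", "property double z"]
    if cloud.normals is not None:
        fields += [("nx", "<f8"), ("ny", "<f8"), ("nz", "<f8")]
        header_props += ["property double nx", "property double ny", "property double nz"]
    if cloud.colors is not None:
        fields += [("red", "u1"), ("green", "u1"), ("blue", "u1")]
        header_props += ["property uchar red", "property uchar green", "property uchar blue"]
    data = np.empty(len(cloud), dtype=fields)
    data["x"], data["y"], data["z"] = cloud.positions.T
    if cloud.normals is not None:
        data["nx"], data["ny"], data["nz"] = cloud.normals.T
    if cloud.colors is not None:
        rgb = np.rint(cloud.colors * 255.0).astype("u1")
        data["red"], data["green"], data["blue"] = rgb.T
    header = "\n".join(
        ["ply", f"format {'binary_little_endian' if binary else 'ascii'} 1.0",
         "comment units mm", f"element vertex {len(cloud)}", *header_props, "end_header", ""]
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(data.tobytes())
        else:
            for row in data:
                parts = [f"{row[n]:.9g}" if d.startswith("<f") else str(int(row[n])) for n, d in fields]
                fh.write((" ".join(parts) + "\n").encode("ascii"))


# ---------------------------------------------------------------- XYZ / OBJ


def _read_xyz(path: Path, frame: str) -> PointCloud:
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            vals = line.split()
            if width is None:
                width = len(vals)
                if width not in (3, 6, 9):
                    raise CloudParseError(f"{path}:{lineno}: expected 3, 6 or 9 columns, got {width}")
            elif len(vals) != width:
                raise CloudParseError(f"{path}:{lineno}: expected {width} columns, got {len(vals)}")
            try:
                rows.append([float(v) for v in vals])
            except ValueError as exc:
                raise CloudParseError(f"{path}:{lineno}: {exc}") from None
    if not rows:
        raise CloudParseError(f"{path}: no data rows")
    arr = np.asarray(rows)
    pos = arr[:, :3]
    normals = arr[:, 3:6] if arr.shape[1] >= 6 else None
    colors = arr[:, 6:9] if arr.shape[1] == 9 else None
    return PointCloud(pos, normals, colors, frame=frame)


def _write_xyz(cloud: PointCloud, path: Path) -> None:
    cols = [cloud.positions]
    if cloud.normals is not None:
        cols.append(cloud.normals)
        if cloud.colors is not None:
            cols.append(cloud.colors)
    elif cloud.colors is not None:
        raise ValueError("XYZ layout stores colors only after normals")
    arr = np.hstack(cols)
    with open(path, "w") as fh:
        fh.write("# x_mm y_mm z_mm" + (" nx ny nz" if cloud.normals is not None else "") + (" r g b" if cloud.colors is not None else "") + "\n")
        for row in arr:
            fh.write(" ".join(f"{v:.9g}" for v in row) + "\n")


def _read_obj(path: Path, frame: str) -> PointCloud:
    pos, colors = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok or tok[0] != "v":
                continue
            if len(tok) not in (4, 7):
                raise CloudParseError(f"{path}:{lineno}: vertex line needs 3 or 6 numbers")
            try:
                vals = [float(v) for v in tok[1:]]
            except ValueError as exc:
                raise CloudParseError(f"{path}:{lineno}: {exc}") from None
            pos.append(vals[:3])
            if len(vals) == 6:
                colors.append(vals[3:])
    if not pos:
        raise CloudParseError(f"{path}: no vertices")
    colors_arr = np.asarray(colors) if len(colors) == len(pos) else None
    return PointCloud(np.asarray(pos), None, colors_arr, frame=frame)


def _write_obj(cloud: PointCloud, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# point cloud, coordinates in mm\n")
        for i, p in enumerate(cloud.positions):
            if cloud.colors is not None:
                c = cloud.colors[i]
                fh.write(f"v {p[0]:.9g} {p[1]:.9g} {p[2]:.9g} {c[0]:.9g} {c[1]:.9g} {c[2]:.9g}\n")
            else:
                fh.write(f"v {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")


# ---------------------------------------------------------------- configs


def save_device(array: LEDArray, path) -> None:
    rows = int(round(np.sqrt(array.n_units)))
    cfg = {
        "rows": rows,
        "cols": array.n_units // rows,
        "pitch_mm": float(np.diff(np.unique(array.unit_positions[:, 0])).min()) if array.n_units > 1 else 10.0,
        "psi_deg": array.spec.psi_deg,
        "i0_default": array.spec.i0,
        "i0_min": array.spec.ls,
        "i0_max": array.spec.hs,
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def load_device(path) -> LEDArray:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    spec = LEDSpec(
        i0=float(cfg.get("i0_default", 372.0)),
        psi_deg=float(cfg.get("psi_deg", 15.0)),
        ls=float(cfg.get("i0_min", 0.0)),
        hs=float(cfg.get("i0_max", 750.0)),
    )
    return LEDArray.grid(
        rows=int(cfg.get("rows", 15)),
        cols=int(cfg.get("cols", 15)),
        pitch_mm=float(cfg.get("pitch_mm", 10.0)),
        spec=spec,
    )


def save_surface_spec(spec: SurfaceSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))


def load_surface_spec(path) -> SurfaceSpec:
    return SurfaceSpec.from_dict(yaml.safe_load(Path(path).read_text()) or {})
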