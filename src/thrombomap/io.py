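"""File formats: surfaces (STL/PLY/OBJ/VTP), WSS series (HDF5/CSV), reports.

STL, PLY and OBJ go through trimesh. VTP is handled by a small reader/
writer for ASCII XML PolyData — the only VTK construct this package
needs — so per-vertex scalar arrays (indices, thickness, region labels)
travel with the geometry. Formats without point data (STL/OBJ) drop the
arrays with a warning.
"""
from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import SurfaceMesh
from .wss import WSSField

__all__ = [
    "read_surface",
    "write_surface",
    "read_wss_series",
    "write_wss_series",
    "write_indices_csv",
]

_TRIMESH_EXT = {".stl", ".ply", ".obj"}


def read_surface(path) -> SurfaceMesh:
    """Read a surface mesh; normals are recomputed if the file has none."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".vtp":
        return _read_vtp(path)
    if ext in _TRIMESH_EXT:
        import trimesh

        tm = trimesh.load(str(path), file_type=ext.lstrip("."), process=False)
        if not hasattr(tm, "faces"):
            raise ValueError(f"{path}: not a triangulated surface")
        faces = np.asarray(tm.faces)
        if faces.shape[1] != 3:
            raise ValueError(f"{path}: only triangle meshes are supported")
        return SurfaceMesh(vertices=np.asarray(tm.vertices, float), faces=faces)
    raise ValueError(f"unsupported surface format {ext!r} (stl/ply/obj/vtp)")


def write_surface(mesh: SurfaceMesh, path) -> None:
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".vtp":
        _write_vtp(mesh, path)
        return
    if ext in _TRIMESH_EXT:
        import trimesh

        if mesh.point_data and ext != ".ply":
            warnings.warn(f"{ext} cannot carry point data; arrays dropped",
                          stacklevel=2)
        tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                             process=False)
        tm.export(str(path))
        return
    raise ValueError(f"unsupported surface format {ext!r} (stl/ply/obj/vtp)")


# -- minimal ASCII VTP --------------------------------------------------------


def _format_floats(a: np.ndarray) -> str:
    return " ".join(format(x, ".17g") for x in np.asarray(a, float).ravel())


def _write_vtp(mesh: SurfaceMesh, path: Path) -> None:
    n, m = mesh.n_vertices, mesh.n_faces
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">',
        "  <PolyData>",
        f'    <Piece NumberOfPoints="{n}" NumberOfVerts="0" NumberOfLines="0" '
        f'NumberOfStrips="0" NumberOfPolys="{m}">',
        "      <Points>",
        '        <DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        "          " + _format_floats(mesh.vertices),
        "        </DataArray>",
        "      </Points>",
    ]
    lines.append("      <PointData>")
    arrays = {"Normals": mesh.normals, **mesh.point_data}
    for name, arr in arrays.items():
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        lines += [
            f'        <DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">',
            "          " + _format_floats(arr),
            "        </DataArray>",
        ]
    lines.append("      </PointData>")
    lines += [
        "      <Polys>",
        '        <DataArray type="Int64" Name="connectivity" format="ascii">',
        "          " + " ".join(map(str, mesh.faces.ravel())),
        "        </DataArray>",
        '        <DataArray type="Int64" Name="offsets" format="ascii">',
        "          " + " ".join(map(str, range(3, 3 * m + 1, 3))),
        "        </DataArray>",
        "      </Polys>",
        "    </Piece>",
        "  </PolyData>",
        "</VTKFile>",
        "",
    ]
    path.write_text("\n".join(lines))


def _read_vtp(path: Path) -> SurfaceMesh:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"{path}: malformed VTP ({exc})") from exc
    piece = root.find("./PolyData/Piece")
    if piece is None:
        raise ValueError(f"{path}: no PolyData Piece element")
    pts = piece.find("./Points/DataArray")
    vertices = np.fromstring(pts.text, sep=" ").reshape(-1, 3)
    conn = None
    for da in piece.findall("./Polys/DataArray"):
        if da.get("Name") == "connectivity":
            conn = np.fromstring(da.text, sep=" ", dtype=np.int64)
    if conn is None:
        raise ValueError(f"{path}: missing connectivity array")
    if conn.size % 3:
        raise ValueError(f"{path}: non-triangular polys are not supported")
    faces = conn.reshape(-1, 3)
    normals = None
    point_data: dict[str, np.ndarray] = {}
    pd_el = piece.find("./PointData")
    if pd_el is not None:
        for da in pd_el.findall("./DataArray"):
            name = da.get("Name", "")
            ncomp = int(da.get("NumberOfComponents", "1"))
            arr = np.fromstring(da.text, sep=" ")
            if ncomp > 1:
                arr = arr.reshape(-1, ncomp)
            if name == "Normals":
                normals = arr
            else:
                point_data[name] = arr
    return SurfaceMesh(vertices=vertices, faces=faces, normals=normals,
                       point_data=point_data)


# -- WSS time series ----------------------------------------------------------


def write_wss_series(field: WSSField, path) -> None:
    """Write /times [K], /vectors [K x N x 3] with attrs period_s, units."""
    import h5py

    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=field.times)
            f.create_dataset("vectors", data=field.vectors)
            f.attrs["period_s"] = field.period
            f.attrs["units"] = "Pa"
        return
    if path.suffix.lower() == ".csv":
        k, n, _ = field.vectors.shape
        df = pd.DataFrame({
            "vertex_id": np.tile(np.arange(n), k),
            "t": np.repeat(field.times, n),
            "tx": field.vectors[:, :, 0].ravel(),
            "ty": field.vectors[:, :, 1].ravel(),
            "tz": field.vectors[:, :, 2].ravel(),
        })
        with path.open("w") as fh:
            fh.write(f"# period_s={field.period}\n")
            df.to_csv(fh, index=False)
        return
    raise ValueError("WSS series format must be .h5/.hdf5 or .csv")


def read_wss_series(path, mesh: SurfaceMesh) -> WSSField:
    """Read an HDF5 or long-format CSV WSS series and validate it."""
    import h5py

    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            times = f["times"][:]
            vectors = f["vectors"][:]
            period = float(f.attrs["period_s"])
    elif path.suffix.lower() == ".csv":
        with path.open() as fh:
            header = fh.readline()
            if not header.startswith("# period_s="):
                raise ValueError(f"{path}: missing '# period_s=' header line")
            period = float(header.split("=", 1)[1])
            df = pd.read_csv(fh)
        times = np.unique(df["t"].to_numpy())
        n = int(df["vertex_id"].max()) + 1
        k = len(times)
        if len(df) != k * n:
            raise ValueError(f"{path}: expected {k}x{n} rows, found {len(df)}")
        df = df.sort_values(["t", "vertex_id"], kind="stable")
        vectors = df[["tx", "ty", "tz"]].to_numpy().reshape(k, n, 3)
    else:
        raise ValueError("WSS series format must be .h5/.hdf5 or .csv")
    if vectors.shape[1] != mesh.n_vertices:
        raise ValueError(
            f"WSS series has {vectors.shape[1]} vertices but the mesh has "
            f"{mesh.n_vertices}"
        )
    return WSSField(mesh=mesh, times=times, period=period, vectors=vectors)


def write_indices_csv(indices, path, flags: bool = True) -> None:
    """Per-vertex index table: vertex_id + six index columns (+ flags)."""
    data = {"vertex_id": np.arange(len(indices.tawss))}
    for name, arr in indices.as_dict().items():
        data[name] = arr
    if flags:
        for name, arr in indices.flags.items():
            data[f"flag_{name}"] = arr.astype(int)
    pd.DataFrame(data).to_csv(path, index=False)
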