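"""File I/O: mesh export, labelled surfaces, results and run manifests.

Conventions: lengths in mm, forces in N, pressures in MPa, angles in
degrees at every interface.  STL/OBJ carry no labels, so region labels
travel in a sidecar JSON file mapping region name to vertex indices;
PLY pressure fields carry a per-vertex float attribute ``pressure_mpa``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .contact import ContactResult
from .errors import FormatError
from .geometry import LabelledSurface, ModelGeometry

__all__ = ["export_mesh", "save_labels", "load_labels", "save_labelled_surface",
           "load_labelled_surface", "save_result_csv", "load_result_csv",
           "save_pressure_ply", "export_geometry", "write_manifest"]

_MESH_FORMATS = {".stl", ".ply", ".obj"}


def export_mesh(mesh: trimesh.Trimesh, path: str | Path,
                ascii_format: bool = True) -> Path:
    """Write a mesh as STL, PLY or OBJ (chosen from the file suffix).

    ASCII encodings are the default so exports are diffable and
    byte-reproducible; ``ascii_format=False`` selects binary STL/PLY.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in _MESH_FORMATS:
        raise FormatError(f"unsupported mesh format {suffix!r}; use .stl/.ply/.obj")
    if suffix == ".stl":
        data = mesh.export(file_type="stl_ascii" if ascii_format else "stl")
    elif suffix == ".ply":
        data = mesh.export(file_type="ply",
                           encoding="ascii" if ascii_format else "binary")
    else:
        data = mesh.export(file_type="obj")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)
    return path


def save_labels(labels: dict[str, np.ndarray], path: str | Path) -> Path:
    """Sidecar JSON: region name -> vertex indices."""
    path = Path(path)
    payload = {"element": "vertex",
               "regions": {k: np.asarray(v).tolist() for k, v in labels.items()}}
    path.write_text(json.dumps(payload))
    return path


def load_labels(path: str | Path) -> dict[str, np.ndarray]:
    data = json.loads(Path(path).read_text())
    if "regions" not in data:
        raise FormatError(f"{path}: not a label sidecar file (no 'regions' key)")
    return {k: np.asarray(v, dtype=np.int64) for k, v in data["regions"].items()}


def save_labelled_surface(surface: LabelledSurface, base: str | Path) -> dict[str, Path]:
    """Write a labelled surface as ``<base>.csv`` (x,y,z,label; one primary
    label per point, edge labels taking precedence) plus lossless
    ``<base>.ply`` / ``<base>.labels.json``."""
    base = Path(base)
    primary = np.full(len(surface.points), "articular", dtype=object)
    for name, idx in surface.labels.items():
        if name != "articular":
            primary[np.asarray(idx)] = name
    df = pd.DataFrame(surface.points, columns=["x", "y", "z"])
    df["label"] = primary
    csv_path = base.with_suffix(".csv")
    df.to_csv(csv_path, index=False, float_format="%.9f")
    cloud = trimesh.PointCloud(surface.points)
    ply_path = base.with_suffix(".ply")
    with open(ply_path, "wb") as fh:
        fh.write(cloud.export(file_type="ply"))
    labels_path = save_labels(surface.labels, base.with_suffix(".labels.json"))
    return {"csv": csv_path, "ply": ply_path, "labels": labels_path}


def load_labelled_surface(path: str | Path, side: str = "right") -> LabelledSurface:
    """Read a labelled surface from a point CSV (x,y,z,label) or from a PLY
    with its ``.labels.json`` sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, comment="#")
        missing = [c for c in ("x", "y", "z", "label") if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
        points = df[["x", "y", "z"]].to_numpy(dtype=float)
        labels: dict[str, np.ndarray] = {}
        lab = df["label"].to_numpy()
        for name in np.unique(lab):
            labels[str(name)] = np.flatnonzero(lab == name)
        # edge rings are part of the articular surface
        if "articular" in labels:
            edge = [labels[k] for k in ("fossa_edge", "notch_edge") if k in labels]
            if edge:
                labels["articular"] = np.sort(np.concatenate(
                    [labels["articular"], *edge]))
        return LabelledSurface(points=points, labels=labels, side=side)
    if path.suffix.lower() == ".ply":
        cloud = trimesh.load(path)
        sidecar = path.with_suffix(".labels.json")
        if not sidecar.exists():
            raise FormatError(f"{sidecar} sidecar not found for {path}")
        return LabelledSurface(points=np.asarray(cloud.vertices, dtype=float),
                               labels=load_labels(sidecar), side=side)
    raise FormatError(f"unsupported surface format {path.suffix!r}; use .csv or .ply")


def save_result_csv(result: ContactResult, path: str | Path) -> Path:
    path = Path(path)
    result.to_frame().to_csv(path, index=False, float_format="%.9f")
    return path


def load_result_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"cycle_fraction", "max_pressure_MPa", "contact_area_mm2"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def save_pressure_ply(geometry: ModelGeometry, pressure: np.ndarray,
                      path: str | Path) -> Path:
    """Write the lunate mesh with a per-vertex ``pressure_mpa`` attribute."""
    mesh = trimesh.Trimesh(vertices=geometry.articular.vertices,
                           faces=geometry.articular.faces, process=False)
    mesh.vertex_attributes["pressure_mpa"] = np.asarray(pressure, dtype=np.float32)
    data = mesh.export(file_type="ply", encoding="ascii")
    path = Path(path)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)
    return path


def export_geometry(geo: ModelGeometry, out_dir: str | Path,
                    mesh_format: str = "stl", ascii_format: bool = True) -> dict:
    """Export all model meshes plus label sidecars into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name in ("bone_block", "bone_cavity", "articular", "cartilage"):
        mesh = getattr(geo, name)
        if mesh is None:
            continue
        written[name] = export_mesh(mesh, out / f"{name}.{mesh_format}",
                                    ascii_format=ascii_format)
        if name in geo.labels:
            written[f"{name}_labels"] = save_labels(
                geo.labels[name], out / f"{name}.labels.json")
    if geo.femoral_head is not None:
        written["femoral_head"] = export_mesh(
            geo.femoral_head.mesh(), out / f"femoral_head.{mesh_format}",
            ascii_format=ascii_format)
    return written


def write_manifest(out_dir: str | Path, config: dict, seed: int | None = None) -> Path:
    """Provenance manifest: full config, its hash, seed and versions."""
    import paramhip

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    canonical = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": json.loads(canonical),
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "versions": {"paramhip": paramhip.__version__,
                     "numpy": np.__version__,
                     "trimesh": trimesh.__version__},
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
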