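"""Point-cloud and record-table I/O.

Supported cloud formats (units mm throughout):

* **PLY** (ascii): element ``vertex`` with ``x y z`` and optional
  ``nx ny nz`` and integer ``label`` properties.  Label names are carried
  in ``comment label <code> <name>`` header lines.  Reading is delegated
  to :mod:`trimesh`; writing uses double precision so coordinates
  round-trip to better than 1e-6 mm.
* **XYZ**: whitespace-delimited ``x y z`` per line.
* **CSV**: header ``x,y,z[,nx,ny,nz][,label]``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .cloud import PointCloud
from .errors import CloudFormatError

__all__ = [
    "read_point_cloud",
    "write_point_cloud",
    "write_records",
    "read_records",
    "write_fit_json",
]

_FORMATS = ("ply", "xyz", "csv")


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.lower()
        if f not in _FORMATS:
            raise CloudFormatError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
        return f
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _FORMATS:
        return suffix
    raise CloudFormatError(
        f"cannot infer format from extension {path.suffix!r}; pass fmt explicitly"
    )


def _normalize(normals: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise CloudFormatError("zero-length normal vector in file")
    return normals / norms


def _read_ply(path: Path) -> PointCloud:
    # label-code -> name mapping travels in header comments
    label_names: dict[int, str] = {}
    with open(path, "r", errors="replace") as fh:
        for i, line in enumerate(fh):
            if i == 0 and line.strip() != "ply":
                raise CloudFormatError(f"{path}: line 1: not a PLY file")
            if line.startswith("comment label "):
                parts = line.split()
                if len(parts) >= 4:
                    label_names[int(parts[2])] = parts[3]
            if line.strip() == "end_header" or i > 200:
                break
    try:
        mesh = trimesh.load(str(path), process=False)
    except Exception as exc:  # trimesh raises assorted types on bad files
        raise CloudFormatError(f"{path}: PLY parse failed: {exc}") from exc
    points = np.asarray(mesh.vertices, dtype=float)
    if points.size == 0:
        raise CloudFormatError(f"{path}: PLY contains no vertices")
    normals = labels = None
    raw = mesh.metadata.get("_ply_raw", {}).get("vertex", {}).get("data")
    if raw is not None:
        names = raw.dtype.names if hasattr(raw, "dtype") else raw.keys()
        def col(name):
            return np.asarray(raw[name], dtype=float).ravel()
        if all(k in names for k in ("nx", "ny", "nz")):
            normals = _normalize(np.column_stack([col("nx"), col("ny"), col("nz")]))
        if "label" in names:
            codes = np.asarray(raw["label"]).ravel().astype(int)
            labels = np.array(
                [label_names.get(c, str(c)) for c in codes], dtype=object
            )
    return PointCloud(points=points, normals=normals, labels=labels)


def _write_ply(path: Path, cloud: PointCloud) -> None:
    n = len(cloud)
    props = ["property double x", "property double y", "property double z"]
    cols = [cloud.points]
    if cloud.normals is not None:
        props += ["property double nx", "property double ny", "property double nz"]
        cols.append(cloud.normals)
    comments = []
    codes = None
    if cloud.labels is not None:
        names = sorted(set(cloud.labels))
        code_of = {name: i for i, name in enumerate(names)}
        comments = [f"comment label {i} {name}" for name, i in code_of.items()]
        codes = np.array([code_of[x] for x in cloud.labels])
        props.append("property int label")
    header = (
        ["ply", "format ascii 1.0"]
        + comments
        + [f"element vertex {n}"]
        + props
        + ["end_header"]
    )
    data = np.hstack(cols)
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        for i in range(n):
            row = " ".join(f"{v:.17g}" for v in data[i])
            if codes is not None:
                row += f" {codes[i]}"
            fh.write(row + "\n")


def _read_xyz(path: Path) -> PointCloud:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) < 3:
                raise CloudFormatError(f"{path}: line {lineno}: expected 3 coordinates")
            try:
                rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
            except ValueError as exc:
                raise CloudFormatError(
                    f"{path}: line {lineno}: non-numeric coordinate"
                ) from exc
    if not rows:
        raise CloudFormatError(f"{path}: no points")
    return PointCloud(points=np.array(rows))


def _write_xyz(path: Path, cloud: PointCloud) -> None:
    np.savetxt(path, cloud.points, fmt="%.17g")


def _read_csv(path: Path) -> PointCloud:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise CloudFormatError(f"{path}: CSV parse failed: {exc}") from exc
    missing = [c for c in ("x", "y", "z") if c not in df.columns]
    if missing:
        raise CloudFormatError(f"{path}: line 1: missing column(s) {missing}")
    for c in ("x", "y", "z"):
        if not np.issubdtype(df[c].dtype, np.number):
            bad = df.index[pd.to_numeric(df[c], errors="coerce").isna()]
            line = int(bad[0]) + 2 if len(bad) else 2  # +2: header + 1-based
            raise CloudFormatError(f"{path}: line {line}: non-numeric {c!r} value")
    points = df[["x", "y", "z"]].to_numpy(dtype=float)
    normals = None
    if all(c in df.columns for c in ("nx", "ny", "nz")):
        normals = _normalize(df[["nx", "ny", "nz"]].to_numpy(dtype=float))
    labels = df["label"].astype(str).to_numpy(dtype=object) if "label" in df.columns else None
    return PointCloud(points=points, normals=normals, labels=labels)


def _write_csv(path: Path, cloud: PointCloud) -> None:
    data = {c: cloud.points[:, i] for i, c in enumerate("xyz")}
    if cloud.normals is not None:
        for i, c in enumerate(("nx", "ny", "nz")):
            data[c] = cloud.normals[:, i]
    if cloud.labels is not None:
        data["label"] = cloud.labels
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_point_cloud(path, fmt: str | None = None) -> PointCloud:
    """Read a point cloud from PLY-ascii, XYZ or CSV."""
    path = Path(path)
    if not path.exists():
        raise CloudFormatError(f"no such file: {path}")
    f = _detect_format(path, fmt)
    return {"ply": _read_ply, "xyz": _read_xyz, "csv": _read_csv}[f](path)


def write_point_cloud(path, cloud: PointCloud, fmt: str | None = None) -> None:
    """Write a point cloud; format inferred from the extension unless given.

    XYZ drops normals and labels (coordinates only, by definition of the
    format); PLY and CSV round-trip everything.
    """
    path = Path(path)
    f = _detect_format(path, fmt)
    {"ply": _write_ply, "xyz": _write_xyz, "csv": _write_csv}[f](path, cloud)


RECORD_COLUMNS = [
    "specimen", "level", "region", "group", "side", "shape", "epsilon",
    "itpr", "rmse", "seed",
]


def write_records(path, records: pd.DataFrame) -> None:
    records.to_csv(path, index=False, columns=[c for c in RECORD_COLUMNS if c in records])


def read_records(path) -> pd.DataFrame:
    """Load an ITPR record table (the schema of the study's raw-data CSVs)."""
    df = pd.read_csv(path)
    missing = [c for c in ("group", "shape", "itpr") if c not in df.columns]
    if missing:
        raise CloudFormatError(f"{path}: records CSV missing column(s) {missing}")
    return df


def write_fit_json(path, fit, config) -> None:
    payload = fit.to_dict()
    payload["config"] = {
        "shape_kind": config.shape_kind,
        "epsilon": config.epsilon,
        "iterations": config.iterations,
        "seed": config.seed,
        "refine": config.refine,
        "normal_k": config.normal_k,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
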