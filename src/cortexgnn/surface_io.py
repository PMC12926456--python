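"""Read/write surface meshes, per-vertex overlays, and parcellation labels.

Supported dialects
------------------
meshes    : FreeSurfer binary surface (triangle-file magic), OFF, PLY
overlays  : FreeSurfer "curv" (new format), plain-text one value per line
labels    : FreeSurfer annot, two-column CSV ``vertex_id,label``

FreeSurfer binary payloads are handled by :mod:`nibabel.freesurfer`; this
module adds magic-number and truncation pre-checks so that malformed files
fail with a :class:`FormatError` naming the offending byte offset, and it
converts every dialect to 0-based vertex indexing at the boundary.
"""

from __future__ import annotations

import os

import numpy as np
import nibabel.freesurfer.io as fsio

__all__ = [
    "FormatError",
    "read_surface",
    "write_surface",
    "read_overlay",
    "write_overlay",
    "read_labels",
    "write_labels",
]

_TRIANGLE_MAGIC = b"\xff\xff\xfe"  # FreeSurfer triangle surface
_CURV_MAGIC = b"\xff\xff\xff"      # FreeSurfer new-format curv


class FormatError(ValueError):
    """A file failed structural validation (bad magic, truncation, size)."""


def _check_magic(path: str | os.PathLike, expected: bytes, kind: str) -> None:
    with open(path, "rb") as fh:
        head = fh.read(3)
    if len(head) < 3:
        raise FormatError(f"{path}: truncated {kind} file at byte offset {len(head)}")
    if head != expected:
        raise FormatError(
            f"{path}: bad {kind} magic number {head!r} at byte offset 0, "
            f"expected {expected!r}"
        )


def _detect(path: str | os.PathLike) -> str:
    ext = os.path.splitext(str(path))[1].lower().lstrip(".")
    if ext in {"off", "ply"}:
        return ext
    if ext in {"csv", "txt"}:
        return ext
    if ext == "annot":
        return "annot"
    if ext in {"curv", "thickness", "sulc"}:
        return "curv"
    return "freesurfer"


def read_surface(path: str | os.PathLike, fmt: str | None = None):
    """Read a triangular mesh; returns a :class:`~cortexgnn.surface_mesh.SurfaceMesh`."""
    from .surface_mesh import SurfaceMesh

    fmt = fmt or _detect(path)
    if fmt in {"off", "ply"}:
        import trimesh

        tm = trimesh.load(str(path), file_type=fmt, process=False)
        return SurfaceMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))
    if fmt != "freesurfer":
        raise ValueError(f"unknown surface format {fmt!r}")
    _check_magic(path, _TRIANGLE_MAGIC, "surface")
    try:
        coords, faces = fsio.read_geometry(str(path))
    except Exception as exc:  # nibabel raises bare ValueError on short reads
        size = os.path.getsize(path)
        raise FormatError(f"{path}: truncated surface file (size {size} bytes): {exc}") from exc
    return SurfaceMesh(vertices=coords, faces=faces)


def write_surface(path: str | os.PathLike, mesh, fmt: str | None = None) -> None:
    fmt = fmt or _detect(path)
    if fmt in {"off", "ply"}:
        import trimesh

        tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
        tm.export(str(path), file_type=fmt)
        return
    if fmt != "freesurfer":
        raise ValueError(f"unknown surface format {fmt!r}")
    fsio.write_geometry(str(path), mesh.vertices, mesh.faces)


def _check_length(values: np.ndarray, expected_vertices: int | None, path) -> np.ndarray:
    if expected_vertices is not None and len(values) != expected_vertices:
        raise FormatError(
            f"{path}: overlay/label length {len(values)} does not match "
            f"mesh vertex count {expected_vertices}"
        )
    return values


def read_overlay(
    path: str | os.PathLike,
    expected_vertices: int | None = None,
    fmt: str | None = None,
) -> np.ndarray:
    """Read a per-vertex scalar overlay (thickness, curvature, ...)."""
    fmt = fmt or _detect(path)
    if fmt == "txt":
        values = np.loadtxt(str(path), dtype=np.float64).reshape(-1)
    else:
        _check_magic(path, _CURV_MAGIC, "curv")
        try:
            values = fsio.read_morph_data(str(path)).astype(np.float64)
        except Exception as exc:
            size = os.path.getsize(path)
            raise FormatError(f"{path}: truncated curv file (size {size} bytes): {exc}") from exc
    return _check_length(values, expected_vertices, path)


def write_overlay(path: str | os.PathLike, values: np.ndarray, fmt: str | None = None) -> None:
    values = np.asarray(values, dtype=np.float64).reshape(-1)
    fmt = fmt or _detect(path)
    if fmt == "txt":
        np.savetxt(str(path), values, fmt="%.17g")
    else:
        fsio.write_morph_data(str(path), values)


def read_labels(
    path: str | os.PathLike,
    expected_vertices: int | None = None,
    fmt: str | None = None,
) -> np.ndarray:
    """Read per-vertex integer region labels (annot or CSV)."""
    fmt = fmt or _detect(path)
    if fmt == "csv":
        import pandas as pd

        df = pd.read_csv(str(path))
        if not {"vertex_id", "label"}.issubset(df.columns):
            raise FormatError(f"{path}: label CSV must have columns vertex_id,label")
        labels = np.full(int(df["vertex_id"].max()) + 1, -1, dtype=np.int64)
        labels[df["vertex_id"].to_numpy()] = df["label"].to_numpy()
    elif fmt == "annot":
        try:
            labels, _, _ = fsio.read_annot(str(path))
        except Exception as exc:
            size = os.path.getsize(path)
            raise FormatError(f"{path}: unreadable annot file (size {size} bytes): {exc}") from exc
        labels = labels.astype(np.int64)
    else:
        raise ValueError(f"unknown label format {fmt!r}")
    return _check_length(labels, expected_vertices, path)


def write_labels(
    path: str | os.PathLike,
    labels: np.ndarray,
    region_names: list[str] | None = None,
    fmt: str | None = None,
) -> None:
    labels = np.asarray(labels, dtype=np.int64).reshape(-1)
    fmt = fmt or _detect(path)
    if fmt == "csv":
        import pandas as pd

        pd.DataFrame({"vertex_id": np.arange(len(labels)), "label": labels}).to_csv(
            str(path), index=False
        )
        return
    if fmt != "annot":
        raise ValueError(f"unknown label format {fmt!r}")
    k = int(labels.max()) + 1 if labels.size else 0
    if region_names is None:
        region_names = [f"region_{i:02d}" for i in range(k)]
    # Deterministic distinct RGB triples; alpha 0 per annot convention.
    rng = np.random.default_rng(0)
    ctab = np.zeros((k, 5), dtype=np.int64)
    seen: set[tuple[int, int, int]] = set()
    for i in range(k):
        while True:
            rgb = tuple(int(x) for x in rng.integers(0, 256, size=3))
            if rgb not in seen:
                seen.add(rgb)
                break
        ctab[i, :3] = rgb
    fsio.write_annot(str(path), labels, ctab, [n.encode() for n in region_names], fill_ctab=True)
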