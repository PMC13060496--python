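"""Readers and writers for the package's on-disk formats.

Volumes are NIfTI-1 (via nibabel); integer datatypes and affines survive
round trips exactly, and RGB volumes are stored with the channel as the
fourth dimension.  Surface meshes use the ASCII OFF format (documented
in ``docs/formats.md``) with per-vertex parcel labels in a plain-text
sidecar, one integer per line.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .metrics import SurfaceMesh


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the expected format."""


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine).

    Integer volumes come back with their stored integer dtype; float
    volumes as float64.
    """
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several types for bad files
        raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
    data = np.asanyarray(img.dataobj)
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float64)
    return data, np.asarray(img.affine, dtype=float)


def write_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a 3D (or 4D multi-channel) array as NIfTI-1, keeping the dtype."""
    data = np.asarray(data)
    if data.ndim not in (3, 4):
        raise ValueError("expected a 3D or 4D array")
    img = nib.Nifti1Image(data, np.asarray(affine, dtype=float))
    img.header.set_data_dtype(data.dtype)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# ASCII OFF meshes
# ---------------------------------------------------------------------------


def write_mesh(mesh: SurfaceMesh, path, labels_path=None) -> None:
    """Write a triangle mesh as ASCII OFF (+ optional parcel sidecar)."""
    path = Path(path)
    lines = ["OFF", f"{len(mesh.vertices)} {len(mesh.triangles)} 0"]
    for v in mesh.vertices:
        lines.append(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
    for t in mesh.triangles:
        lines.append(f"3 {t[0]} {t[1]} {t[2]}")
    path.write_text("\n".join(lines) + "\n")
    if mesh.parcels is not None:
        lp = Path(labels_path) if labels_path else path.with_suffix(".labels.txt")
        lp.write_text("\n".join(str(int(x)) for x in mesh.parcels) + "\n")


def read_mesh(path, labels_path=None) -> SurfaceMesh:
    """Read an ASCII OFF triangle mesh (+ optional parcel sidecar)."""
    path = Path(path)
    tokens = path.read_text().split()
    if not tokens or tokens[0] != "OFF":
        raise FormatError(f"{path}: missing OFF header")
    try:
        nv, nf = int(tokens[1]), int(tokens[2])
        pos = 4  # skip the (unused) edge count
        verts = np.array(tokens[pos:pos + 3 * nv], dtype=float).reshape(nv, 3)
        pos += 3 * nv
        faces = []
        for _ in range(nf):
            k = int(tokens[pos])
            if k != 3:
                raise FormatError(f"{path}: only triangle faces supported")
            faces.append([int(t) for t in tokens[pos + 1:pos + 4]])
            pos += 1 + k
        tris = np.array(faces, dtype=np.int64).reshape(nf, 3)
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: malformed OFF file ({exc})") from exc
    parcels = None
    lp = Path(labels_path) if labels_path else path.with_suffix(".labels.txt")
    if lp.exists():
        parcels = np.array(lp.read_text().split(), dtype=np.int64)
    return SurfaceMesh(verts, tris, parcels)


def make_sphere_mesh(radius: float = 10.0, subdivisions: int = 3,
                     center=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Icosphere fixture: all vertices exactly at ``radius`` from ``center``."""
    import trimesh
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    verts = np.asarray(ico.vertices, dtype=float) + np.asarray(center, dtype=float)
    return SurfaceMesh(verts, np.asarray(ico.faces, dtype=np.int64))
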