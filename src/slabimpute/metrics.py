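"""Quantitative evaluation operators.

Three families of measures quantify how well a reconstructed volume
matches a gold standard:

* region-specific Dice overlap between paired integer segmentations,
* closest-point surface distance between triangle meshes (point-to-
  triangle, not vertex-to-vertex), aggregated per cortical parcel as an
  unweighted mean of parcel means,
* cortical thickness (white-to-pial closest-point distance) and its
  per-parcel absolute error.

The operators evaluate whatever pair of segmentations or meshes they are
given; producing those inputs (segmentation networks, surface
extraction) is outside this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SegmentationVolume:
    """3D integer label volume with an affine and an ID -> name dictionary."""

    labels: np.ndarray
    affine: np.ndarray = None
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be a 3D integer array")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=float)


@dataclass
class SurfaceMesh:
    """Triangle mesh in world mm with optional per-vertex parcel labels."""

    vertices: np.ndarray
    triangles: np.ndarray
    parcels: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (N, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (M, 3)")
        if self.triangles.size and (self.triangles.min() < 0
                                    or self.triangles.max() >= len(self.vertices)):
            raise ValueError("triangle indices out of range")
        if self.parcels is not None:
            self.parcels = np.asarray(self.parcels)
            if len(self.parcels) != len(self.vertices):
                raise ValueError("parcel labels must cover all vertices")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------


def _check_same_grid(a: SegmentationVolume, b: SegmentationVolume) -> None:
    if a.labels.shape != b.labels.shape:
        raise ValueError("segmentations are on different grids (shape)")
    if not np.allclose(a.affine, b.affine, atol=1e-6):
        raise ValueError("segmentations are on different grids (affine); "
                         "resample explicitly first")


def dice_score(a: SegmentationVolume, b: SegmentationVolume, label: int) -> float:
    """Dice overlap 2|A.B| / (|A| + |B|) of one label's voxel masks.

    Convention: 1.0 when the label is absent from both volumes
    (empty-empty agreement), 0.0 when it is present in exactly one.
    """
    _check_same_grid(a, b)
    ma = a.labels == label
    mb = b.labels == label
    na, nb = int(ma.sum()), int(mb.sum())
    if na == 0 and nb == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / (na + nb)


def region_dice_table(a: SegmentationVolume, b: SegmentationVolume,
                      labels) -> pd.DataFrame:
    """Per-region Dice scores, one row per requested label (stable order)."""
    rows = []
    for lab in labels:
        lab = int(lab)
        present_a = bool((a.labels == lab).any())
        present_b = bool((b.labels == lab).any())
        score = dice_score(a, b, lab)
        rows.append({
            "label": lab,
            "name": a.names.get(lab, b.names.get(lab, str(lab))),
            "dice": score,
            "note": "empty-empty" if not (present_a or present_b) else "",
        })
    return pd.DataFrame(rows, columns=["label", "name", "dice", "note"])


def resample_labels_nearest(seg: SegmentationVolume, target_affine: np.ndarray,
                            target_shape) -> SegmentationVolume:
    """Nearest-neighbor resample onto a target grid (opt-in utility).

    Resampling changes overlap scores; callers must request it
    explicitly rather than having Dice silently align grids.
    """
    target_affine = np.asarray(target_affine, dtype=float)
    src_inv = np.linalg.inv(seg.affine)
    m = src_inv @ target_affine
    coords = np.indices(tuple(target_shape), dtype=float).reshape(3, -1)
    sample = m[:3, :3] @ coords + m[:3, 3:4]
    out = ndimage.map_coordinates(seg.labels, sample.reshape(3, *target_shape),
                                  order=0, mode="constant", cval=0)
    return SegmentationVolume(out.astype(seg.labels.dtype), target_affine,
                              dict(seg.names))


# ---------------------------------------------------------------------------
# closest-point surface distances
# ---------------------------------------------------------------------------


def _point_triangle_distance_sq(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Squared distances from points to triangles, fully vectorized.

    ``p`` is (n, 1, 3) against ``tri`` (1, m, 3, 3); returns (n, m).
    Implements the standard closest-point-on-triangle region case
    analysis (vertex / edge / face regions) with branch-free selection.
    """
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    ab, ac = b - a, c - a
    ap = p - a
    d1 = np.einsum("...i,...i->...", ab, ap)
    d2 = np.einsum("...i,...i->...", ac, ap)
    bp = p - b
    d3 = np.einsum("...i,...i->...", ab, bp)
    d4 = np.einsum("...i,...i->...", ac, bp)
    cp = p - c
    d5 = np.einsum("...i,...i->...", ab, cp)
    d6 = np.einsum("...i,...i->...", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
        w_ac = d2 / (d2 - d6)
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        denom = va + vb + vc
        v_in = vb / denom
        w_in = vc / denom
    v_ab = np.nan_to_num(v_ab)
    w_ac = np.nan_to_num(w_ac)
    w_bc = np.nan_to_num(w_bc)
    v_in = np.nan_to_num(v_in)
    w_in = np.nan_to_num(w_in)

    conds = [
        (d1 <= 0) & (d2 <= 0),                      # vertex a
        (d3 >= 0) & (d4 <= d3),                     # vertex b
        (vc <= 0) & (d1 >= 0) & (d3 <= 0),          # edge ab
        (d6 >= 0) & (d5 <= d6),                     # vertex c
        (vb <= 0) & (d2 >= 0) & (d6 <= 0),          # edge ac
        (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),  # edge bc
    ]
    closests = [
        a,
        b,
        a + v_ab[..., None] * ab,
        c,
        a + w_ac[..., None] * ac,
        b + w_bc[..., None] * (c - b),
    ]
    closest = a + v_in[..., None] * ab + w_in[..., None] * ac  # face region
    for cond, cand in zip(reversed(conds), reversed(closests)):
        closest = np.where(cond[..., None], cand, closest)
    diff = p - closest
    return np.einsum("...i,...i->...", diff, diff)


def closest_point_distances(src: SurfaceMesh, ref: SurfaceMesh,
                            chunk_points: int = 512) -> np.ndarray:
    """Per-src-vertex Euclidean distance to the nearest point on ref.

    The reference is treated as a triangle set (point-to-triangle
    distance), so distances are exact even where src vertices face the
    interior of a reference triangle.  The direction matters: this is
    src -> ref only.
    """
    if src.n_vertices == 0 or ref.n_vertices == 0 or len(ref.triangles) == 0:
        raise ValueError("meshes must be nonempty")
    tri = ref.vertices[ref.triangles][None]  # (1, m, 3, 3)
    out = np.empty(src.n_vertices)
    # chunk the vertex set: the (chunk, m) distance matrix stays small
    for s in range(0, src.n_vertices, chunk_points):
        pts = src.vertices[s:s + chunk_points, None, :]
        d2 = _point_triangle_distance_sq(pts, tri)
        out[s:s + chunk_points] = np.sqrt(d2.min(axis=1))
    return out


def mean_parcel_distance(distances: np.ndarray, parcel_labels: np.ndarray
                         ) -> tuple[pd.Series, float]:
    """Unweighted per-parcel mean distances and their grand mean.

    The grand value is the mean of parcel means (every parcel counts
    equally regardless of vertex count), matching the convention of
    averaging across labeled cortical areas.
    """
    distances = np.asarray(distances, dtype=float)
    parcel_labels = np.asarray(parcel_labels)
    if distances.shape != parcel_labels.shape:
        raise ValueError("one parcel label per distance required")
    per_parcel = pd.Series(distances).groupby(pd.Series(parcel_labels)).mean()
    per_parcel.index.name = "parcel"
    return per_parcel, float(per_parcel.mean())


def cortical_thickness(white: SurfaceMesh, pial: SurfaceMesh) -> np.ndarray:
    """Per-white-vertex thickness: closest-point distance to the pial surface."""
    return closest_point_distances(white, pial)


def thickness_error(thickness_a: np.ndarray, thickness_b: np.ndarray,
                    parcel_labels: np.ndarray) -> tuple[pd.Series, float]:
    """Per-parcel |mean_a - mean_b| thickness errors and their grand mean.

    Both thickness maps must share the same vertex set (and hence the
    same parcel labeling); comparison is parcel-mean-wise.
    """
    a = np.asarray(thickness_a, dtype=float)
    b = np.asarray(thickness_b, dtype=float)
    labels = np.asarray(parcel_labels)
    if not (a.shape == b.shape == labels.shape):
        raise ValueError("thickness maps and parcel labels must align")
    ma = pd.Series(a).groupby(pd.Series(labels)).mean()
    mb = pd.Series(b).groupby(pd.Series(labels)).mean()
    err = (ma - mb).abs()
    err.index.name = "parcel"
    return err, float(err.mean())
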