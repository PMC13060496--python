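"""Volume-level inference: from an anisotropic slice stack to an
isotropic volume.

An anisotropic reconstruction is an ordered stack of observed 2D coronal
slices with known (possibly non-uniform) anterior-posterior world
coordinates in mm.  Imputation places an arithmetic grid of target
coordinates (default spacing 1 mm) across the observed span; each target
strictly between two observed slices is predicted from its bounding pair
and the distances to each, while targets coinciding with observed
coordinates (within a small tolerance) copy the observed slice verbatim.
Multi-channel (RGB) stacks are processed channel by channel with
identical queries.

The method never extrapolates: the output grid spans exactly
[first, last] observed coordinate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import ImputationQuery, impute_slice, linear_interpolate
from .nn import UNet

logger = logging.getLogger(__name__)

PASSTHROUGH_TOL_MM = 1e-6


@dataclass
class ReconstructionVolume:
    """Ordered stack of observed slices with per-slice AP coordinates (mm).

    ``slices`` has shape (n_slices, H, W) or (n_slices, H, W, n_channels);
    ``ap_coords`` is strictly increasing.  ``affine`` maps in-plane voxel
    indices to world mm (the AP position comes from ``ap_coords``).
    """

    slices: np.ndarray
    ap_coords: np.ndarray
    affine: np.ndarray = None

    def __post_init__(self):
        self.slices = np.asarray(self.slices, dtype=float)
        self.ap_coords = np.asarray(self.ap_coords, dtype=float)
        if self.slices.ndim not in (3, 4):
            raise ValueError("slices must be (n, H, W) or (n, H, W, C)")
        if self.ap_coords.ndim != 1 or len(self.ap_coords) != self.slices.shape[0]:
            raise ValueError("one AP coordinate per slice required")
        if len(self.ap_coords) < 2:
            raise ValueError("need at least two observed slices")
        if not (np.diff(self.ap_coords) > 0).all():
            raise ValueError("AP coordinates must be strictly increasing")
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_channels(self) -> int:
        return 1 if self.slices.ndim == 3 else self.slices.shape[3]

    def channel(self, c: int) -> np.ndarray:
        if self.slices.ndim == 3:
            if c != 0:
                raise IndexError("single-channel volume")
            return self.slices
        return self.slices[..., c]


@dataclass
class PlanEntry:
    """One output coordinate: its bounding observed slices and distances."""

    target_mm: float
    anterior_index: int
    posterior_index: int
    d1: float
    d2: float
    passthrough: bool


@dataclass
class ImputationPlan:
    """The full arithmetic target grid for one reconstruction."""

    entries: list[PlanEntry]
    spacing_mm: float

    def __len__(self) -> int:
        return len(self.entries)


def plan_imputation_grid(recon: ReconstructionVolume,
                         spacing_mm: float = 1.0,
                         tol_mm: float = PASSTHROUGH_TOL_MM) -> ImputationPlan:
    """Place targets at fixed spacing across the observed AP span.

    The grid is aligned at the first observed slice and spans
    [first, last] inclusive.  Each target is bound by the nearest
    observed slices below and above; targets within ``tol_mm`` of an
    observed coordinate are flagged passthrough.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    coords = recon.ap_coords
    first, last = coords[0], coords[-1]
    n_targets = int(np.floor((last - first) / spacing_mm + tol_mm)) + 1
    entries = []
    for k in range(n_targets):
        t = first + k * spacing_mm
        # nearest observed slice at-or-below; the next one bounds above
        i = int(np.searchsorted(coords, t + tol_mm) - 1)
        i = min(max(i, 0), len(coords) - 2)
        j = i + 1
        near = np.abs(coords - t)
        nearest = int(np.argmin(near))
        if near[nearest] <= tol_mm:
            entries.append(PlanEntry(t, nearest, nearest, 0.0, 0.0, True))
        else:
            entries.append(PlanEntry(t, i, j, float(t - coords[i]),
                                     float(coords[j] - t), False))
    return ImputationPlan(entries, spacing_mm)


def impute_volume(recon: ReconstructionVolume, net: UNet,
                  spacing_mm: float = 1.0, *,
                  clip: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Impute slices on a uniform AP grid and assemble the isotropic volume.

    Observed slices reappear bit-exactly at their own coordinates; every
    other target is the residual-corrected prediction from its bounding
    pair, computed independently per channel.  Returns ``(volume,
    affine)`` where the volume has shape (H, W, n_targets[, C]) and the
    affine equals the reconstruction's in-plane affine with the AP voxel
    size set to ``spacing_mm`` (AP origin at the first observed slice).
    """
    plan = plan_imputation_grid(recon, spacing_mm)
    lo_t, hi_t = 2.0, 12.0
    thicknesses = {round(e.d1 + e.d2, 9) for e in plan.entries if not e.passthrough}
    outside = sorted(t for t in thicknesses if not lo_t <= t <= hi_t)
    if outside:
        logger.warning("slab thicknesses %s mm outside the trained range "
                       "[%g, %g] mm; imputing anyway", outside, lo_t, hi_t)
    h, w = recon.slices.shape[1:3]
    nc = recon.n_channels
    shape = (h, w, len(plan)) if nc == 1 else (h, w, len(plan), nc)
    out = np.empty(shape)
    for k, e in enumerate(plan.entries):
        if e.passthrough:
            sl = recon.slices[e.anterior_index]
            out[:, :, k] = sl if nc > 1 else sl
            continue
        for c in range(nc):
            q = ImputationQuery(recon.channel(c)[e.anterior_index],
                                recon.channel(c)[e.posterior_index],
                                e.d1, e.d2)
            pred = impute_slice(q, net, clip=clip)
            if nc == 1:
                out[:, :, k] = pred
            else:
                out[:, :, k, c] = pred
    affine = recon.affine.copy()
    ap_dir = affine[:3, 2]
    nrm = np.linalg.norm(ap_dir)
    affine[:3, 2] = (ap_dir / nrm if nrm > 0 else [0, 0, 1]) * spacing_mm
    affine[:3, 3] = affine[:3, 3] + affine[:3, 2] / spacing_mm * recon.ap_coords[0]
    return out, affine


def linear_volume(recon: ReconstructionVolume,
                  spacing_mm: float = 1.0) -> np.ndarray:
    """Purely linear (zero-residual) reconstruction on the same grid."""
    plan = plan_imputation_grid(recon, spacing_mm)
    h, w = recon.slices.shape[1:3]
    nc = recon.n_channels
    shape = (h, w, len(plan)) if nc == 1 else (h, w, len(plan), nc)
    out = np.empty(shape)
    for k, e in enumerate(plan.entries):
        if e.passthrough:
            out[:, :, k] = recon.slices[e.anterior_index]
            continue
        for c in range(nc):
            q = ImputationQuery(recon.channel(c)[e.anterior_index],
                                recon.channel(c)[e.posterior_index],
                                e.d1, e.d2)
            if nc == 1:
                out[:, :, k] = linear_interpolate(q)
            else:
                out[:, :, k, c] = linear_interpolate(q)
    return out


def decimate_volume(volume: np.ndarray, thickness_mm: float,
                    spacing_mm: float = 1.0,
                    affine: np.ndarray | None = None) -> ReconstructionVolume:
    """Subsample an isotropic volume into a thick-slab reconstruction.

    Keeps every k-th coronal slice (k = thickness / spacing, which must
    be a positive integer multiple) and records their AP coordinates;
    used to build matched anisotropic/isotropic evaluation pairs.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim not in (3, 4):
        raise ValueError("expected (H, W, D) or (H, W, D, C) volume")
    ratio = thickness_mm / spacing_mm
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-9:
        raise ValueError(f"thickness {thickness_mm} must be a positive "
                         f"multiple of the spacing {spacing_mm}")
    idx = np.arange(0, volume.shape[2], k)
    slices = np.moveaxis(volume[:, :, idx], 2, 0)
    coords = idx * spacing_mm
    return ReconstructionVolume(slices, coords,
                                affine if affine is not None else np.eye(4))
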