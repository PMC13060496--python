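"""Procedural label-map phantoms.

The synthesis pipeline only needs label geometry with cortex-like
folding to exercise every code path, not real anatomy.  The phantom is a
set of nested ellipsoidal shells — an outer folded ribbon standing in
for cortex, an interior bulk for white matter, and an optional central
cavity for the ventricle — whose outer boundary is perturbed by smooth
sinusoidal "folds" so that coarse through-plane sampling visibly
degrades it, mirroring how thick slabs break up the real cortical
ribbon.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import LabelVolume


@dataclass
class PhantomSpec:
    """Parameters of the procedural phantom.

    ``grid_shape`` is in voxels at ``voxel_mm`` isotropic resolution (the
    third axis is anterior-posterior and must span more than 12 mm so a
    maximal slab fits).  ``n_labels`` counts background: 3 gives
    {0: background, 1: outer shell, 2: core}; 4 adds a central cavity.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 80)
    voxel_mm: float = 1.0
    n_labels: int = 4
    fold_amplitude: float = 0.09
    fold_frequency: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.n_labels < 3:
            raise ValueError("need at least 3 labels (background, shell, core)")
        if self.n_labels > 4:
            raise ValueError("the nested-shell phantom defines at most 4 labels")
        if self.grid_shape[2] * self.voxel_mm <= 12:
            raise ValueError("AP extent must exceed 12 mm")
        if min(self.grid_shape) < 16:
            raise ValueError("grid too small for the nested-shell structure")


def generate_phantom(spec: PhantomSpec) -> LabelVolume:
    """Build the folded nested-shell label volume for ``spec``.

    The outer shell occupies normalized radii [0.72, 1] of a folded
    ellipsoid, the core everything inside, and (with 4 labels) the
    cavity the innermost 28%.  Fold phases and mild semi-axis jitter are
    drawn from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.grid_shape
    # normalized coordinates in [-1, 1] per axis
    x, y, z = np.meshgrid(np.linspace(-1, 1, nx), np.linspace(-1, 1, ny),
                          np.linspace(-1, 1, nz), indexing="ij")
    semi = 0.82 + 0.06 * rng.uniform(-1, 1, size=3)
    xs, ys, zs = x / semi[0], y / semi[1], z / semi[2]
    r = np.sqrt(xs ** 2 + ys ** 2 + zs ** 2)

    theta = np.arctan2(ys, xs)
    phi = np.arctan2(zs, np.sqrt(xs ** 2 + ys ** 2))
    f = spec.fold_frequency
    phase = rng.uniform(0, 2 * np.pi, size=3)
    folds = (np.sin(f * theta + phase[0]) * np.cos(f * phi + phase[1])
             + 0.6 * np.sin((f + 2) * phi + phase[2]))
    rho = 1.0 + spec.fold_amplitude * folds  # folded outer boundary
    rn = r / rho

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    labels[rn < 1.0] = 1                       # outer (cortex-like) shell
    labels[rn < 0.72] = 2                      # core (white-matter-like)
    if spec.n_labels >= 4:
        labels[rn < 0.28] = 3                  # central cavity (ventricle-like)
    affine = np.diag([spec.voxel_mm] * 3 + [1.0])
    return LabelVolume(labels, affine)
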