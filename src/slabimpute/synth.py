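"""Domain-randomized synthetic pseudo-photograph generator.

Training data for the slice-imputation network is produced entirely on the
fly from 3D label maps (integer segmentations).  Each synthetic volume is
built in four stages:

1. geometric augmentation — a random affine (rotation, anisotropic scale,
   shear, translation) composed with a smooth random displacement field
   that varies *faster* along the anterior-posterior (AP) axis, emulating
   the imperfect through-plane alignment of reconstructed photograph
   stacks;
2. GMM synthesis — every voxel's intensity is drawn from a Gaussian whose
   mean and standard deviation depend only on the voxel's label, with the
   per-label parameters themselves randomized per volume;
3. gamma augmentation — min-max normalization to [0, 1] followed by a
   random power, skewing the intensity histogram;
4. illumination — multiplication by a smooth, strictly positive gain
   field, again rougher along AP, emulating uneven lighting across slabs.

"Digital slabbing" then cuts training triplets out of the synthetic
volume: two coronal slices a random thickness d in [2, 12] mm apart and a
target slice at a random intermediate coordinate.

All sampling is driven by an explicit ``numpy.random.Generator``; replay
with the same seed is bit-identical.  The AP axis is voxel axis 2 by
convention, and the synthetic grid is 1 mm isotropic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

AP_AXIS = 2


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class LabelVolume:
    """3D integer segmentation with a voxel-to-world affine (mm).

    Label 0 is background.  The anterior-posterior axis is voxel axis 2.
    """

    labels: np.ndarray
    affine: np.ndarray = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or not np.isfinite(self.affine).all():
            raise ValueError("affine must be a finite 4x4 matrix")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def label_ids(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass
class GMMParams:
    """Per-label Gaussian intensity parameters (mean, sd >= 0)."""

    means: dict[int, float]
    sds: dict[int, float]

    def __post_init__(self):
        if set(self.means) != set(self.sds):
            raise ValueError("means and sds must cover the same labels")
        if any(s < 0 for s in self.sds.values()):
            raise ValueError("standard deviations must be nonnegative")


@dataclass
class DeformationField:
    """Dense displacement field (mm) over the volume grid, shape (3, X, Y, Z)."""

    displacement: np.ndarray
    correlation_mm: tuple[float, float, float] = (20.0, 20.0, 5.0)

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 4 or self.displacement.shape[0] != 3:
            raise ValueError("displacement must have shape (3, X, Y, Z)")
        if not np.isfinite(self.displacement).all():
            raise ValueError("displacement must be finite")


@dataclass
class IlluminationField:
    """Smooth, strictly positive multiplicative gain field."""

    gain: np.ndarray

    def __post_init__(self):
        self.gain = np.asarray(self.gain, dtype=float)
        if (self.gain <= 0).any():
            raise ValueError("illumination gain must be strictly positive")


@dataclass
class SlabTriplet:
    """One training sample: bounding slices x1 (anterior), x2 (posterior),
    target y between them, and the mm distances d1 = |y - x1|, d2 = |y - x2|."""

    x1: np.ndarray
    x2: np.ndarray
    y: np.ndarray
    d1: float
    d2: float

    def __post_init__(self):
        if not (self.x1.shape == self.x2.shape == self.y.shape):
            raise ValueError("triplet slices must share one in-plane shape")
        if self.d1 < 0 or self.d2 < 0:
            raise ValueError("distances must be nonnegative")

    @property
    def thickness(self) -> float:
        return self.d1 + self.d2


@dataclass
class SynthConfig:
    """Randomization ranges of the generator.

    The published description of the generator leaves every numeric range
    open; the defaults below follow the conventions of the SynthSeg family
    of generators and are all overridable (and YAML-serializable).  Ranges
    are inclusive ``(low, high)`` pairs; a degenerate range ``(v, v)``
    pins the value.
    """

    rotation_deg: tuple[float, float] = (-15.0, 15.0)
    scale: tuple[float, float] = (0.85, 1.15)
    shear: tuple[float, float] = (-0.1, 0.1)
    translation_mm: tuple[float, float] = (-10.0, 10.0)
    # nonlinear deformation: component sd in mm, per-axis correlation lengths;
    # AP correlation is deliberately the shortest (faster variation along AP)
    nonlinear_sd_mm: float = 4.0
    nonlinear_corr_mm: tuple[float, float, float] = (20.0, 20.0, 5.0)
    # GMM intensity randomization
    gmm_mean: tuple[float, float] = (0.0, 255.0)
    gmm_sd: tuple[float, float] = (0.0, 25.0)
    # gamma exponent is exp(U(log_gamma)); (0, 0) pins gamma = 1
    log_gamma: tuple[float, float] = (-0.3, 0.3)
    # illumination gain = exp(field with given sd), same anisotropy rule
    illumination_sd: float = 0.2
    illumination_corr_mm: tuple[float, float, float] = (32.0, 32.0, 8.0)
    # digital slabbing
    thickness_mm: tuple[float, float] = (2.0, 12.0)
    minibatch: int = 32

    def __post_init__(self):
        for name in ("rotation_deg", "scale", "shear", "translation_mm",
                     "gmm_mean", "gmm_sd", "log_gamma", "thickness_mm"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name}: empty range ({lo}, {hi})")
        if self.nonlinear_sd_mm < 0:
            raise ValueError("nonlinear_sd_mm must be nonnegative")
        if self.minibatch < 1:
            raise ValueError("minibatch must be >= 1")

    @classmethod
    def identity(cls, **overrides) -> "SynthConfig":
        """A configuration with all randomization disabled."""
        base = dict(rotation_deg=(0.0, 0.0), scale=(1.0, 1.0),
                    shear=(0.0, 0.0), translation_mm=(0.0, 0.0),
                    nonlinear_sd_mm=0.0, log_gamma=(0.0, 0.0),
                    illumination_sd=0.0)
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------


def _uniform(rng: np.random.Generator, rng_pair) -> float:
    lo, hi = rng_pair
    if lo == hi:
        return float(lo)
    return float(rng.uniform(lo, hi))


def sample_affine(rng: np.random.Generator, config: SynthConfig) -> np.ndarray:
    """Draw a random 4x4 affine: translation . rotation . shear . scale.

    Angles, scales, shears and translations are drawn uniformly and
    independently per axis from the configured ranges.  Degenerate ranges
    collapse to constants, so the identity configuration returns the
    identity matrix exactly.
    """
    ang = np.deg2rad([_uniform(rng, config.rotation_deg) for _ in range(3)])
    sc = [_uniform(rng, config.scale) for _ in range(3)]
    sh = [_uniform(rng, config.shear) for _ in range(3)]
    tr = [_uniform(rng, config.translation_mm) for _ in range(3)]

    cx, cy, cz = np.cos(ang)
    sx, sy, sz = np.sin(ang)
    rot_x = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    rot_y = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rot_z = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    shear = np.array([[1, sh[0], sh[1]], [0, 1, sh[2]], [0, 0, 1]])
    scale = np.diag(sc)

    out = np.eye(4)
    out[:3, :3] = rot_x @ rot_y @ rot_z @ shear @ scale
    out[:3, 3] = tr
    logger.debug("sampled affine: angles=%s scale=%s shear=%s trans=%s",
                 np.rad2deg(ang).round(3), sc, sh, tr)
    return out


def sample_smooth_field(rng: np.random.Generator, grid_shape, sd: float,
                        corr_mm, n_components: int = 1) -> np.ndarray:
    """Smooth zero-mean random scalar/vector field with per-axis correlation.

    White noise is drawn on a coarse grid whose spacing equals the per-axis
    correlation length and linearly upsampled, so the field's
    autocorrelation half-width along each axis tracks the requested length.
    The result is rescaled to the requested pointwise standard deviation.
    Returns shape ``(n_components, *grid_shape)``.
    """
    grid_shape = tuple(grid_shape)
    if len(grid_shape) != 3:
        raise ValueError("grid_shape must be 3D")
    if sd < 0:
        raise ValueError("field sd must be nonnegative")
    if sd == 0:
        return np.zeros((n_components,) + grid_shape)
    coarse = tuple(max(2, int(np.ceil(s / c)) + 1)
                   for s, c in zip(grid_shape, corr_mm))
    out = np.empty((n_components,) + grid_shape)
    for k in range(n_components):
        noise = rng.standard_normal(coarse)
        zoom = [g / c for g, c in zip(grid_shape, coarse)]
        smooth = ndimage.zoom(noise, zoom, order=1, mode="nearest",
                              grid_mode=True)
        smooth = smooth[:grid_shape[0], :grid_shape[1], :grid_shape[2]]
        s = smooth.std()
        out[k] = smooth * (sd / s) if s > 0 else 0.0
    return out


def sample_nonlinear_field(rng: np.random.Generator, grid_shape,
                           config: SynthConfig) -> DeformationField:
    """Random smooth displacement field, rougher along the AP axis."""
    corr = config.nonlinear_corr_mm
    if not (corr[AP_AXIS] < corr[0] and corr[AP_AXIS] < corr[1]):
        raise ValueError("AP correlation length must be shorter than in-plane")
    disp = sample_smooth_field(rng, grid_shape, config.nonlinear_sd_mm,
                               corr, n_components=3)
    return DeformationField(disp, correlation_mm=tuple(corr))


def sample_illumination(rng: np.random.Generator, grid_shape,
                        config: SynthConfig) -> IlluminationField:
    """Multiplicative gain exp(smooth field); strictly positive by construction."""
    corr = config.illumination_corr_mm
    if not (corr[AP_AXIS] < corr[0] and corr[AP_AXIS] < corr[1]):
        raise ValueError("AP correlation length must be shorter than in-plane")
    logf = sample_smooth_field(rng, grid_shape, config.illumination_sd, corr)[0]
    return IlluminationField(np.exp(logf))


def sample_gmm_params(rng: np.random.Generator, labels, config: SynthConfig) -> GMMParams:
    """Randomize one (mean, sd) pair per label present in ``labels``."""
    ids = [int(v) for v in np.unique(labels)]
    means = {i: _uniform(rng, config.gmm_mean) for i in ids}
    sds = {i: _uniform(rng, config.gmm_sd) for i in ids}
    logger.debug("sampled GMM params: means=%s sds=%s", means, sds)
    return GMMParams(means, sds)


# ---------------------------------------------------------------------------
# volume synthesis
# ---------------------------------------------------------------------------


def deform_labels(vol: LabelVolume, affine: np.ndarray,
                  deformation: DeformationField | None = None) -> LabelVolume:
    """Geometrically augment a label volume (nearest-neighbor resampling).

    The affine acts about the volume center in voxel/mm coordinates (the
    synthesis grid is 1 mm isotropic); the displacement field is added to
    the pull-back sampling coordinates.  Vacated voxels become background,
    and no new label can appear (labels are categorical).
    """
    shape = vol.labels.shape
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    center = (np.array(shape, dtype=float) - 1) / 2
    coords = np.indices(shape, dtype=float)
    rel = coords - center[:, None, None, None]
    sample = np.einsum("ij,jxyz->ixyz", inv[:3, :3], rel) \
        + (inv[:3, 3] + center)[:, None, None, None]
    if deformation is not None:
        if deformation.displacement.shape[1:] != shape:
            raise ValueError("deformation field grid does not match volume")
        sample = sample + deformation.displacement
    out = ndimage.map_coordinates(vol.labels, sample, order=0,
                                  mode="constant", cval=0)
    return LabelVolume(out.astype(vol.labels.dtype), vol.affine.copy())


def synthesize_intensity(vol: LabelVolume, gmm: GMMParams,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw each voxel's intensity from the Gaussian of its label."""
    present = set(int(v) for v in vol.label_ids)
    missing = present - set(gmm.means)
    if missing:
        raise ValueError(f"labels without GMM parameters: {sorted(missing)}")
    top = max(present)
    mean_lut = np.zeros(top + 1)
    sd_lut = np.zeros(top + 1)
    for i in present:
        mean_lut[i] = gmm.means[i]
        sd_lut[i] = gmm.sds[i]
    img = mean_lut[vol.labels] + sd_lut[vol.labels] * rng.standard_normal(vol.labels.shape)
    return img


def gamma_augment(img: np.ndarray, rng: np.random.Generator,
                  config: SynthConfig) -> np.ndarray:
    """Min-max normalize to [0, 1] and raise to a random exponent.

    The power transform is monotone, so intensity ranks are preserved.  A
    constant input has no dynamic range; it maps to all zeros by
    convention (logged).
    """
    img = np.asarray(img, dtype=float)
    if not np.isfinite(img).all():
        raise ValueError("input intensities must be finite")
    lo, hi = img.min(), img.max()
    if hi == lo:
        logger.warning("gamma_augment: constant input volume; returning zeros")
        return np.zeros_like(img)
    gamma = np.exp(_uniform(rng, config.log_gamma))
    logger.debug("sampled gamma exponent: %.4f", gamma)
    return ((img - lo) / (hi - lo)) ** gamma


def apply_illumination(img: np.ndarray, field: IlluminationField) -> np.ndarray:
    """Elementwise product of the image with a positive gain field."""
    if field.gain.shape != img.shape:
        raise ValueError("illumination field grid does not match volume")
    return img * field.gain


def generate_synthetic_volume(vol: LabelVolume, rng: np.random.Generator,
                              config: SynthConfig | None = None
                              ) -> tuple[np.ndarray, LabelVolume]:
    """Full synthesis pipeline: deform -> GMM -> gamma -> illumination.

    Returns the synthetic intensity volume together with the deformed
    label map (the labels remain useful downstream as evaluation
    fixtures).
    """
    config = config or SynthConfig()
    affine = sample_affine(rng, config)
    if config.nonlinear_sd_mm > 0:
        nl = sample_nonlinear_field(rng, vol.labels.shape, config)
    else:
        nl = None
    deformed = deform_labels(vol, affine, nl)
    gmm = sample_gmm_params(rng, deformed.labels, config)
    img = synthesize_intensity(deformed, gmm, rng)
    img = gamma_augment(img, rng, config)
    if config.illumination_sd > 0:
        illum = sample_illumination(rng, img.shape, config)
        img = apply_illumination(img, illum)
    return img, deformed


# ---------------------------------------------------------------------------
# digital slabbing
# ---------------------------------------------------------------------------


def extract_slice(volume: np.ndarray, ap_coord: float) -> np.ndarray:
    """Coronal slice at a continuous AP coordinate (linear interpolation).

    The volume grid is 1 mm isotropic, so slice k lives at AP coordinate
    k mm; intermediate coordinates blend the two neighboring slices.
    """
    n_ap = volume.shape[AP_AXIS]
    if ap_coord < 0 or ap_coord > n_ap - 1:
        raise ValueError(f"AP coordinate {ap_coord} outside volume [0, {n_ap - 1}]")
    k = int(np.floor(ap_coord))
    f = ap_coord - k
    if f == 0.0:
        return volume[:, :, k].astype(float, copy=True)
    return (1.0 - f) * volume[:, :, k] + f * volume[:, :, k + 1]


def digital_slab_sample(volume: np.ndarray, rng: np.random.Generator,
                        config: SynthConfig | None = None) -> SlabTriplet:
    """Cut one random training triplet out of a synthetic volume.

    A slab thickness d is drawn uniformly from the configured range
    (default [2, 12] mm) and an anterior face coordinate a such that the
    slab fits inside the volume; the target lies at a + d1 with d1 drawn
    uniformly in (0, d).
    """
    config = config or SynthConfig()
    n_ap = volume.shape[AP_AXIS]
    lo, hi = config.thickness_mm
    if n_ap - 1 <= hi:
        raise ValueError(f"volume AP extent {n_ap - 1} mm too small for "
                         f"slab thickness up to {hi} mm")
    d = _uniform(rng, config.thickness_mm)
    a = rng.uniform(0.0, (n_ap - 1) - d)
    d1 = rng.uniform(0.0, d)
    x1 = extract_slice(volume, a)
    x2 = extract_slice(volume, a + d)
    y = extract_slice(volume, a + d1)
    logger.debug("sampled slab: a=%.3f d=%.3f d1=%.3f", a, d, d1)
    return SlabTriplet(x1=x1, x2=x2, y=y, d1=d1, d2=d - d1)


def make_minibatch(volume: np.ndarray, rng: np.random.Generator,
                   config: SynthConfig | None = None) -> list[SlabTriplet]:
    """Sample ``config.minibatch`` (default 32) triplets from one volume."""
    config = config or SynthConfig()
    return [digital_slab_sample(volume, rng, config)
            for _ in range(config.minibatch)]
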