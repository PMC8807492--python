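"""Synthetic MR-microscopy phantoms with paired ground-truth label maps.

A phantom mimics the qualitative contrasts of an ex vivo high-field
acquisition of a tumor implant: bright, fairly uniform tumor lobules packed
inside a tissue envelope ("cauliflower" morphology), darker and spatially
heterogeneous stroma filling the space between lobules, an optional
peripheral fat rim, small zero-signal void structures (glandular lumens,
psammoma bodies, hyaline foci), a smooth multiplicative bias field, and
additive Gaussian or Rician magnitude noise.  The label map is generated on
the same grid, perfectly registered; a misalignment injector exists to
stress-test downstream robustness.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import BACKGROUND, FAT, STROMA, TUMOR, VOID, IntensityVolume, LabelMap


class PhantomConfigError(ValueError):
    """Raised for contradictory or out-of-range phantom parameters."""


@dataclass
class PhantomConfig:
    """Parameters of the synthetic image / label-map pair.

    Texture scales are fractional heterogeneity amplitudes: a region with
    mean ``m`` and scale ``s`` has intensity ``m * (1 + s * n)`` where ``n``
    is unit-variance band-limited spatial noise.  Defaults give stroma a
    much rougher texture than tumor and a lower mean signal.
    """

    image_shape: tuple[int, ...] = (128, 128)
    voxel_spacing: tuple[float, ...] = (90.0, 90.0)
    n_lobules: int = 30
    lobule_radius_range: tuple[float, float] = (6.0, 14.0)
    tumor_mean_si: float = 120.0
    stroma_mean_si: float = 60.0
    fat_mean_si: float = 25.0
    tumor_texture_scale: float = 0.05
    stroma_texture_scale: float = 0.35
    texture_corr_length: float = 1.2
    n_voids: int = 6
    void_radius_range: tuple[float, float] = (1.0, 2.5)
    fat_band_px: int = 4
    target_stroma_fraction: float | None = 0.5
    bias_field_amplitude: float = 0.15
    bias_field_kind: str = "gaussian"
    noise_sigma: float = 4.0
    noise_model: str = "rician"
    misalignment_amplitude: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        shape = tuple(int(n) for n in self.image_shape)
        if len(shape) not in (2, 3):
            raise PhantomConfigError("image_shape must be 2D or 3D")
        if any(n < 32 for n in shape[-2:]):
            raise PhantomConfigError("in-plane axes must be >= 32 pixels")
        if len(self.voxel_spacing) != len(shape):
            raise PhantomConfigError("voxel_spacing rank must match image_shape")
        if any(s <= 0 for s in self.voxel_spacing):
            raise PhantomConfigError("voxel_spacing must be positive")
        for m in (self.tumor_mean_si, self.stroma_mean_si, self.fat_mean_si):
            if m < 0:
                raise PhantomConfigError("mean signal intensities must be >= 0")
        lo, hi = self.lobule_radius_range
        if not (0 < lo <= hi):
            raise PhantomConfigError("lobule_radius_range must satisfy 0 < lo <= hi")
        if hi >= min(shape[-2:]) / 2:
            raise PhantomConfigError("lobule radius exceeds half the image extent")
        if self.noise_model not in ("gaussian", "rician"):
            raise PhantomConfigError(f"unknown noise_model {self.noise_model!r}")
        if self.bias_field_kind not in ("gaussian", "linear"):
            raise PhantomConfigError(f"unknown bias_field_kind {self.bias_field_kind!r}")
        if self.noise_sigma < 0 or self.bias_field_amplitude < 0:
            raise PhantomConfigError("noise_sigma and bias_field_amplitude must be >= 0")
        if not 0 <= self.bias_field_amplitude < 1:
            raise PhantomConfigError("bias_field_amplitude must lie in [0, 1)")
        if self.target_stroma_fraction is not None and not (
            0 < self.target_stroma_fraction < 1
        ):
            raise PhantomConfigError("target_stroma_fraction must lie in (0, 1)")
        if self.misalignment_amplitude < 0:
            raise PhantomConfigError("misalignment_amplitude must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def _band_limited_noise(shape, corr_length, rng) -> np.ndarray:
    """Smoothed white noise, rescaled to zero mean / unit variance."""
    raw = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(raw, sigma=corr_length)
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return (smooth - smooth.mean()) / sd


def make_bias_field(
    shape: tuple[int, ...],
    amplitude: float,
    kind: str = "gaussian",
    seed: int = 0,
) -> np.ndarray:
    """Smooth strictly positive multiplicative field with values in
    ``[1 - amplitude, 1 + amplitude]``.

    ``kind='linear'`` ramps along the last axis (useful for recovery tests
    with a known ground truth); ``kind='gaussian'`` is a broad random blob.
    """
    if amplitude == 0:
        return np.ones(shape)
    if kind == "linear":
        ramp = np.linspace(-1.0, 1.0, shape[-1])
        field = np.broadcast_to(ramp, shape).copy()
    elif kind == "gaussian":
        rng = np.random.default_rng(seed)
        raw = rng.standard_normal(shape)
        sigma = [max(n / 4.0, 1.0) for n in shape]
        field = ndimage.gaussian_filter(raw, sigma=sigma)
        peak = np.abs(field).max()
        field = field / peak if peak > 0 else field
    else:
        raise PhantomConfigError(f"unknown bias field kind {kind!r}")
    return 1.0 + amplitude * field


def generate_phantom(config: PhantomConfig) -> tuple[IntensityVolume, LabelMap]:
    """Build one co-registered (image, label map) pair.

    Deterministic: identical config (including seed) gives bit-identical
    arrays.  The applied bias field is stored in ``volume.meta['bias_field']``
    so preprocessing recovery can be validated against ground truth.
    """
    config.validate()
    shape = tuple(int(n) for n in config.image_shape)
    rng = np.random.default_rng(config.seed)

    # Tissue envelope: centred ellipse/ellipsoid spanning most of the grid.
    center = tuple((n - 1) / 2.0 for n in shape)
    envelope = _ellipsoid_mask(shape, center, tuple(0.44 * n for n in shape))

    interior = envelope
    fat = np.zeros(shape, dtype=bool)
    if config.fat_band_px > 0:
        # erode in-plane only, so thin 3D stacks keep their interior
        structure = np.ones((1,) * (len(shape) - 2) + (3, 3), dtype=bool)
        eroded = ndimage.binary_erosion(
            envelope, structure=structure, iterations=config.fat_band_px
        )
        fat = envelope & ~eroded
        interior = eroded

    n_interior = int(interior.sum())
    if n_interior == 0:
        raise PhantomConfigError("tissue interior is empty; reduce fat_band_px")

    # Pack tumor lobules until the requested stroma fraction is reached
    # (or exactly n_lobules when no target is set).
    tumor = np.zeros(shape, dtype=bool)
    lo, hi = config.lobule_radius_range
    target = config.target_stroma_fraction
    max_tries = max(20 * config.n_lobules, 200)
    placed = 0
    for _ in range(max_tries):
        if target is None and placed >= config.n_lobules:
            break
        if target is not None:
            tumor_frac = tumor.sum() / n_interior
            if tumor_frac >= 1.0 - target:
                break
        c = tuple(rng.uniform(0, n - 1) for n in shape)
        if not interior[tuple(int(round(x)) for x in c)]:
            continue
        radii = tuple(rng.uniform(lo, hi) for _ in shape)
        tumor |= _ellipsoid_mask(shape, c, radii)
        placed += 1
    tumor &= interior
    stroma = interior & ~tumor

    labels = np.full(shape, BACKGROUND, dtype=np.uint8)
    labels[stroma] = STROMA
    labels[tumor] = TUMOR
    labels[fat] = FAT

    # Zero-signal structures (lumens, psammoma bodies, hyaline foci).
    vlo, vhi = config.void_radius_range
    for _ in range(config.n_voids):
        c = tuple(rng.uniform(0, n - 1) for n in shape)
        if not interior[tuple(int(round(x)) for x in c)]:
            continue
        radii = tuple(rng.uniform(vlo, vhi) for _ in shape)
        labels[_ellipsoid_mask(shape, c, radii) & interior] = VOID

    # Clean image: region means modulated by band-limited texture noise.
    texture = _band_limited_noise(shape, config.texture_corr_length, rng)
    img = np.zeros(shape, dtype=np.float64)
    for lab, mean, scale in (
        (TUMOR, config.tumor_mean_si, config.tumor_texture_scale),
        (STROMA, config.stroma_mean_si, config.stroma_texture_scale),
        (FAT, config.fat_mean_si, 0.05),
    ):
        sel = labels == lab
        img[sel] = mean * (1.0 + scale * texture[sel])
    np.clip(img, 0.0, None, out=img)
    # VOID and BACKGROUND stay exactly zero before bias and noise.

    bias = make_bias_field(
        shape, config.bias_field_amplitude, config.bias_field_kind, seed=config.seed + 1
    )
    img = img * bias

    if config.noise_sigma > 0:
        if config.noise_model == "gaussian":
            img = img + config.noise_sigma * rng.standard_normal(shape)
        else:  # rician magnitude noise
            n1 = config.noise_sigma * rng.standard_normal(shape)
            n2 = config.noise_sigma * rng.standard_normal(shape)
            img = np.sqrt((img + n1) ** 2 + n2**2)

    mask = labels != BACKGROUND
    spacing = tuple(float(s) for s in config.voxel_spacing)
    vol = IntensityVolume(
        img,
        spacing,
        mask,
        meta={"bias_field": bias, "phantom_config": config.to_dict()},
    )
    lmap = LabelMap(labels, spacing)
    if config.misalignment_amplitude > 0:
        lmap = inject_misalignment(
            lmap, config.misalignment_amplitude, seed=config.seed + 2
        )
    return vol, lmap


def inject_misalignment(
    label_map: LabelMap, amplitude: float, seed: int = 0, smoothness: float = 8.0
) -> LabelMap:
    """Warp a label map by a smooth random displacement field.

    The field is scaled so its maximum displacement magnitude equals
    ``amplitude`` pixels; labels are pulled with nearest-neighbor
    interpolation, so the output label set is a subset of the input's.
    ``amplitude=0`` returns an unchanged copy.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        return label_map.copy()
    rng = np.random.default_rng(seed)
    shape = label_map.shape
    disp = np.stack(
        [
            ndimage.gaussian_filter(rng.standard_normal(shape), sigma=smoothness)
            for _ in shape
        ]
    )
    mag = np.sqrt((disp**2).sum(axis=0))
    peak = mag.max()
    if peak > 0:
        disp *= amplitude / peak
    coords = np.indices(shape).astype(np.float64) + disp
    warped = ndimage.map_coordinates(
        label_map.labels, coords, order=0, mode="nearest"
    )
    return LabelMap(warped, label_map.spacing, dict(label_map.label_names))
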