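"""Intensity preprocessing: denoise, bias-field correction, isotropic
resampling, and mean +/- 3 SD outlier exclusion.

The chain runs in that fixed order.  Outliers are removed from the validity
mask rather than clipped, so they propagate as invalid pixels through
texture mapping and classification.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.restoration import denoise_nl_means

from .types import IntensityVolume

OUTLIER_SD = 3.0


@dataclass
class PreprocessConfig:
    denoise_method: str = "gaussian"
    denoise_strength: float = 0.5
    bias_correction: bool = True
    bias_poly_order: int = 2
    target_spacing: float | None = None  # None -> min(input spacings)
    outlier_filter: bool = True


def denoise(
    vol: IntensityVolume, method: str = "gaussian", strength: float = 0.5
) -> IntensityVolume:
    """Smooth the image; ``strength=0`` is the exact identity.

    ``gaussian`` uses ``strength`` as the kernel sigma in pixels; ``nlm``
    uses it as the non-local-means cut-off ``h`` in intensity units.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    if strength == 0:
        return vol.copy()
    if method == "gaussian":
        smoothed = ndimage.gaussian_filter(vol.data, sigma=strength)
    elif method == "nlm":
        smoothed = denoise_nl_means(
            vol.data, h=strength, fast_mode=True, preserve_range=True
        )
    else:
        raise ValueError(f"unknown denoise method {method!r}; use 'gaussian' or 'nlm'")
    return IntensityVolume(smoothed, vol.spacing, vol.mask.copy(), dict(vol.meta))


def _poly_design(shape: tuple[int, ...], order: int) -> np.ndarray:
    """Polynomial design matrix over the full grid, coords scaled to [-1, 1]."""
    axes = [
        np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n) for n in shape
    ]
    grids = np.meshgrid(*axes, indexing="ij")
    cols = []
    for powers in itertools.product(range(order + 1), repeat=len(shape)):
        if sum(powers) > order:
            continue
        term = np.ones(shape)
        for g, p in zip(grids, powers):
            if p:
                term = term * g**p
        cols.append(term.ravel())
    return np.column_stack(cols)


def _kmeans_1d(values: np.ndarray, k: int, n_iter: int = 25) -> np.ndarray:
    """Deterministic 1D k-means (quantile init); returns assignments."""
    centers = np.quantile(values, (2 * np.arange(k) + 1) / (2 * k))
    assign = np.zeros(values.size, dtype=np.int64)
    for _ in range(n_iter):
        assign = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        new = centers.copy()
        for c in range(k):
            sel = assign == c
            if sel.any():
                new[c] = values[sel].mean()
        if np.allclose(new, centers):
            break
        centers = new
    return assign


def correct_bias_field(
    vol: IntensityVolume, order: int = 2, n_classes: int = 3, n_iter: int = 5
) -> tuple[IntensityVolume, np.ndarray]:
    """Estimate and remove a smooth multiplicative intensity field.

    Log intensities of positive masked pixels are modeled as a per-class
    offset (tissue classes found by 1D k-means) plus a degree-``order``
    polynomial surface; class assignment and the joint fit alternate for
    ``n_iter`` rounds.  Fitting tissue contrast explicitly keeps spatially
    structured tissue (e.g. a dark peripheral rim) from masquerading as
    inhomogeneity.  The exponentiated surface, normalized to mean 1 over
    the mask, is divided out; the corrected image is rescaled so its masked
    mean equals the input's masked mean exactly.
    """
    positive = vol.mask & (vol.data > 0)
    if not positive.any():
        raise ValueError("bias field indeterminate: no positive masked pixels")
    sel = positive.ravel()
    y = np.log(vol.data.ravel()[sel])
    design = _poly_design(vol.shape, order)[:, 1:]  # smooth terms, no constant
    X = design[sel]
    k = min(n_classes, np.unique(y).size)
    assign = _kmeans_1d(y, k)
    beta = np.zeros(X.shape[1])
    for _ in range(max(1, n_iter)):
        onehot = np.zeros((y.size, k))
        onehot[np.arange(y.size), assign] = 1.0
        coef, *_ = np.linalg.lstsq(np.hstack([onehot, X]), y, rcond=None)
        beta = coef[k:]
        new_assign = _kmeans_1d(y - X @ beta, k)
        if (new_assign == assign).all():
            assign = new_assign
            break
        assign = new_assign
    field = np.exp(design @ beta).reshape(vol.shape)
    field = field / field[vol.mask].mean()
    corrected = vol.data / field
    mean_in = vol.data[vol.mask].mean()
    mean_out = corrected[vol.mask].mean()
    if mean_out != 0:
        corrected = corrected * (mean_in / mean_out)
    out = IntensityVolume(corrected, vol.spacing, vol.mask.copy(), dict(vol.meta))
    return out, field


def resample_isotropic(
    vol: IntensityVolume, target_spacing: float | None = None
) -> IntensityVolume:
    """Resample to equal spacing on all axes.

    Default target is the smallest input spacing (minimum interpolation
    factor).  Intensities are linearly interpolated, the mask with nearest
    neighbor; the physical extent is preserved to within one voxel.
    """
    if target_spacing is None:
        target_spacing = min(vol.spacing)
    target_spacing = float(target_spacing)
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    if all(s == target_spacing for s in vol.spacing):
        return vol.copy()
    factors = tuple(s / target_spacing for s in vol.spacing)
    data = ndimage.zoom(vol.data, factors, order=1, mode="nearest", grid_mode=True)
    mask = (
        ndimage.zoom(
            vol.mask.astype(np.uint8), factors, order=0, mode="nearest", grid_mode=True
        )
        > 0
    )
    spacing = tuple(target_spacing for _ in vol.spacing)
    return IntensityVolume(data, spacing, mask, dict(vol.meta))


def filter_outliers(vol: IntensityVolume, n_sd: float = OUTLIER_SD) -> IntensityVolume:
    """Drop pixels outside mean +/- ``n_sd`` SD of the masked distribution.

    Excluded pixels are removed from the mask; intensities are untouched.
    A zero-variance image is returned unchanged.
    """
    if not vol.mask.any():
        raise ValueError("mask is empty")
    vals = vol.data[vol.mask]
    mu = vals.mean()
    sigma = vals.std()
    if sigma == 0:
        return vol.copy()
    keep = (vol.data >= mu - n_sd * sigma) & (vol.data <= mu + n_sd * sigma)
    return IntensityVolume(
        vol.data.copy(), vol.spacing, vol.mask & keep, dict(vol.meta)
    )


def _stage_summary(vol: IntensityVolume) -> dict:
    vals = vol.masked_values()
    return {
        "n_masked": int(vals.size),
        "mean": float(vals.mean()) if vals.size else float("nan"),
        "sd": float(vals.std()) if vals.size else float("nan"),
    }


def preprocess(
    vol: IntensityVolume, config: PreprocessConfig | None = None
) -> tuple[IntensityVolume, list[dict]]:
    """Run the full chain in fixed order and log per-stage mask statistics.

    Returns the cleaned volume and a list of ``{stage, n_masked, mean, sd}``
    records (input state first).
    """
    config = config or PreprocessConfig()
    log = [{"stage": "input", **_stage_summary(vol)}]
    vol = denoise(vol, config.denoise_method, config.denoise_strength)
    log.append({"stage": "denoise", **_stage_summary(vol)})
    if config.bias_correction:
        vol, _field = correct_bias_field(vol, config.bias_poly_order)
        log.append({"stage": "bias_correction", **_stage_summary(vol)})
    vol = resample_isotropic(vol, config.target_spacing)
    log.append({"stage": "resample", **_stage_summary(vol)})
    if config.outlier_filter:
        vol = filter_outliers(vol)
        log.append({"stage": "outlier_filter", **_stage_summary(vol)})
    return vol, log
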