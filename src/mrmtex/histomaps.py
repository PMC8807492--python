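"""Histology-derived maps: label resampling, stromal-proportion maps, and
the Dice overlap coefficient.

The stromal proportion of a pixel is the percentage of stroma among the
stroma + tumor pixels inside a Euclidean disk around it (default radius 3,
which contains exactly 29 pixels).  Fat, void, and background pixels count
in neither numerator nor denominator; a pixel whose disk contains no tumor
or stroma at all has no defined proportion and is masked out.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import ndimage

from .types import (
    RESAMPLE_PRIORITY,
    STROMA,
    TUMOR,
    LabelMap,
    StromalProportionMap,
)

logger = logging.getLogger(__name__)

DEFAULT_RADIUS = 3


def resample_labels(
    source: LabelMap,
    target_shape: tuple[int, ...],
    target_spacing: tuple[float, ...],
) -> LabelMap:
    """Majority-vote resampling of a (typically finer) label raster.

    Grids are assumed to share an origin at the corner of pixel (0, 0).
    Each source pixel votes, by its centre position, for the target pixel
    covering it; ties are broken by the fixed priority
    stroma > tumor > fat > void > background.  Target pixels covered by no
    source pixel become background.
    """
    target_shape = tuple(int(n) for n in target_shape)
    target_spacing = tuple(float(s) for s in target_spacing)
    if len(target_shape) != source.labels.ndim:
        raise ValueError("target rank differs from source rank")
    src_extent = [n * s for n, s in zip(source.shape, source.spacing)]
    tgt_extent = [n * s for n, s in zip(target_shape, target_spacing)]
    if any(min(a, b) <= 0 for a, b in zip(src_extent, tgt_extent)):
        raise ValueError("physical extents do not overlap")

    # Target index of each source pixel centre, per axis.
    idx = []
    inside = np.ones(source.shape, dtype=bool)
    for ax, (n, s_sp, t_sp, t_n) in enumerate(
        zip(source.shape, source.spacing, target_spacing, target_shape)
    ):
        centers = (np.arange(n) + 0.5) * s_sp
        ti = np.floor(centers / t_sp).astype(np.int64)
        shape1 = [1] * source.labels.ndim
        shape1[ax] = n
        ti_b = ti.reshape(shape1)
        inside &= np.broadcast_to((ti_b >= 0) & (ti_b < t_n), source.shape)
        idx.append(np.broadcast_to(ti_b.clip(0, t_n - 1), source.shape))
    flat = np.ravel_multi_index(tuple(idx), target_shape)

    n_labels = max(source.label_names) + 1
    votes = np.zeros((int(np.prod(target_shape)), n_labels), dtype=np.int64)
    np.add.at(votes, (flat[inside], source.labels[inside]), 1)

    # Reorder label columns by priority so argmax resolves ties correctly.
    priority = [lab for lab in RESAMPLE_PRIORITY if lab < n_labels]
    priority += [lab for lab in range(n_labels) if lab not in priority]
    winner_pos = np.argmax(votes[:, priority], axis=1)
    out = np.asarray(priority, dtype=np.uint8)[winner_pos]
    out[votes.sum(axis=1) == 0] = 0
    n_ties = int(
        ((votes[:, priority] == votes[np.arange(len(votes)), priority[0]][:, None]).sum(1) > 1).sum()
    )
    logger.debug("label resampling: %d target pixels, ties broken by priority", n_ties)
    return LabelMap(out.reshape(target_shape), target_spacing, dict(source.label_names))


def disk_footprint(radius: int) -> np.ndarray:
    """Pixels whose centre lies within Euclidean distance ``radius``."""
    r = int(radius)
    y, x = np.ogrid[-r : r + 1, -r : r + 1]
    return (y**2 + x**2) <= r**2


def stromal_proportion(
    labels: LabelMap, radius: int = DEFAULT_RADIUS
) -> StromalProportionMap:
    """Per-pixel stroma percentage in a circular neighborhood.

    ``proportion = 100 * n_stroma / (n_stroma + n_tumor)`` over the disk;
    computed per slice for 3D input.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    fp = disk_footprint(radius).astype(np.float64)
    if labels.labels.ndim == 3:
        fp = fp[None, :, :]
    stroma = (labels.labels == STROMA).astype(np.float64)
    tumor = (labels.labels == TUMOR).astype(np.float64)
    n_s = np.round(ndimage.convolve(stroma, fp, mode="constant", cval=0.0))
    n_t = np.round(ndimage.convolve(tumor, fp, mode="constant", cval=0.0))
    denom = n_s + n_t
    mask = denom > 0
    prop = np.zeros(labels.shape, dtype=np.float64)
    np.divide(100.0 * n_s, denom, out=prop, where=mask)
    if not mask.any():
        warnings.warn(
            "no tumor or stroma pixels anywhere: proportion map fully masked",
            stacklevel=2,
        )
    return StromalProportionMap(prop, mask, labels.spacing)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient ``2|A & B| / (|A| + |B|)``.

    Two empty masks are taken as perfectly overlapping (coefficient 1).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    size = int(a.sum()) + int(b.sum())
    if size == 0:
        logger.debug("dice of two empty masks defined as 1")
        return 1.0
    return 2.0 * int((a & b).sum()) / size
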