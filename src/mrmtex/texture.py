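"""Per-pixel gray-level co-occurrence matrices and the 13 texture features.

For every valid pixel, a symmetric GLCM is accumulated inside a square
window (default radius 3, i.e. 7x7) from distance-1 co-occurring valid pixel
pairs, separately per direction; the 13 features are computed per direction
and averaged over directions that produced at least one pair.  Logarithms
are base 2, so entropies are in bits.

Two code paths exist: :func:`glcm_window` + :func:`haralick_features` form a
transparent numpy reference for a single window, and :func:`texture_map`
runs a compiled per-pixel kernel over the whole grid.  They are checked
against each other in the test suite.
"""
from __future__ import annotations

import warnings

import numba as nb
import numpy as np

from .types import (
    FEATURE_NAMES,
    CooccurrenceMatrix,
    IntensityVolume,
    QuantizedVolume,
    TextureMapStack,
)

DEFAULT_LEVELS = 64
DEFAULT_RADIUS = 3

# In-plane distance-1 directions: 0, 45, 90, 135 degrees (row, col).
OFFSETS_2D: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

# The 13 unique 3D distance-1 directions (one of each +/- pair).
OFFSETS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)


def quantize(vol: IntensityVolume, n_levels: int = DEFAULT_LEVELS) -> QuantizedVolume:
    """Fixed-bin-number quantization over the masked intensity range.

    ``level = floor(G * (x - min) / (max - min))`` with ``x = max`` mapped to
    ``G - 1``.  Pixels outside the mask are assigned level 0 but carry no
    meaning.  A constant image maps everything to level 0 with a warning.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if not vol.mask.any():
        raise ValueError("mask is empty")
    vals = vol.data[vol.mask]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(vol.shape, dtype=np.int64)
    if hi == lo:
        warnings.warn("constant masked intensities: all levels set to 0", stacklevel=2)
    else:
        lv = np.floor(n_levels * (vol.data - lo) / (hi - lo)).astype(np.int64)
        np.clip(lv, 0, n_levels - 1, out=lv)
        levels[vol.mask] = lv[vol.mask]
    return QuantizedVolume(
        levels,
        n_levels,
        vol.mask.copy(),
        vol.spacing,
        provenance={"min": lo, "max": hi, "n_levels": n_levels},
    )


def _window_bounds(center, radius, shape):
    los, his = [], []
    for c, n in zip(center, shape):
        los.append(max(0, c - radius))
        his.append(min(n - 1, c + radius))
    return tuple(los), tuple(his)


def glcm_window(
    q: QuantizedVolume,
    center: tuple[int, ...],
    radius: int = DEFAULT_RADIUS,
    offsets: tuple[tuple[int, ...], ...] | None = None,
) -> CooccurrenceMatrix:
    """Symmetric GLCM of the window around one pixel, pooled over offsets.

    Counts every ordered pair ``(p, p + offset)`` with both members inside
    the window and the mask, plus its reverse, then normalizes.  Returns an
    all-zero matrix flagged ``empty`` when no pair exists.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if offsets is None:
        offsets = OFFSETS_2D if q.levels.ndim == 2 else OFFSETS_3D
    los, his = _window_bounds(center, radius, q.shape)
    win = q.levels[tuple(slice(lo, hi + 1) for lo, hi in zip(los, his))]
    wmask = q.mask[tuple(slice(lo, hi + 1) for lo, hi in zip(los, his))]
    G = q.n_levels
    counts = np.zeros((G, G), dtype=np.int64)
    for off in offsets:
        src = tuple(
            slice(max(0, -d), n - max(0, d)) for d, n in zip(off, win.shape)
        )
        dst = tuple(
            slice(max(0, d), n - max(0, -d)) for d, n in zip(off, win.shape)
        )
        a, b = win[src], win[dst]
        sel = wmask[src] & wmask[dst]
        np.add.at(counts, (a[sel], b[sel]), 1)
        np.add.at(counts, (b[sel], a[sel]), 1)
    total = counts.sum()
    window = {"center": tuple(center), "radius": radius, "lo": los, "hi": his}
    if total == 0:
        return CooccurrenceMatrix(
            np.zeros((G, G)), tuple(offsets), window, empty=True
        )
    return CooccurrenceMatrix(counts / total, tuple(offsets), window)


def haralick_features(p: CooccurrenceMatrix | np.ndarray) -> dict[str, float]:
    """The 13 scalar features of one co-occurrence matrix.

    Conventions: ``0 * log 0 = 0``; correlation is 0 when either marginal
    variance vanishes; the joint variance uses the mean of the joint index
    distribution.
    """
    arr = p.p if isinstance(p, CooccurrenceMatrix) else np.asarray(p, dtype=np.float64)
    total = arr.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"probabilities sum to {total}, expected 1")
    if (arr < 0).any():
        raise ValueError("negative probabilities")
    G = arr.shape[0]
    i = np.arange(G)[:, None]
    j = np.arange(G)[None, :]
    px = arr.sum(axis=1)
    py = arr.sum(axis=0)
    mu_x = (np.arange(G) * px).sum()
    mu_y = (np.arange(G) * py).sum()
    sd_x = np.sqrt(((np.arange(G) - mu_x) ** 2 * px).sum())
    sd_y = np.sqrt(((np.arange(G) - mu_y) ** 2 * py).sum())
    p_sum = np.bincount((i + j).ravel(), weights=arr.ravel(), minlength=2 * G - 1)
    p_diff = np.bincount(np.abs(i - j).ravel(), weights=arr.ravel(), minlength=G)
    k_sum = np.arange(2 * G - 1)
    k_diff = np.arange(G)

    nz = arr > 0
    entropy = float(-(arr[nz] * np.log2(arr[nz])).sum())
    if sd_x * sd_y > 0:
        correlation = float(((i - mu_x) * (j - mu_y) * arr).sum() / (sd_x * sd_y))
    else:
        correlation = 0.0
    mu_joint = (i * arr).sum()  # mean of the joint index distribution
    mu_d = (k_diff * p_diff).sum()
    nzs = p_sum > 0
    nzd = p_diff > 0
    return {
        "energy": float((arr**2).sum()),
        "contrast": float(((i - j) ** 2 * arr).sum()),
        "entropy": entropy,
        "homogeneity": float((arr / (1.0 + (i - j) ** 2)).sum()),
        "dissimilarity": float((np.abs(i - j) * arr).sum()),
        "correlation": correlation,
        "variance": float(((i - mu_joint) ** 2 * arr).sum()),
        "sum_average": float((k_sum * p_sum).sum()),
        "sum_entropy": float(-(p_sum[nzs] * np.log2(p_sum[nzs])).sum()),
        "difference_variance": float(((k_diff - mu_d) ** 2 * p_diff).sum()),
        "difference_entropy": float(-(p_diff[nzd] * np.log2(p_diff[nzd])).sum()),
        "autocorrelation": float((i * j * arr).sum()),
        "cluster_tendency": float(((i + j - mu_x - mu_y) ** 2 * arr).sum()),
    }


@nb.njit(cache=True)
def _features_from_counts(counts, touched, ntouch, total, px, psum, pdiff, out):
    """13 features from a sparse symmetric count matrix (numba kernel)."""
    G = px.shape[0]
    px[:] = 0.0
    psum[:] = 0.0
    pdiff[:] = 0.0
    energy = 0.0
    entropy = 0.0
    contrast = 0.0
    homog = 0.0
    dissim = 0.0
    autoc = 0.0
    for t in range(ntouch):
        ii = touched[t, 0]
        jj = touched[t, 1]
        pr = counts[ii, jj] / total
        px[ii] += pr
        psum[ii + jj] += pr
        d = ii - jj if ii >= jj else jj - ii
        pdiff[d] += pr
        energy += pr * pr
        entropy -= pr * np.log2(pr)
        contrast += (ii - jj) * (ii - jj) * pr
        homog += pr / (1.0 + (ii - jj) * (ii - jj))
        dissim += d * pr
        autoc += ii * jj * pr
    mu = 0.0
    for g in range(G):
        mu += g * px[g]
    var = 0.0
    for g in range(G):
        var += (g - mu) * (g - mu) * px[g]
    corr = 0.0
    if var > 0:
        num = 0.0
        for t in range(ntouch):
            ii = touched[t, 0]
            jj = touched[t, 1]
            num += (ii - mu) * (jj - mu) * counts[ii, jj] / total
        corr = num / var  # symmetric matrix: sigma_x * sigma_y = var
    sum_avg = 0.0
    sum_ent = 0.0
    clus = 0.0
    for k in range(2 * G - 1):
        ps = psum[k]
        sum_avg += k * ps
        if ps > 0:
            sum_ent -= ps * np.log2(ps)
        clus += (k - 2.0 * mu) * (k - 2.0 * mu) * ps
    mu_d = 0.0
    for k in range(G):
        mu_d += k * pdiff[k]
    dvar = 0.0
    dent = 0.0
    for k in range(G):
        pd = pdiff[k]
        dvar += (k - mu_d) * (k - mu_d) * pd
        if pd > 0:
            dent -= pd * np.log2(pd)
    out[0] = energy
    out[1] = contrast
    out[2] = entropy
    out[3] = homog
    out[4] = dissim
    out[5] = corr
    out[6] = var
    out[7] = sum_avg
    out[8] = sum_ent
    out[9] = dvar
    out[10] = dent
    out[11] = autoc
    out[12] = clus


@nb.njit(cache=True)
def _texture_kernel_2d(levels, mask, offsets, radius, G):
    H, W = levels.shape
    D = offsets.shape[0]
    out = np.full((13, H, W), np.nan)
    ok = np.zeros((H, W), np.bool_)
    counts = np.zeros((G, G), np.int64)
    side = 2 * radius + 1
    touched = np.empty((2 * side * side, 2), np.int64)
    px = np.zeros(G)
    psum = np.zeros(2 * G - 1)
    pdiff = np.zeros(G)
    fdir = np.empty(13)
    facc = np.empty(13)
    for cy in range(H):
        for cx in range(W):
            if not mask[cy, cx]:
                continue
            y0 = cy - radius if cy - radius > 0 else 0
            y1 = cy + radius if cy + radius < H - 1 else H - 1
            x0 = cx - radius if cx - radius > 0 else 0
            x1 = cx + radius if cx + radius < W - 1 else W - 1
            ndir = 0
            for f in range(13):
                facc[f] = 0.0
            for d in range(D):
                dy = offsets[d, 0]
                dx = offsets[d, 1]
                ntouch = 0
                total = 0
                for y in range(y0, y1 + 1):
                    yy = y + dy
                    if yy < y0 or yy > y1:
                        continue
                    for x in range(x0, x1 + 1):
                        xx = x + dx
                        if xx < x0 or xx > x1:
                            continue
                        if mask[y, x] and mask[yy, xx]:
                            a = levels[y, x]
                            b = levels[yy, xx]
                            if counts[a, b] == 0:
                                touched[ntouch, 0] = a
                                touched[ntouch, 1] = b
                                ntouch += 1
                            counts[a, b] += 1
                            if counts[b, a] == 0:
                                touched[ntouch, 0] = b
                                touched[ntouch, 1] = a
                                ntouch += 1
                            counts[b, a] += 1
                            total += 2
                if total > 0:
                    _features_from_counts(
                        counts, touched, ntouch, float(total), px, psum, pdiff, fdir
                    )
                    for f in range(13):
                        facc[f] += fdir[f]
                    ndir += 1
                for t in range(ntouch):
                    counts[touched[t, 0], touched[t, 1]] = 0
            if ndir > 0:
                ok[cy, cx] = True
                for f in range(13):
                    out[f, cy, cx] = facc[f] / ndir
    return out, ok


@nb.njit(cache=True)
def _texture_kernel_3d(levels, mask, offsets, radius, G):
    Z, H, W = levels.shape
    D = offsets.shape[0]
    out = np.full((13, Z, H, W), np.nan)
    ok = np.zeros((Z, H, W), np.bool_)
    counts = np.zeros((G, G), np.int64)
    side = 2 * radius + 1
    touched = np.empty((2 * side * side * side, 2), np.int64)
    px = np.zeros(G)
    psum = np.zeros(2 * G - 1)
    pdiff = np.zeros(G)
    fdir = np.empty(13)
    facc = np.empty(13)
    for cz in range(Z):
        for cy in range(H):
            for cx in range(W):
                if not mask[cz, cy, cx]:
                    continue
                z0 = cz - radius if cz - radius > 0 else 0
                z1 = cz + radius if cz + radius < Z - 1 else Z - 1
                y0 = cy - radius if cy - radius > 0 else 0
                y1 = cy + radius if cy + radius < H - 1 else H - 1
                x0 = cx - radius if cx - radius > 0 else 0
                x1 = cx + radius if cx + radius < W - 1 else W - 1
                ndir = 0
                for f in range(13):
                    facc[f] = 0.0
                for d in range(D):
                    dz = offsets[d, 0]
                    dy = offsets[d, 1]
                    dx = offsets[d, 2]
                    ntouch = 0
                    total = 0
                    for z in range(z0, z1 + 1):
                        zz = z + dz
                        if zz < z0 or zz > z1:
                            continue
                        for y in range(y0, y1 + 1):
                            yy = y + dy
                            if yy < y0 or yy > y1:
                                continue
                            for x in range(x0, x1 + 1):
                                xx = x + dx
                                if xx < x0 or xx > x1:
                                    continue
                                if mask[z, y, x] and mask[zz, yy, xx]:
                                    a = levels[z, y, x]
                                    b = levels[zz, yy, xx]
                                    if counts[a, b] == 0:
                                        touched[ntouch, 0] = a
                                        touched[ntouch, 1] = b
                                        ntouch += 1
                                    counts[a, b] += 1
                                    if counts[b, a] == 0:
                                        touched[ntouch, 0] = b
                                        touched[ntouch, 1] = a
                                        ntouch += 1
                                    counts[b, a] += 1
                                    total += 2
                    if total > 0:
                        _features_from_counts(
                            counts, touched, ntouch, float(total), px, psum, pdiff, fdir
                        )
                        for f in range(13):
                            facc[f] += fdir[f]
                        ndir += 1
                    for t in range(ntouch):
                        counts[touched[t, 0], touched[t, 1]] = 0
                if ndir > 0:
                    ok[cz, cy, cx] = True
                    for f in range(13):
                        out[f, cz, cy, cx] = facc[f] / ndir
    return out, ok


def texture_map(
    q: QuantizedVolume,
    radius: int = DEFAULT_RADIUS,
    mode: str = "2d-4dir",
    distance: int = 1,
    si: np.ndarray | None = None,
) -> TextureMapStack:
    """Per-pixel feature maps over the whole grid.

    ``mode='2d-4dir'`` uses the four in-plane directions (applied per slice
    on 3D input); ``mode='3d-13dir'`` uses the 13 unique 3D directions.
    Pixels whose window yields no valid pair are masked out of the stack.
    When ``si`` is given (the preprocessed intensities), an ``si`` map is
    included alongside the 13 feature maps.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if not q.mask.any():
        raise ValueError("mask is empty")
    levels = np.ascontiguousarray(q.levels)
    mask = np.ascontiguousarray(q.mask)
    if mode == "2d-4dir":
        offsets = distance * np.array(OFFSETS_2D, dtype=np.int64)
        if q.levels.ndim == 2:
            feat, ok = _texture_kernel_2d(levels, mask, offsets, radius, q.n_levels)
        else:
            feat = np.full((13,) + q.shape, np.nan)
            ok = np.zeros(q.shape, dtype=bool)
            for z in range(q.shape[0]):
                fz, okz = _texture_kernel_2d(
                    np.ascontiguousarray(levels[z]),
                    np.ascontiguousarray(mask[z]),
                    offsets,
                    radius,
                    q.n_levels,
                )
                feat[:, z] = fz
                ok[z] = okz
    elif mode == "3d-13dir":
        if q.levels.ndim != 3:
            raise ValueError("mode '3d-13dir' requires a 3D volume")
        offsets = distance * np.array(OFFSETS_3D, dtype=np.int64)
        feat, ok = _texture_kernel_3d(levels, mask, offsets, radius, q.n_levels)
    else:
        raise ValueError(f"unknown mode {mode!r}; use '2d-4dir' or '3d-13dir'")

    maps: dict[str, np.ndarray] = {}
    if si is not None:
        si = np.asarray(si, dtype=np.float64)
        if si.shape != q.shape:
            raise ValueError("si shape differs from quantized grid")
        maps["si"] = si.copy()
    for k, name in enumerate(FEATURE_NAMES):
        maps[name] = feat[k]
    return TextureMapStack(
        maps,
        ok,
        q.spacing,
        meta={
            "radius": radius,
            "mode": mode,
            "distance": distance,
            "n_levels": q.n_levels,
            "quantization": dict(q.provenance),
        },
    )
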