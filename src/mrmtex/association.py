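"""Binned association between texture maps and stromal proportion.

The stromal-proportion map is divided into ten 10-percentage-point
increments; the mean of each feature map (and of the signal intensity) is
computed within each increment, and the Pearson correlation between the
bin centers and the bin means is reported with its two-sided p-value.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import StromalProportionMap, TextureMapStack

N_BINS = 10
BIN_EDGES = np.arange(0.0, 101.0, 10.0)  # [0,10), ..., [90,100]
BIN_CENTERS = BIN_EDGES[:-1] + 5.0
ALPHA = 0.05
MIN_BINS = 3


def bin_index(proportion: np.ndarray) -> np.ndarray:
    """Bin number 0..9 for proportions in [0, 100]; 100 falls in the last bin."""
    prop = np.asarray(proportion, dtype=np.float64)
    if prop.size and (np.nanmin(prop) < 0 or np.nanmax(prop) > 100):
        raise ValueError("proportions outside [0, 100]")
    return np.minimum((prop // 10).astype(np.int64), N_BINS - 1)


@dataclass
class BinnedAssociation:
    """Binned means and Pearson statistics for one variable."""

    feature: str
    bin_centers: np.ndarray
    bin_means: np.ndarray  # NaN for empty bins
    bin_counts: np.ndarray
    r: float = np.nan
    p: float = np.nan
    n_bins_used: int = 0
    significant: bool = False
    note: str = ""


def bin_by_proportion(
    proportion: np.ndarray, values: np.ndarray, feature: str = ""
) -> BinnedAssociation:
    """Mean of ``values`` within each 10-point proportion increment."""
    proportion = np.asarray(proportion, dtype=np.float64).ravel()
    values = np.asarray(values, dtype=np.float64).ravel()
    if proportion.shape != values.shape:
        raise ValueError("proportion and values lengths differ")
    idx = bin_index(proportion)
    counts = np.bincount(idx, minlength=N_BINS)
    sums = np.bincount(idx, weights=values, minlength=N_BINS)
    means = np.full(N_BINS, np.nan)
    nonempty = counts > 0
    means[nonempty] = sums[nonempty] / counts[nonempty]
    return BinnedAssociation(feature, BIN_CENTERS.copy(), means, counts)


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-sided t-distribution p-value (n - 2 df).

    Returns ``(nan, nan)`` when fewer than 3 points remain or either input
    has zero variance — undefined, deliberately not reported as 0.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < MIN_BINS or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _finish(assoc: BinnedAssociation, alpha: float) -> BinnedAssociation:
    used = ~np.isnan(assoc.bin_means)
    assoc.n_bins_used = int(used.sum())
    if assoc.n_bins_used < MIN_BINS:
        assoc.note = f"only {assoc.n_bins_used} nonempty bins; correlation skipped"
        return assoc
    assoc.r, assoc.p = pearson(assoc.bin_centers[used], assoc.bin_means[used])
    if np.isnan(assoc.r):
        assoc.note = "zero variance in bin means; r undefined"
    else:
        assoc.significant = bool(assoc.p < alpha)
    return assoc


def associate(
    proportion: np.ndarray,
    values: np.ndarray,
    feature: str = "",
    alpha: float = ALPHA,
) -> BinnedAssociation:
    """Bin one variable by stromal proportion and correlate the bin means."""
    return _finish(bin_by_proportion(proportion, values, feature), alpha)


def association_report(
    stack: TextureMapStack,
    prop: StromalProportionMap,
    alpha: float = ALPHA,
    fdr: bool = False,
) -> pd.DataFrame:
    """Full per-feature report (SI plus the 13 texture features).

    Rows: one per map in the stack; columns: r, p, n_bins, significant, and
    the ten bin means.  ``fdr=True`` applies Benjamini-Hochberg to the
    p-values (off by default — one test per feature at ``alpha``).
    """
    if stack.shape != prop.shape:
        raise ValueError(
            f"misaligned grids: texture {stack.shape} vs proportion {prop.shape}"
        )
    valid = stack.mask & prop.mask
    if not valid.any():
        raise ValueError("no jointly valid pixels")
    rows = []
    for name in stack.names:
        assoc = associate(prop.proportion[valid], stack[name][valid], name, alpha)
        row = {
            "feature": name,
            "r": assoc.r,
            "p": assoc.p,
            "n_bins": assoc.n_bins_used,
            "significant": assoc.significant,
            "note": assoc.note,
        }
        for c, m, k in zip(assoc.bin_centers, assoc.bin_means, assoc.bin_counts):
            row[f"mean_bin_{int(c)}"] = m
            row[f"n_bin_{int(c)}"] = int(k)
        rows.append(row)
    report = pd.DataFrame(rows)
    if fdr:
        report["p_adj"] = _benjamini_hochberg(report["p"].to_numpy())
        report["significant"] = report["p_adj"] < alpha
    return report


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    q = p[ok]
    m = q.size
    order = np.argsort(q)
    ranked = q[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def raw_pixel_report(
    stack: TextureMapStack, prop: StromalProportionMap, alpha: float = ALPHA
) -> pd.DataFrame:
    """Secondary diagnostic: Pearson on raw pixels instead of bin means."""
    if stack.shape != prop.shape:
        raise ValueError("misaligned grids")
    valid = stack.mask & prop.mask
    rows = []
    for name in stack.names:
        r, p = pearson(prop.proportion[valid], stack[name][valid])
        rows.append(
            {
                "feature": name,
                "r": r,
                "p": p,
                "n_pixels": int(valid.sum()),
                "significant": bool(np.isfinite(p) and p < alpha),
            }
        )
    return pd.DataFrame(rows)
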