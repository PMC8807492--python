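"""Derived PNG visualizations (never read back by the pipeline)."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .classify import EXCLUDED, POOR, RICH

# Fig-style color conventions: rich=green, poor=red; correct=yellow, wrong=blue.
_PRED_COLORS = {RICH: (0, 170, 0), POOR: (200, 30, 30), EXCLUDED: (0, 0, 0)}
_EVAL_COLORS = {1: (240, 220, 40), 0: (40, 60, 220), EXCLUDED: (0, 0, 0)}


def _class_png(raster: np.ndarray, colors: dict, path: Path) -> Path:
    if raster.ndim == 3:
        raster = raster[raster.shape[0] // 2]
    rgb = np.zeros(raster.shape + (3,), dtype=np.uint8)
    for val, col in colors.items():
        rgb[raster == val] = col
    plt.imsave(path, rgb)
    return path


def save_prediction_png(predicted: np.ndarray, path: str | Path) -> Path:
    return _class_png(predicted, _PRED_COLORS, Path(path))


def save_evaluation_png(evaluation: np.ndarray, path: str | Path) -> Path:
    return _class_png(evaluation, _EVAL_COLORS, Path(path))


def save_map_png(
    data: np.ndarray, mask: np.ndarray, path: str | Path, cmap: str = "viridis"
) -> Path:
    """8-bit rendering of a scalar map; invalid pixels shown black."""
    path = Path(path)
    if data.ndim == 3:
        mid = data.shape[0] // 2
        data, mask = data[mid], mask[mid]
    shown = np.ma.array(data, mask=~mask)
    fig, ax = plt.subplots(figsize=(4, 4), dpi=120)
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad("black")
    im = ax.imshow(shown, cmap=cm)
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path


def save_correlation_plot(
    centers: np.ndarray,
    means: np.ndarray,
    feature: str,
    r: float,
    path: str | Path,
) -> Path:
    path = Path(path)
    fig, ax = plt.subplots(figsize=(4, 3), dpi=120)
    ok = np.isfinite(means)
    ax.plot(centers[ok], means[ok], "o-", color="tab:blue")
    ax.set_xlabel("stromal proportion (%)")
    ax.set_ylabel(f"mean {feature}")
    ax.set_title(f"{feature}: r = {r:.2f}" if np.isfinite(r) else feature)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
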