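"""Core data containers shared across the pipeline.

All images are numpy arrays indexed ``(row, col)`` in 2D or
``(slice, row, col)`` in 3D, with a per-axis physical spacing in
micrometres and a boolean validity mask (``True`` = analyzable pixel).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

# Tissue label codes used by every label raster in the package.
BACKGROUND = 0
TUMOR = 1
STROMA = 2
FAT = 3
VOID = 4

LABEL_NAMES: dict[int, str] = {
    BACKGROUND: "background",
    TUMOR: "tumor",
    STROMA: "stroma",
    FAT: "fat",
    VOID: "void",
}
LABEL_IDS: dict[str, int] = {v: k for k, v in LABEL_NAMES.items()}

# Tie-break priority for majority-vote label resampling (highest first).
RESAMPLE_PRIORITY: tuple[int, ...] = (STROMA, TUMOR, FAT, VOID, BACKGROUND)

#: The 13 co-occurrence features, in reporting order.
FEATURE_NAMES: tuple[str, ...] = (
    "energy",
    "contrast",
    "entropy",
    "homogeneity",
    "dissimilarity",
    "correlation",
    "variance",
    "sum_average",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "autocorrelation",
    "cluster_tendency",
)

#: Map names in a full texture stack: signal intensity plus the 13 features.
ALL_MAP_NAMES: tuple[str, ...] = ("si",) + FEATURE_NAMES


def _check_spacing(spacing: tuple[float, ...], ndim: int) -> tuple[float, ...]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != ndim:
        raise ValueError(f"spacing has {len(spacing)} entries for a {ndim}-D array")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be strictly positive, got {spacing}")
    return spacing


@dataclass
class IntensityVolume:
    """Grayscale image (2D slice or 3D stack) with spacing and validity mask."""

    data: np.ndarray
    spacing: tuple[float, ...]
    mask: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"expected a 2D or 3D array, got ndim={self.data.ndim}")
        if self.mask is None:
            self.mask = np.ones(self.data.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} differs from data shape {self.data.shape}"
            )
        self.spacing = _check_spacing(self.spacing, self.data.ndim)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def masked_values(self) -> np.ndarray:
        """Intensities of valid pixels, flattened."""
        return self.data[self.mask]

    def copy(self) -> "IntensityVolume":
        return IntensityVolume(
            self.data.copy(), self.spacing, self.mask.copy(), dict(self.meta)
        )


@dataclass
class LabelMap:
    """Integer tissue-label raster over a regular grid."""

    labels: np.ndarray
    spacing: tuple[float, ...]
    label_names: dict[int, str] = field(default_factory=lambda: dict(LABEL_NAMES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"labels must be integer, got dtype {self.labels.dtype}")
        self.labels = self.labels.astype(np.uint8)
        if self.labels.ndim not in (2, 3):
            raise ValueError(f"expected a 2D or 3D raster, got ndim={self.labels.ndim}")
        self.spacing = _check_spacing(self.spacing, self.labels.ndim)
        known = set(self.label_names)
        present = set(np.unique(self.labels).tolist())
        if not present <= known:
            raise ValueError(f"unknown label values {sorted(present - known)}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def region(self, label: int) -> np.ndarray:
        """Boolean mask of one label."""
        return self.labels == label

    def copy(self) -> "LabelMap":
        return LabelMap(self.labels.copy(), self.spacing, dict(self.label_names))


@dataclass
class QuantizedVolume:
    """Gray-level-quantized image: integer levels in ``[0, n_levels - 1]``.

    ``provenance`` records the intensity bounds used for the fixed-bin-number
    quantization so that level values remain interpretable.
    """

    levels: np.ndarray
    n_levels: int
    mask: np.ndarray
    spacing: tuple[float, ...]
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.levels.shape != self.mask.shape:
            raise ValueError("levels and mask shapes differ")
        self.spacing = _check_spacing(self.spacing, self.levels.ndim)
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        vals = self.levels[self.mask]
        if vals.size and (vals.min() < 0 or vals.max() >= self.n_levels):
            raise ValueError("masked levels outside [0, n_levels - 1]")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.levels.shape


@dataclass
class CooccurrenceMatrix:
    """Symmetric gray-level co-occurrence probabilities for one window."""

    p: np.ndarray
    offsets: tuple[tuple[int, ...], ...]
    window: dict[str, Any] = field(default_factory=dict)
    empty: bool = False

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.p.ndim != 2 or self.p.shape[0] != self.p.shape[1]:
            raise ValueError("co-occurrence matrix must be square")
        if self.empty:
            if self.p.any():
                raise ValueError("empty matrix must be all zero")
        else:
            total = self.p.sum()
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError(f"probabilities sum to {total}, expected 1")
            if (self.p < 0).any():
                raise ValueError("negative probability entries")


@dataclass
class TextureMapStack:
    """Per-pixel feature maps sharing one grid and one joint validity mask."""

    maps: dict[str, np.ndarray]
    mask: np.ndarray
    spacing: tuple[float, ...]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        for name, arr in self.maps.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.shape != self.mask.shape:
                raise ValueError(f"map {name!r} shape differs from mask shape")
            self.maps[name] = arr
        self.spacing = _check_spacing(self.spacing, self.mask.ndim)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.maps)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]


@dataclass
class StromalProportionMap:
    """Per-pixel stroma percentage among stroma + tumor pixels, in [0, 100]."""

    proportion: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, ...]

    def __post_init__(self) -> None:
        self.proportion = np.asarray(self.proportion, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.proportion.shape != self.mask.shape:
            raise ValueError("proportion and mask shapes differ")
        self.spacing = _check_spacing(self.spacing, self.proportion.ndim)
        vals = self.proportion[self.mask]
        if vals.size and (vals.min() < 0 or vals.max() > 100):
            raise ValueError("masked proportions outside [0, 100]")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.proportion.shape
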