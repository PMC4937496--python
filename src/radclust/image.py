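"""Core image containers: 3D CT volumes, tumor masks and gray-level discretization.

Intensities are in Hounsfield units (HU); geometry is carried as a per-axis
voxel spacing in millimetres so that shape features can be reported in
physical units while texture operators work on the native voxel grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageVolume", "TumorMask", "DiscretizationSpec", "discretize"]


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar image with anisotropic voxel spacing.

    Parameters
    ----------
    values : ndarray
        3D array of intensities (HU). Must be finite.
    spacing : tuple of float
        Per-axis voxel size in mm, all positive.
    origin : tuple of float
        Physical coordinate of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 3:
            raise ValueError(f"image must be 3D, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("image contains non-finite values")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class TumorMask:
    """A binary segmentation on the same grid as its image.

    ``values`` is stored as bool; at least one foreground voxel is required.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError(f"mask must be binary, found values {uniq}")
        arr = arr.astype(bool)
        if not arr.any():
            raise ValueError("mask is empty (no foreground voxels)")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def check_grid(self, img: ImageVolume) -> None:
        if self.values.shape != img.values.shape:
            raise ValueError(
                f"mask grid {self.values.shape} does not match image grid {img.values.shape}"
            )


@dataclass(frozen=True)
class DiscretizationSpec:
    """Gray-level discretization used by histogram and texture features.

    ``fixed_bin_count`` rebins the in-mask intensity range into ``n_bins``
    equal-width levels (scale-robust, the default, applied per wavelet
    sub-band); ``fixed_bin_width`` uses absolute ``bin_width`` HU bins
    anchored at the in-mask minimum.
    """

    mode: str = "fixed_bin_count"
    n_bins: int = 32
    bin_width: float = 25.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_bin_count", "fixed_bin_width"):
            raise ValueError(f"unknown discretization mode {self.mode!r}")
        if self.mode == "fixed_bin_count" and self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.mode == "fixed_bin_width" and self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")


def discretize(values: np.ndarray, mask: np.ndarray, disc: DiscretizationSpec) -> np.ndarray:
    """Map intensities to integer gray levels 1..Ng inside the mask.

    Returns a full-grid int array; voxels outside the mask are level 0.
    A constant region maps to a single level 1.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    inside = values[mask]
    if inside.size == 0:
        raise ValueError("cannot discretize an empty region")
    lo, hi = float(inside.min()), float(inside.max())
    levels = np.zeros(values.shape, dtype=np.int64)
    if hi == lo:
        levels[mask] = 1
        return levels
    if disc.mode == "fixed_bin_count":
        width = (hi - lo) / disc.n_bins
        lv = np.floor((inside - lo) / width).astype(np.int64)
        np.clip(lv, 0, disc.n_bins - 1, out=lv)
    else:
        lv = np.floor((inside - lo) / disc.bin_width).astype(np.int64)
    levels[mask] = lv + 1
    return levels
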