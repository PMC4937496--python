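"""First-order (intensity histogram) statistics of the masked tumor region.

15 statistics computed over the raw in-mask intensities; entropy and
uniformity are computed on the discretized histogram. Entropy is in bits.
Skewness and kurtosis of a zero-variance region are defined as 0 to keep
constant phantoms NaN-free (documented convention).
"""

from __future__ import annotations

import numpy as np

from ..image import DiscretizationSpec, ImageVolume, TumorMask, discretize

FIRST_ORDER_NAMES = (
    "energy",
    "entropy",
    "kurtosis",
    "maximum",
    "mean",
    "mean_absolute_deviation",
    "median",
    "minimum",
    "range",
    "root_mean_square",
    "skewness",
    "standard_deviation",
    "uniformity",
    "variance",
    "total_energy",
)


def first_order_features(
    img: ImageVolume, mask: TumorMask, disc: DiscretizationSpec
) -> dict[str, float]:
    """15 first-order statistics of the in-mask intensity distribution."""
    mask.check_grid(img)
    return _first_order_on_array(img.values, mask.values, disc, img.voxel_volume)


def _first_order_on_array(
    values: np.ndarray, mask: np.ndarray, disc: DiscretizationSpec, voxel_volume: float
) -> dict[str, float]:
    x = np.asarray(values, dtype=float)[mask]
    if x.size == 0:
        raise ValueError("empty mask")
    n = x.size
    mean = x.mean()
    dev = x - mean
    m2 = float(np.mean(dev**2))
    # sample variance (ddof=1) reported; moment ratios use population moments
    var = float(np.var(x, ddof=1)) if n > 1 else 0.0
    if m2 > 0:
        skew = float(np.mean(dev**3)) / m2**1.5
        kurt = float(np.mean(dev**4)) / m2**2
    else:
        skew = 0.0
        kurt = 0.0

    levels = discretize(values, mask, disc)[mask]
    counts = np.bincount(levels)[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    energy = float((x**2).sum())
    return {
        "energy": energy,
        "entropy": entropy,
        "kurtosis": kurt,
        "maximum": float(x.max()),
        "mean": float(mean),
        "mean_absolute_deviation": float(np.abs(dev).mean()),
        "median": float(np.median(x)),
        "minimum": float(x.min()),
        "range": float(x.max() - x.min()),
        "root_mean_square": float(np.sqrt(np.mean(x**2))),
        "skewness": skew,
        "standard_deviation": float(np.sqrt(var)),
        "uniformity": uniformity,
        "variance": var,
        "total_energy": voxel_volume * energy,
    }
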