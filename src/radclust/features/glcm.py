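"""Gray-level co-occurrence matrix (GLCM) features.

For each of the 13 directions a symmetric, normalized co-occurrence matrix
is built from in-mask voxel pairs at the configured distance; the 22
statistics are computed per direction and averaged. Degenerate conventions
(constant region): correlation := 1, IMC1 := 0; these keep constant phantoms
NaN-free and are configurable at the call site via `degenerate_correlation`.
"""

from __future__ import annotations

import numpy as np

from ..image import DiscretizationSpec, ImageVolume, TumorMask, discretize
from .directions import TEXTURE_DIRECTIONS, paired_slices

GLCM_NAMES = (
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_entropy",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity1",
    "homogeneity2",
    "imc1",
    "imc2",
    "idmn",
    "idn",
    "inverse_variance",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "sum_variance",
    "variance",
)

_EPS = np.finfo(float).tiny


def cooccurrence_matrix(
    levels: np.ndarray,
    mask: np.ndarray,
    offset: tuple[int, int, int],
    distance: int = 1,
) -> np.ndarray | None:
    """Symmetric normalized GLCM for one direction, or None if no valid pair.

    `levels` is the discretized full-grid array (0 outside mask).
    """
    off = tuple(int(distance) * o for o in offset)
    s1, s2 = paired_slices(off, levels.shape)
    valid = mask[s1] & mask[s2]
    if not valid.any():
        return None
    a = levels[s1][valid] - 1
    b = levels[s2][valid] - 1
    ng = int(levels.max())
    counts = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng).astype(float)
    counts += counts.T  # symmetrize before normalization
    return counts / counts.sum()


def glcm_statistics(p: np.ndarray) -> dict[str, float]:
    """The 22 GLCM statistics of one symmetric normalized matrix."""
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py by symmetry
    mu_x = float((i * px).sum())
    sigma_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))

    diff = np.abs(ii - jj)
    # p_{x+y}(k), k = 2..2Ng and p_{x-y}(k), k = 0..Ng-1
    psum = np.zeros(2 * ng - 1)
    np.add.at(psum, (ii + jj).astype(int).ravel() - 2, p.ravel())
    pdiff = np.zeros(ng)
    np.add.at(pdiff, diff.astype(int).ravel(), p.ravel())
    ksum = np.arange(2, 2 * ng + 1, dtype=float)

    def ent(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    entropy = ent(p.ravel())
    hx = ent(px)
    pxpy = np.outer(px, px)
    with np.errstate(divide="ignore"):
        log_pxpy = np.log2(np.maximum(pxpy, _EPS))
    hxy1 = float(-(p * log_pxpy).sum())
    hxy2 = float(-(pxpy[pxpy > 0] * np.log2(pxpy[pxpy > 0])).sum())

    if sigma_x > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_x) / (sigma_x * sigma_x))
    else:
        correlation = 1.0  # constant region: perfectly correlated by convention
    if hx > 0:
        imc1 = (entropy - hxy1) / hx
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    off_diag = diff > 0
    inverse_variance = float((p[off_diag] / diff[off_diag] ** 2).sum()) if ng > 1 else 0.0

    sum_average = float((ksum * psum).sum())
    centered = ii + jj - 2.0 * mu_x
    return {
        "autocorrelation": float((ii * jj * p).sum()),
        "cluster_prominence": float((centered**4 * p).sum()),
        "cluster_shade": float((centered**3 * p).sum()),
        "cluster_tendency": float((centered**2 * p).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "correlation": correlation,
        "difference_entropy": ent(pdiff),
        "dissimilarity": float((diff * p).sum()),
        "energy": float((p**2).sum()),
        "entropy": entropy,
        "homogeneity1": float((p / (1.0 + diff)).sum()),
        "homogeneity2": float((p / (1.0 + diff**2)).sum()),
        "imc1": float(imc1),
        "imc2": imc2,
        "idmn": float((p / (1.0 + diff**2 / ng**2)).sum()),
        "idn": float((p / (1.0 + diff / ng)).sum()),
        "inverse_variance": inverse_variance,
        "maximum_probability": float(p.max()),
        "sum_average": sum_average,
        "sum_entropy": ent(psum),
        "sum_variance": float(((ksum - sum_average) ** 2 * psum).sum()),
        "variance": float(((ii - mu_x) ** 2 * p).sum()),
    }


def glcm_features(
    img: ImageVolume,
    mask: TumorMask,
    disc: DiscretizationSpec,
    directions=TEXTURE_DIRECTIONS,
    distance: int = 1,
) -> dict[str, float]:
    """22 GLCM statistics averaged over the 13 directions."""
    mask.check_grid(img)
    levels = discretize(img.values, mask.values, disc)
    return glcm_features_from_levels(levels, mask.values, directions, distance)


def glcm_features_from_levels(
    levels: np.ndarray, mask: np.ndarray, directions=TEXTURE_DIRECTIONS, distance: int = 1
) -> dict[str, float]:
    if len(set(directions)) != len(directions):
        raise ValueError("texture directions must be unique")
    per_dir = []
    for d in directions:
        p = cooccurrence_matrix(levels, mask, d, distance)
        if p is not None:  # directions without any in-mask pair are skipped
            per_dir.append(glcm_statistics(p))
    if not per_dir:
        raise ValueError("no direction produced a valid voxel pair")
    return {name: float(np.mean([s[name] for s in per_dir])) for name in GLCM_NAMES}
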