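"""Gray-level run-length matrix (GLRLM) features.

Runs are maximal sequences of in-mask voxels with the same discretized level
along one of the 13 directions; runs break at mask boundaries. The 11
statistics are averaged over directions (directions in which the mask admits
no voxel are skipped).
"""

from __future__ import annotations

import numpy as np

from ..image import DiscretizationSpec, ImageVolume, TumorMask, discretize
from .directions import TEXTURE_DIRECTIONS

GLRLM_NAMES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "run_length_nonuniformity",
    "run_percentage",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
)


def run_lengths(
    levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """(gray level, length) of every in-mask run along one direction.

    Voxels are ordered along the direction by sorting on (line id, step);
    a new run starts where the line id changes, the step is non-consecutive
    (mask gap) or the level changes.
    """
    coords = np.argwhere(mask)
    if coords.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    d = np.asarray(offset)
    axis = int(np.nonzero(d)[0][0])
    t = coords[:, axis] // d[axis]  # signed step index along the line
    base = coords - t[:, None] * d  # constant along a line; identifies it
    key = np.concatenate([base, t[:, None]], axis=1)
    order = np.lexsort(key.T[::-1])
    key = key[order]
    lv = levels[tuple(coords[order].T)]

    same_line = np.all(key[1:, :3] == key[:-1, :3], axis=1)
    consecutive = key[1:, 3] == key[:-1, 3] + 1
    same_level = lv[1:] == lv[:-1]
    new_run = np.concatenate([[True], ~(same_line & consecutive & same_level)])
    starts = np.flatnonzero(new_run)
    lengths = np.diff(np.append(starts, lv.size))
    return lv[starts], lengths


def glrlm_statistics(gray: np.ndarray, lengths: np.ndarray, n_voxels: int) -> dict[str, float]:
    g = gray.astype(float)
    l = lengths.astype(float)
    nr = float(len(lengths))
    # nonuniformities need the counts per gray level / per run length
    gl_counts = np.bincount(gray)[1:]
    rl_counts = np.bincount(lengths)[1:]
    return {
        "short_run_emphasis": float((1.0 / l**2).sum() / nr),
        "long_run_emphasis": float((l**2).sum() / nr),
        "gray_level_nonuniformity": float((gl_counts.astype(float) ** 2).sum() / nr),
        "run_length_nonuniformity": float((rl_counts.astype(float) ** 2).sum() / nr),
        "run_percentage": nr / float(n_voxels),
        "low_gray_level_run_emphasis": float((1.0 / g**2).sum() / nr),
        "high_gray_level_run_emphasis": float((g**2).sum() / nr),
        "short_run_low_gray_level_emphasis": float((1.0 / (g**2 * l**2)).sum() / nr),
        "short_run_high_gray_level_emphasis": float((g**2 / l**2).sum() / nr),
        "long_run_low_gray_level_emphasis": float((l**2 / g**2).sum() / nr),
        "long_run_high_gray_level_emphasis": float((g**2 * l**2).sum() / nr),
    }


def glrlm_features(
    img: ImageVolume,
    mask: TumorMask,
    disc: DiscretizationSpec,
    directions=TEXTURE_DIRECTIONS,
) -> dict[str, float]:
    """11 run-length statistics averaged over the 13 directions."""
    mask.check_grid(img)
    levels = discretize(img.values, mask.values, disc)
    return glrlm_features_from_levels(levels, mask.values, directions)


def glrlm_features_from_levels(
    levels: np.ndarray, mask: np.ndarray, directions=TEXTURE_DIRECTIONS
) -> dict[str, float]:
    if len(set(directions)) != len(directions):
        raise ValueError("texture directions must be unique")
    n_vox = int(mask.sum())
    per_dir = []
    for d in directions:
        gray, lengths = run_lengths(levels, mask, d)
        if lengths.size == 0:
            continue
        per_dir.append(glrlm_statistics(gray, lengths, n_vox))
    if not per_dir:
        raise ValueError("no direction produced a run")
    return {name: float(np.mean([s[name] for s in per_dir])) for name in GLRLM_NAMES}
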