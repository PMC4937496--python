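"""Undecimated (stationary) one-level 3D coiflet-1 decomposition.

The stationary wavelet transform keeps every sub-band on the original voxel
grid, so the tumor mask applies unchanged to all 8 sub-bands (LLL..HHH).
Odd axes are edge-padded to even length for the transform and cropped back;
boundary effects stay within the filter support, so masks a few voxels away
from the volume edge are unaffected. The energy-preserving normalization is
used, so the LLL band is a unit-DC-gain low pass (white-noise variance drops
by ~8x) and the eight sub-band energies sum to the image energy.
"""

from __future__ import annotations

import numpy as np
import pywt

from ..image import DiscretizationSpec, ImageVolume, TumorMask
from .firstorder import FIRST_ORDER_NAMES, _first_order_on_array
from .glcm import GLCM_NAMES, glcm_features_from_levels
from .glrlm import GLRLM_NAMES, glrlm_features_from_levels
from ..image import discretize

SUBBAND_NAMES = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

_WAVELET = "coif1"


def swt_subbands(values: np.ndarray, wavelet: str = _WAVELET) -> dict[str, np.ndarray]:
    """8 stationary-wavelet sub-bands of a 3D array, each on the input grid."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ValueError("expected a 3D array")
    filt_len = pywt.Wavelet(wavelet).dec_len
    if min(values.shape) < filt_len:
        raise ValueError(
            f"image shape {values.shape} smaller than the {wavelet} filter support ({filt_len})"
        )
    pad = [(0, s % 2) for s in values.shape]
    padded = np.pad(values, pad, mode="edge")
    coeffs = pywt.swtn(padded, wavelet, level=1, norm=True)[0]
    crop = tuple(slice(0, s) for s in values.shape)
    out = {}
    for band in SUBBAND_NAMES:
        key = band.replace("L", "a").replace("H", "d").lower()
        out[band] = coeffs[key][crop]
    return out


def reconstruct_from_subbands(bands: dict[str, np.ndarray], wavelet: str = _WAVELET) -> np.ndarray:
    """Inverse stationary transform; with untouched sub-bands returns the input."""
    shape = next(iter(bands.values())).shape
    pad = [(0, s % 2) for s in shape]
    coeffs = {}
    for band, arr in bands.items():
        key = band.replace("L", "a").replace("H", "d").lower()
        coeffs[key] = np.pad(arr, pad, mode="edge")
    rec = pywt.iswtn([coeffs], wavelet, norm=True)
    return rec[tuple(slice(0, s) for s in shape)]


def wavelet_features(
    img: ImageVolume, mask: TumorMask, disc: DiscretizationSpec
) -> dict[str, float]:
    """First-order + GLCM + GLRLM features on each of the 8 sub-bands (384 values).

    Sub-bands are computed from the full image (they see mask-exterior
    voxels within the filter support); features are then evaluated inside
    the original mask, discretizing each sub-band over its own in-mask range.
    """
    mask.check_grid(img)
    out: dict[str, float] = {}
    for band, arr in swt_subbands(img.values).items():
        fo = _first_order_on_array(arr, mask.values, disc, img.voxel_volume)
        levels = discretize(arr, mask.values, disc)
        glcm = glcm_features_from_levels(levels, mask.values)
        glrlm = glrlm_features_from_levels(levels, mask.values)
        prefix = f"wavelet_{band}"
        for name in FIRST_ORDER_NAMES:
            out[f"{prefix}_firstorder_{name}"] = fo[name]
        for name in GLCM_NAMES:
            out[f"{prefix}_glcm_{name}"] = glcm[name]
        for name in GLRLM_NAMES:
            out[f"{prefix}_glrlm_{name}"] = glrlm[name]
    return out
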