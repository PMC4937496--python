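"""Assembly of the full 440-feature radiomic vector and the cohort table.

Groups: intensity (15 first-order), shape (8), texture (22 GLCM + 11 GLRLM)
and wavelet (8 sub-bands x 48 = 384). 15 + 8 + 33 + 384 = 440.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..image import DiscretizationSpec, ImageVolume, TumorMask, discretize
from .firstorder import FIRST_ORDER_NAMES, first_order_features
from .glcm import GLCM_NAMES, glcm_features_from_levels
from .glrlm import GLRLM_NAMES, glrlm_features_from_levels
from .shape import SHAPE_NAMES, shape_features
from .wavelet import SUBBAND_NAMES, wavelet_features

N_FEATURES = 440


def feature_roster() -> tuple[list[str], dict[str, str]]:
    """Canonical ordered feature names and their group labels."""
    names: list[str] = []
    groups: dict[str, str] = {}
    for n in FIRST_ORDER_NAMES:
        name = f"firstorder_{n}"
        names.append(name)
        groups[name] = "intensity"
    for n in SHAPE_NAMES:
        name = f"shape_{n}"
        names.append(name)
        groups[name] = "shape"
    for n in GLCM_NAMES:
        name = f"glcm_{n}"
        names.append(name)
        groups[name] = "texture"
    for n in GLRLM_NAMES:
        name = f"glrlm_{n}"
        names.append(name)
        groups[name] = "texture"
    for band in SUBBAND_NAMES:
        for n in FIRST_ORDER_NAMES:
            name = f"wavelet_{band}_firstorder_{n}"
            names.append(name)
            groups[name] = "wavelet"
        for n in GLCM_NAMES:
            name = f"wavelet_{band}_glcm_{n}"
            names.append(name)
            groups[name] = "wavelet"
        for n in GLRLM_NAMES:
            name = f"wavelet_{band}_glrlm_{n}"
            names.append(name)
            groups[name] = "wavelet"
    assert len(names) == N_FEATURES
    return names, groups


FEATURE_NAMES, FEATURE_GROUPS = feature_roster()


@dataclass(frozen=True)
class FeatureVector:
    """One patient's 440 named feature values with group labels."""

    values: dict[str, float]
    groups: dict[str, str] = field(default_factory=lambda: dict(FEATURE_GROUPS))

    def __post_init__(self) -> None:
        if list(self.values) != FEATURE_NAMES:
            missing = set(FEATURE_NAMES) - set(self.values)
            extra = set(self.values) - set(FEATURE_NAMES)
            raise ValueError(f"feature roster mismatch: missing={missing} extra={extra}")
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad}")


@dataclass
class FeatureTable:
    """Patients x features matrix plus per-feature group labels.

    Tables built by :func:`extract_cohort` carry the canonical 440-feature
    roster; downstream operations (clustering, associations) also accept
    other feature tables, e.g. latent-redundancy phantoms.
    """

    data: pd.DataFrame  # index: patient ids, columns: feature names
    groups: pd.Series  # feature name -> group

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        if self.data.isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def patient_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @classmethod
    def from_vectors(cls, ids, vectors: list[FeatureVector]) -> "FeatureTable":
        df = pd.DataFrame([v.values for v in vectors], index=list(ids))
        return cls(data=df, groups=pd.Series(FEATURE_GROUPS))


def extract_all(
    img: ImageVolume, mask: TumorMask, disc: DiscretizationSpec | None = None
) -> FeatureVector:
    """Extract all 440 features from one image/mask pair. Deterministic."""
    if disc is None:
        disc = DiscretizationSpec()
    mask.check_grid(img)
    values: dict[str, float] = {}
    fo = first_order_features(img, mask, disc)
    for n in FIRST_ORDER_NAMES:
        values[f"firstorder_{n}"] = fo[n]
    sh = shape_features(mask, img.spacing)
    for n in SHAPE_NAMES:
        values[f"shape_{n}"] = sh[n]
    levels = discretize(img.values, mask.values, disc)
    glcm = glcm_features_from_levels(levels, mask.values)
    for n in GLCM_NAMES:
        values[f"glcm_{n}"] = glcm[n]
    glrlm = glrlm_features_from_levels(levels, mask.values)
    for n in GLRLM_NAMES:
        values[f"glrlm_{n}"] = glrlm[n]
    values.update(wavelet_features(img, mask, disc))
    ordered = {name: values[name] for name in FEATURE_NAMES}
    return FeatureVector(values=ordered)


def extract_cohort(images, masks, ids=None, disc: DiscretizationSpec | None = None) -> FeatureTable:
    """Extract the feature table for a whole cohort."""
    if ids is None:
        ids = [f"P{i:04d}" for i in range(len(images))]
    vectors = [extract_all(im, mk, disc) for im, mk in zip(images, masks)]
    return FeatureTable.from_vectors(ids, vectors)
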