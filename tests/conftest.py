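import numpy as np
import pytest

from radclust import (
    DiscretizationSpec,
    ImageVolume,
    PhantomSpec,
    TumorMask,
    extract_cohort,
    generate_cohort,
)


def small_spec(**overrides) -> PhantomSpec:
    """A fast phantom: small grid, small tumors, few patients."""
    defaults = dict(
        n_patients=12,
        grid_shape=(34, 34, 34),
        radii_range=(4.0, 6.0),
        seed=42,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_spec())


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return extract_cohort(
        small_cohort.images, small_cohort.masks, small_cohort.patient_ids
    )


@pytest.fixture(scope="session")
def one_pair(small_cohort):
    return small_cohort.images[0], small_cohort.masks[0]


@pytest.fixture()
def disc():
    return DiscretizationSpec()


def ball_mask(radius: int, pad: int = 3) -> TumorMask:
    n = 2 * (radius + pad) + 1
    c = (n - 1) / 2
    zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    return TumorMask((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2)


def volume_from(values: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> ImageVolume:
    return ImageVolume(np.asarray(values, dtype=float), spacing)
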