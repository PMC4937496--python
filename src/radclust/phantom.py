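"""Synthetic tumor-cohort generator with planted redundancy structure.

Each patient carries latent standard-normal factors that drive distinct,
well-separated aspects of the simulated tumor:

  factor 0 ("size")       scales the ellipsoid radii,
  factor 1 ("mean")       shifts the interior mean attenuation (HU),
  factor 2 ("texture")    sets the correlation length of the interior field,
  factor 3 ("amplitude")  scales the heterogeneity amplitude (HU sd).

Radiomic features extracted from such a cohort form redundant groups, each
group correlated with one factor — the ground truth that downstream
clustering is scored against. Survival follows an exponential proportional-
hazards model on the factors with independent uniform censoring; categorical
outcomes (histology, stage, HPV) follow logistic / ordinal-logit models.

The generator is fully reproducible from ``spec.seed`` (one RNG stream per
cohort).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import ImageVolume, TumorMask

FACTOR_NAMES = ("size", "mean", "texture", "amplitude")


@dataclass(frozen=True)
class FactorEffects:
    """How strongly each latent factor moves its image property.

    Units: ``size`` is a log radius multiplier per factor sd; ``mean`` is HU
    per sd; ``texture`` a log smoothing-kernel multiplier per sd;
    ``amplitude`` a log heterogeneity-sd multiplier per sd.
    """

    size: float = 0.18
    mean: float = 25.0
    texture: float = 0.35
    amplitude: float = 0.4


@dataclass(frozen=True)
class PhantomSpec:
    """Configuration of one synthetic cohort."""

    n_patients: int = 200
    grid_shape: tuple[int, int, int] = (44, 44, 44)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_latent: int = 4
    radii_range: tuple[float, float] = (5.0, 8.5)  # mm, per axis
    shape_perturbation_sd: float = 0.06  # degree-2 spherical-harmonic radius modulation
    mean_hu: float = 40.0
    background_hu: float = -100.0
    base_texture_sigma: float = 1.2  # voxels, Gaussian kernel of the correlated field
    base_amplitude: float = 30.0  # HU sd of the correlated field
    noise_sd: float = 3.0  # white noise, HU
    factor_effects: FactorEffects = field(default_factory=FactorEffects)
    survival_betas: tuple[float, ...] = (0.0, 0.8, 0.0, 0.0)  # log-hazard per factor sd
    baseline_hazard: float = 0.05
    censoring_rate: float = 0.3
    # log-odds per factor sd for each categorical outcome
    class_effects: dict = field(
        default_factory=lambda: {
            "histology": (0.0, 0.0, 0.0, 1.0),
            "stage": (1.2, 0.0, 0.0, 0.0),
            "hpv": (0.0, 0.0, 0.8, 0.0),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not (0.0 <= self.censoring_rate <= 1.0):
            raise ValueError("censoring_rate must be in [0, 1]")
        if self.censoring_rate >= 1.0:
            raise ValueError("censoring_rate 1 leaves no events; use < 1")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        if self.radii_range[0] <= 0 or self.radii_range[1] < self.radii_range[0]:
            raise ValueError("invalid radii_range")
        if self.noise_sd < 0 or self.base_amplitude < 0:
            raise ValueError("negative standard deviation")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not (1 <= self.n_latent <= len(FACTOR_NAMES)):
            raise ValueError(f"n_latent must be in [1, {len(FACTOR_NAMES)}]")
        if len(self.survival_betas) != self.n_latent:
            raise ValueError("survival_betas length must equal n_latent")
        # the largest perturbed, size-inflated ellipsoid must fit with margin
        # for the wavelet filter support (6 voxels); the size factor is
        # clipped at +-2 sd during generation so this bound is hard
        max_r = self.radii_range[1] * np.exp(2.0 * abs(self.factor_effects.size))
        max_r *= 1.0 + 4.0 * self.shape_perturbation_sd
        for n, sp in zip(self.grid_shape, self.voxel_spacing):
            if max_r / sp + 6 > n / 2:
                raise ValueError(
                    f"grid {self.grid_shape} too small for radii up to {max_r:.1f} mm "
                    f"plus a 6-voxel margin"
                )


@dataclass
class PhantomCohort:
    """Generated images, masks, clinical outcomes and the latent truth."""

    images: list[ImageVolume]
    masks: list[TumorMask]
    clinical: pd.DataFrame
    latent: pd.DataFrame  # patients x factors, the planted ground truth
    spec: PhantomSpec

    def __post_init__(self) -> None:
        n = len(self.images)
        if not (len(self.masks) == len(self.clinical) == len(self.latent) == n):
            raise ValueError("cohort components have inconsistent lengths")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.latent.index)


# --- tumor geometry -------------------------------------------------------

def _real_sh2(u: np.ndarray) -> np.ndarray:
    """Five real degree-2 spherical harmonics (unnormalized) at unit vectors u."""
    x, y, z = u[..., 0], u[..., 1], u[..., 2]
    return np.stack(
        [3.0 * z**2 - 1.0, x * y, x * z, y * z, x**2 - y**2], axis=-1
    )


def _tumor_mask(
    grid_shape, spacing, radii_mm, sh_coeffs, rng
) -> np.ndarray:
    center = (np.asarray(grid_shape) - 1) / 2.0
    axes = [np.arange(n) for n in grid_shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([zz, yy, xx], axis=-1).astype(float)
    phys = (coords - center) * np.asarray(spacing)
    r = np.linalg.norm(phys, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(r[..., None] > 0, phys / np.maximum(r, 1e-12)[..., None], 0.0)
    modulation = 1.0 + _real_sh2(u) @ sh_coeffs
    modulation = np.clip(modulation, 0.5, 1.5)
    ellip = np.sqrt(((phys / np.asarray(radii_mm)) ** 2).sum(axis=-1))
    return ellip <= modulation


# --- outcome models -------------------------------------------------------

def draw_survival(
    latent: np.ndarray,
    betas,
    baseline_hazard: float,
    censoring_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential proportional-hazards times with independent uniform censoring.

    The censoring horizon T_max is solved by bisection on the drawn event
    times so the realized censoring fraction matches ``censoring_rate``.
    """
    betas = np.asarray(betas, dtype=float)
    hazard = baseline_hazard * np.exp(latent @ betas)
    t_event = rng.exponential(1.0 / hazard)
    if censoring_rate <= 0:
        return t_event, np.ones(len(t_event), dtype=int)
    u = rng.uniform(size=len(t_event))

    def censored_fraction(t_max: float) -> float:
        return float(np.mean(u * t_max < t_event))

    lo, hi = 1e-9, float(t_event.max()) * 4.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if censored_fraction(mid) > censoring_rate:
            lo = mid
        else:
            hi = mid
    t_cens = u * hi
    event = (t_event <= t_cens).astype(int)
    time = np.where(event == 1, t_event, t_cens)
    time = np.maximum(time, 1e-9)
    return time, event


def draw_outcomes(
    latent: pd.DataFrame,
    survival_betas,
    baseline_hazard: float,
    censoring_rate: float,
    class_effects: dict,
    seed: int,
) -> pd.DataFrame:
    """Clinical table (time, event, histology, stage, hpv) from latent factors.

    Usable on its own to redraw outcomes — e.g. null outcomes independent of
    the images — without regenerating the cohort's images.
    """
    rng = np.random.default_rng(seed)
    z = latent.to_numpy()
    time, event = draw_survival(z, survival_betas, baseline_hazard, censoring_rate, rng)

    def logit_draw(effects) -> np.ndarray:
        eta = z @ np.asarray(effects, dtype=float)[: z.shape[1]]
        p = 1.0 / (1.0 + np.exp(-eta))
        return (rng.uniform(size=len(p)) < p).astype(int)

    histology = np.where(logit_draw(class_effects["histology"]) == 1, "squamous", "adeno")
    # ordinal 3-level stage: latent score + logistic noise against two cutpoints
    eta = z @ np.asarray(class_effects["stage"], dtype=float)[: z.shape[1]]
    score = eta + rng.logistic(size=len(eta))
    stage = np.select([score < -0.7, score < 0.7], ["I", "II"], default="III")
    hpv = np.where(logit_draw(class_effects["hpv"]) == 1, "positive", "negative")
    return pd.DataFrame(
        {
            "patient_id": list(latent.index),
            "time": time,
            "event": event,
            "histology": histology,
            "stage": stage,
            "hpv": hpv,
        }
    ).set_index("patient_id", drop=False)


# --- cohort generation ----------------------------------------------------

def generate_cohort(spec: PhantomSpec) -> PhantomCohort:
    """Generate a reproducible synthetic cohort from a validated spec."""
    rng = np.random.default_rng(spec.seed)
    ids = [f"P{i:04d}" for i in range(spec.n_patients)]
    z = rng.standard_normal((spec.n_patients, spec.n_latent))
    latent = pd.DataFrame(z, index=ids, columns=list(FACTOR_NAMES[: spec.n_latent]))
    eff = spec.factor_effects

    def factor(name: str) -> np.ndarray:
        return latent[name].to_numpy() if name in latent.columns else np.zeros(spec.n_patients)

    z_size, z_mean = factor("size"), factor("mean")
    z_tex, z_amp = factor("texture"), factor("amplitude")

    images, masks = [], []
    for i in range(spec.n_patients):
        radii = rng.uniform(*spec.radii_range, size=3) * np.exp(
            eff.size * np.clip(z_size[i], -2, 2)
        )
        sh = rng.normal(0.0, spec.shape_perturbation_sd, size=5)
        mask = _tumor_mask(spec.grid_shape, spec.voxel_spacing, radii, sh, rng)

        sigma = spec.base_texture_sigma * np.exp(eff.texture * np.clip(z_tex[i], -3, 3))
        field_ = ndimage.gaussian_filter(rng.standard_normal(spec.grid_shape), sigma)
        inside = field_[mask]
        field_ = (field_ - inside.mean()) / max(inside.std(), 1e-12)
        amplitude = spec.base_amplitude * np.exp(eff.amplitude * np.clip(z_amp[i], -3, 3))

        img = np.full(spec.grid_shape, spec.background_hu, dtype=float)
        img[mask] = spec.mean_hu + eff.mean * z_mean[i] + amplitude * field_[mask]
        if spec.noise_sd > 0:
            img += spec.noise_sd * rng.standard_normal(spec.grid_shape)
        images.append(ImageVolume(img, spec.voxel_spacing))
        masks.append(TumorMask(mask))

    clinical = draw_outcomes(
        latent,
        spec.survival_betas,
        spec.baseline_hazard,
        spec.censoring_rate,
        spec.class_effects,
        seed=int(rng.integers(2**31 - 1)),
    )
    return PhantomCohort(images=images, masks=masks, clinical=clinical, latent=latent, spec=spec)


def latent_feature_table(
    n_patients: int = 200,
    n_factors: int = 4,
    features_per_factor: int = 15,
    noise_sd: float = 0.7,
    seed: int = 0,
):
    """Feature-level redundancy phantom: groups of features sharing one factor.

    Each feature is its group's latent standard-normal factor plus independent
    Gaussian noise (positive unit loading), so the within-group correlation is
    1/(1 + noise_sd^2) — about 0.67 at the default, comparable to a compact
    radiomic cluster — and between-group correlation is 0. The planted
    partition is known by construction. Returns ``(FeatureTable, truth)``
    where ``truth`` maps feature name -> factor label.

    This is the ground-truth instrument for cluster-recovery experiments:
    unlike image-derived features, whose dispersion statistics load on any
    latent factor with both signs (splitting each factor into two
    anti-correlated poles under the 1 - r dissimilarity), its loadings are
    one-signed, so a k-cluster solution can match the k planted groups.
    """
    from .features.extract import FeatureTable

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_patients, n_factors))
    cols, labels = {}, {}
    for g in range(n_factors):
        for j in range(features_per_factor):
            name = f"factor{g}_feat{j:02d}"
            cols[name] = z[:, g] + noise_sd * rng.standard_normal(n_patients)
            labels[name] = f"factor{g}"
    ids = [f"P{i:04d}" for i in range(n_patients)]
    data = pd.DataFrame(cols, index=ids)
    table = FeatureTable(data=data, groups=pd.Series({c: "latent" for c in cols}))
    return table, pd.Series(labels, name="factor")


def planted_feature_groups(cohort: PhantomCohort, table, floor: float = 0.3) -> pd.Series:
    """Ground-truth partition: each feature -> its most-correlated latent factor.

    Features whose best absolute Pearson correlation with any factor falls
    below ``floor`` (and constant features, whose correlation is undefined)
    are labelled ``"unassigned"`` — they have no planted cluster.
    """
    data = table.data
    if list(data.index) != cohort.patient_ids:
        raise ValueError("feature table patients do not match the cohort")
    x = data.to_numpy()
    z = cohort.latent.to_numpy()
    xs = x.std(axis=0)
    zc = (z - z.mean(axis=0)) / z.std(axis=0)
    labels = []
    with np.errstate(invalid="ignore", divide="ignore"):
        xc = (x - x.mean(axis=0)) / np.where(xs > 0, xs, 1.0)
        corr = np.abs(xc.T @ zc) / len(z)
    for j, name in enumerate(data.columns):
        if xs[j] == 0 or corr[j].max() < floor:
            labels.append("unassigned")
        else:
            labels.append(cohort.latent.columns[int(corr[j].argmax())])
    return pd.Series(labels, index=data.columns, name="factor")
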