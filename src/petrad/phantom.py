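"""Synthetic PET/CT cohort generator.

Each phantom patient carries a single lung lesion on a cold background.  The
lesion support is an ellipsoid whose radius is modulated by low-order random
spherical harmonics (degrees 2-4), giving tunable boundary irregularity and
hence concavity while keeping the region star-shaped and connected.  Lesion
intensities are a Gaussian random field — white noise smoothed with a
Gaussian kernel whose width is the texture correlation length — scaled by a
heterogeneity amplitude around a class-specific mean, generated directly in
SUV units for PET and HU for CT.  Injected dose and body weight are
back-filled consistently so the activity-to-SUV conversion path can be
exercised end to end.

The two classes (EGFR mutant / wild-type) differ in lesion uptake level,
texture correlation length, heterogeneity amplitude and boundary
irregularity, with the contrast placed predominantly in the PET channel;
clinical covariates follow the marginal distributions of a 115-patient
(64 mutant / 51 wild-type) NSCLC cohort and depend on the class only through
their class-specific prevalences.  Everything is deterministic given the
configuration seed: patient ``i`` uses the independent stream seeded by
``(seed, i)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .image_io import VolumePair, write_cohort_table, write_volume_pair

__all__ = [
    "ClassParams",
    "PhantomConfig",
    "SyntheticCohort",
    "generate_lesion_mask",
    "synthesize_pet_ct",
    "simulate_cohort_table",
    "generate_cohort",
    "write_cohort",
]

# Table-derived cohort marginals the generator emulates
AGE_RANGE = (28, 77)
STAGE_12_PROB = 0.783
LOCATION_CATEGORIES = ("upper", "middle", "lower", "overlapping")
LOCATION_PROBS = (0.600, 0.078, 0.296, 0.026)
FEMALE_PROB = {"mutant": 0.578, "wild": 0.490}
FDG_DOSE_MCI_PER_KG = 0.108  # ~4 MBq/kg


@dataclass
class ClassParams:
    """Lesion appearance parameters for one class."""

    suv_mean: float
    texture_corr_mm: float
    heterogeneity: float
    boundary_irregularity: float
    ct_mean: float
    ct_texture: float
    ct_corr_mm: float = 5.0


def default_class_params() -> dict[str, ClassParams]:
    """PET-dominant class contrast: mutant lesions are hotter, more
    heterogeneous (shorter correlation length, larger amplitude) and more
    irregular; the CT channel carries a weaker, complementary density
    contrast so combining modalities genuinely helps."""
    return {
        "mutant": ClassParams(
            suv_mean=6.9,
            texture_corr_mm=3.7,
            heterogeneity=1.7,
            boundary_irregularity=0.20,
            ct_mean=40.0,
            ct_texture=24.0,
            ct_corr_mm=4.5,
        ),
        "wild": ClassParams(
            suv_mean=6.5,
            texture_corr_mm=4.5,
            heterogeneity=1.5,
            boundary_irregularity=0.16,
            ct_mean=28.0,
            ct_texture=19.0,
            ct_corr_mm=5.0,
        ),
    }


@dataclass
class PhantomConfig:
    n_mutant: int = 64
    n_wild: int = 51
    grid_shape: tuple[int, int, int] = (40, 44, 44)
    voxel_spacing: tuple[float, float, float] = (2.5, 2.0, 2.0)
    lesion_radius_mm: tuple[float, float] = (9.0, 15.0)
    radius_anisotropy: float = 0.10
    class_params: dict[str, ClassParams] = field(default_factory=default_class_params)
    background_suv: float = 0.6
    noise_sd: float = 0.15
    ct_background: float = -650.0
    ct_noise_sd: float = 20.0
    smoking_prevalence: tuple[float, float] = (0.234, 0.412)  # (mutant, wild)
    center_jitter_vox: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mutant < 2 or self.n_wild < 2:
            raise ValueError("need at least 2 patients per class")
        if self.noise_sd < 0 or self.ct_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        for label, cp in self.class_params.items():
            if cp.heterogeneity < 0 or cp.boundary_irregularity < 0 or cp.ct_texture < 0:
                raise ValueError(f"amplitudes must be >= 0 for class {label!r}")
        r_lo, r_hi = self.lesion_radius_mm
        if not 0 < r_lo <= r_hi:
            raise ValueError("lesion radius range must be positive and ordered")
        max_irr = max(cp.boundary_irregularity for cp in self.class_params.values())
        # radial factor is clipped at 3x below; bound the worst-case extent
        factor = 1.0 + min(2.0, 3.0 * max_irr) + self.radius_anisotropy
        half_extent = [
            n * s / 2.0 for n, s in zip(self.grid_shape, self.voxel_spacing)
        ]
        jitter_mm = self.center_jitter_vox * max(self.voxel_spacing)
        if r_hi * factor + jitter_mm >= min(half_extent):
            raise ValueError(
                f"largest lesion (radius {r_hi} mm, factor {factor:.2f}) does not "
                f"fit in the grid (half extent {min(half_extent):.1f} mm)"
            )


@dataclass
class SyntheticCohort:
    volumes: list[VolumePair]
    cohort_table: pd.DataFrame
    truth: list[dict]


def _real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    y = special.sph_harm_y(l, abs(m), theta, phi)
    if m == 0:
        return y.real
    if m > 0:
        return np.sqrt(2.0) * y.real
    return np.sqrt(2.0) * y.imag


def generate_lesion_mask(
    config: PhantomConfig, rng: np.random.Generator, class_label: str = "mutant"
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Random irregular ellipsoid lesion mask.

    Returns ``(mask, center_voxel)``.  The boundary irregularity amplitude of
    the class scales a fixed set of random harmonic coefficients, so with the
    same generator state a larger amplitude gives a strictly more perturbed
    version of the same shape (amplitude 0 gives a digitized ellipsoid).
    """
    cp = config.class_params[class_label]
    shape = config.grid_shape
    spacing = np.asarray(config.voxel_spacing, dtype=float)

    center = np.array([n // 2 for n in shape]) + rng.integers(
        -config.center_jitter_vox, config.center_jitter_vox + 1, size=3
    )
    r0 = float(rng.uniform(*config.lesion_radius_mm))
    radii = r0 * (1.0 + config.radius_anisotropy * rng.uniform(-1.0, 1.0, size=3))

    orders = [(l, m) for l in (2, 3, 4) for m in range(-l, l + 1)]
    coeffs = rng.standard_normal(len(orders))
    rms = np.sqrt((coeffs**2).sum() / (4.0 * np.pi))

    zz, yy, xx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    d = np.stack(
        [(zz - center[0]) * spacing[0], (yy - center[1]) * spacing[1], (xx - center[2]) * spacing[2]]
    )
    r = np.sqrt((d**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(r > 0, d[0] / r, 1.0), -1.0, 1.0))
    phi = np.arctan2(d[1], d[2])

    if cp.boundary_irregularity > 0 and rms > 0:
        f = np.zeros(shape)
        for (l, m), c in zip(orders, coeffs):
            f += c * _real_sph_harm(l, m, theta, phi)
        perturb = np.clip(cp.boundary_irregularity * f / rms, -0.6, 2.0)
    else:
        perturb = 0.0

    rho = np.sqrt(((d / radii[:, None, None, None]) ** 2).sum(axis=0))
    mask = rho <= 1.0 + perturb

    # guarantees: one 26-connected component, no internal holes
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    if not mask[tuple(center)]:
        raise RuntimeError("lesion mask does not contain its center voxel")
    return mask.astype(bool), tuple(int(c) for c in center)


def _correlated_field(
    shape: tuple[int, int, int],
    spacing: np.ndarray,
    corr_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    noise = rng.standard_normal(shape)
    sigma_vox = np.maximum(corr_mm / spacing, 1e-6)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="wrap")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def synthesize_pet_ct(
    mask: np.ndarray,
    config: PhantomConfig,
    class_label: str,
    rng: np.random.Generator,
    patient_id: str = "P000",
    meta: dict | None = None,
) -> VolumePair:
    """PET (SUV) and CT (HU) grids for one lesion mask.

    Lesion voxels follow a spatially correlated field around the class mean;
    the background is flat around ``background_suv``; independent Gaussian
    noise with the configured standard deviation is added to both channels.
    """
    cp = config.class_params[class_label]
    spacing = np.asarray(config.voxel_spacing, dtype=float)
    shape = config.grid_shape

    pet_field = _correlated_field(shape, spacing, cp.texture_corr_mm, rng)
    pet = np.full(shape, config.background_suv)
    pet[mask] = cp.suv_mean + cp.heterogeneity * pet_field[mask]
    if config.noise_sd > 0:
        pet = pet + config.noise_sd * rng.standard_normal(shape)
    pet = np.clip(pet, 0.0, None)

    ct_field = _correlated_field(shape, spacing, cp.ct_corr_mm, rng)
    ct = np.full(shape, config.ct_background)
    ct[mask] = cp.ct_mean + cp.ct_texture * ct_field[mask]
    if config.ct_noise_sd > 0:
        ct = ct + config.ct_noise_sd * rng.standard_normal(shape)

    if meta is None:
        weight_g = float(np.clip(rng.normal(70000.0, 12000.0), 45000.0, 110000.0))
        meta = {
            "body_weight_g": round(weight_g, 0),
            "injected_dose_mCi": round(FDG_DOSE_MCI_PER_KG * weight_g / 1000.0, 2),
        }
    return VolumePair(
        pet=pet, ct=ct, spacing=tuple(spacing), patient_id=patient_id, meta=dict(meta)
    )


def simulate_cohort_table(config: PhantomConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Clinical covariate table with the emulated cohort marginals.

    Ages are integers in 28-77 with median near 63 (right-weighted Beta
    draw); smoking is per-class Bernoulli; gender is per-class; stage and
    lobe location are class-independent.
    """
    labels = ["mutant"] * config.n_mutant + ["wild"] * config.n_wild
    n = len(labels)
    smoking_p = dict(zip(("mutant", "wild"), config.smoking_prevalence))

    rows = []
    for i, label in enumerate(labels):
        age = int(round(AGE_RANGE[0] + (AGE_RANGE[1] - AGE_RANGE[0]) * rng.beta(2.0, 1.0)))
        weight_g = float(np.clip(rng.normal(70000.0, 12000.0), 45000.0, 110000.0))
        rows.append(
            {
                "patient_id": f"P{i:03d}",
                "age": age,
                "gender": "female" if rng.random() < FEMALE_PROB[label] else "male",
                "smoking": "yes" if rng.random() < smoking_p[label] else "no",
                "stage": "I-II" if rng.random() < STAGE_12_PROB else "III-IV",
                "location": rng.choice(LOCATION_CATEGORIES, p=LOCATION_PROBS),
                "egfr_label": label,
                "injected_dose_mCi": round(FDG_DOSE_MCI_PER_KG * weight_g / 1000.0, 2),
                "body_weight_g": round(weight_g, 0),
            }
        )
    return pd.DataFrame(rows)


def generate_cohort(config: PhantomConfig) -> SyntheticCohort:
    """Full synthetic cohort: volumes, clinical table and generating truth.

    Bit-identical for identical configurations: patient ``i`` draws from the
    stream seeded by ``(config.seed, i)`` and the table from ``(seed, 2**20)``.
    """
    table = simulate_cohort_table(
        config, np.random.default_rng([config.seed, 2**20])
    )
    volumes: list[VolumePair] = []
    truth: list[dict] = []
    for i, row in table.iterrows():
        label = row["egfr_label"]
        rng = np.random.default_rng([config.seed, int(i)])
        mask, center = generate_lesion_mask(config, rng, label)
        meta = {
            "injected_dose_mCi": row["injected_dose_mCi"],
            "body_weight_g": row["body_weight_g"],
        }
        pair = synthesize_pet_ct(
            mask, config, label, rng, patient_id=row["patient_id"], meta=meta
        )
        volumes.append(pair)
        truth.append(
            {
                "patient_id": row["patient_id"],
                "label": label,
                "seed_point": center,
                "lesion_voxels": int(mask.sum()),
                "class_params": asdict(config.class_params[label]),
            }
        )
    return SyntheticCohort(volumes=volumes, cohort_table=table, truth=truth)


def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Persist a cohort as per-patient NIfTI pairs plus the cohort CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for pair in cohort.volumes:
        write_volume_pair(pair, out_dir)
    write_cohort_table(cohort.cohort_table, out_dir / "cohort.csv")
    seeds = pd.DataFrame(
        [
            {"patient_id": t["patient_id"],
             "seed_z": t["seed_point"][0],
             "seed_y": t["seed_point"][1],
             "seed_x": t["seed_point"][2]}
            for t in cohort.truth
        ]
    )
    seeds.to_csv(out_dir / "seed_points.csv", index=False)
    return out_dir
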