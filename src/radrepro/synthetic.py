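"""Synthetic paired test-retest cohort with known true reliability.

Each lesion carries a latent smoothed Gaussian texture field T drawn
once; scan s observes

    gain_s * (base + a * T + e_s * U_s + noise) + offset_s

where the amplitude a ~ N(0, var_shared) is common to both scans,
e_s ~ N(0, var_independent) is scan-specific with its own field U_s,
and scan 2 additionally drifts in gain/offset (T2-weighted intensities
are arbitrary units).  The true reliability of any statistic linear in
the amplitude is var_shared / (var_shared + var_independent) when noise
and drift are off.

Lesion masks are ellipsoids with small per-scan boundary jitter
(single-reader re-delineation); fat and muscle reference boxes carry
fixed mean levels plus noise for dual-reference normalization.
Clinical variables are drawn independently of texture by default, with
marginals matching the study cohort (74 lesions over 50 patients,
PI-RADS 18/30/26, one index lesion per patient).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "ClinicalVariables",
    "SimulationConfig",
    "PairedLesionCase",
    "generate_cohort",
    "expected_reliability",
    "simulate_feature_table",
]


@dataclass(frozen=True)
class ClinicalVariables:
    psad: float  # ng/mL^2, > 0
    prostate_volume: float  # mL, > 0
    pirads: int  # {3, 4, 5}
    isup: int  # {0..5}; 0 encodes a negative (ISUP < 1) lesion
    is_index: bool

    def __post_init__(self) -> None:
        if self.psad <= 0:
            raise ValueError("psad must be > 0")
        if self.prostate_volume <= 0:
            raise ValueError("prostate_volume must be > 0")
        if self.pirads not in (3, 4, 5):
            raise ValueError("pirads must be in {3, 4, 5} (PI-RADS < 3 excluded)")
        if self.isup not in range(6):
            raise ValueError("isup must be in {0..5}")


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 50
    n_lesions: int = 74  # total over all patients; >= n_patients
    grid_shape: tuple[int, int, int] = (96, 96, 20)
    voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 3.0)
    var_shared: float = 1.0  # sigma_a^2, between-lesion latent variance
    var_independent: float = 0.25  # sigma_e^2, scan-specific variance
    noise_sd: float = 5.0  # additive voxel noise, arbitrary units
    gain_range: tuple[float, float] = (0.8, 1.25)  # scan-2 drift
    offset_range: tuple[float, float] = (-50.0, 50.0)
    lesion_radius_range: tuple[float, float] = (4.0, 12.0)  # mm
    base_level: float = 400.0
    texture_scale: float = 100.0  # amplitude units of the latent field
    smoothing_mm: float = 1.5  # latent-field smoothing scale
    fat_level: float = 800.0
    muscle_level: float = 200.0
    reference_noise_sd: float = 10.0
    mask_jitter: int = 2  # per-scan one-voxel boundary patches
    seed: int = 0

    def __post_init__(self) -> None:
        if self.var_shared < 0 or self.var_independent < 0:
            raise ValueError("variances must be >= 0")
        if self.n_lesions < self.n_patients:
            raise ValueError("need at least one lesion per patient")


@dataclass
class PairedLesionCase:
    lesion_id: str
    patient_id: str
    scan1_volume: np.ndarray
    scan2_volume: np.ndarray
    scan1_mask: np.ndarray
    scan2_mask: np.ndarray
    fat_mask: np.ndarray
    muscle_mask: np.ndarray
    spacing: tuple[float, float, float]
    clinical: ClinicalVariables


def expected_reliability(config: SimulationConfig) -> float:
    """True ICC of amplitude-linear statistics: sa^2 / (sa^2 + se^2)."""
    total = config.var_shared + config.var_independent
    if total == 0:
        raise ValueError("reliability undefined: both variances are zero")
    return config.var_shared / total


def _latent_field(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    smoothing_mm: float,
) -> np.ndarray:
    """Unit-variance smoothed Gaussian random field."""
    raw = rng.standard_normal(shape)
    sigma_vox = [max(smoothing_mm / s, 1e-6) for s in spacing]
    smooth = ndimage.gaussian_filter(raw, sigma=sigma_vox)
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center: np.ndarray,
    radii_mm: np.ndarray,
    spacing: tuple[float, float, float],
) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    dist2 = sum(
        ((g - c) * s / r) ** 2
        for g, c, s, r in zip(grids, center, spacing, radii_mm)
    )
    return dist2 <= 1.0


def _jitter_mask(rng: np.random.Generator, mask: np.ndarray, n_patches: int) -> np.ndarray:
    """Randomly dilate or erode the boundary at a few seed voxels."""
    out = mask.copy()
    structure = ndimage.generate_binary_structure(3, 1)
    boundary = mask & ~ndimage.binary_erosion(mask, structure)
    outer = ndimage.binary_dilation(mask, structure) & ~mask
    for _ in range(n_patches):
        if rng.random() < 0.5:
            candidates = np.argwhere(outer)
            if len(candidates):
                v = candidates[rng.integers(len(candidates))]
                out[tuple(v)] = True
        else:
            candidates = np.argwhere(boundary)
            if len(candidates):
                v = candidates[rng.integers(len(candidates))]
                trial = out.copy()
                trial[tuple(v)] = False
                # never disconnect or empty the mask
                if trial.any():
                    out = trial
    return out


def _corner_box(shape, lo_frac, hi_frac) -> tuple[slice, ...]:
    return tuple(
        slice(int(lo * n), max(int(lo * n) + 2, int(hi * n)))
        for n, lo, hi in zip(shape, (lo_frac,) * 3, (hi_frac,) * 3)
    )


def _draw_clinical(
    rng: np.random.Generator, n_patients: int, n_lesions: int
) -> list[tuple[str, ClinicalVariables]]:
    """Per-lesion clinical rows with study-cohort marginals."""
    # lesion counts per patient: each patient gets one, the remainder
    # spread at random (max 3 extra per patient)
    extra = n_lesions - n_patients
    counts = np.ones(n_patients, dtype=int)
    while extra > 0:
        i = int(rng.integers(n_patients))
        if counts[i] < 4:
            counts[i] += 1
            extra -= 1
    rows: list[tuple[str, ClinicalVariables]] = []
    pirads_p = np.array([18, 30, 26], dtype=float) / 74.0
    # index-lesion ISUP marginals: 11 negative, then 8/15/8/6/2 for 1..5
    isup_p = np.array([11, 8, 15, 8, 6, 2], dtype=float) / 50.0
    for pi in range(n_patients):
        psad = float(np.exp(rng.normal(np.log(0.25), 0.7)))
        volume = float(np.clip(rng.normal(46.94, 19.49), 15.0, 120.0))
        isup = int(rng.choice(6, p=isup_p))
        index_slot = int(rng.integers(counts[pi]))
        for li in range(counts[pi]):
            is_index = li == index_slot
            clin = ClinicalVariables(
                psad=psad,
                prostate_volume=volume,
                pirads=int(3 + rng.choice(3, p=pirads_p)),
                # non-index lesions are lower-or-equal grade
                isup=isup if is_index else int(rng.integers(0, max(isup, 0) + 1)),
                is_index=is_index,
            )
            rows.append((f"P{pi + 1:03d}", clin))
    return rows


def generate_cohort(config: SimulationConfig) -> list[PairedLesionCase]:
    """Generate the full paired cohort; bit-identical under one seed."""
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.grid_shape)
    spacing = tuple(config.voxel_spacing)
    extent_mm = np.array([n * s for n, s in zip(shape, spacing)])

    r_lo, r_hi = config.lesion_radius_range
    margin_mm = 2.0 * np.asarray(spacing) + 2.0  # jitter + center wobble room
    too_big = r_hi >= extent_mm / 2.0 - margin_mm
    if np.any(too_big):
        axis = int(np.argmax(too_big))
        raise ValueError(
            f"lesion (max radius {r_hi} mm) does not fit grid axis {axis} "
            f"({shape[axis]} voxels x {spacing[axis]} mm = {extent_mm[axis]} mm)"
        )

    # reference boxes in opposite corners, shared across the cohort grid
    fat_box = _corner_box(shape, 0.02, 0.15)
    muscle_box = _corner_box(shape, 0.85, 0.98)

    clinical_rows = _draw_clinical(rng, config.n_patients, config.n_lesions)
    cases: list[PairedLesionCase] = []
    sd_a = np.sqrt(config.var_shared)
    sd_e = np.sqrt(config.var_independent)
    for i, (patient_id, clin) in enumerate(clinical_rows):
        lesion_id = f"L{i + 1:03d}"
        center = np.array(shape, dtype=float) / 2.0 + rng.uniform(-2, 2, size=3)
        radii = rng.uniform(r_lo, r_hi, size=3)
        radii[2] = min(radii[2], extent_mm[2] * 0.3)  # respect thick slices
        base_mask = _ellipsoid_mask(shape, center, radii, spacing)

        latent = _latent_field(rng, shape, spacing, config.smoothing_mm)
        amplitude = rng.normal(0.0, sd_a) if sd_a > 0 else 0.0

        volumes, masks = [], []
        for scan in (1, 2):
            e = rng.normal(0.0, sd_e) if sd_e > 0 else 0.0
            indep = (
                _latent_field(rng, shape, spacing, config.smoothing_mm)
                if sd_e > 0
                else np.zeros(shape)
            )
            noise = (
                rng.normal(0.0, config.noise_sd, size=shape)
                if config.noise_sd > 0
                else 0.0
            )
            vol = (
                config.base_level
                + config.texture_scale * (amplitude * latent + e * indep)
                + noise
            )
            if scan == 2:
                gain = rng.uniform(*config.gain_range)
                offset = rng.uniform(*config.offset_range)
            else:
                gain, offset = 1.0, 0.0
            vol = gain * vol + offset
            # reference tissues (after drift: they drift with the scan)
            ref_noise = (
                rng.normal(0.0, config.reference_noise_sd, size=shape)
                if config.reference_noise_sd > 0
                else 0.0
            )
            ref = np.zeros(shape)
            ref[fat_box] = config.fat_level
            ref[muscle_box] = config.muscle_level
            ref_mask = np.zeros(shape, dtype=bool)
            ref_mask[fat_box] = True
            ref_mask[muscle_box] = True
            vol = np.where(ref_mask, gain * (ref + ref_noise) + offset, vol)
            volumes.append(vol)
            mask = (
                _jitter_mask(rng, base_mask, config.mask_jitter)
                if config.mask_jitter > 0
                else base_mask.copy()
            )
            masks.append(mask)

        fat_mask = np.zeros(shape, dtype=bool)
        fat_mask[fat_box] = True
        muscle_mask = np.zeros(shape, dtype=bool)
        muscle_mask[muscle_box] = True
        for m in masks:
            assert not (m & (fat_mask | muscle_mask)).any()

        cases.append(
            PairedLesionCase(
                lesion_id=lesion_id,
                patient_id=patient_id,
                scan1_volume=volumes[0],
                scan2_volume=volumes[1],
                scan1_mask=masks[0],
                scan2_mask=masks[1],
                fat_mask=fat_mask,
                muscle_mask=muscle_mask,
                spacing=spacing,
                clinical=clin,
            )
        )
    return cases


def simulate_feature_table(
    n_subjects: int,
    true_icc: float,
    n_features: int = 1,
    seed: int | None = None,
    rater_sd: float = 0.0,
) -> np.ndarray:
    """Paired measurements from the two-way random model.

    Returns an array shaped (n_features, n_subjects, 2) where each
    feature column pair is subject_effect + residual, with
    Var(subject) = true_icc and Var(residual) = 1 - true_icc, so the
    expected ICC(2,1) equals ``true_icc``.  An optional rater effect of
    standard deviation ``rater_sd`` can be added to scan 2.
    """
    if not 0.0 <= true_icc < 1.0:
        raise ValueError("true_icc must lie in [0, 1)")
    if n_subjects < 3:
        raise ValueError("need n_subjects >= 3")
    rng = np.random.default_rng(seed)
    subj = rng.normal(0.0, np.sqrt(true_icc), size=(n_features, n_subjects, 1))
    resid = rng.normal(0.0, np.sqrt(1.0 - true_icc), size=(n_features, n_subjects, 2))
    table = subj + resid
    if rater_sd > 0:
        table[:, :, 1] += rng.normal(0.0, rater_sd, size=(n_features, 1))
    return table
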