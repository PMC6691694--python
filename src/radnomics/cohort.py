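"""Synthetic study cohort: MR phantoms, clinical covariates, censored outcomes.

The generator emulates a 140-patient nasopharyngeal-carcinoma cohort imaged
with two co-registered MR modalities on an anisotropic grid (in-plane
~0.9 mm, effective slice spacing 5 mm = 4 mm thickness + 1 mm gap).  Each
patient carries a latent *texture heterogeneity* value in [0, 1] that drives
both the in-tumor intensity texture (a spatially correlated random field
whose amplitude scales with heterogeneity) and, through a proportional-
hazards model with known coefficients, the hazard of local recurrence.
The heterogeneity value and the true coefficients are ground truth: they are
stored with the cohort but never consumed by any pipeline stage.

Survival times are exponential under the linear predictor; censoring is
uniform on [36, 68] months so that every censored patient has at least the
36-month minimum follow-up of the study design.  The baseline hazard is
calibrated so that the expected event fraction is ~30%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from radnomics.io import VolumePair, TumorMask, save_patient

__all__ = [
    "PhantomParams",
    "SurvivalParams",
    "CohortParams",
    "SyntheticCohort",
    "generate_tumor_phantom",
    "generate_clinical",
    "generate_survival",
    "generate_cohort",
    "write_cohort",
    "TABLE1_MARGINALS",
]

# Pooled training+validation category frequencies of the study population
# (n = 140) used as sampling marginals for the clinical covariates.
TABLE1_MARGINALS = {
    "male_fraction": 103 / 140,
    "age_mean": 46.0,
    "age_sd": 10.0,
    "age_range": (14.0, 71.0),
    "t_stage_probs": (11 / 140, 41 / 140, 63 / 140, 25 / 140),
    "n_stage_probs": (11 / 140, 44 / 140, 73 / 140, 12 / 140),
    # WHO histological types I/II/III
    "histology_probs": (0.0, 3 / 140, 137 / 140),
    "hgb_mean": 135.0,
    "hgb_sd": 13.0,
    "platelet_mean": 235.0,
    "platelet_sd": 55.0,
}


@dataclass
class PhantomParams:
    """Geometry and texture parameters of the image phantoms.

    Attributes
    ----------
    grid_shape : voxels per axis (all >= 16).
    voxel_spacing : mm per axis; default (0.9, 0.9, 5.0) — 23 cm FOV / 256
        in-plane and 4 mm slices with a 1 mm gap.
    tumor_radius_range : (min, max) mean tumor radius in mm.
    modality_base : background-free in-tumor mean intensity per modality.
    modality_texture_scale : texture-field amplitude per modality at
        heterogeneity = 1 (intensity units).
    background_level : surrounding-tissue intensity (both modalities).
    noise_sd : additive Gaussian noise SD (intensity units), everywhere.
    correlation_voxels : Gaussian smoothing sigma (voxels) of the texture
        field; gives a correlation length of ~3 voxels at the default 1.5.
    """

    n_patients: int = 140
    grid_shape: tuple[int, int, int] = (48, 48, 16)
    voxel_spacing: tuple[float, float, float] = (0.9, 0.9, 5.0)
    tumor_radius_range: tuple[float, float] = (6.0, 11.0)
    modality_base: dict = field(default_factory=lambda: {"CET1-w": 300.0, "T2-w": 420.0})
    modality_texture_scale: dict = field(default_factory=lambda: {"CET1-w": 60.0, "T2-w": 45.0})
    background_level: float = 120.0
    noise_sd: float = 6.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(g < 16 for g in self.grid_shape):
            raise ValueError(f"grid_shape must be >= 16 per axis, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        lo, hi = self.tumor_radius_range
        if not (0 < lo <= hi):
            raise ValueError("tumor_radius_range must satisfy 0 < min <= max")


@dataclass
class SurvivalParams:
    """Ground-truth proportional-hazards model for local-recurrence times.

    ``true_betas`` maps covariate names (``heterogeneity`` plus any clinical
    column) to log-hazard-ratios.  ``baseline_scale`` is the constant baseline
    hazard per month, or ``None`` to calibrate it so that the expected event
    fraction equals ``target_event_fraction`` under the censoring scheme.
    """

    true_betas: dict = field(default_factory=lambda: {"heterogeneity": 2.0, "n_stage": 0.2})
    baseline_scale: float | None = None
    target_event_fraction: float = 0.30
    censor_window: tuple[float, float] = (36.0, 68.0)
    min_followup: float = 36.0
    max_retries: int = 10


@dataclass
class CohortParams:
    phantom: PhantomParams = field(default_factory=PhantomParams)
    survival: SurvivalParams = field(default_factory=SurvivalParams)


def _patient_rng(seed: int, patient_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(patient_index,)))


def _correlated_field(shape, rng, sigma) -> np.ndarray:
    """Unit-variance spatially correlated Gaussian field (smoothed white noise)."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=sigma, mode="wrap")
    sd = smooth.std()
    if sd > 0:
        smooth /= sd
    return smooth


def generate_tumor_phantom(
    params: PhantomParams,
    patient_index: int,
    heterogeneity: float,
) -> tuple[VolumePair, TumorMask]:
    """Generate one patient's dual-modality phantom and tumor mask.

    The tumor is an ellipsoid with 2-4 attached spherical lobes, placed at
    the grid centre (with a small jitter).  In-mask intensities are
    ``base + heterogeneity * texture_scale * field + noise`` where ``field``
    is a unit-variance spatially correlated Gaussian field, independent per
    modality.  Outside the mask the intensity is the background level plus
    the same additive noise.

    Deterministic: the same ``(rng_seed, patient_index)`` always yields
    bit-identical volumes.

    Raises
    ------
    ValueError
        If the requested tumor cannot fit inside the grid.
    """
    if not 0.0 <= heterogeneity <= 1.0:
        raise ValueError("heterogeneity must be in [0, 1]")
    rng = _patient_rng(params.rng_seed, patient_index)
    shape = tuple(params.grid_shape)
    spacing = np.asarray(params.voxel_spacing, dtype=float)
    half_extent_mm = (np.asarray(shape) - 1) / 2.0 * spacing

    lo, hi = params.tumor_radius_range
    r_mean = rng.uniform(lo, hi)
    # mildly anisotropic semi-axes around the mean radius
    radii = r_mean * rng.uniform(0.8, 1.2, size=3)
    lobe_r = 0.45 * r_mean
    if np.any(radii + lobe_r + spacing >= half_extent_mm):
        raise ValueError(
            f"tumor (semi-axes {np.round(radii, 1)} mm + lobes {lobe_r:.1f} mm) does not fit "
            f"inside grid half-extent {np.round(half_extent_mm, 1)} mm"
        )

    centre_mm = (rng.uniform(-1.0, 1.0, size=3)) * spacing  # sub-voxel-ish jitter
    idx = np.indices(shape).astype(float)
    coords = (idx - (np.asarray(shape)[:, None, None, None] - 1) / 2.0) * spacing[:, None, None, None]
    rel = coords - centre_mm[:, None, None, None]
    mask = (rel[0] / radii[0]) ** 2 + (rel[1] / radii[1]) ** 2 + (rel[2] / radii[2]) ** 2 <= 1.0

    n_lobes = int(rng.integers(2, 5))
    for _ in range(n_lobes):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        lobe_centre = centre_mm + u * radii * 0.9
        d2 = ((coords[0] - lobe_centre[0]) ** 2
              + (coords[1] - lobe_centre[1]) ** 2
              + (coords[2] - lobe_centre[2]) ** 2)
        mask |= d2 <= lobe_r ** 2

    volumes = {}
    for modality in ("CET1-w", "T2-w"):
        fieldv = _correlated_field(shape, rng, sigma=1.5)
        vol = np.full(shape, params.background_level, dtype=float)
        vol[mask] = (
            params.modality_base[modality]
            + heterogeneity * params.modality_texture_scale[modality] * fieldv[mask]
        )
        if params.noise_sd > 0:
            vol += rng.normal(0.0, params.noise_sd, size=shape)
        volumes[modality] = vol

    pid = f"P{patient_index:03d}"
    pair = VolumePair(volumes["CET1-w"], volumes["T2-w"], tuple(spacing), patient_id=pid)
    return pair, TumorMask(mask.astype(np.uint8), tuple(spacing))


def generate_clinical(n_patients: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw a clinical table from the pooled study marginals.

    Ages are truncated-normal(46, 10) on [14, 71]; gender, T/N stage and WHO
    histology follow the pooled category frequencies; hemoglobin and platelet
    counts are normal draws whose dichotomized fractions (>= 136 g/L,
    >= 238 x 10^9/L) match the study's split.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    m = TABLE1_MARGINALS
    a = (m["age_range"][0] - m["age_mean"]) / m["age_sd"]
    b = (m["age_range"][1] - m["age_mean"]) / m["age_sd"]
    age = stats.truncnorm.rvs(a, b, loc=m["age_mean"], scale=m["age_sd"],
                              size=n_patients, random_state=rng)
    gender = (rng.random(n_patients) < m["male_fraction"]).astype(int)  # male=1, female=0
    t_stage = rng.choice([1, 2, 3, 4], size=n_patients, p=m["t_stage_probs"])
    n_stage = rng.choice([1, 2, 3, 4], size=n_patients, p=m["n_stage_probs"])
    histology = rng.choice([1, 2, 3], size=n_patients, p=m["histology_probs"])
    hgb = np.maximum(rng.normal(m["hgb_mean"], m["hgb_sd"], size=n_patients), 60.0)
    platelets = np.maximum(rng.normal(m["platelet_mean"], m["platelet_sd"], size=n_patients), 50.0)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n_patients)],
            "age": age,
            "gender": gender,
            "t_stage": t_stage,
            "n_stage": n_stage,
            "histology": histology,
            "hgb": hgb,
            "platelets": platelets,
        }
    )


def _calibrate_baseline(linpred: np.ndarray, censor_window, target: float) -> float:
    """Solve for the constant baseline hazard giving the target event fraction.

    With T ~ Exp(rate = lam * exp(lp)) and independent censoring
    C ~ U(c0, c1), P(event) has the closed form
    1 - (exp(-r c0) - exp(-r c1)) / (r (c1 - c0)) with r = lam * exp(lp),
    averaged over patients; solved for lam by bisection.
    """
    c0, c1 = censor_window

    def p_event(lam: float) -> float:
        r = lam * np.exp(linpred)
        return float(np.mean(1.0 - (np.exp(-r * c0) - np.exp(-r * c1)) / (r * (c1 - c0))))

    return float(optimize.brentq(lambda lam: p_event(lam) - target, 1e-8, 1.0, xtol=1e-10))


def generate_survival(
    clinical: pd.DataFrame,
    heterogeneity: np.ndarray,
    params: SurvivalParams,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Draw censored local-recurrence-free survival outcomes.

    Event times follow an exponential proportional-hazards model with linear
    predictor ``sum(true_betas[c] * covariate[c])``; censoring times are
    uniform on ``censor_window`` so every censored time is at least the
    minimum follow-up.  Returns ``(outcomes, ground_truth)`` where outcomes
    has columns patient_id/time/event and ground_truth records the true
    coefficients and per-patient linear predictors.

    Raises
    ------
    RuntimeError
        If every draw is censored after ``max_retries`` attempts.
    """
    n = len(clinical)
    covs = {"heterogeneity": np.asarray(heterogeneity, dtype=float)}
    for c in clinical.columns:
        if c != "patient_id":
            covs[c] = clinical[c].to_numpy(dtype=float)
    missing = [k for k in params.true_betas if k not in covs]
    if missing:
        raise KeyError(f"true_betas reference unknown covariates: {missing}")
    lp = np.zeros(n)
    for name, beta in params.true_betas.items():
        lp += beta * covs[name]

    lam0 = params.baseline_scale
    if lam0 is None:
        lam0 = _calibrate_baseline(lp, params.censor_window, params.target_event_fraction)

    c0, c1 = params.censor_window
    if c0 < params.min_followup:
        raise ValueError("censor_window must start at or after min_followup")
    for _ in range(params.max_retries):
        t_event = rng.exponential(1.0 / (lam0 * np.exp(lp)))
        t_cens = rng.uniform(c0, c1, size=n)
        event = t_event <= t_cens
        if event.any():
            break
    else:
        raise RuntimeError(
            f"no events in {params.max_retries} draws at baseline hazard {lam0:.3g}"
        )
    time = np.where(event, t_event, t_cens)
    time = np.maximum(time, 1e-6)
    outcomes = pd.DataFrame(
        {"patient_id": clinical["patient_id"], "time": time, "event": event.astype(int)}
    )
    ground_truth = {
        "true_betas": dict(params.true_betas),
        "baseline_scale": lam0,
        "linear_predictor": lp.tolist(),
        "heterogeneity": np.asarray(heterogeneity, dtype=float).tolist(),
    }
    return outcomes, ground_truth


@dataclass
class SyntheticCohort:
    """A complete synthetic study cohort.

    ``patients`` holds (VolumePair, TumorMask) per patient; ``clinical`` and
    ``outcomes`` are the pipeline-facing tables.  ``ground_truth`` holds the
    generating coefficients and latent heterogeneity — it exists for
    validation of the generator itself and is never read by pipeline stages.
    """

    params: CohortParams
    patients: list
    clinical: pd.DataFrame
    outcomes: pd.DataFrame
    ground_truth: dict

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def patient_ids(self) -> list:
        return list(self.clinical["patient_id"])


def generate_cohort(params: CohortParams | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate the full cohort (images, masks, clinical table, outcomes).

    ``seed`` overrides ``params.phantom.rng_seed`` when given.  Identical
    seeds give bit-identical cohorts.
    """
    params = params or CohortParams()
    if seed is not None:
        params.phantom.rng_seed = int(seed)
    pp = params.phantom
    master = np.random.default_rng(np.random.SeedSequence(entropy=pp.rng_seed, spawn_key=(10_000,)))
    heterogeneity = master.uniform(0.0, 1.0, size=pp.n_patients)
    clinical = generate_clinical(pp.n_patients, master)
    outcomes, ground_truth = generate_survival(clinical, heterogeneity, params.survival, master)
    patients = [
        generate_tumor_phantom(pp, i, heterogeneity[i]) for i in range(pp.n_patients)
    ]
    return SyntheticCohort(params, patients, clinical, outcomes, ground_truth)


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write the cohort to disk: NIfTI volumes/masks, CSV tables, manifest.

    The manifest records the seed and generator parameters; the ground truth
    goes to a separate ``ground_truth.json`` which no pipeline stage reads.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img_dir = directory / "images"
    patients = []
    for (pair, mask), pid in zip(cohort.patients, cohort.patient_ids):
        paths = save_patient(pair, mask, img_dir, patient_id=pid)
        patients.append({"patient_id": pid, **paths})
    cohort.clinical.to_csv(directory / "clinical.csv", index=False)
    cohort.outcomes.to_csv(directory / "outcomes.csv", index=False)
    pp = asdict(cohort.params.phantom)
    # generator settings minus the ground-truth effects (those stay in
    # ground_truth.json, which pipeline stages never read)
    sp = asdict(cohort.params.survival)
    for hidden in ("true_betas", "baseline_scale", "target_event_fraction"):
        sp.pop(hidden, None)
    manifest = {
        "seed": cohort.params.phantom.rng_seed,
        "phantom_params": pp,
        "censoring": sp,
        "patients": patients,
        "column_dictionary": {
            "age": "years",
            "gender": "1=male, 0=female",
            "t_stage": "ordinal 1-4",
            "n_stage": "ordinal 1-4",
            "histology": "WHO type 1/2/3",
            "hgb": "hemoglobin, g/L",
            "platelets": "platelet count, 10^9/L",
            "time": "local-recurrence-free survival, months",
            "event": "1=local recurrence observed, 0=censored",
        },
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(directory / "ground_truth.json", "w") as fh:
        json.dump(cohort.ground_truth, fh, indent=2)
    return manifest
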