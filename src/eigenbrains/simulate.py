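"""Synthetic FDG-PET cohort generator with planted latent structure.

The generator stands in for a four-group dementia cohort (dysexecutive AD,
behavioural-variant FTD, behavioural AD, amnestic AD; 52/30/7/28 patients)
plus 117 matched cognitively unimpaired controls.  Each subject image is

    g_i * ( baseline + sum_k loading_ik * pattern_k + noise )

where the ``pattern_k`` are k_true orthonormal, bipolar, spatially smooth
maps on the brain mask (zero over the reference region — the pons
stand-in is spared, which is exactly why it anchors normalization),
subject loadings are Gaussian around group-specific means, and ``g_i`` is
a multiplicative global-uptake nuisance that reference normalization
removes.  Loadings drive the clinical table: cognitive composites are
linear functions of loadings on the scaled-score convention (population
mean 10, SD 3), behavioural flags are Bernoulli draws through a logistic
link, and ages, sex, education and biomarkers follow the published
per-group demographics.

Everything is deterministic given ``SimConfig.seed``: one seed sequence
per cohort, with per-subject child streams spawned deterministically.

``make_reference_cohort`` is separate from the stochastic generator: it is
a fixed 117-row categorical table reproducing the published per-group
symptom, sex and APOE4 counts exactly (continuous fields filled with
per-group means), for tests that need the printed cells rather than a
random draw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grid import TemplateGrid, default_grid
from .images import FWHM_TO_SIGMA, SubjectImage
from .decoding import TopicMap

__all__ = [
    "SimConfig",
    "GroundTruth",
    "PATIENT_GROUPS",
    "GROUP_SIZES",
    "REFERENCE_STATS",
    "generate_cohort",
    "generate_topic_maps",
    "make_reference_cohort",
    "save_cohort",
]

PATIENT_GROUPS = ("dAD", "bvFTD", "bvAD", "aAD")
GROUP_SIZES = (52, 30, 7, 28)

#: Published per-group demographic/clinical reference values (columns:
#: dAD, bvFTD, bvAD, aAD).  Ages in years, STMS on its 0-38 scale,
#: biomarkers as median values; counts as (numerator per group).
REFERENCE_STATS = {
    "age_onset_mean": (53.70, 54.40, 62.70, 74.90),
    "age_onset_sd": (5.35, 11.20, 5.53, 4.83),
    "age_scan_mean": (57.10, 59.2, 66.40, 78.6),
    "age_scan_sd": (5.30, 9.97, 5.38, 4.33),
    "males": (34, 13, 4, 16),
    "education_mean": (15.10, 15.30, 17.00, 15.20),
    "education_sd": (2.22, 2.35, 2.10, 3.22),
    "stms_mean": (21.20, 29.40, 30.00, 27.10),
    "stms_sd": (8.59, 6.05, 5.20, 4.44),
    "social_disinhibition": (0, 25, 5, 1),
    "apathy": (14, 19, 4, 2),
    "lack_of_empathy": (0, 9, 3, 0),
    "perseverative": (0, 10, 6, 0),
    "hyperorality": (1, 15, 3, 0),
    "executive_dysfunction": (52, 30, 7, 22),
    "apoe4_available": (29, 28, 1, 26),
    "apoe4_carriers": (15, 6, 0, 18),
    "ptau_median": (76.3, 31.1, 27.4, 80.6),
    "ab42_median": (359.0, 1084.0, 612.0, 397.0),
    "ttau_median": (504.0, 149.0, 271.0, 632.0),
    "ati_median": (0.42, 2.0, 0.41, 0.40),
    "pib_median": (2.39, np.nan, 2.15, 2.60),
    "av1451_median": (2.1, np.nan, 1.29, 1.73),
}

BEHAVIOUR_FLAGS = (
    "social_disinhibition",
    "apathy",
    "lack_of_empathy",
    "perseverative",
    "hyperorality",
    "executive_dysfunction",
)

# Default generative links (rows: flag/domain; entries: intercept + one
# weight per latent component).  Magnitudes are free parameters of the
# simulation: the literature provides estimates on real data, not
# generative truth, so these are plausibility choices exposed in
# SimConfig.  Component roles under the default loading means: 1 =
# frontotemporal/behavioural, 2 = heteromodal/cognitive, 3 =
# temporo-parietal/perceptual.
_DEFAULT_COGNITION_WEIGHTS = {
    "composite_executive": (-0.5, -1.8, -0.6),
    "composite_memory": (-0.3, -0.8, -1.2),
    "composite_fluency": (-1.0, -0.8, 0.0),
    "composite_visuospatial": (-0.2, -0.9, -1.0),
}
_DEFAULT_BEHAVIOUR_WEIGHTS = {
    "social_disinhibition": (-2.5, 1.8, -1.0, -0.8),
    "apathy": (-1.5, 1.0, -0.3, -0.5),
    "lack_of_empathy": (-3.0, 1.5, -0.8, -0.3),
    "perseverative": (-3.0, 1.5, -0.5, 0.2),
    "hyperorality": (-2.8, 1.4, -0.6, -0.2),
    "executive_dysfunction": (1.5, 0.2, 1.2, 0.8),
}
_DEFAULT_STMS_WEIGHTS = (-0.5, -2.0, -0.8)

# Default group-mean loadings (rows: dAD, bvFTD, bvAD, aAD, CU).
# Qualitative ordering: component 1 highest for bvAD, component 2 highest
# for dAD, component 3 higher for dAD/aAD than bvFTD; controls 0.  The
# magnitudes were solved (once, at the default grid/noise settings) so
# that the size-weighted covariance of the EFFECTIVE subject loadings —
# after the per-image IQR scaling, which shrinks rows in proportion to
# their total signal content — is diagonal with well-separated variances
# (about 4.1, 2.6, 1.5 including the within-group part).  Correlated or
# near-degenerate effective loadings would rotate the population
# principal axes away from the planted patterns, making "pattern
# recovery" a property of the simulation rather than of the
# decomposition.
_DEFAULT_LOADING_MEANS = (
    (-7.50, 5.53, -1.04),  # dAD
    (6.75, 4.51, -5.92),   # bvFTD
    (7.35, -1.12, 7.50),   # bvAD
    (-7.50, -7.50, -5.42), # aAD
    (0.0, 0.0, 0.0),       # CU
)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    grid_dims: tuple[int, int, int] = (18, 22, 18)
    voxel_mm: float = 6.0
    k_true: int = 3
    group_sizes: tuple[int, int, int, int] = GROUP_SIZES
    n_controls: int = 117
    loading_group_means: tuple = _DEFAULT_LOADING_MEANS
    loading_sd: float = 1.0
    noise_sd: float = 0.06  # ~6% voxel CV, typical of smoothed normalized FDG-PET
    global_scale_range: tuple[float, float] = (0.7, 1.4)
    pattern_fwhm_mm: float = 14.0
    baseline: float = 1.0
    cognition_noise_sd: float = 1.0
    age_params: dict = field(default_factory=lambda: {
        "onset_mean": REFERENCE_STATS["age_onset_mean"],
        "onset_sd": REFERENCE_STATS["age_onset_sd"],
        "scan_mean": REFERENCE_STATS["age_scan_mean"],
        "scan_sd": REFERENCE_STATS["age_scan_sd"],
    })
    cognition_weights: dict = field(
        default_factory=lambda: dict(_DEFAULT_COGNITION_WEIGHTS))
    behaviour_weights: dict = field(
        default_factory=lambda: dict(_DEFAULT_BEHAVIOUR_WEIGHTS))

    def __post_init__(self):
        if any(d <= 0 for d in self.grid_dims):
            raise ValueError("grid_dims must be positive")
        if not (1 <= self.k_true <= 9):
            raise ValueError("k_true must be in 1..9")
        if self.loading_sd <= 0 or self.noise_sd <= 0:
            raise ValueError("all SDs must be positive")
        means = np.asarray(self.loading_group_means, dtype=float)
        if means.shape != (5, self.k_true):
            raise ValueError(
                f"loading_group_means must be 5 x k_true={self.k_true}, got {means.shape}"
            )
        lo, hi = self.global_scale_range
        if not (0 < lo <= hi):
            raise ValueError("global_scale_range must be a positive interval")

    def to_json(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, default=lambda o: np.asarray(o).tolist())


@dataclass(frozen=True)
class GroundTruth:
    planted_patterns: np.ndarray  # k_true x masked voxels, orthonormal
    loadings: np.ndarray  # subjects x k_true (patients then controls)
    subject_ids: tuple[str, ...]
    link_coefficients: dict
    seed: int


def _smooth_field(rng: np.random.Generator, grid: TemplateGrid, fwhm_mm: float) -> np.ndarray:
    """Masked, mean-centred smooth random field as a vector (not normalized)."""
    sigma = fwhm_mm * FWHM_TO_SIGMA / grid.voxel_mm
    vol = gaussian_filter(rng.standard_normal(grid.dims), sigma=sigma, mode="reflect")
    vec = grid.flatten(vol)
    return vec - vec.mean()


def _planted_patterns(rng: np.random.Generator, grid: TemplateGrid, config: SimConfig) -> np.ndarray:
    """Smooth white noise -> mask -> zero over reference -> Gram-Schmidt."""
    ref_vec = grid.flatten(grid.reference_mask.astype(float)) > 0
    pats = []
    for _ in range(config.k_true):
        v = _smooth_field(rng, grid, config.pattern_fwhm_mm)
        v[ref_vec] = 0.0  # the reference region is spared by construction
        v -= v.mean()
        v[ref_vec] = 0.0
        for u in pats:
            v -= (v @ u) * u
        nrm = np.linalg.norm(v)
        if nrm < 1e-8:
            raise ValueError("degenerate pattern draw; mask too small for k_true")
        pats.append(v / nrm)
    return np.stack(pats)


def _scaled_scores(raw: np.ndarray, weights: np.ndarray, loading_sd: float,
                   noise_sd: float) -> np.ndarray:
    """Map raw linear outcomes to the scaled-score convention (mean 10, SD 3)
    calibrated on the control population (loadings centred at 0)."""
    cu_sd = float(np.sqrt(loading_sd**2 * np.sum(np.asarray(weights) ** 2) + noise_sd**2))
    return 10.0 + 3.0 * raw / cu_sd


def generate_cohort(config: SimConfig, grid: TemplateGrid | None = None):
    """Generate images, clinical table and ground truth for one cohort.

    Returns ``(images, clinical, truth, grid)``.  Images are raw (global
    scale still present, not normalized); run the preprocessing pipeline
    to remove the nuisance before decomposition.
    """
    if grid is None:
        grid = default_grid(config.grid_dims, config.voxel_mm)
    if config.k_true > min(sum(config.group_sizes) + config.n_controls, grid.n_voxels):
        raise ValueError("k_true exceeds the rank limit")
    ss = np.random.SeedSequence(config.seed)
    pattern_ss, clin_ss, loading_ss, subj_ss = ss.spawn(4)
    pattern_rng = np.random.default_rng(pattern_ss)
    clin_rng = np.random.default_rng(clin_ss)
    loading_rng = np.random.default_rng(loading_ss)

    patterns = _planted_patterns(pattern_rng, grid, config)
    means = np.asarray(config.loading_group_means, dtype=float)

    group_of: list[str] = []
    for g, nmem in zip(PATIENT_GROUPS, config.group_sizes):
        group_of += [g] * nmem
    group_of += ["CU"] * config.n_controls
    n_subjects = len(group_of)
    ids = tuple(f"{g}_{i:03d}" for i, g in enumerate(group_of, start=1))

    gidx = {g: k for k, g in enumerate(PATIENT_GROUPS + ("CU",))}
    subj_streams = subj_ss.spawn(n_subjects)

    # Loadings: Gaussian-shaped around the group means with exact moment
    # conditioning — each group's sampled deviations are recentred and
    # sample-whitened so the group's sample mean and covariance equal the
    # configured mean and loading_sd^2 * I exactly.  This removes sampling
    # noise from the loading first and second moments, so the planted
    # components carry exactly the designed (orthogonal) group structure
    # in every realization; only image noise remains stochastic at the
    # covariance level.
    group_arr = np.asarray([gidx[g] for g in group_of])
    loadings = np.empty((n_subjects, config.k_true))
    for gi in range(len(PATIENT_GROUPS) + 1):
        sel = np.flatnonzero(group_arr == gi)
        if sel.size == 0:
            continue
        z = loading_rng.standard_normal((sel.size, config.k_true))
        if sel.size > config.k_true:
            z -= z.mean(axis=0)
            cov = z.T @ z / (sel.size - 1)
            w, v = np.linalg.eigh(cov)
            z = z @ (v * (1.0 / np.sqrt(np.maximum(w, 1e-12)))) @ v.T
        loadings[sel] = means[gi] + config.loading_sd * z

    images = []
    lo, hi = config.global_scale_range
    # baseline is spatially constant over the whole volume: a structured
    # shared profile would survive per-row median centring and masquerade
    # as an extra common component
    for i, sid in enumerate(ids):
        rng = np.random.default_rng(subj_streams[i])
        signal = grid.unflatten(patterns.T @ loadings[i])
        noise = rng.normal(0.0, config.noise_sd, grid.dims)
        scale = rng.uniform(lo, hi)
        images.append(
            SubjectImage(subject_id=sid, values=scale * (config.baseline + signal + noise))
        )

    clinical = _clinical_table(config, clin_rng, ids, group_of, gidx, loadings)
    truth = GroundTruth(
        planted_patterns=patterns,
        loadings=loadings,
        subject_ids=ids,
        link_coefficients={
            "cognition": dict(config.cognition_weights),
            "behaviour": dict(config.behaviour_weights),
        },
        seed=config.seed,
    )
    return images, clinical, truth, grid


def _clinical_table(config, rng, ids, group_of, gidx, loadings) -> pd.DataFrame:
    n = len(ids)
    k = np.array([gidx[g] for g in group_of])
    is_cu = np.array([g == "CU" for g in group_of])
    ap = config.age_params

    onset_mu = np.asarray(ap["onset_mean"])
    onset_sd = np.asarray(ap["onset_sd"])
    scan_mu = np.asarray(ap["scan_mean"])
    scan_sd = np.asarray(ap["scan_sd"])

    # control demographics: mixture of the patient groups, weighted by size
    mix_p = np.asarray(config.group_sizes, dtype=float)
    mix_p /= mix_p.sum()
    pg = np.where(is_cu, rng.choice(len(PATIENT_GROUPS), size=n, p=mix_p), np.minimum(k, 3))

    onset = rng.normal(onset_mu[pg], onset_sd[pg])
    duration = np.clip(rng.normal(scan_mu[pg] - onset_mu[pg], 1.0), 0.5, None)
    age_scan = onset + duration
    onset = np.where(is_cu, np.nan, onset)

    male_p = np.asarray(REFERENCE_STATS["males"], dtype=float) / np.asarray(GROUP_SIZES)
    sex = np.where(rng.random(n) < male_p[pg], "M", "F")
    edu = rng.normal(np.asarray(REFERENCE_STATS["education_mean"])[pg],
                     np.asarray(REFERENCE_STATS["education_sd"])[pg])

    rows = {
        "subject_id": ids,
        "group": group_of,
        "age_onset": np.round(onset, 1),
        "age_scan": np.round(age_scan, 1),
        "sex": sex,
        "education": np.round(edu, 1),
    }

    stms_raw = loadings @ np.asarray(_DEFAULT_STMS_WEIGHTS[: config.k_true]) + rng.normal(
        0, config.cognition_noise_sd, n
    )
    cu_sd = np.sqrt(config.loading_sd**2
                    * np.sum(np.asarray(_DEFAULT_STMS_WEIGHTS[: config.k_true]) ** 2)
                    + config.cognition_noise_sd**2)
    rows["stms"] = np.clip(np.round(32 + 3.0 * stms_raw / cu_sd), 0, 38).astype(int)

    for name, w in config.cognition_weights.items():
        w = np.asarray(w, dtype=float)[: config.k_true]
        raw = loadings @ w + rng.normal(0, config.cognition_noise_sd, n)
        rows[name] = np.round(
            _scaled_scores(raw, w, config.loading_sd, config.cognition_noise_sd), 2
        )

    for flag, coefs in config.behaviour_weights.items():
        icpt, w = float(coefs[0]), np.asarray(coefs[1:], dtype=float)[: config.k_true]
        prob = 1.0 / (1.0 + np.exp(-(icpt + loadings @ w)))
        draw = (rng.random(n) < prob).astype(int)
        rows[f"flag_{flag}"] = np.where(is_cu, 0, draw)

    # biomarkers: per-group medians with lognormal jitter; controls
    # amyloid/tau negative by construction
    def biom(key, cu_value, jitter=0.12):
        med = np.append(np.asarray(REFERENCE_STATS[key], dtype=float), cu_value)
        vals = med[np.where(is_cu, 4, pg)] * np.exp(rng.normal(0, jitter, n))
        return np.round(vals, 2)

    rows["ptau"] = biom("ptau_median", 20.0)
    rows["ab42"] = biom("ab42_median", 1100.0)
    rows["ttau"] = biom("ttau_median", 140.0)
    rows["ati"] = biom("ati_median", 2.5)
    rows["pib_suvr"] = biom("pib_median", 1.15, 0.05)
    rows["av1451_suvr"] = biom("av1451_median", 1.10, 0.05)
    # bvFTD PiB/AV1451 medians are unavailable in the source table; give
    # amyloid-negative values consistent with non-AD pathology
    bvftd = np.array([g == "bvFTD" for g in group_of])
    rows["pib_suvr"] = np.where(bvftd, np.round(1.15 * np.exp(rng.normal(0, 0.05, n)), 2),
                                rows["pib_suvr"])
    rows["av1451_suvr"] = np.where(bvftd, np.round(1.12 * np.exp(rng.normal(0, 0.05, n)), 2),
                                   rows["av1451_suvr"])

    apoe_p = (np.asarray(REFERENCE_STATS["apoe4_carriers"], dtype=float)
              / np.asarray(REFERENCE_STATS["apoe4_available"], dtype=float))
    apoe_p = np.append(apoe_p, 0.25)  # population carrier rate for controls
    rows["apoe4"] = (rng.random(n) < apoe_p[np.where(is_cu, 4, pg)]).astype(int)

    df = pd.DataFrame(rows)
    return df


# ---------------------------------------------------------------------------
# Topic maps
# ---------------------------------------------------------------------------

def generate_topic_maps(
    config: SimConfig,
    truth: GroundTruth,
    n_topics: int = 22,
    n_matched: int | None = None,
    match_r: float = 0.8,
    grid: TemplateGrid | None = None,
) -> list[TopicMap]:
    """Labelled topic maps: some noisy copies of planted patterns, the rest
    independent smooth fields.

    The first ``n_matched`` topics (default ``k_true``) correlate with
    patterns 1..n_matched at expected |r| = ``match_r``; set
    ``match_r=1.0`` for exact copies.
    """
    if n_topics < 1:
        raise ValueError("need n_topics >= 1")
    if grid is None:
        grid = default_grid(config.grid_dims, config.voxel_mm)
    if n_matched is None:
        n_matched = min(config.k_true, n_topics)
    if not (0.0 <= match_r <= 1.0):
        raise ValueError("match_r must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x70B1C)))
    maps = []
    for t in range(n_topics):
        if t < n_matched:
            pat = truth.planted_patterns[t]
            if match_r >= 1.0:
                vec = pat.copy()
            else:
                other = _smooth_field(rng, grid, config.pattern_fwhm_mm)
                other -= (other @ pat) * pat  # orthogonal complement
                other /= np.linalg.norm(other)
                vec = match_r * pat + np.sqrt(1.0 - match_r**2) * other
            label = f"topic_{t + 1:02d}_match{t + 1}"
        else:
            vec = _smooth_field(rng, grid, config.pattern_fwhm_mm)
            vec /= np.linalg.norm(vec)
            label = f"topic_{t + 1:02d}"
        maps.append(TopicMap(label=label, values=grid.unflatten(vec)))
    return maps


# ---------------------------------------------------------------------------
# Fixed categorical fixture
# ---------------------------------------------------------------------------

def make_reference_cohort() -> pd.DataFrame:
    """117-row categorical table reproducing the published per-group counts.

    Boolean fields are assigned deterministically to the first rows of
    each group so every per-group count (behavioural symptoms, executive
    dysfunction, sex, APOE4 availability and carriers) matches the
    published cells exactly; continuous fields carry per-group means.
    """
    rows = []
    for gi, (g, size) in enumerate(zip(PATIENT_GROUPS, GROUP_SIZES)):
        for j in range(size):
            row = {
                "subject_id": f"{g}_{j + 1:03d}",
                "group": g,
                "age_onset": REFERENCE_STATS["age_onset_mean"][gi],
                "age_scan": REFERENCE_STATS["age_scan_mean"][gi],
                "education": REFERENCE_STATS["education_mean"][gi],
                "stms": REFERENCE_STATS["stms_mean"][gi],
                "sex": "M" if j < REFERENCE_STATS["males"][gi] else "F",
            }
            for flag in BEHAVIOUR_FLAGS:
                row[f"flag_{flag}"] = int(j < REFERENCE_STATS[flag][gi])
            avail = j < REFERENCE_STATS["apoe4_available"][gi]
            row["apoe4"] = (
                int(j < REFERENCE_STATS["apoe4_carriers"][gi]) if avail else np.nan
            )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_cohort(images, clinical, truth, grid, config, out_dir) -> None:
    """Write the cohort bundle: NIfTI images/masks, CSV table, JSON truth."""
    from pathlib import Path

    import nibabel as nib

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    grid.save_masks(out / "brain_mask.nii.gz", out / "reference_mask.nii.gz")
    for im in images:
        nib.save(grid.to_nifti(im.values), str(out / "images" / f"{im.subject_id}.nii.gz"))
    clinical.to_csv(out / "clinical.csv", index=False)
    config.to_json(out / "sim_config.json")
    pat4d = np.stack([grid.unflatten(p) for p in truth.planted_patterns], axis=-1)
    nib.save(nib.Nifti1Image(pat4d.astype(np.float32), grid.affine),
             str(out / "planted_patterns.nii.gz"))
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "subject_ids": list(truth.subject_ids),
                "loadings": truth.loadings.tolist(),
                "link_coefficients": truth.link_coefficients,
                "seed": truth.seed,
            },
            fh,
        )
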