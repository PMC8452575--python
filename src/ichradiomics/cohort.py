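"""Synthetic CT phantoms and feature-level cohorts for pipeline testing.

Two generators share the clinical/outcome schema:

* **image-level**: ellipsoidal brain phantoms with haematoma, perihaematomal
  oedema and ventricle blobs at standard CT tissue attenuations, acquired at
  one of three slice thicknesses (1 / 3 / 5 mm) by slab-averaging, then run
  through the real feature extraction;
* **feature-level**: correlated Gaussian feature tables (fast), with
  injectable per-batch location-scale effects and a configurable
  high-correlation block for redundancy-filter tests.

Outcomes come from a known generative model: haematoma growth is
log-normal with a feature-dependent mean (expansion labelled by the
>6 mL / >33% rule), and poor functional outcome is Bernoulli-logistic.
Intercepts are calibrated by bisection to hit the cohort prevalences of the
target population (about 27% expansion, 50% poor outcome).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .combat import assign_batch
from .evaluation import label_haematoma_expansion, ultra_early_growth
from .imaging import LABEL_ICH, LABEL_IVH, LABEL_PHE, RegionMask, VolumeGrid

DEFAULT_HU = {
    "background": -1000.0,
    "brain": 30.0,
    "haematoma": 65.0,
    "oedema": 18.0,
    "csf": 8.0,
}
DEFAULT_HU_SD = {
    "background": 0.0,
    "brain": 5.0,
    "haematoma": 8.0,
    "oedema": 4.0,
    "csf": 3.0,
}


class CohortError(ValueError):
    pass


@dataclass
class PhantomSpec:
    """Geometry and intensity model of one synthetic head CT."""

    fov_mm: tuple[float, float, float] = (72.0, 72.0, 60.0)
    in_plane_mm: float = 1.0
    slice_thickness_mm: float = 5.0
    brain_semiaxes_mm: tuple[float, float, float] = (33.0, 33.0, 27.0)
    haematoma_centre_mm: tuple[float, float, float] = (8.0, 0.0, 0.0)
    haematoma_radius_mm: float = 12.0
    oedema_thickness_mm: float = 4.0
    ventricle_centres_mm: tuple = ((-12.0, 6.0, 4.0), (-12.0, -6.0, 4.0))
    ventricle_radius_mm: float = 6.0
    hu_mean: dict = field(default_factory=lambda: dict(DEFAULT_HU))
    hu_sd: dict = field(default_factory=lambda: dict(DEFAULT_HU_SD))
    seed: int = 0


def generate_phantom(spec: PhantomSpec):
    """Generate ``(VolumeGrid, RegionMask)`` at the acquisition geometry.

    The phantom is built on a 1 mm axial grid, Gaussian noise added per
    tissue, then z-slabs are averaged down to the requested slice thickness
    (which must be an integer number of millimetres); the stored spacing is
    (in-plane, in-plane, thickness). Mask labels are slab majority votes.
    """
    if any(sd < 0 for sd in spec.hu_sd.values()):
        raise CohortError("HU standard deviations must be non-negative")
    nz1 = int(round(spec.fov_mm[2]))
    nzs = int(round(spec.slice_thickness_mm))
    if nzs < 1 or abs(nzs - spec.slice_thickness_mm) > 1e-9:
        raise CohortError("slice thickness must be a positive integer number of mm")
    nx = int(round(spec.fov_mm[0] / spec.in_plane_mm))
    ny = int(round(spec.fov_mm[1] / spec.in_plane_mm))
    nz1 -= nz1 % nzs
    cx = np.arange(nx) * spec.in_plane_mm - spec.fov_mm[0] / 2
    cy = np.arange(ny) * spec.in_plane_mm - spec.fov_mm[1] / 2
    cz = np.arange(nz1) * 1.0 - nz1 / 2
    X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")

    def ellipsoid(centre, semi):
        return (
            ((X - centre[0]) / semi[0]) ** 2
            + ((Y - centre[1]) / semi[1]) ** 2
            + ((Z - centre[2]) / semi[2]) ** 2
        ) <= 1.0

    brain = ellipsoid((0, 0, 0), spec.brain_semiaxes_mm)
    r_h = spec.haematoma_radius_mm
    c_h = np.asarray(spec.haematoma_centre_mm)
    haem = ellipsoid(c_h, (r_h,) * 3)
    if (haem & ~brain).any():
        raise CohortError("haematoma extends beyond the brain envelope")
    oed = ellipsoid(c_h, (r_h + spec.oedema_thickness_mm,) * 3) & ~haem & brain
    vent = np.zeros_like(brain)
    for c in spec.ventricle_centres_mm:
        vent |= ellipsoid(c, (spec.ventricle_radius_mm,) * 3)
    vent &= brain & ~haem
    oed &= ~vent

    labels1 = np.zeros(brain.shape, dtype=np.int32)
    labels1[oed] = LABEL_PHE
    labels1[vent] = LABEL_IVH
    labels1[haem] = LABEL_ICH

    rng = np.random.default_rng(spec.seed)
    hu = np.full(brain.shape, spec.hu_mean["background"])
    hu[brain] = spec.hu_mean["brain"]
    hu[oed] = spec.hu_mean["oedema"]
    hu[vent] = spec.hu_mean["csf"]
    hu[haem] = spec.hu_mean["haematoma"]
    sd = np.full(brain.shape, spec.hu_sd["background"])
    sd[brain] = spec.hu_sd["brain"]
    sd[oed] = spec.hu_sd["oedema"]
    sd[vent] = spec.hu_sd["csf"]
    sd[haem] = spec.hu_sd["haematoma"]
    hu = hu + sd * rng.standard_normal(brain.shape)

    # acquisition: average z-slabs to the requested thickness
    nslab = nz1 // nzs
    hu_acq = hu.reshape(nx, ny, nslab, nzs).mean(axis=3)
    lab_slabs = labels1.reshape(nx, ny, nslab, nzs)
    lab_acq = np.apply_along_axis(
        lambda v: np.bincount(v, minlength=4).argmax(), 3, lab_slabs
    ).astype(np.int32)
    spacing = (spec.in_plane_mm, spec.in_plane_mm, float(nzs))
    vol = VolumeGrid(hu_acq, spacing)
    mask = RegionMask(lab_acq, spacing)
    return vol, mask


# ---------------------------------------------------------------------------
# feature-level cohort


@dataclass
class CohortSpec:
    """Population model for a synthetic cohort.

    Defaults mirror the target population: age ~ N(69, 13), 56% male, 1:1
    treatment allocation, three slice-thickness batches, expansion prevalence
    0.27 and poor-outcome prevalence 0.50.
    """

    n: int = 500
    n_features: int = 50
    n_informative: int = 5
    beta_scale: float = 1.0
    corr_block_size: int = 0          # size of a high-correlation block
    corr_block_r: float = 0.95
    batch_probs: tuple[float, float, float] = (0.3, 0.4, 0.3)
    batch_thickness_mm: tuple[float, float, float] = (1.0, 3.0, 5.0)
    batch_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    batch_scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    age_mean: float = 69.0
    age_sd: float = 13.0
    male_prop: float = 0.56
    treatment_prop: float = 0.5
    antiplatelet_prop: float = 0.25
    expansion_prevalence: float = 0.27
    poor_outcome_prevalence: float = 0.50
    growth_sd: float = 0.35
    age_effect_poor: float = 0.8      # log-odds per SD of age
    missing_mrs_prob: float = 0.0075
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.batch_probs) - 1.0) > 1e-9:
            raise CohortError("batch proportions must sum to 1")
        if any(p < 0 or p > 1 for p in self.batch_probs):
            raise CohortError("batch proportions must be in [0, 1]")
        if any(s <= 0 for s in self.batch_scale):
            raise CohortError("batch scale factors must be positive")


def _feature_matrix(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    p = spec.n_features
    x = rng.standard_normal((spec.n, p))
    b = min(spec.corr_block_size, p)
    if b >= 2:
        # x_j = sqrt(r) f + sqrt(1-r) e_j gives pairwise correlation r
        f = rng.standard_normal(spec.n)
        r = spec.corr_block_r
        for j in range(b):
            x[:, p - b + j] = np.sqrt(r) * f + np.sqrt(1.0 - r) * rng.standard_normal(spec.n)
    cols = [f"feat_{j:03d}" for j in range(p)]
    return pd.DataFrame(x, columns=cols)


def inject_batch_effects(
    table: pd.DataFrame,
    batches,
    shift,
    scale,
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Apply per-batch location-scale effects x -> scale_b * x + shift_b.

    ``shift``/``scale`` map batch label -> value (dict) or are sequences
    aligned to sorted batch labels. Optional pre-transform feature noise.
    """
    batches = np.asarray(batches)
    levels = sorted(pd.unique(batches).tolist())
    if not isinstance(shift, dict):
        shift = dict(zip(levels, shift))
    if not isinstance(scale, dict):
        scale = dict(zip(levels, scale))
    if any(scale[b] <= 0 for b in levels):
        raise CohortError("scale factors must be positive")
    x = table.to_numpy(dtype=np.float64).copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + noise_sd * rng.standard_normal(x.shape)
    for b in levels:
        sel = batches == b
        x[sel] = scale[b] * x[sel] + shift[b]
    return pd.DataFrame(x, index=table.index, columns=table.columns)


def _calibrate_intercept(fun, target: float, lo: float = -30.0, hi: float = 30.0) -> float:
    """Bisection for the intercept c with E[outcome rate](c) = target."""
    f_lo, f_hi = fun(lo) - target, fun(hi) - target
    if f_lo > 0 or f_hi < 0:
        raise CohortError("target prevalence unattainable under the outcome model")
    return float(optimize.brentq(lambda c: fun(c) - target, lo, hi, xtol=1e-6))


def simulate_outcomes(
    features: pd.DataFrame, clinical: pd.DataFrame, spec: CohortSpec
) -> pd.DataFrame:
    """Draw expansion and functional outcomes from the generative model.

    Expansion: v24 = v0 exp(g) with g ~ N(mu + x'beta_g, sigma^2); mu is
    bisected so the expected expansion rate matches the target prevalence
    (the expansion threshold on g depends on v0 through the 6 mL rule).
    Poor outcome: Bernoulli(logistic(c + x'beta_o + age effect)), c bisected
    for the target prevalence.
    """
    rng = np.random.default_rng(spec.seed + 1)
    x = features.to_numpy(dtype=np.float64)
    x_std = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
    p = x.shape[1]
    k = min(spec.n_informative, p)
    beta_g = np.zeros(p)
    beta_o = np.zeros(p)
    if k:
        signs = np.resize([1.0, -1.0], k)
        beta_g[:k] = spec.beta_scale * signs
        beta_o[:k] = spec.beta_scale * signs
    eta_g = x_std @ beta_g
    eta_g = (eta_g - eta_g.mean()) / (eta_g.std() + 1e-12) if k else eta_g
    v0 = clinical["baseline_volume_ml"].to_numpy(dtype=np.float64)
    # growth threshold implied by the >6 mL / >33% rule: the OR of the two
    # criteria binds at whichever relative threshold is smaller
    g_thr = np.log(1.0 + np.minimum(0.33, 6.0 / v0))
    sig = spec.growth_sd

    def exp_rate(mu):
        return float(np.mean(1.0 - stats.norm.cdf((g_thr - mu - sig * eta_g) / sig)))

    mu_star = _calibrate_intercept(exp_rate, spec.expansion_prevalence, -10, 10)
    g = mu_star + sig * eta_g + sig * rng.standard_normal(spec.n)
    v24 = v0 * np.exp(g)
    expansion = np.array(
        [label_haematoma_expansion(a, b) for a, b in zip(v0, v24)], dtype=bool
    )

    age_std = (clinical["age"].to_numpy() - spec.age_mean) / spec.age_sd
    eta_o_raw = x_std @ beta_o
    if k:
        eta_o_raw = (eta_o_raw - eta_o_raw.mean()) / (eta_o_raw.std() + 1e-12)
    eta_o = eta_o_raw + spec.age_effect_poor * age_std

    def poor_rate(c):
        return float(np.mean(1.0 / (1.0 + np.exp(-(c + eta_o)))))

    c_star = _calibrate_intercept(poor_rate, spec.poor_outcome_prevalence)
    poor = rng.random(spec.n) < 1.0 / (1.0 + np.exp(-(c_star + eta_o)))
    mrs = np.where(poor, rng.integers(4, 7, spec.n), rng.integers(0, 4, spec.n))
    mrs = mrs.astype(float)
    mrs[rng.random(spec.n) < spec.missing_mrs_prob] = np.nan

    out = pd.DataFrame(
        {
            "baseline_ich_ml": v0,
            "followup_ich_ml": v24,
            "haematoma_expansion": expansion,
            "mrs_day90": mrs,
            "poor_outcome": np.where(np.isnan(mrs), np.nan, poor.astype(float)),
        },
        index=features.index,
    )
    out.attrs["true_beta_expansion"] = beta_g
    out.attrs["true_beta_poor"] = beta_o
    return out


def generate_cohort(spec: CohortSpec):
    """Feature-level cohort: ``(features, clinical, outcomes)`` DataFrames.

    ``clinical`` carries age, gender (1 = male), treatment (1 = placebo),
    antiplatelet, onset-to-scan hours, baseline volume, slice thickness,
    batch, ultra-early growth, and the four radiological sign flags.
    """
    rng = np.random.default_rng(spec.seed)
    features = _feature_matrix(spec, rng)
    n = spec.n
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 18, 100)
    gender = (rng.random(n) < spec.male_prop).astype(int)
    treatment = (rng.random(n) < spec.treatment_prop).astype(int)
    antiplatelet = (rng.random(n) < spec.antiplatelet_prop).astype(int)
    onset = np.exp(rng.normal(np.log(1.9), 0.45, n))
    v0 = np.exp(rng.normal(np.log(12.0), 0.9, n))
    thick = rng.choice(spec.batch_thickness_mm, size=n, p=spec.batch_probs)
    batch = np.array([assign_batch(t) for t in thick])
    uehg = np.array([ultra_early_growth(v, t) for v, t in zip(v0, onset)])

    clinical = pd.DataFrame(
        {
            "age": age,
            "gender": gender,
            "treatment": treatment,
            "antiplatelet": antiplatelet,
            "onset_to_scan_h": onset,
            "baseline_volume_ml": v0,
            "slice_thickness_mm": thick,
            "batch": batch,
            "ultra_early_growth": uehg,
        },
        index=features.index,
    )
    outcomes = simulate_outcomes(features, clinical, spec)

    # radiological signs: correlated with the expansion-driving signal
    latent = features.to_numpy() @ outcomes.attrs["true_beta_expansion"]
    latent = (latent - latent.mean()) / (latent.std() + 1e-12)
    rng2 = np.random.default_rng(spec.seed + 2)
    base = np.log(0.15 / 0.85)
    for sign in ("blend_sign", "black_hole_sign", "hypodensities", "island_sign"):
        pr = 1.0 / (1.0 + np.exp(-(base + 0.8 * latent)))
        clinical[sign] = (rng2.random(n) < pr).astype(int)

    if any(s != 0 for s in spec.batch_shift) or any(s != 1 for s in spec.batch_scale):
        features = inject_batch_effects(
            features, batch,
            dict(zip((1, 2, 3), spec.batch_shift)),
            dict(zip((1, 2, 3), spec.batch_scale)),
        )
    return features, clinical, outcomes


def generate_image_cohort(n: int, seed: int = 0, base: PhantomSpec | None = None):
    """Small image-level cohort: list of (subject_id, VolumeGrid, RegionMask)
    plus a clinical table; haematoma size and slice thickness vary by seed."""
    rng = np.random.default_rng(seed)
    base = base or PhantomSpec()
    rows, phantoms = [], []
    for i in range(n):
        thickness = float(rng.choice([1.0, 3.0, 5.0]))
        radius = float(rng.uniform(8.0, 14.0))
        spec = PhantomSpec(
            fov_mm=base.fov_mm,
            in_plane_mm=base.in_plane_mm,
            slice_thickness_mm=thickness,
            haematoma_radius_mm=radius,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        vol, mask = generate_phantom(spec)
        sid = f"sub-{i:03d}"
        phantoms.append((sid, vol, mask))
        rows.append({
            "subject_id": sid,
            "age": float(np.clip(rng.normal(69, 13), 18, 100)),
            "gender": int(rng.random() < 0.56),
            "treatment": int(rng.random() < 0.5),
            "slice_thickness_mm": thickness,
            "batch": assign_batch(thickness),
        })
    return phantoms, pd.DataFrame(rows).set_index("subject_id")
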