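"""Synthetic dual-stained TMA cores and simulated survival cohorts.

Two generators with exact ground truth:

* :func:`generate_core_image` renders one 0.6 mm circular tissue core as an
  8-bit RGB image under the Beer-Lambert stain model: CD34-like vessels are
  non-overlapping red-stain annuli with empty lumina, each wrapped in a
  perivascular blue-stain coat of controllable OD, plus diffuse blue-stain
  stroma patches covering a controllable fraction of the disc.  The returned
  :class:`GroundTruth` records the rendered geometry (pixel-counted, before
  noise), so segmentation and metric recovery can be tested exactly.

* :func:`generate_cohort` draws a serous ovarian-cancer-like cohort: clinical
  covariates with configurable category frequencies, 13 stroma/vessel metrics
  at primary and metastatic sites with configurable per-metric rank
  concordance (Gaussian copula), and overall survival from an exponential
  proportional-hazards model with configurable log hazard ratios and
  exponential censoring.

Both are bit-deterministic given (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.measure import perimeter_crofton

from .stains import VECTOR_RED, VECTOR_BLUE, TissueCoreImage, od_to_rgb

__all__ = [
    "METRICS",
    "ImageSimParams",
    "GroundTruth",
    "CohortSimParams",
    "generate_core_image",
    "generate_cohort",
    "expected_censoring_fraction",
]

#: The 13 stroma-related metrics, in the order they are reported.
METRICS = [
    "vessel_density",
    "mean_lumen_area",
    "mean_lumen_perimeter",
    "asma_stroma_intensity",
    "asma_stroma_fraction",
    "asma_perivascular_intensity",
    "asma_perivascular_fraction",
    "desmin_perivascular_intensity",
    "desmin_perivascular_fraction",
    "pdgfrb_stroma_intensity",
    "pdgfrb_stroma_fraction",
    "pdgfrb_perivascular_intensity",
    "pdgfrb_perivascular_fraction",
]


# --------------------------------------------------------------------------
# core image simulation
# --------------------------------------------------------------------------

@dataclass
class ImageSimParams:
    """Parameters of one synthetic core.

    Lengths in micrometers, stain amounts in optical density.  The default
    geometry emulates a 0.6 mm TMA core biopsy scanned at 0.5477 um/px
    (the calibration at which 50 px^2 = 15 um^2 and 20 px ~ 11 um).
    """

    core_diameter_um: float = 600.0
    pixel_size_um: float = 0.5477
    n_vessels: int = 12
    lumen_radius_um_range: tuple[float, float] = (4.0, 15.0)
    wall_thickness_um: float = 3.0
    coat_width_um: float = 10.0
    perivascular_od_per_vessel: Sequence[float] | None = None
    covered_target_fraction: float = 0.7
    covered_od_range: tuple[float, float] = (0.3, 0.9)
    uncovered_od_range: tuple[float, float] = (0.0, 0.02)
    stroma_fraction_target: float = 0.3
    stroma_od_mean: float = 0.5
    stroma_positive_od_floor: float = 0.15
    cd34_wall_od: float = 1.0
    tissue_background_od: float = 0.04
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.core_diameter_um > 0:
            raise ValueError("core_diameter_um must be positive")
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be nonnegative")
        lo, hi = self.lumen_radius_um_range
        if not (0 < lo <= hi):
            raise ValueError("lumen_radius_um_range must satisfy 0 < min <= max")
        for name in ("covered_target_fraction", "stroma_fraction_target"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0 or self.stroma_od_mean < 0:
            raise ValueError("noise_sd and stroma_od_mean must be nonnegative")
        if self.perivascular_od_per_vessel is not None:
            ods = np.asarray(self.perivascular_od_per_vessel, dtype=float)
            if len(ods) != self.n_vessels:
                raise ValueError("perivascular_od_per_vessel length must equal n_vessels")
            if np.any(ods < 0):
                raise ValueError("perivascular ODs must be nonnegative")


@dataclass
class GroundTruth:
    """Exact rendered scene content, recorded before noise is added."""

    vessel_count: int
    lumen_radii_um: list[float]
    lumen_areas_um2: list[float]
    lumen_perimeters_um: list[float]
    per_vessel_od: list[float]
    covered_flags: list[bool]
    true_stroma_fraction: float
    true_stroma_mean_od: float
    tumor_area_um2: float

    def __post_init__(self) -> None:
        n = self.vessel_count
        for name in ("lumen_radii_um", "lumen_areas_um2", "lumen_perimeters_um",
                     "per_vessel_od", "covered_flags"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have length vessel_count={n}")
        if not 0.0 <= self.true_stroma_fraction <= 1.0:
            raise ValueError("true_stroma_fraction must lie in [0, 1]")


def _draw_vessel_ods(params: ImageSimParams, rng: np.random.Generator) -> np.ndarray:
    if params.perivascular_od_per_vessel is not None:
        return np.asarray(params.perivascular_od_per_vessel, dtype=float)
    n = params.n_vessels
    n_cov = int(round(params.covered_target_fraction * n))
    ods = np.empty(n)
    ods[:n_cov] = rng.uniform(*params.covered_od_range, size=n_cov)
    ods[n_cov:] = rng.uniform(*params.uncovered_od_range, size=n - n_cov)
    return rng.permutation(ods)


def generate_core_image(
    params: ImageSimParams,
    case_id: str = "SIM",
    block_id: str = "",
    site: str = "primary",
    marker: str = "PDGFBR",
    epithelial_positive: bool = False,
    max_placement_tries: int = 500,
) -> tuple[TissueCoreImage, GroundTruth]:
    """Render one synthetic core and its exact ground truth.

    Vessels are placed by rejection sampling with non-overlapping halos
    (wall + coat + clearance) fully inside the disc; a ``RuntimeError`` is
    raised when ``n_vessels`` does not fit after bounded retries.  The
    perivascular coat is rendered 1 um wider than ``coat_width_um`` so that
    a measurement ring of that width sits strictly inside it.
    """
    params.validate()
    px = params.pixel_size_um
    radius_px = params.core_diameter_um / 2.0 / px
    margin = 4
    n_side = int(np.ceil(2 * radius_px)) + 2 * margin
    c = (n_side - 1) / 2.0
    yy, xx = np.mgrid[0:n_side, 0:n_side]
    dist_c = np.hypot(yy - c, xx - c)
    disc = dist_c <= radius_px

    rng = np.random.default_rng(params.seed)

    od_red = np.zeros((n_side, n_side))
    od_blue = np.zeros((n_side, n_side))
    od_red[disc] = params.tissue_background_od
    od_blue[disc] = params.tissue_background_od

    vessel_ods = _draw_vessel_ods(params, rng)
    coat_render_um = params.coat_width_um + 1.0
    clearance_um = 2.0

    # --- place vessels: centers + lumen radii, non-overlapping halos ---
    centers: list[tuple[float, float]] = []
    radii_um: list[float] = []
    halos_um: list[float] = []
    for i in range(params.n_vessels):
        r_um = rng.uniform(*params.lumen_radius_um_range)
        halo_um = r_um + params.wall_thickness_um + coat_render_um + clearance_um
        placed = False
        for _ in range(max_placement_tries):
            ang = rng.uniform(0, 2 * np.pi)
            rad = radius_px - halo_um / px
            if rad <= 0:
                break
            rho = np.sqrt(rng.uniform()) * rad
            cy, cx = c + rho * np.sin(ang), c + rho * np.cos(ang)
            ok = all(
                np.hypot(cy - py, cx - px_) * px >= halo_um + h
                for (py, px_), h in zip(centers, halos_um)
            )
            if ok:
                centers.append((cy, cx))
                radii_um.append(r_um)
                halos_um.append(halo_um)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place vessel {i + 1}/{params.n_vessels} after "
                f"{max_placement_tries} tries; core too crowded"
            )

    lumen_areas: list[float] = []
    lumen_perims: list[float] = []
    halo_mask = np.zeros((n_side, n_side), dtype=bool)
    for (cy, cx), r_um, od_i in zip(centers, radii_um, vessel_ods):
        d_um = np.hypot(yy - cy, xx - cx) * px
        lumen = d_um < r_um
        wall = (d_um >= r_um) & (d_um < r_um + params.wall_thickness_um)
        coat = (d_um >= r_um + params.wall_thickness_um) & (
            d_um < r_um + params.wall_thickness_um + coat_render_um
        )
        od_red[wall] = params.cd34_wall_od
        od_blue[wall] = params.tissue_background_od
        od_blue[coat] = od_i
        od_red[coat] = params.tissue_background_od
        od_red[lumen] = 0.0
        od_blue[lumen] = 0.0
        halo_mask |= d_um < (r_um + params.wall_thickness_um + coat_render_um + clearance_um)
        lumen_areas.append(float(lumen.sum()) * px**2)
        lumen_perims.append(float(perimeter_crofton(lumen, directions=4)) * px)

    # --- stroma patches: random discs avoiding vessel halos ---
    # marker-positive area includes the perivascular coats whose OD clears
    # the positivity floor, exactly as it would in the assay; the patch
    # budget therefore targets the TOTAL positive fraction.  Targets below
    # the coat footprint alone are unattainable and the ground truth then
    # records the realized (larger) fraction.
    disc_area = int(disc.sum())
    coat_positive = int(((od_blue > params.stroma_positive_od_floor) & disc).sum())
    stroma_mask = np.zeros((n_side, n_side), dtype=bool)
    target_px = params.stroma_fraction_target * disc_area
    patch_tries = 0
    while coat_positive + stroma_mask.sum() < target_px and patch_tries < 4000:
        patch_tries += 1
        remaining_px = target_px - coat_positive - stroma_mask.sum()
        max_r_um = min(35.0, np.sqrt(remaining_px / np.pi) * px * 1.1 + 4.0)
        pr_um = rng.uniform(6.0, max(6.5, max_r_um))
        ang = rng.uniform(0, 2 * np.pi)
        rho = np.sqrt(rng.uniform()) * max(radius_px - pr_um / px, 1.0)
        cy, cx = c + rho * np.sin(ang), c + rho * np.cos(ang)
        patch = (np.hypot(yy - cy, xx - cx) * px < pr_um) & disc
        if (patch & halo_mask).any():
            continue
        new = patch & ~stroma_mask
        if coat_positive + new.sum() + stroma_mask.sum() > target_px + 0.015 * disc_area:
            continue  # would overshoot the target band
        od_patch = float(np.clip(rng.normal(params.stroma_od_mean, 0.05), 0.25, None))
        od_blue[new] = od_patch
        stroma_mask |= new

    positive_mask = (od_blue > params.stroma_positive_od_floor) & disc
    true_fraction = float(positive_mask.sum()) / disc_area
    true_mean_od = (float(od_blue[positive_mask].mean())
                    if positive_mask.any() else float("nan"))

    gt = GroundTruth(
        vessel_count=params.n_vessels,
        lumen_radii_um=list(radii_um),
        lumen_areas_um2=lumen_areas,
        lumen_perimeters_um=lumen_perims,
        per_vessel_od=[float(v) for v in vessel_ods],
        covered_flags=_coverage_flags(vessel_ods),
        true_stroma_fraction=true_fraction,
        true_stroma_mean_od=true_mean_od,
        tumor_area_um2=disc_area * px**2,
    )

    if params.noise_sd > 0:
        od_red = np.clip(od_red + rng.normal(0, params.noise_sd, od_red.shape), 0, None)
        od_blue = np.clip(od_blue + rng.normal(0, params.noise_sd, od_blue.shape), 0, None)

    od_rgb = od_red[..., None] * VECTOR_RED + od_blue[..., None] * VECTOR_BLUE
    image = TissueCoreImage(
        pixels=od_to_rgb(od_rgb),
        pixel_size_um=px,
        case_id=case_id,
        block_id=block_id,
        site=site,
        marker=marker,
        epithelial_positive=epithelial_positive,
    )
    return image, gt


def _coverage_flags(ods: np.ndarray, cutoff_fraction: float = 0.10) -> list[bool]:
    """Ground-truth covered/uncovered calls by the 10 %-of-maximum rule."""
    ods = np.asarray(ods, dtype=float)
    if ods.size == 0:
        return []
    m = float(ods.max())
    return [bool(v > cutoff_fraction * m) for v in ods]


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

#: Per-metric marginal distributions: ("lognormal", median, sigma_log) or
#: ("beta", a, b).  Chosen to give realistic magnitudes: vessel densities of
#: tens per mm^2, lumina of a few hundred um^2, stain ODs well below 1.
DEFAULT_METRIC_DISTRIBUTIONS: dict[str, tuple] = {
    "vessel_density": ("lognormal", 60.0, 0.4),
    "mean_lumen_area": ("lognormal", 250.0, 0.5),
    "mean_lumen_perimeter": ("lognormal", 60.0, 0.35),
    "asma_stroma_intensity": ("lognormal", 0.45, 0.3),
    "asma_stroma_fraction": ("beta", 3.0, 7.0),
    "asma_perivascular_intensity": ("lognormal", 0.40, 0.35),
    "asma_perivascular_fraction": ("beta", 7.0, 3.0),
    "desmin_perivascular_intensity": ("lognormal", 0.35, 0.35),
    "desmin_perivascular_fraction": ("beta", 6.0, 4.0),
    "pdgfrb_stroma_intensity": ("lognormal", 0.50, 0.3),
    "pdgfrb_stroma_fraction": ("beta", 3.5, 6.5),
    "pdgfrb_perivascular_intensity": ("lognormal", 0.45, 0.35),
    "pdgfrb_perivascular_fraction": ("beta", 7.0, 3.0),
}

#: Default primary/metastasis rank concordance per metric — the observed
#: paired-cohort coefficients this generator emulates.
DEFAULT_CONCORDANCE: dict[str, float] = {
    "vessel_density": 0.208,
    "mean_lumen_area": 0.132,
    "mean_lumen_perimeter": 0.279,
    "asma_stroma_intensity": 0.047,
    "asma_stroma_fraction": -0.031,
    "asma_perivascular_intensity": 0.210,
    "asma_perivascular_fraction": 0.201,
    "desmin_perivascular_intensity": 0.292,
    "desmin_perivascular_fraction": 0.287,
    "pdgfrb_stroma_intensity": 0.474,
    "pdgfrb_stroma_fraction": 0.341,
    "pdgfrb_perivascular_intensity": 0.414,
    "pdgfrb_perivascular_fraction": 0.287,
}

#: Default true log hazard ratios for the survival mechanism (multivariate-
#: adjusted scale): strong effects of stage and residual disease, a moderate
#: effect (HR 1.66) of the high/low prognostic-metric indicator.
DEFAULT_TRUE_LOG_HR: dict[str, float] = {
    "age": np.log(0.99),
    "stage_III": np.log(2.58),
    "stage_IV": np.log(4.11),
    "grade_2": np.log(1.11),
    "grade_3": np.log(1.32),
    "residual_tumor": np.log(4.68),
    "metric_high": np.log(1.66),
}

#: Category frequencies among cases with known status.
DEFAULT_COVARIATE_FREQUENCIES: dict[str, dict[str, float]] = {
    "figo_stage": {"I+II": 0.125, "III": 0.703, "IV": 0.172},
    "grade": {"1": 0.124, "2": 0.300, "3": 0.576},
    "residual_tumor": {"none": 0.209, "present": 0.791},
}


@dataclass
class CohortSimParams:
    """Parameters of one simulated cohort.

    ``site_fractions`` controls tissue availability: cases with both sites,
    primary only, metastasis only (defaults 91/186, 47/186, 48/186).
    ``prognostic_metric`` names the metric whose mean-split high/low
    indicator carries ``true_log_hr["metric_high"]`` in the hazard.
    """

    n_cases: int = 186
    metric_distributions: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_METRIC_DISTRIBUTIONS))
    primary_metastasis_concordance: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONCORDANCE))
    true_log_hr: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_LOG_HR))
    prognostic_metric: str = "pdgfrb_stroma_fraction"
    baseline_hazard: float = 0.002
    censoring_rate: float = 0.011
    covariate_frequencies: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_FREQUENCIES.items()})
    site_fractions: tuple[float, float, float] = (91 / 186, 47 / 186, 48 / 186)
    age_mean: float = 60.0
    age_sd: float = 11.0
    age_range: tuple[float, float] = (22.0, 84.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be positive")
        if self.baseline_hazard <= 0 or self.censoring_rate <= 0:
            raise ValueError("hazard rates must be positive")
        for m, r in self.primary_metastasis_concordance.items():
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"concordance for {m} must lie in [-1, 1]")
        for cov, freqs in self.covariate_frequencies.items():
            if abs(sum(freqs.values()) - 1.0) > 1e-6:
                raise ValueError(f"frequencies for {cov} must sum to 1")
        if abs(sum(self.site_fractions) - 1.0) > 1e-6:
            raise ValueError("site_fractions must sum to 1")


def _metric_ppf(spec: tuple, u: np.ndarray) -> np.ndarray:
    kind = spec[0]
    if kind == "lognormal":
        _, median, sigma = spec
        return np.exp(np.log(median) + sigma * sps.norm.ppf(u))
    if kind == "beta":
        _, a, b = spec
        return sps.beta.ppf(u, a, b)
    raise ValueError(f"unknown metric distribution kind {kind!r}")


def generate_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Simulate one cohort table: one row per case.

    Columns: ``case_id, age, figo_stage, grade, residual_tumor, os_months,
    event`` plus ``<metric>_primary`` / ``<metric>_metastasis`` for the 13
    metrics (NaN where that site's tissue is unavailable).

    Primary and metastatic metric values are tied by a Gaussian copula whose
    latent correlation is chosen so the population Spearman coefficient
    equals the requested concordance (rho_latent = 2 sin(pi rho_s / 6)).
    Event times are exponential with rate
    ``baseline_hazard * exp(true_log_hr . x)``; censoring times are
    exponential with ``censoring_rate``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    df, lp = _draw_covariates(params, rng)
    n = params.n_cases

    hazard = params.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / params.censoring_rate, size=n)
    df["os_months"] = np.minimum(t_event, t_cens)
    df["event"] = (t_event <= t_cens).astype(int)
    return df


def _draw_covariates(params: CohortSimParams,
                     rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw clinical covariates and metrics; return (frame, linear predictor)."""
    n = params.n_cases
    age = np.clip(rng.normal(params.age_mean, params.age_sd, n), *params.age_range)

    def draw_cat(freqs: Mapping[str, float]) -> np.ndarray:
        cats = list(freqs)
        return rng.choice(cats, size=n, p=[freqs[c] for c in cats])

    stage = draw_cat(params.covariate_frequencies["figo_stage"])
    grade = draw_cat(params.covariate_frequencies["grade"])
    residual = draw_cat(params.covariate_frequencies["residual_tumor"])

    p_both, p_prim, p_met = params.site_fractions
    avail = rng.choice(["both", "primary", "metastasis"], size=n, p=[p_both, p_prim, p_met])
    has_primary = avail != "metastasis"
    has_met = avail != "primary"

    df = pd.DataFrame({
        "case_id": [f"case_{i:04d}" for i in range(n)],
        "age": age,
        "figo_stage": stage,
        "grade": grade,
        "residual_tumor": residual,
    })

    for metric in METRICS:
        spec = params.metric_distributions[metric]
        rho_s = float(params.primary_metastasis_concordance.get(metric, 0.0))
        rho = 2.0 * np.sin(np.pi * rho_s / 6.0)
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n)
        vp = _metric_ppf(spec, sps.norm.cdf(z1))
        vm = _metric_ppf(spec, sps.norm.cdf(z2))
        df[f"{metric}_primary"] = np.where(has_primary, vp, np.nan)
        df[f"{metric}_metastasis"] = np.where(has_met, vm, np.nan)

    # survival driven by the site-resolved prognostic metric (primary when
    # available, else metastasis), dichotomized at the cohort mean
    pm = params.prognostic_metric
    resolved = np.where(has_primary, df[f"{pm}_primary"], df[f"{pm}_metastasis"])
    metric_high = resolved > np.nanmean(resolved)

    beta = params.true_log_hr
    lp = (
        beta.get("age", 0.0) * (age - params.age_mean)
        + beta.get("stage_III", 0.0) * (stage == "III")
        + beta.get("stage_IV", 0.0) * (stage == "IV")
        + beta.get("grade_2", 0.0) * (grade == "2")
        + beta.get("grade_3", 0.0) * (grade == "3")
        + beta.get("residual_tumor", 0.0) * (residual == "present")
        + beta.get("metric_high", 0.0) * metric_high
    )
    lp = np.asarray(lp, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite linear predictor in survival simulation")
    return df, lp


def expected_censoring_fraction(params: CohortSimParams, n_monte_carlo: int = 100_000,
                                seed: int = 12345) -> float:
    """Expected censoring proportion E[c / (c + h_i)] for the stated rates.

    With exponential event times (rate h = h0 exp(lp)) and independent
    exponential censoring (rate c), P(censored | lp) = c / (c + h) in closed
    form; only the expectation over the covariate distribution is taken by
    Monte Carlo, with a seed independent of the cohort's.
    """
    big = CohortSimParams(**{**params.__dict__, "n_cases": n_monte_carlo, "seed": seed})
    _, lp = _draw_covariates(big, np.random.default_rng(seed))
    h = params.baseline_hazard * np.exp(lp)
    c = params.censoring_rate
    return float(np.mean(c / (c + h)))
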