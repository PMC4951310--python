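"""Orchestration: simulate -> analyze -> stats as reproducible runs.

The analysis stage consumes a CSV manifest (one row per core image with
columns ``path, core_id, case_id, block_id, site, marker,
epithelial_positive``), measures every core, applies the cohort-scope
coverage call and the epithelial-positivity exclusion, aggregates cores to
cases and writes per-core / per-case CSVs plus a machine-readable run log.
The statistics stage turns a per-case analysis table into correlation,
concordance, survival and association outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__
from .aggregate import METRICS, aggregate_cores_to_case, build_analysis_table
from .config import RunConfig
from .simulate import (CohortSimParams, ImageSimParams, generate_cohort,
                       generate_core_image)
from .stains import TissueCoreImage, separate_core
from .stats import (chi_square_association, cox_fit, backward_selection,
                    dichotomize, km_logrank, plot_correlation_heatmap, plot_km,
                    site_concordance, spearman_matrix)
from .stroma import (clean_positive_mask, exclude_epithelial_positive,
                     stroma_fraction, stroma_intensity, threshold_positive)
from .vessels import (classify_coverage, perivascular_intensity,
                      perivascular_rings, segment_vessels, vessel_density)

log = logging.getLogger("stromascope")

MANIFEST_COLUMNS = ["path", "core_id", "case_id", "block_id", "site", "marker",
                    "epithelial_positive"]

CLINICAL_COLUMNS = ["case_id", "age", "figo_stage", "grade", "residual_tumor",
                    "os_months", "event"]

CORE_COLUMNS_WITH_STATUS = [
    "core_id", "case_id", "block_id", "site", "marker", "epithelial_positive",
    "tumor_area_um2", "status", "perivascular_intensity", "n_vessels",
    "vessel_density", "mean_lumen_area", "mean_lumen_perimeter",
    "stroma_fraction", "stroma_intensity", "perivascular_fraction",
]


# --------------------------------------------------------------------------
# analyze
# --------------------------------------------------------------------------

def analyze_core(image: TissueCoreImage, config: RunConfig) -> tuple[dict, pd.DataFrame]:
    """Measure one core; returns (core metric dict, per-vessel table).

    The covered/uncovered call is deferred: the per-vessel table carries the
    ring mean ODs and the caller applies :func:`finalize_coverage` once the
    in-scope maximal intensity is known.
    """
    od = separate_core(image, config.stains)
    core: dict = {
        "core_id": "", "case_id": image.case_id, "block_id": image.block_id,
        "site": image.site, "marker": image.marker,
        "epithelial_positive": image.epithelial_positive,
        "tumor_area_um2": od.tumor_area_um2,
    }
    if not od.tissue_mask.any():
        core["status"] = "empty"
        return core, pd.DataFrame()
    core["status"] = "ok"

    labels, records = segment_vessels(od, config.vessels)
    rings = perivascular_rings(labels, config.vessels.ring_width_um,
                               od.pixel_size_um, od.tissue_mask)
    core["perivascular_intensity"] = perivascular_intensity(rings, od.od_marker, records)
    core["n_vessels"] = len(records)
    core["vessel_density"] = vessel_density(len(records), od.tumor_area_um2)
    if records:
        core["mean_lumen_area"] = float(np.mean([r.lumen_area_um2 for r in records]))
        core["mean_lumen_perimeter"] = float(np.mean([r.lumen_perimeter_um for r in records]))
    else:
        core["mean_lumen_area"] = np.nan
        core["mean_lumen_perimeter"] = np.nan

    if image.marker == "DESMIN":
        core["stroma_fraction"] = np.nan  # desmin scores perivascular only
        core["stroma_intensity"] = np.nan
    else:
        positive = threshold_positive(od.od_marker, od.tissue_mask, config.stroma)
        cleaned = clean_positive_mask(positive, config.stroma)
        core["stroma_fraction"] = stroma_fraction(cleaned, od.tissue_mask)
        core["stroma_intensity"] = stroma_intensity(od.od_marker, cleaned)

    vessels_df = pd.DataFrame([{
        "label": r.label, "lumen_area_um2": r.lumen_area_um2,
        "lumen_perimeter_um": r.lumen_perimeter_um, "ring_mean_od": r.ring_mean_od,
    } for r in records])
    return core, vessels_df


def finalize_coverage(cores: list[dict], vessel_tables: list[pd.DataFrame],
                      config: RunConfig) -> None:
    """Apply the 10 %-of-maximal-intensity rule at the configured scope.

    Mutates each core dict (adds ``perivascular_fraction``) and each vessel
    table (adds ``covered``).  With ``per_marker_cohort`` scope the maximal
    detected intensity is taken over all vessels of all cores sharing a
    marker; with ``per_core`` scope, within each core.
    """
    from .vessels import VesselRecord

    scope = config.vessels.max_od_scope
    marker_max: dict[str, float] = {}
    if scope == "per_marker_cohort":
        for core, vt in zip(cores, vessel_tables):
            if len(vt) and vt["ring_mean_od"].notna().any():
                m = float(vt["ring_mean_od"].max())
                marker_max[core["marker"]] = max(marker_max.get(core["marker"], 0.0), m)
    for core, vt in zip(cores, vessel_tables):
        if not len(vt):
            core["perivascular_fraction"] = np.nan
            continue
        recs = [VesselRecord(label=int(r.label), lumen_area_um2=0, lumen_perimeter_um=0,
                             ring_mean_od=float(r.ring_mean_od))
                for r in vt.itertuples()]
        max_od = marker_max.get(core["marker"]) if scope == "per_marker_cohort" else None
        core["perivascular_fraction"] = classify_coverage(recs, config.vessels, max_od=max_od)
        vt["covered"] = [r.covered for r in recs]


def load_core_image(row: pd.Series, pixel_size_um: float) -> TissueCoreImage:
    pixels = iio.imread(row["path"])
    if pixels.ndim == 3 and pixels.shape[2] == 4:
        pixels = pixels[..., :3]
    return TissueCoreImage(
        pixels=pixels, pixel_size_um=pixel_size_um,
        case_id=str(row["case_id"]), block_id=str(row.get("block_id", "")),
        site=str(row["site"]), marker=str(row["marker"]),
        epithelial_positive=bool(row.get("epithelial_positive", False)),
    )


def run_analyze(manifest: pd.DataFrame | str | Path, config: RunConfig,
                outdir: str | Path, pixel_size_um: float = 0.5477) -> dict:
    """Analyze every core in the manifest; write CSVs and a run log.

    Unreadable images are skipped and logged; a malformed manifest aborts.
    Returns a dict with the per-core table, per-case table and run metadata.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    missing = {"path", "case_id", "site", "marker"} - set(manifest.columns)
    if missing:
        raise ValueError(f"malformed manifest: missing columns {sorted(missing)}")

    cores: list[dict] = []
    vessel_tables: list[pd.DataFrame] = []
    skipped: list[dict] = []
    for _, row in manifest.iterrows():
        try:
            image = load_core_image(row, pixel_size_um)
        except Exception as exc:  # noqa: BLE001 - any reader failure skips the core
            log.warning("skipping unreadable core %s: %s", row["path"], exc)
            skipped.append({"path": row["path"], "reason": str(exc)})
            continue
        core, vt = analyze_core(image, config)
        core["core_id"] = str(row.get("core_id", Path(str(row["path"])).stem))
        if len(vt):
            vt.insert(0, "core_id", core["core_id"])
        cores.append(core)
        vessel_tables.append(vt)

    finalize_coverage(cores, vessel_tables, config)
    core_df = pd.DataFrame(cores) if cores else pd.DataFrame(
        columns=CORE_COLUMNS_WITH_STATUS)
    core_df, n_excluded = exclude_epithelial_positive(core_df)

    ok = core_df[core_df["status"] == "ok"].copy()
    case_df = aggregate_cores_to_case(ok, config.core_combiner) if len(ok) else pd.DataFrame()

    core_df.to_csv(outdir / "core_metrics.csv", index=False)
    case_df.to_csv(outdir / "case_metrics.csv", index=False)
    all_vessels = pd.concat([v for v in vessel_tables if len(v)], ignore_index=True) \
        if any(len(v) for v in vessel_tables) else pd.DataFrame()
    all_vessels.to_csv(outdir / "vessel_records.csv", index=False)

    run_log = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(repr(config).encode()).hexdigest()[:16],
        "n_cores": int(len(core_df)),
        "n_skipped": len(skipped),
        "skipped": skipped,
        "n_epithelial_excluded": n_excluded,
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2))
    return {"cores": core_df, "cases": case_df, "vessels": all_vessels, "log": run_log}


# --------------------------------------------------------------------------
# stats
# --------------------------------------------------------------------------

def run_stats(analysis_table: pd.DataFrame, paired_table: pd.DataFrame | None,
              config: RunConfig, outdir: str | Path, plots: bool = True) -> dict:
    """Cohort statistics on a per-case analysis table.

    ``analysis_table`` must contain the 13 metric columns plus the clinical
    columns; ``paired_table`` (optional) the ``_primary``/``_metastasis``
    pairs for the concordance analysis.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict = {}

    corr = spearman_matrix(analysis_table, METRICS)
    corr.to_csv(outdir / "correlation_matrix.csv", index=False)
    out["correlations"] = corr
    if plots:
        plot_correlation_heatmap(corr, METRICS, str(outdir / "correlation_heatmap.png"))

    if paired_table is not None and len(paired_table):
        conc = site_concordance(paired_table, METRICS)
        conc.to_csv(outdir / "site_concordance.csv", index=False)
        out["concordance"] = conc

    survival_rows = []
    chi_rows = []
    for metric in config.prognostic_metrics:
        rule = (config.stroma_fraction_rule if metric.endswith("fraction")
                else config.perivascular_intensity_rule)
        sub = analysis_table.dropna(subset=[metric, "os_months", "event"]).copy()
        if len(sub) < 8:
            warnings.warn(f"too few cases for survival analysis of {metric}", stacklevel=2)
            continue
        high = dichotomize(sub[metric].to_numpy(), rule)
        sub["metric_high"] = high.astype(float)
        km = km_logrank(high, sub["os_months"].to_numpy(), sub["event"].to_numpy())
        if plots:
            plot_km(km, str(outdir / f"km_{metric}.png"), title=metric)
        for mode in ("univariate", "multivariate"):
            try:
                fit = cox_fit(sub, "metric_high", mode, config=config.cox)
            except RuntimeError as exc:
                warnings.warn(f"{mode} Cox fit for {metric} failed: {exc}", stacklevel=2)
                continue
            fit.insert(0, "metric", metric)
            fit.insert(1, "mode", mode)
            fit.insert(2, "dichotomization", rule)
            survival_rows.append(fit)
        try:
            sel = backward_selection(sub, "metric_high", config=config.cox)
            retained = "metric_high" if sel["metric_retained"] else "(eliminated)"
        except RuntimeError as exc:
            warnings.warn(f"backward selection for {metric} failed: {exc}", stacklevel=2)
            retained = "(failed)"
        survival_rows.append(pd.DataFrame([{
            "metric": metric, "mode": "backward_selection",
            "dichotomization": rule, "term": retained,
            "coef": np.nan, "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
            "p_value": np.nan, "n": len(sub), "n_events": int(sub["event"].sum()),
        }]))
        chi = chi_square_association(high, sub)
        chi.insert(0, "metric", metric)
        chi_rows.append(chi)
        out[f"km_{metric}"] = {k: v for k, v in km.items() if k != "_fitters"}

    if survival_rows:
        surv = pd.concat(survival_rows, ignore_index=True)
        surv.to_csv(outdir / "survival_analysis.csv", index=False)
        out["survival"] = surv
    if chi_rows:
        chi = pd.concat(chi_rows, ignore_index=True)
        chi.to_csv(outdir / "clinical_associations.csv", index=False)
        out["associations"] = chi
    return out


# --------------------------------------------------------------------------
# simulate (image cohort) and demo
# --------------------------------------------------------------------------

def _image_params_from_metrics(row: pd.Series, marker: str, site: str,
                               base: ImageSimParams, seed: int) -> ImageSimParams:
    """Derive per-core rendering parameters from a case's simulated metrics."""
    prefix = {"ASMA": "asma", "DESMIN": "desmin", "PDGFBR": "pdgfrb"}[marker]
    core_area_mm2 = np.pi * (base.core_diameter_um / 2000.0) ** 2
    density = row.get(f"vessel_density_{site}", np.nan)
    n_vessels = int(np.clip(np.round((density if np.isfinite(density) else 40.0)
                                     * core_area_mm2), 3, 40))
    area = row.get(f"mean_lumen_area_{site}", np.nan)
    r_mean = float(np.sqrt((area if np.isfinite(area) else 200.0) / np.pi))
    r_mean = float(np.clip(r_mean, 3.0, 18.0))
    pv = row.get(f"{prefix}_perivascular_intensity_{site}", 0.4)
    pv = float(np.clip(pv, 0.1, 1.2)) if np.isfinite(pv) else 0.4
    frac = row.get(f"{prefix}_perivascular_fraction_{site}", 0.7)
    frac = float(np.clip(frac, 0.0, 1.0)) if np.isfinite(frac) else 0.7
    if marker == "DESMIN":
        sf, si = 0.0, 0.5
    else:
        sf = row.get(f"{prefix}_stroma_fraction_{site}", 0.3)
        sf = float(np.clip(sf, 0.0, 0.6)) if np.isfinite(sf) else 0.3
        si = row.get(f"{prefix}_stroma_intensity_{site}", 0.5)
        si = float(np.clip(si, 0.3, 1.2)) if np.isfinite(si) else 0.5
    return ImageSimParams(
        core_diameter_um=base.core_diameter_um,
        pixel_size_um=base.pixel_size_um,
        n_vessels=n_vessels,
        lumen_radius_um_range=(0.7 * r_mean, 1.3 * r_mean),
        wall_thickness_um=base.wall_thickness_um,
        coat_width_um=base.coat_width_um,
        covered_target_fraction=frac,
        covered_od_range=(max(0.15, 0.8 * pv), min(1.4, 1.2 * pv)),
        stroma_fraction_target=sf,
        stroma_od_mean=si,
        noise_sd=base.noise_sd,
        seed=seed,
    )


def simulate_image_cohort(cohort: pd.DataFrame, outdir: str | Path,
                          n_image_cases: int = 4, cores_per_case: int = 2,
                          base: ImageSimParams | None = None,
                          seed: int = 0, image_format: str = "png") -> pd.DataFrame:
    """Render core images for the first ``n_image_cases`` cohort cases.

    One image per (case, available site, marker, core); rendering parameters
    are derived from the case's simulated metric values so the measurement
    pipeline should approximately recover them.  Writes images plus
    ``manifest.csv`` and ``image_ground_truth.csv``; returns the manifest.
    """
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    base = base or ImageSimParams(core_diameter_um=420.0, n_vessels=10)
    rows, gt_rows = [], []
    counter = 0
    for _, case in cohort.head(n_image_cases).iterrows():
        for site in ("primary", "metastasis"):
            if not np.isfinite(case.get(f"vessel_density_{site}", np.nan)):
                continue
            for marker in ("ASMA", "DESMIN", "PDGFBR"):
                for k in range(cores_per_case):
                    counter += 1
                    params = _image_params_from_metrics(
                        case, marker, site, base, seed=seed * 1_000_003 % (2**31) + counter)
                    core_id = f"{case['case_id']}_{site}_{marker}_{k}"
                    image, gt = generate_core_image(
                        params, case_id=case["case_id"], site=site, marker=marker)
                    path = outdir / "images" / f"{core_id}.{image_format}"
                    iio.imwrite(path, image.pixels)
                    rows.append({"path": str(path), "core_id": core_id,
                                 "case_id": case["case_id"], "block_id": "",
                                 "site": site, "marker": marker,
                                 "epithelial_positive": False})
                    gt_rows.append({
                        "core_id": core_id, "vessel_count": gt.vessel_count,
                        "true_stroma_fraction": gt.true_stroma_fraction,
                        "true_stroma_mean_od": gt.true_stroma_mean_od,
                        "tumor_area_um2": gt.tumor_area_um2,
                    })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    pd.DataFrame(gt_rows).to_csv(outdir / "image_ground_truth.csv", index=False)
    return manifest


def run_full_demo(outdir: str | Path, config: RunConfig | None = None,
                  seed: int = 0, n_cases: int = 186, n_image_cases: int = 3,
                  plots: bool = True) -> dict:
    """End-to-end demonstration on synthetic data.

    1. simulate a cohort of ``n_cases`` cases (clinical + metric table);
    2. render and analyze core images for the first ``n_image_cases`` cases
       (writes the image-derived per-core and per-case metric tables);
    3. run the cohort statistics on the simulated metric table (correlation
       matrix, paired concordance, KM / Cox survival, associations).
    """
    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = generate_cohort(CohortSimParams(n_cases=n_cases, seed=seed))
    clinical = cohort[CLINICAL_COLUMNS]
    clinical.to_csv(outdir / "clinical.csv", index=False)
    cohort.to_csv(outdir / "cohort_metrics.csv", index=False)

    manifest = simulate_image_cohort(cohort, outdir / "simulated_images",
                                     n_image_cases=n_image_cases, seed=seed)
    analysis = run_analyze(manifest, config, outdir / "image_analysis",
                           pixel_size_um=0.5477)

    # per-case analysis table from the simulated metric cohort
    resolved = {}
    for m in METRICS:
        prim, met = cohort[f"{m}_primary"], cohort[f"{m}_metastasis"]
        if config.site_policy == "primary_only":
            resolved[m] = prim
        else:
            resolved[m] = prim.where(prim.notna(), met)
    table = pd.DataFrame(resolved)
    table = pd.concat([table, clinical], axis=1)
    if config.site_policy == "primary_only":
        table = table[cohort[f"{METRICS[0]}_primary"].notna()]

    paired = cohort[cohort[f"{METRICS[0]}_primary"].notna()
                    & cohort[f"{METRICS[0]}_metastasis"].notna()]
    stats_out = run_stats(table, paired, config, outdir / "stats", plots=plots)

    return {"cohort": cohort, "analysis_table": table, "image_analysis": analysis,
            "stats": stats_out}
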