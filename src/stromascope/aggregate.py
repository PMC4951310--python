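"""Core-to-case aggregation and the per-case analysis table.

Each case contributes up to four cores per marker and site.  Vessel metrics
(density, mean lumen area/perimeter) derive from the CD34 channel of every
double-stained core regardless of marker and are averaged across all of a
case-site's cores; marker-specific perivascular and stroma metrics are
averaged within their marker.  Desmin is scored in the perivascular
compartment only, so desmin stroma metrics do not exist — the full panel is
the 13-metric vector in :data:`stromascope.simulate.METRICS`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import METRICS

__all__ = ["METRICS", "CORE_COLUMNS", "aggregate_cores_to_case", "build_analysis_table"]

VESSEL_METRICS = ["vessel_density", "mean_lumen_area", "mean_lumen_perimeter"]
MARKER_PREFIX = {"ASMA": "asma", "DESMIN": "desmin", "PDGFBR": "pdgfrb"}

#: Schema of the per-core metric table produced by the analysis pipeline.
CORE_COLUMNS = [
    "core_id", "case_id", "block_id", "site", "marker", "epithelial_positive",
    "vessel_density", "mean_lumen_area", "mean_lumen_perimeter",
    "perivascular_intensity", "perivascular_fraction",
    "stroma_intensity", "stroma_fraction",
]

SITE_POLICIES = ("primary_only", "primary_else_metastasis", "paired_only")


def aggregate_cores_to_case(cores: pd.DataFrame, combiner: str = "mean") -> pd.DataFrame:
    """Collapse per-core metrics to one 13-metric row per (case, site).

    Each metric is the unweighted mean (or median) over the cores where it
    is non-missing; a slot stays missing when no core provides it.  Vessel
    metrics pool the CD34 measurements of all markers' cores.  Raises on
    conflicting metadata (one core id mapped to two cases).
    """
    if combiner not in ("mean", "median"):
        raise ValueError("combiner must be 'mean' or 'median'")
    agg = "mean" if combiner == "mean" else "median"
    cores = cores.copy()

    dup = cores.groupby("core_id")["case_id"].nunique()
    if (dup > 1).any():
        bad = dup[dup > 1].index.tolist()
        raise ValueError(f"conflicting case metadata for core ids {bad}")

    rows = []
    for (case_id, site), grp in cores.groupby(["case_id", "site"], sort=True):
        row: dict = {"case_id": case_id, "site": site}
        for m in VESSEL_METRICS:
            row[m] = getattr(grp[m].dropna(), agg)() if grp[m].notna().any() else np.nan
        for marker, prefix in MARKER_PREFIX.items():
            sub = grp[grp["marker"] == marker]
            for kind in ("perivascular_intensity", "perivascular_fraction",
                         "stroma_intensity", "stroma_fraction"):
                name = f"{prefix}_{kind}"
                if name not in METRICS:
                    continue  # desmin carries no stroma metrics
                vals = sub[kind].dropna() if len(sub) else pd.Series(dtype=float)
                row[name] = getattr(vals, agg)() if len(vals) else np.nan
        rows.append(row)
    out = pd.DataFrame(rows, columns=["case_id", "site"] + METRICS)
    return out


def build_analysis_table(case_metrics: pd.DataFrame, clinical: pd.DataFrame | None,
                         site_policy: str = "primary_else_metastasis") -> pd.DataFrame:
    """Resolve sites into one flat row per case and join clinical data.

    Policies: ``primary_only`` keeps cases with primary-site metrics;
    ``primary_else_metastasis`` substitutes metastatic metrics for cases
    without primary tissue (the extended-cohort analysis);``paired_only``
    keeps cases with both sites and emits ``<metric>_primary`` and
    ``<metric>_metastasis`` columns (the paired concordance analysis).
    """
    if site_policy not in SITE_POLICIES:
        raise ValueError(f"unknown site policy {site_policy!r}; choose from {SITE_POLICIES}")
    wide = case_metrics.pivot_table(index="case_id", columns="site", values=METRICS,
                                    aggfunc="first", observed=True)
    has = {
        s: (wide.xs(s, axis=1, level=1).notna().any(axis=1)
            if s in case_metrics["site"].unique() else pd.Series(False, index=wide.index))
        for s in ("primary", "metastasis")
    }

    if site_policy == "paired_only":
        keep = wide.index[has["primary"] & has["metastasis"]]
        if len(keep) == 0:
            import warnings
            warnings.warn("no paired cases under paired_only policy", stacklevel=2)
        cols = {}
        for m in METRICS:
            for s in ("primary", "metastasis"):
                cols[f"{m}_{s}"] = (wide[(m, s)].loc[keep]
                                    if (m, s) in wide.columns else np.nan)
        out = pd.DataFrame(cols, index=keep)
    else:
        if site_policy == "primary_only":
            keep = wide.index[has["primary"]]
        else:
            keep = wide.index[has["primary"] | has["metastasis"]]
        cols = {}
        site_used = np.where(has["primary"].loc[keep], "primary", "metastasis")
        for m in METRICS:
            prim = wide[(m, "primary")] if (m, "primary") in wide.columns else pd.Series(np.nan, index=wide.index)
            met = wide[(m, "metastasis")] if (m, "metastasis") in wide.columns else pd.Series(np.nan, index=wide.index)
            if site_policy == "primary_only":
                cols[m] = prim.loc[keep]
            else:
                cols[m] = prim.loc[keep].where(has["primary"].loc[keep], met.loc[keep])
        out = pd.DataFrame(cols, index=keep)
        out["site_used"] = site_used
    out.index.name = "case_id"
    out = out.reset_index()
    if clinical is not None:
        out = out.merge(clinical, on="case_id", how="left")
    return out
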