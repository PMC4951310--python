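"""CD34+ vessel segmentation and vascular / perivascular metrics.

A vessel is a connected component of CD34 optical density above threshold
inside the tissue mask; its lumen is the set of enclosed holes.  Around each
vessel a concentric measurement ring of fixed physical width samples the
stroma-marker OD, yielding per-vessel perivascular intensity.  Vessels are
then called "covered" when their ring mean OD strictly exceeds 10 % of the
maximal detected intensity (equality counts as uncovered), and the
perivascular fraction is the covered share.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as sk_label, perimeter, perimeter_crofton

from .stains import ODChannelPair

__all__ = [
    "VesselAnalysisConfig",
    "VesselRecord",
    "segment_vessels",
    "vessel_density",
    "perivascular_rings",
    "perivascular_intensity",
    "classify_coverage",
    "analyze_vessels",
]


@dataclass
class VesselAnalysisConfig:
    """Segmentation and coverage-call parameters.

    ``coverage_cutoff_fraction`` is the 10 %-of-maximal-intensity rule;
    ``max_od_scope`` chooses whether the maximum is taken per core or across
    all cores of a marker in the run (the default, which makes the
    covered/uncovered call comparable between cases).
    """

    cd34_od_threshold: float = 0.15
    min_vessel_area_um2: float = 20.0
    ring_width_um: float = 10.0
    coverage_cutoff_fraction: float = 0.10
    max_od_scope: str = "per_marker_cohort"  # or "per_core"
    perimeter_estimator: str = "crofton"  # or "marching"
    include_zero_lumen: bool = True

    def validate(self) -> None:
        if not 0.0 < self.coverage_cutoff_fraction < 1.0:
            raise ValueError("coverage_cutoff_fraction must lie in (0, 1)")
        if self.ring_width_um <= 0:
            raise ValueError("ring_width_um must be positive")
        if self.max_od_scope not in ("per_marker_cohort", "per_core"):
            raise ValueError("max_od_scope must be 'per_marker_cohort' or 'per_core'")
        if self.perimeter_estimator not in ("crofton", "marching"):
            raise ValueError("perimeter_estimator must be 'crofton' or 'marching'")


@dataclass
class VesselRecord:
    """One segmented vessel; `ring_mean_od` / `covered` filled in later."""

    label: int
    lumen_area_um2: float
    lumen_perimeter_um: float
    ring_mean_od: float = float("nan")
    covered: bool | None = None


def _lumen_perimeter(hole_mask: np.ndarray, estimator: str) -> float:
    if not hole_mask.any():
        return 0.0
    if estimator == "crofton":
        return float(perimeter_crofton(hole_mask, directions=4))
    return float(perimeter(hole_mask, neighborhood=4))


def segment_vessels(od: ODChannelPair, cfg: VesselAnalysisConfig | None = None
                    ) -> tuple[np.ndarray, list[VesselRecord]]:
    """Segment vessels; return (label raster, geometry records).

    Components of ``od_cd34 > cd34_od_threshold`` within the tissue mask
    (8-connected) below ``min_vessel_area_um2`` are discarded; the survivors
    are relabeled 1..n in raster order.  Each record carries the lumen
    (enclosed-hole) area and perimeter; a solid component has lumen area 0.
    """
    cfg = cfg or VesselAnalysisConfig()
    cfg.validate()
    if not od.tissue_mask.any():
        raise ValueError("empty tissue mask: core should be excluded upstream")
    px = od.pixel_size_um
    binary = (od.od_cd34 > cfg.cd34_od_threshold) & od.tissue_mask
    raw = sk_label(binary, connectivity=2)
    min_px = cfg.min_vessel_area_um2 / px**2

    labels = np.zeros_like(raw)
    records: list[VesselRecord] = []
    next_id = 0
    for obj_slice, lab in zip(ndimage.find_objects(raw), range(1, raw.max() + 1)):
        comp = raw[obj_slice] == lab
        area_px = int(comp.sum())
        if area_px < min_px:
            continue
        next_id += 1
        labels[obj_slice][comp] = next_id
        filled = ndimage.binary_fill_holes(comp)
        holes = filled & ~comp
        records.append(VesselRecord(
            label=next_id,
            lumen_area_um2=float(holes.sum()) * px**2,
            lumen_perimeter_um=_lumen_perimeter(holes, cfg.perimeter_estimator) * px,
        ))
    return labels, records


def vessel_density(n_vessels: int, tumor_area_um2: float) -> float:
    """Vessel count per mm^2 of tumor area."""
    if not tumor_area_um2 > 0:
        raise ValueError("tumor area must be positive (empty cores are excluded)")
    return n_vessels / (tumor_area_um2 / 1e6)


def perivascular_rings(labels: np.ndarray, ring_width_um: float, pixel_size_um: float,
                       tissue_mask: np.ndarray | None = None) -> np.ndarray:
    """Assign each pixel within ``ring_width_um`` of a vessel to its ring.

    Returns an integer raster: 0 outside all rings, else the label of the
    assigned vessel.  Ring pixels exclude vessel pixels and their enclosed
    lumina (the ring samples the tissue surrounding the vessel, not the
    vessel interior); a pixel near two vessels goes to the nearer one, ties
    to the lower label (labels are scanned in increasing order with a
    strict-improvement update, so the first, i.e. lowest, label wins ties).
    """
    ring_px = ring_width_um / pixel_size_um
    ring_labels = np.zeros_like(labels, dtype=np.int32)
    if labels.max() == 0 or ring_px <= 0:
        return ring_labels
    best = np.full(labels.shape, np.inf, dtype=np.float32)
    eligible = ~ndimage.binary_fill_holes(labels > 0)
    if tissue_mask is not None:
        eligible &= tissue_mask
    for lab in range(1, int(labels.max()) + 1):
        if not (labels == lab).any():
            continue
        d = ndimage.distance_transform_edt(labels != lab)
        m = eligible & (d <= ring_px) & (d < best)
        ring_labels[m] = lab
        best[m] = d[m]
    return ring_labels


def perivascular_intensity(ring_labels: np.ndarray, od_marker: np.ndarray,
                           records: list[VesselRecord]) -> float:
    """Fill each record's ring mean marker OD; return the core-level mean.

    The core metric is the unweighted mean over vessels with non-empty
    rings; vessels with empty rings are dropped from intensity metrics with
    a warning.  Returns NaN when no vessel has a ring.
    """
    means = []
    for rec in records:
        m = ring_labels == rec.label
        if not m.any():
            warnings.warn(f"vessel {rec.label} has an empty perivascular ring; "
                          "dropped from intensity metrics", stacklevel=2)
            rec.ring_mean_od = float("nan")
            continue
        rec.ring_mean_od = float(od_marker[m].mean())
        means.append(rec.ring_mean_od)
    return float(np.mean(means)) if means else float("nan")


def classify_coverage(records: list[VesselRecord], cfg: VesselAnalysisConfig | None = None,
                      max_od: float | None = None) -> float:
    """Covered/uncovered calls and the perivascular fraction.

    covered <=> ring_mean_od > cutoff_fraction * M, strictly: a vessel at
    exactly the cutoff is uncovered.  ``max_od`` supplies M for cohort-scope
    runs; otherwise M is the per-core maximum of the ring means.  With zero
    vessels the fraction is NaN; with M = 0 all vessels are uncovered.
    """
    cfg = cfg or VesselAnalysisConfig()
    cfg.validate()
    with_rings = [r for r in records if np.isfinite(r.ring_mean_od)]
    if not with_rings:
        return float("nan")
    m = max_od if max_od is not None else max(r.ring_mean_od for r in with_rings)
    cut = cfg.coverage_cutoff_fraction * m
    for r in with_rings:
        r.covered = bool(r.ring_mean_od > cut)
    return sum(r.covered for r in with_rings) / len(with_rings)


def analyze_vessels(od: ODChannelPair, cfg: VesselAnalysisConfig | None = None,
                    cohort_max_od: float | None = None
                    ) -> tuple[dict, pd.DataFrame, np.ndarray]:
    """Full per-core vessel analysis.

    Returns (core metric dict, per-vessel table, label raster).  With
    ``max_od_scope='per_marker_cohort'`` the coverage call needs the cohort
    maximum; pass it as ``cohort_max_od`` (a second pass over cores), else
    the per-core maximum is used.
    """
    cfg = cfg or VesselAnalysisConfig()
    labels, records = segment_vessels(od, cfg)
    ring_labels = perivascular_rings(labels, cfg.ring_width_um, od.pixel_size_um,
                                     od.tissue_mask)
    pv_int = perivascular_intensity(ring_labels, od.od_marker, records)
    use_max = cohort_max_od if cfg.max_od_scope == "per_marker_cohort" else None
    pv_frac = classify_coverage(records, cfg, max_od=use_max)

    if records:
        areas = [r.lumen_area_um2 for r in records]
        perims = [r.lumen_perimeter_um for r in records]
        if not cfg.include_zero_lumen:
            keep = [a > 0 for a in areas]
            areas = [a for a, k in zip(areas, keep) if k] or [0.0]
            perims = [p for p, k in zip(perims, keep) if k] or [0.0]
        mean_area = float(np.mean(areas))
        mean_perim = float(np.mean(perims))
    else:
        mean_area = float("nan")
        mean_perim = float("nan")

    core = {
        "n_vessels": len(records),
        "vessel_density": vessel_density(len(records), od.tumor_area_um2),
        "mean_lumen_area": mean_area,
        "mean_lumen_perimeter": mean_perim,
        "perivascular_intensity": pv_int,
        "perivascular_fraction": pv_frac,
    }
    table = pd.DataFrame(
        [{
            "label": r.label,
            "lumen_area_um2": r.lumen_area_um2,
            "lumen_perimeter_um": r.lumen_perimeter_um,
            "ring_mean_od": r.ring_mean_od,
            "covered": r.covered,
        } for r in records]
    )
    return core, table, labels
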