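"""Marker-positive stroma fraction and intensity with size-based clean-up.

The marker-positive area is every tissue pixel whose marker OD exceeds a
pre-set background threshold, cleaned in two passes:

1. positive components of at most 50 px (15 um^2 at 0.5477 um/px) are set
   negative ("up to" is boundary-inclusive: exactly 50 px is removed);
2. negative regions fully enclosed by positive area whose minimal
   bounding-box side is at most 20 px (~11 um) are set positive.

Stroma fraction = cleaned positive pixels / tissue pixels; stroma intensity
= mean marker OD over the cleaned positive pixels.  Positive components use
8-connectivity, holes 4-connectivity (the standard complementary pairing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

__all__ = [
    "StromaConfig",
    "threshold_positive",
    "remove_small_positive",
    "fill_small_negative_holes",
    "clean_positive_mask",
    "stroma_fraction",
    "stroma_intensity",
    "exclude_epithelial_positive",
    "calibrate_background",
]


@dataclass
class StromaConfig:
    """Thresholds of the positive-area clean-up.

    The pixel defaults correspond to 15 um^2 (50 px) and 11 um (20 px) at
    0.5477 um/px.  ``hole_rule`` selects how "20 square pixels / minimal
    linear dimension 11 um" is read: ``"min_bbox_side"`` (default, <= 20 px
    on the shorter bounding-box side) or ``"area"`` (<= 20 px area).
    """

    background_od_threshold: float = 0.15
    small_positive_max_area_px: int = 50
    hole_fill_max_dim_px: int = 20
    hole_rule: str = "min_bbox_side"  # or "area"

    def validate(self) -> None:
        if self.background_od_threshold <= 0:
            raise ValueError("background_od_threshold must be positive")
        if self.small_positive_max_area_px < 0 or self.hole_fill_max_dim_px < 0:
            raise ValueError("size thresholds must be nonnegative")
        if self.hole_rule not in ("min_bbox_side", "area"):
            raise ValueError("hole_rule must be 'min_bbox_side' or 'area'")


def threshold_positive(od_marker: np.ndarray, tissue_mask: np.ndarray,
                       cfg: StromaConfig | None = None) -> np.ndarray:
    """Positive <=> inside tissue mask and marker OD above the background threshold."""
    cfg = cfg or StromaConfig()
    cfg.validate()
    return (np.asarray(od_marker) > cfg.background_od_threshold) & np.asarray(tissue_mask, bool)


def remove_small_positive(binary: np.ndarray, cfg: StromaConfig | None = None) -> np.ndarray:
    """Set 8-connected positive components of area <= 50 px to negative."""
    cfg = cfg or StromaConfig()
    cfg.validate()
    binary = np.asarray(binary, bool)
    labels = sk_label(binary, connectivity=2)
    if labels.max() == 0:
        return binary.copy()
    areas = np.bincount(labels.ravel())
    keep = areas > cfg.small_positive_max_area_px  # "up to 50 px" removed
    keep[0] = False
    return keep[labels]


def fill_small_negative_holes(binary: np.ndarray, cfg: StromaConfig | None = None) -> np.ndarray:
    """Fill enclosed negative regions with minimal bounding-box side <= 20 px.

    A negative 4-connected component is "enclosed" when it does not touch
    the raster border (so it is completely surrounded by positive pixels
    under the complementary-connectivity pairing); border-touching holes
    are never filled.
    """
    cfg = cfg or StromaConfig()
    cfg.validate()
    binary = np.asarray(binary, bool).copy()
    holes = sk_label(~binary, connectivity=1, background=0)
    border = np.unique(np.concatenate([
        holes[0, :], holes[-1, :], holes[:, 0], holes[:, -1]]))
    border_set = set(int(b) for b in border)
    for obj_slice, lab in zip(ndimage.find_objects(holes), range(1, holes.max() + 1)):
        if obj_slice is None or lab in border_set:
            continue
        comp = holes[obj_slice] == lab
        if cfg.hole_rule == "min_bbox_side":
            small = min(comp.shape) <= cfg.hole_fill_max_dim_px
        else:
            small = comp.sum() <= cfg.hole_fill_max_dim_px
        if small:
            binary[obj_slice][comp] = True
    return binary


def clean_positive_mask(binary: np.ndarray, cfg: StromaConfig | None = None) -> np.ndarray:
    """Small-positive removal followed by small-hole filling (idempotent)."""
    return fill_small_negative_holes(remove_small_positive(binary, cfg), cfg)


def stroma_fraction(binary_clean: np.ndarray, tissue_mask: np.ndarray) -> float:
    """Cleaned positive area / tissue area, in [0, 1]; NaN for an empty mask."""
    n_tissue = int(np.asarray(tissue_mask, bool).sum())
    if n_tissue == 0:
        return float("nan")
    return float(np.asarray(binary_clean, bool).sum()) / n_tissue


def stroma_intensity(od_marker: np.ndarray, binary_clean: np.ndarray) -> float:
    """Mean marker OD over the cleaned positive area; NaN when empty."""
    m = np.asarray(binary_clean, bool)
    if not m.any():
        return float("nan")
    return float(np.asarray(od_marker, dtype=float)[m].mean())


def exclude_epithelial_positive(cores: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Null the stroma metrics of epithelial-positive PDGFbR cores.

    ``cores`` is a per-core metric table with ``marker`` and
    ``epithelial_positive`` columns; flagged PDGFBR cores keep their vessel
    metrics but lose ``stroma_fraction`` / ``stroma_intensity``.  Returns
    the filtered table and the exclusion count.
    """
    cores = cores.copy()
    if "epithelial_positive" not in cores.columns:
        warnings.warn("epithelial_positive flag missing; treating all cores as "
                      "epithelial-negative", stacklevel=2)
        cores["epithelial_positive"] = False
    flagged = (cores["marker"] == "PDGFBR") & cores["epithelial_positive"].fillna(False)
    for col in ("stroma_fraction", "stroma_intensity"):
        if col in cores.columns:
            cores.loc[flagged, col] = np.nan
    return cores, int(flagged.sum())


def calibrate_background(od_samples: list[np.ndarray],
                         masks: list[np.ndarray] | None = None,
                         n_bins: int = 256) -> dict:
    """Advisory background-threshold suggestion from sample cores.

    Pools marker OD values (within the tissue masks when given), reports the
    histogram background mode, a robust spread (MAD) and an Otsu split, and
    suggests ``max(otsu, mode + 3 * 1.4826 * MAD)``.  Deterministic; the
    run's threshold is always the configured value, never this suggestion.
    """
    if not od_samples:
        raise ValueError("at least one sample image is required")
    vals = []
    for i, od in enumerate(od_samples):
        od = np.asarray(od, dtype=float).ravel()
        if masks is not None:
            od = od[np.asarray(masks[i], bool).ravel()]
        vals.append(od)
    pooled = np.concatenate(vals)
    hist, edges = np.histogram(pooled, bins=n_bins)
    mode = float(0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1]))
    mad = float(np.median(np.abs(pooled - np.median(pooled))))
    try:
        otsu = float(threshold_otsu(pooled, nbins=n_bins))
    except ValueError:  # constant input
        otsu = mode
    suggestion = max(otsu, mode + 3 * 1.4826 * mad)
    return {"background_mode": mode, "mad": mad, "otsu": otsu,
            "suggested_threshold": float(suggestion)}
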