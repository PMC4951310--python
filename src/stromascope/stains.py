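"""Stain separation: RGB core images to per-stain optical-density channels.

Double-stained TMA cores carry two alkaline-phosphatase chromogens: Vector
Red marking CD34+ endothelium and Vector Blue marking a stroma/pericyte
marker (alpha-SMA, desmin or PDGFbR).  Under the Beer-Lambert model the
optical density (OD = -log10 transmittance) of a pixel is the sum of the two
stain contributions along fixed per-stain RGB absorbance directions, so the
two stain amounts can be recovered pixel-wise by least squares.

Real chromogen vectors must be calibrated per staining batch; the defaults
here match the synthetic renderer so that separation is exactly invertible
on noiseless simulated images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "TissueCoreImage",
    "ODChannelPair",
    "StainConfig",
    "VECTOR_RED",
    "VECTOR_BLUE",
    "rgb_to_od",
    "od_to_rgb",
    "unmix_stains",
    "tissue_mask",
    "separate_core",
]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


#: Absorbance direction of the CD34 chromogen (Vector Red): absorbs mostly
#: green and blue light, so stained pixels appear red/magenta.
VECTOR_RED = _unit([0.10, 0.80, 0.59])

#: Absorbance direction of the stroma-marker chromogen (Vector Blue):
#: absorbs mostly red and green light, so stained pixels appear blue.
VECTOR_BLUE = _unit([0.75, 0.60, 0.28])

VALID_MARKERS = ("ASMA", "DESMIN", "PDGFBR")
VALID_SITES = ("primary", "metastasis")


@dataclass
class TissueCoreImage:
    """One RGB tissue-microarray core raster with calibration and identity.

    Parameters
    ----------
    pixels : (H, W, 3) uint8 array
    pixel_size_um : physical side length of a pixel in micrometers.
    case_id, block_id : patient / paraffin-block identifiers.
    site : ``"primary"`` (ovary) or ``"metastasis"``.
    marker : which Vector-Blue stain this core carries
        (``"ASMA"``, ``"DESMIN"`` or ``"PDGFBR"``).
    epithelial_positive : pathologist QC flag; PDGFbR cores with positive
        epithelial staining are excluded from stroma metrics downstream.
    """

    pixels: np.ndarray
    pixel_size_um: float
    case_id: str = ""
    block_id: str = ""
    site: str = "primary"
    marker: str = "PDGFBR"
    epithelial_positive: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty (H, W, 3) raster")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.site not in VALID_SITES:
            raise ValueError(f"site must be one of {VALID_SITES}")
        if self.marker not in VALID_MARKERS:
            raise ValueError(f"marker must be one of {VALID_MARKERS}")


@dataclass
class ODChannelPair:
    """Per-pixel stain optical densities plus the tissue mask.

    ``od_cd34`` and ``od_marker`` are nonnegative float rasters with the
    same shape as the source image; ``tissue_mask`` delimits the tumor
    area used as denominator for all fraction metrics.
    """

    od_cd34: np.ndarray
    od_marker: np.ndarray
    tissue_mask: np.ndarray
    pixel_size_um: float

    @property
    def tumor_area_um2(self) -> float:
        return float(self.tissue_mask.sum()) * self.pixel_size_um**2


@dataclass
class StainConfig:
    """Separation parameters; vectors must be calibrated for real slides."""

    stain_vector_cd34: np.ndarray = field(default_factory=lambda: VECTOR_RED.copy())
    stain_vector_marker: np.ndarray = field(default_factory=lambda: VECTOR_BLUE.copy())
    white_point: tuple = (255.0, 255.0, 255.0)
    tissue_od_floor: float = 0.05
    closing_radius_px: int = 2
    max_condition_number: float = 1e3


def rgb_to_od(pixels: np.ndarray, white_point: Sequence[float] = (255.0, 255.0, 255.0),
              eps: float = 1e-6) -> np.ndarray:
    """Convert an RGB raster to per-channel optical density.

    OD = -log10((I + eps) / W) per channel, clipped at zero; ``eps`` guards
    against log(0) for saturated-black pixels.
    """
    w = np.asarray(white_point, dtype=float)
    if np.any(w <= 0):
        raise ValueError("white point channels must be positive")
    od = -np.log10((np.asarray(pixels, dtype=float) + eps) / w)
    return np.clip(od, 0.0, None)


def od_to_rgb(od: np.ndarray, white_point: Sequence[float] = (255.0, 255.0, 255.0)) -> np.ndarray:
    """Forward Beer-Lambert rendering of a per-channel OD raster to uint8 RGB."""
    w = np.asarray(white_point, dtype=float)
    rgb = w * np.power(10.0, -np.asarray(od, dtype=float))
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def unmix_stains(od_rgb: np.ndarray, stain_vectors: np.ndarray | None = None,
                 max_condition_number: float = 1e3) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares projection of per-pixel OD onto two stain directions.

    Parameters
    ----------
    od_rgb : (H, W, 3) nonnegative OD raster.
    stain_vectors : (2, 3) array of unit absorbance vectors
        (row 0: CD34 / Vector Red, row 1: marker / Vector Blue).

    Returns
    -------
    (od_cd34, od_marker) : nonnegative (H, W) rasters; negative least-squares
    coefficients are clipped to zero.
    """
    if stain_vectors is None:
        stain_vectors = np.stack([VECTOR_RED, VECTOR_BLUE])
    S = np.asarray(stain_vectors, dtype=float)
    if S.shape != (2, 3):
        raise ValueError("stain_vectors must have shape (2, 3)")
    S = S / np.linalg.norm(S, axis=1, keepdims=True)
    gram = S @ S.T
    if np.linalg.cond(gram) > max_condition_number:
        raise ValueError(
            "stain vectors are near-parallel (Gram condition number "
            f"{np.linalg.cond(gram):.3g} exceeds {max_condition_number:g})"
        )
    # coefficients c = (S S^T)^-1 S od, evaluated for all pixels at once
    proj = np.linalg.solve(gram, S)  # (2, 3)
    coeffs = np.tensordot(np.asarray(od_rgb, dtype=float), proj, axes=([-1], [1]))
    coeffs = np.clip(coeffs, 0.0, None)
    return coeffs[..., 0], coeffs[..., 1]


def tissue_mask(od_rgb: np.ndarray, od_floor: float = 0.05,
                closing_radius_px: int = 2) -> np.ndarray:
    """Segment the tissue disc: summed OD above a floor, opened (to drop
    isolated noise speckle off the tissue), closed, hole-filled, largest
    connected component retained.

    Returns an all-false mask (with a warning) for blank images; callers
    treat an empty mask as an excluded core.
    """
    total = np.asarray(od_rgb, dtype=float).sum(axis=-1)
    raw = total > od_floor
    if not raw.any():
        warnings.warn("tissue mask is empty: blank image, core excluded", stacklevel=2)
        return raw
    st = ndimage.generate_binary_structure(2, 2)
    raw = ndimage.binary_opening(raw, structure=st)
    if closing_radius_px > 0:
        raw = ndimage.binary_closing(raw, structure=st, iterations=closing_radius_px)
    raw = ndimage.binary_fill_holes(raw)
    labels, n = ndimage.label(raw)
    if n == 0:
        warnings.warn("tissue mask is empty after morphology: core excluded", stacklevel=2)
        return np.zeros_like(raw, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def separate_core(image: TissueCoreImage, config: StainConfig | None = None) -> ODChannelPair:
    """Full separation: RGB -> OD -> unmixed stain channels + tissue mask."""
    cfg = config or StainConfig()
    od_rgb = rgb_to_od(image.pixels, cfg.white_point)
    od_cd34, od_marker = unmix_stains(
        od_rgb,
        np.stack([cfg.stain_vector_cd34, cfg.stain_vector_marker]),
        cfg.max_condition_number,
    )
    mask = tissue_mask(od_rgb, cfg.tissue_od_floor, cfg.closing_radius_px)
    return ODChannelPair(od_cd34=od_cd34, od_marker=od_marker,
                         tissue_mask=mask, pixel_size_um=image.pixel_size_um)
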