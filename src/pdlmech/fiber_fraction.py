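"""Collagen-fiber volume fraction from segmented histology sections.

Masson-stained PDL sections render collagen blue; after segmentation the
fiber volume fraction of a section is the area ratio Vf = Px/PI, where Px
is the collagen-pixel count inside the region of interest (ROI) and PI the
ROI pixel count. Per-region fractions are aggregated as the arithmetic
mean over sections. "Volume" fraction is measured as an area fraction on
2-D sections, with no stereological correction — the sections sample the
tissue thinly enough that area fraction is the standard surrogate.

This module consumes already-binarised masks or pixel counts. Interactive
colour segmentation is deliberately not reproduced; a clearly labelled
hue-threshold convenience (:func:`masson_collagen_mask`) is offered for
users who want a starting point on raw RGB images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SectionMeasurement",
    "RegionFractionSummary",
    "REGION_SECTION_FRACTIONS_PCT",
    "volume_fraction",
    "mask_fraction",
    "region_summary",
    "masson_collagen_mask",
]

#: Reference per-section collagen area fractions (percent) measured on five
#: Masson-stained sections per root region of a human incisor; the regional
#: means of these values are the Vf presets used by the synthetic module.
REGION_SECTION_FRACTIONS_PCT: dict[str, tuple[float, ...]] = {
    "neck": (60.007, 51.991, 53.889, 67.895, 67.78),
    "middle": (58.249, 65.771, 65.65, 61.369, 64.669),
    "apex": (62.198, 59.01, 41.2, 51.417, 46.116),
}


@dataclass(frozen=True)
class SectionMeasurement:
    """One section's fiber/ROI areas and the derived fraction."""

    fiber_area: float
    roi_area: float
    vf: float
    section_id: str = ""
    region: str = ""

    @classmethod
    def from_counts(cls, fiber_area, roi_area, section_id="", region=""):
        return cls(
            fiber_area=float(fiber_area),
            roi_area=float(roi_area),
            vf=volume_fraction(fiber_area, roi_area),
            section_id=section_id,
            region=region,
        )


@dataclass(frozen=True)
class RegionFractionSummary:
    """Per-section fractions and their arithmetic mean for one root region."""

    region: str
    fractions: tuple[float, ...]
    mean_vf: float


def volume_fraction(fiber_area: float, roi_area: float) -> float:
    """Area fraction Px/PI of collagen within the ROI.

    Strict entry point for externally supplied counts: fiber area must not
    exceed the ROI area (segmentation outside the ROI is an error here).
    """
    fiber_area = float(fiber_area)
    roi_area = float(roi_area)
    if roi_area <= 0:
        raise ValueError(f"ROI area must be positive, got {roi_area}")
    if fiber_area < 0:
        raise ValueError(f"fiber area must be non-negative, got {fiber_area}")
    if fiber_area > roi_area:
        raise ValueError(
            f"fiber area {fiber_area} exceeds ROI area {roi_area} "
            "(segmentation outside ROI)"
        )
    return fiber_area / roi_area


def mask_fraction(fiber_mask: np.ndarray, roi_mask: np.ndarray) -> float:
    """Fraction of ROI pixels that are fiber: count(fiber ∧ roi)/count(roi).

    Fiber pixels outside the ROI are clipped, not treated as errors —
    hand-traced ROIs routinely overlap the segmentation boundary.
    """
    fiber_mask = np.asarray(fiber_mask).astype(bool)
    roi_mask = np.asarray(roi_mask).astype(bool)
    if fiber_mask.shape != roi_mask.shape:
        raise ValueError(
            f"mask shapes differ: {fiber_mask.shape} vs {roi_mask.shape}"
        )
    roi_count = int(roi_mask.sum())
    if roi_count == 0:
        raise ValueError("ROI mask is empty")
    return int((fiber_mask & roi_mask).sum()) / roi_count


def region_summary(
    measurements: Iterable[SectionMeasurement] | Sequence[float],
    region: str = "",
) -> RegionFractionSummary:
    """Aggregate per-section fractions into a regional mean.

    Accepts either :class:`SectionMeasurement` objects or bare fractions
    (any consistent scale — proportions or percent). The mean is the plain
    arithmetic mean; reports round to 3 decimals on the percent scale.
    """
    items = list(measurements)
    if not items:
        raise ValueError("no section measurements supplied")
    if isinstance(items[0], SectionMeasurement):
        fractions = tuple(m.vf for m in items)
        region = region or items[0].region
    else:
        fractions = tuple(float(v) for v in items)
    return RegionFractionSummary(
        region=region,
        fractions=fractions,
        mean_vf=float(np.mean(fractions)),
    )


def masson_collagen_mask(
    rgb: np.ndarray,
    hue_range: tuple[float, float] = (0.5, 0.75),
    min_saturation: float = 0.15,
) -> np.ndarray:
    """Heuristic blue-hue threshold for Masson-stained RGB images.

    A convenience only: selects pixels whose HSV hue falls in ``hue_range``
    (default: the blue band, where Masson renders collagen) with saturation
    above ``min_saturation``. Real analyses should curate the segmentation
    interactively; this recipe has no validated thresholds.
    """
    from skimage.color import rgb2hsv

    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got {rgb.shape}")
    hsv = rgb2hsv(rgb)
    lo, hi = hue_range
    return (hsv[..., 0] >= lo) & (hsv[..., 0] <= hi) & (hsv[..., 1] >= min_saturation)
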