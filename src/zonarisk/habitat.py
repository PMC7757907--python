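"""Habitat-suitability overlay: normalization, merging, classification.

Climatic suitability (a model's logistic output) and host availability
(harvested area in hectares) are each min–max normalized to [0, 1] and
averaged with equal weight into the overall habitat suitability

    S = (n(cs) + n(h)) / 2,

which stays in [0, 1]. Suitability maps are reclassified into four classes
using the conventional breakpoints 0.15 / 0.30 / 0.60 (not suitable, low,
medium, high).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .raster import RasterGrid

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassScheme:
    """Ordered class breaks over [0, 1] and their labels.

    The printed class bounds ("<= 0.15", "0.16-0.30", "0.31-0.60",
    ">= 0.61") leave gaps between the rounded edges; the scheme closes them
    with half-open intervals (-inf, b1], (b1, b2], (b2, b3], (b3, 1] so
    every value receives exactly one class.
    """

    breaks: tuple[float, ...] = (0.15, 0.30, 0.60)
    labels: tuple[str, ...] = ("not suitable", "low", "medium", "high")

    def __post_init__(self) -> None:
        b = np.asarray(self.breaks, dtype=float)
        if not np.all(np.diff(b) > 0):
            raise ValueError(f"breaks must be strictly increasing, got {self.breaks}")
        if np.any(b <= 0) or np.any(b >= 1):
            raise ValueError(f"breaks must lie inside (0, 1), got {self.breaks}")
        if len(self.labels) != len(self.breaks) + 1:
            raise ValueError("need one more label than breaks")

    def legend(self) -> dict[int, str]:
        return {k + 1: lab for k, lab in enumerate(self.labels)}


def normalize(
    raster: RasterGrid,
    min_override: float | None = None,
    max_override: float | None = None,
) -> RasterGrid:
    """Min–max rescale valid cells to [0, 1]: n = (x - min) / (max - min).

    Extrema default to the raster's own valid-cell min/max; overrides allow
    dataset-wide extrema (e.g. a global host-area maximum) so that tiles of
    a larger dataset normalize consistently. A degenerate range
    (max == min) yields all zeros with a warning.
    """
    vals = raster.valid_values()
    if vals.size == 0:
        raise ValueError("raster has no valid cells to normalize")
    lo = float(vals.min()) if min_override is None else float(min_override)
    hi = float(vals.max()) if max_override is None else float(max_override)
    if hi <= lo:
        warnings.warn(f"degenerate normalization range [{lo}, {hi}]; output set to 0")
        return raster.with_values(np.zeros_like(raster.values), units="normalized")
    scaled = np.clip((raster.values - lo) / (hi - lo), 0.0, 1.0)
    return raster.with_values(scaled, units="normalized")


def overall_suitability(cs: RasterGrid, h: RasterGrid) -> RasterGrid:
    """Equal-weight mean of normalized climatic suitability and host availability.

    Inputs must be co-registered and already normalized to [0, 1]; the
    output is nodata wherever either input is nodata.
    """
    if not cs.same_grid(h):
        raise ValueError(
            "climatic-suitability and host rasters are not co-registered; "
            "resample them to a common grid first"
        )
    for name, r in (("climatic suitability", cs), ("host availability", h)):
        v = r.valid_values()
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError(f"{name} raster is not normalized to [0, 1]")
    s = (cs.values + h.values) / 2.0
    mask = cs.mask | h.mask
    return RasterGrid(values=np.where(mask, np.nan, s), transform=cs.transform,
                      mask=mask, units="suitability")


def classify(surface: RasterGrid, scheme: ClassScheme = ClassScheme()) -> RasterGrid:
    """Reclassify a [0, 1] suitability surface into integer classes 1..k.

    Class c iff breaks[c-2] < v <= breaks[c-1] (half-open upward), class 1
    below the first break, top class above the last. Nodata cells get 0.
    """
    vals = surface.valid_values()
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError(
            f"values outside [0, 1] (range {vals.min():.4g}..{vals.max():.4g}); "
            "classify expects a normalized suitability surface"
        )
    # searchsorted with side='left': v <= break stays below it
    classes = np.searchsorted(np.asarray(scheme.breaks), surface.values, side="left") + 1
    classes = np.where(surface.mask, 0, classes).astype(np.uint8)
    out = RasterGrid(values=classes.astype(float), transform=surface.transform,
                     mask=surface.mask.copy(), units="class")
    return out


def class_counts(classified: RasterGrid, scheme: ClassScheme = ClassScheme()) -> dict[str, int]:
    """Cell counts per class label (valid cells only)."""
    vals = classified.valid_values().astype(int)
    return {lab: int((vals == k).sum()) for k, lab in scheme.legend().items()}
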