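"""Gaussian-kernel model of short-distance natural spread.

The pest is assumed to diffuse isotropically from each known occurrence,
with colonization likelihood decaying with great-circle distance x (km)
from the nearest source following a Gaussian profile

    kernel(x) = c1 * exp(-c2 * x^2).

The constants come from the species' maximum recorded natural dispersal
distance D_max, read as the 3-sigma point of a normal displacement
distribution: sigma = D_max / 3, c1 = 1 / (sigma * sqrt(2*pi)) (the normal
pdf height at the mean) and c2 = 1 / (2 * sigma^2). For the peach fruit
fly, D_max = 40.2 km (25 miles) gives sigma = 13.4 km, and — at the
precision conventionally printed — c1 = 0.03 and c2 = 0.003.

The dispersal likelihood weights the kernel by local habitat quality:

    l = [(k1 * n(cs) + k2 * n(h)) / (k1 + k2)] * c1 * exp(-c2 * x^2),

with n(cs), n(h) the normalized climatic suitability and host availability
and k1 = k2 = 0.5 by default (equal weights), so 0 <= l <= c1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .occurrences import OccurrenceSet, haversine_km
from .raster import RasterGrid

logger = logging.getLogger(__name__)

KM_PER_MILE = 1.609344


def miles_to_km(miles: float, decimals: int | None = 1) -> float:
    """Statute miles to kilometres, rounded to the conventional precision."""
    km = miles * KM_PER_MILE
    return km if decimals is None else round(km, decimals)


@dataclass(frozen=True)
class DispersalParams:
    """Kernel constants and habitat weights for the spread model."""

    d_max: float = 40.2  # km, maximum natural dispersal distance (3 sigma)
    mu: float = 0.0  # km, displacement mean
    sigma: float = 13.4  # km
    c1: float = 0.03  # kernel height
    c2: float = 0.003  # per km^2 decay
    k1: float = 0.5
    k2: float = 0.5
    paper_rounding: bool = True

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("sigma, c1 and c2 must be positive")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be positive")
        if self.mu != 0.0:
            raise ValueError("the displacement mean is fixed at 0")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path


def derive_params(
    d_max: float = 40.2,
    k1: float = 0.5,
    k2: float = 0.5,
    paper_rounding: bool = True,
    unit_height: bool = False,
) -> DispersalParams:
    """Derive kernel constants from the maximum dispersal distance.

    ``d_max`` is taken as 3 sigma of the displacement distribution, so
    sigma = d_max / 3, c2 = 1 / (2 sigma^2), c1 = 1 / (sigma sqrt(2 pi)).
    With ``paper_rounding`` (default) c1 and c2 are rounded to the
    conventionally printed 2 and 3 decimals (0.03 and 0.003 for
    d_max = 40.2 km). ``unit_height`` forces c1 = 1, turning the kernel
    into a pure decay profile with peak 1.
    """
    if d_max <= 0:
        raise ValueError(f"d_max must be positive, got {d_max}")
    sigma = d_max / 3.0
    c1 = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    c2 = 1.0 / (2.0 * sigma * sigma)
    if paper_rounding:
        c1 = round(c1, 2)
        c2 = round(c2, 3)
    if unit_height:
        c1 = 1.0
    return DispersalParams(d_max=d_max, sigma=sigma, c1=c1, c2=c2,
                           k1=k1, k2=k2, paper_rounding=paper_rounding)


def gaussian_kernel(x, params: DispersalParams) -> np.ndarray:
    """Kernel value c1 * exp(-c2 * x^2) at distance(s) x in km."""
    x = np.asarray(x, dtype=float)
    return params.c1 * np.exp(-params.c2 * x * x)


def distance_to_nearest_source(grid: RasterGrid, sources: OccurrenceSet) -> RasterGrid:
    """Great-circle distance (km) from every cell center to the nearest source."""
    if len(sources) == 0:
        raise ValueError("source set is empty")
    lon_g, lat_g = grid.transform.center_grids()
    lon_g = lon_g.ravel()
    lat_g = lat_g.ravel()
    lon_s, lat_s = sources.lon, sources.lat
    # chunk over sources to bound memory on big grids
    d_min = np.full(lon_g.size, np.inf)
    chunk = max(1, int(5e6 // max(lon_g.size, 1)) or 1)
    for start in range(0, lon_s.size, chunk):
        sl = slice(start, start + chunk)
        d = haversine_km(lon_g[:, None], lat_g[:, None], lon_s[None, sl], lat_s[None, sl])
        d_min = np.minimum(d_min, d.min(axis=1))
    vals = d_min.reshape(grid.transform.shape)
    return RasterGrid(values=vals, transform=grid.transform, mask=grid.mask.copy(), units="km")


def dispersal_likelihood(
    cs_norm: RasterGrid,
    h_norm: RasterGrid,
    sources: OccurrenceSet,
    params: DispersalParams,
    distance: RasterGrid | None = None,
) -> RasterGrid:
    """Per-cell dispersal likelihood l = habitat term x Gaussian kernel.

    The habitat term is (k1 n(cs) + k2 n(h)) / (k1 + k2); the kernel is
    evaluated at the distance to the *nearest* source, which — the kernel
    being monotone decreasing — equals the maximum over per-source kernels.
    """
    if not cs_norm.same_grid(h_norm):
        raise ValueError("cs and host rasters are not co-registered")
    for name, r in (("n(cs)", cs_norm), ("n(h)", h_norm)):
        v = r.valid_values()
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError(f"{name} must be normalized to [0, 1]")
    if distance is None:
        distance = distance_to_nearest_source(cs_norm, sources)
    habitat = (params.k1 * cs_norm.values + params.k2 * h_norm.values) / (params.k1 + params.k2)
    lik = habitat * gaussian_kernel(distance.values, params)
    mask = cs_norm.mask | h_norm.mask
    return RasterGrid(values=np.where(mask, np.nan, lik), transform=cs_norm.transform,
                      mask=mask, units="likelihood")


def run_generations(
    cs_norm: RasterGrid,
    h_norm: RasterGrid,
    sources: OccurrenceSet,
    params: DispersalParams,
    n_gen: int = 1,
    reseed_threshold: float | None = None,
) -> list[RasterGrid]:
    """Iterate the spread model over generations.

    Generation 1 is :func:`dispersal_likelihood` from the original sources
    (the standard single-generation run, roughly one 46-day generation).
    For ``n_gen > 1`` — an optional extension, off by default — cells whose
    likelihood reaches ``reseed_threshold`` become additional sources for
    the next generation, so the reachable front can only grow.
    """
    if n_gen < 1:
        raise ValueError("n_gen must be >= 1")
    if n_gen > 1 and reseed_threshold is None:
        raise ValueError("multi-generation runs need a reseed_threshold")
    import pandas as pd

    from .occurrences import FilterStep

    results: list[RasterGrid] = []
    current = sources
    for gen in range(1, n_gen + 1):
        lik = dispersal_likelihood(cs_norm, h_norm, current, params)
        results.append(lik)
        if gen == n_gen:
            break
        hot = lik.valid & (lik.values >= reseed_threshold)
        rows, cols = np.nonzero(hot)
        if rows.size == 0:
            logger.info("generation %d: no cells reach the reseed threshold", gen)
            current = current  # unchanged; later generations equal this one
            continue
        lon, lat = lik.transform.cell_center(rows, cols)
        extra = pd.DataFrame({
            "id": [f"gen{gen}_{k}" for k in range(rows.size)],
            "lon": lon, "lat": lat,
            "status": "invaded", "source": f"reseeded_generation_{gen}",
        })
        merged = pd.concat([current.records, extra], ignore_index=True)
        merged = merged.drop_duplicates(subset=["lon", "lat"], keep="first")
        current = OccurrenceSet(
            records=merged.reset_index(drop=True),
            provenance=[*current.provenance,
                        FilterStep(step=f"reseed_gen{gen}", n_in=len(current), n_kept=len(merged))],
        )
    return results
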