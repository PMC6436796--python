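"""Thresholding and expert-feedback post-processing.

Continuous suitability is turned into a binary range map with the
*p-th percentile training presence* rule: the threshold is the largest
suitability value that leaves at most p% of the training presences
strictly below it (p = 0 is the minimum training presence).  Reviewers
pick p with a slider anywhere in [0, 30]; ties at the threshold value
count as predicted present, so the training omission bound always holds
and binaries at increasing p are nested.

Expert edits are applied to the binary in a fixed order: over-prediction
polygons zero cells, under-prediction polygons set cells to one, and the
habitat mask (allowed land-cover classes) vetoes last — an ecological
constraint that trumps hand-drawn presence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .geo_core import Grid, Raster, rasterize_geometry

__all__ = [
    "ExpertFeedback",
    "ExpertMapSpec",
    "percentile_threshold_value",
    "threshold_at_percentile",
    "apply_feedback",
    "build_expert_map",
]


@dataclass
class ExpertFeedback:
    """One reviewer's corrections to a thresholded model."""

    omission_percent: float = 0.0
    over_polygons: list = field(default_factory=list)
    under_polygons: list = field(default_factory=list)
    habitat_classes: set | None = None
    reviewer: str = "anonymous"

    def __post_init__(self) -> None:
        if not (0.0 <= self.omission_percent <= 30.0):
            raise ValueError("omission_percent must lie in [0, 30]")
        for g in list(self.over_polygons) + list(self.under_polygons):
            if g.is_empty or not g.is_valid:
                raise ValueError("feedback polygons must be valid and non-empty")


@dataclass
class ExpertMapSpec:
    """A hand-drawn range hypothesis for species too data-poor to model."""

    range_polygon: object
    elevation_range: tuple[float, float] | None = None
    barrier_polygons: list = field(default_factory=list)
    habitat_classes: set | None = None

    def __post_init__(self) -> None:
        if self.range_polygon.is_empty or not self.range_polygon.is_valid:
            raise ValueError("range polygon must be valid and non-empty")
        if self.elevation_range is not None:
            lo, hi = self.elevation_range
            if lo > hi:
                raise ValueError("elevation_range minimum exceeds maximum")


def percentile_threshold_value(training_values, p: float) -> float:
    """The p-th percentile training presence threshold of a score vector.

    With n training values sorted ascending and k = floor(n·p/100), the
    threshold is the (k+1)-th smallest value: the largest score for which
    the count of presences strictly below stays ≤ k, hence training
    omission ≤ p%.
    """
    v = np.asarray(training_values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no training presence values")
    if not (0.0 <= p <= 100.0):
        raise ValueError("percentile must lie in [0, 100]")
    k = math.floor(v.size * p / 100.0)
    k = min(k, v.size - 1)
    return float(np.sort(v)[k])


def threshold_at_percentile(suitability: Raster, presence_xy,
                            p: float) -> tuple[Raster, float]:
    """Binary range map at the p-th percentile training presence.

    Returns (binary raster, threshold value).  Cells with suitability ≥
    threshold are 1; nodata cells are 0.
    """
    presence_xy = np.asarray(presence_xy, dtype=float)
    vals = suitability.sample(presence_xy[:, 0], presence_xy[:, 1])
    if np.isnan(vals).any():
        raise ValueError("some training presences fall outside valid cells")
    t = percentile_threshold_value(vals, p)
    data = suitability.data
    mask = np.where(np.isnan(data), False, data >= t)
    return Raster(suitability.grid, mask.astype(np.uint8), nodata=None), t


def apply_feedback(binary: Raster, feedback: ExpertFeedback,
                   landcover: Raster | None = None) -> Raster:
    """Apply reviewer corrections to a binary map (over → under → habitat).

    Over-prediction polygons clear cells, under-prediction polygons set
    them, and finally cells whose land-cover class is not in
    ``habitat_classes`` are cleared.  Idempotent for fixed feedback.
    """
    grid = binary.grid
    data = binary.data.astype(np.uint8).copy()
    for geom in feedback.over_polygons:
        m = rasterize_geometry(geom, grid)
        if not m.any():
            warnings.warn("over-prediction polygon outside raster extent; "
                          "no effect", stacklevel=2)
        data[m] = 0
    for geom in feedback.under_polygons:
        m = rasterize_geometry(geom, grid)
        if not m.any():
            warnings.warn("under-prediction polygon outside raster extent; "
                          "no effect", stacklevel=2)
        data[m] = 1
    if feedback.habitat_classes is not None:
        if landcover is None:
            raise ValueError("habitat_classes given but no land-cover raster")
        if landcover.grid != grid:
            raise ValueError("land-cover raster not on the template grid")
        if not feedback.habitat_classes:
            raise ValueError("habitat class set is empty")
        keep = np.isin(landcover.data, list(feedback.habitat_classes))
        data[~keep] = 0
    return Raster(grid, data, nodata=None)


def build_expert_map(spec: ExpertMapSpec, grid: Grid,
                     dem: Raster | None = None,
                     landcover: Raster | None = None) -> Raster:
    """Rasterize an expert range hypothesis onto the template grid.

    The range polygon is rasterized, barrier polygons are cut out, then
    the map is intersected with the requested elevation band (requires a
    DEM) and the allowed land-cover classes.
    """
    mask = rasterize_geometry(spec.range_polygon, grid)
    for geom in spec.barrier_polygons:
        mask &= ~rasterize_geometry(geom, grid)
    if spec.elevation_range is not None:
        if dem is None:
            raise ValueError("elevation_range requires a DEM raster")
        if dem.grid != grid:
            raise ValueError("DEM not on the template grid")
        lo, hi = spec.elevation_range
        dv = np.asarray(dem.data, dtype=float)
        mask &= (dv >= lo) & (dv <= hi) & dem.valid_mask
    if spec.habitat_classes is not None:
        if landcover is None:
            raise ValueError("habitat_classes requires a land-cover raster")
        if landcover.grid != grid:
            raise ValueError("land-cover raster not on the template grid")
        mask &= np.isin(landcover.data, list(spec.habitat_classes))
    return Raster(grid, mask.astype(np.uint8), nodata=None)
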