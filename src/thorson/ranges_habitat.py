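"""Species potential distributions from literature ranges and habitat masks.

A species' distribution is encoded as one or more lat/lon rectangles (its
literature range), a depth range, and a set of bottom-habitat classes.  The
potential distribution on the working grid is the conjunction of the three
filters; its area (km^2) is the sum of latitude-corrected pixel areas, a
proxy of the total potential habitat surface.  Range-mean environmental
values are plain means of each environmental layer over the distribution's
cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids_env import EnvGrid, pixel_area, water_column_mean


@dataclass(frozen=True)
class RangeSpec:
    """Geographic bounds, depth range and habitat classes of one species.

    ``rects`` is a sequence of (lat_min, lat_max, lon_min, lon_max)
    rectangles (multiple segments encode e.g. Atlantic-only boundaries);
    ``depth_range`` is inclusive (min, max) metres; ``habitat_classes`` is
    a frozenset of labels from the habitat map's legend (None = all).
    """

    rects: tuple
    depth_range: tuple = (0.0, np.inf)
    habitat_classes: frozenset | None = None

    def __post_init__(self) -> None:
        if not self.rects:
            raise ValueError("empty geographic bounds")
        for lat0, lat1, lon0, lon1 in self.rects:
            if lat0 > lat1 or lon0 > lon1:
                raise ValueError("malformed rectangle (min > max)")
        if self.depth_range[0] > self.depth_range[1]:
            raise ValueError("depth_range min > max")


@dataclass
class HabitatMap:
    """Categorical bottom-type raster with its legend."""

    classes: np.ndarray  # integer codes indexing into legend, -1 = missing
    legend: tuple

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        codes = self.classes[self.classes >= 0]
        if codes.size and codes.max() >= len(self.legend):
            raise ValueError("habitat cell code outside legend")

    def mask_for(self, labels) -> np.ndarray:
        unknown = set(labels) - set(self.legend)
        if unknown:
            raise ValueError(
                f"habitat classes {sorted(unknown)} not in legend; "
                f"valid labels: {sorted(self.legend)}"
            )
        wanted = np.array([self.legend.index(lab) for lab in labels])
        return np.isin(self.classes, wanted)


@dataclass
class PotentialDistribution:
    """Boolean occupancy mask on the working grid, with its area in km^2."""

    mask: np.ndarray
    area: float


def rasterize_range(spec: RangeSpec, grid: EnvGrid, species: str = "?") -> np.ndarray:
    """Boolean mask: cell centre inside any of the range's rectangles."""
    lat2, lon2 = np.meshgrid(grid.lats, grid.lons, indexing="ij")
    mask = np.zeros(grid.shape, dtype=bool)
    for lat0, lat1, lon0, lon1 in spec.rects:
        mask |= (lat2 >= lat0) & (lat2 <= lat1) & (lon2 >= lon0) & (lon2 <= lon1)
    if not mask.any():
        raise ValueError(f"range of species {species!r} does not intersect the grid")
    return mask


def potential_habitat(mask: np.ndarray, grid: EnvGrid,
                      depth_range=(0.0, np.inf),
                      habitat_map: HabitatMap | None = None,
                      habitat_classes=None) -> PotentialDistribution:
    """Filter a range mask by depth (inclusive) and bottom-habitat classes.

    Area is the sum of latitude-corrected pixel areas over the surviving
    cells; an all-filtered distribution yields area 0 with a warning.
    """
    lo, hi = depth_range
    out = mask & np.isfinite(grid.depth) & (grid.depth >= lo) & (grid.depth <= hi)
    if habitat_map is not None and habitat_classes is not None:
        out = out & habitat_map.mask_for(habitat_classes)
    if not out.any():
        warnings.warn("no cells pass the depth/habitat filters; empty distribution",
                      stacklevel=2)
        return PotentialDistribution(mask=out, area=0.0)
    lat2 = np.meshgrid(grid.lats, grid.lons, indexing="ij")[0]
    area = float(np.sum(pixel_area(lat2[out], grid.resolution)))
    return PotentialDistribution(mask=out, area=area)


def species_env_means(dist: PotentialDistribution, layers: dict,
                      depth_range=None, stacks: dict | None = None,
                      stack_depths=None) -> dict:
    """Mean of each environmental layer over the distribution's cells.

    ``layers`` maps variable name to a 2-D field co-registered with the
    mask.  Optionally, ``stacks`` maps variable name to a 3-D (depth, lat,
    lon) field; those variables are first averaged over the depth levels
    inside ``depth_range`` per cell, then over cells — the taxon-specific
    depth-restricted average used for T, U and DS.
    """
    if not dist.mask.any():
        raise ValueError("empty distribution: no cells to average")
    out = {}
    for name, layer in layers.items():
        layer = np.asarray(layer, dtype=float)
        out[name] = float(np.nanmean(layer[dist.mask]))
    if stacks:
        if depth_range is None or stack_depths is None:
            raise ValueError("depth-resolved stacks need depth_range and stack_depths")
        for name, stack in stacks.items():
            stack = np.asarray(stack, dtype=float)
            profile = stack[:, dist.mask]  # (n_depth, n_cells)
            out[name] = water_column_mean(profile, stack_depths, depth_range)
    return out
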