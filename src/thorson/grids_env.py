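"""Hydrographic scalar fields from gridded current/temperature series.

Three per-pixel summaries drive everything downstream:

* ``T`` — mean water-column temperature (degC), averaged over all depth
  levels and time steps within a pixel.
* ``U`` — mean current magnitude (m/s): the magnitude ``sqrt(u^2 + v^2)``
  is taken per sample first, then averaged.
* ``DS`` — dynamic stratification (m/s): the vector combination of the
  standard deviations of the zonal and meridional components,
  ``sqrt(sd(u)^2 + sd(v)^2)``, over the pixel's whole depth/time stack.
  Unlike ``sd(|velocity|)`` it is sensitive to directional variability.

Grids are cell-centre registered on regular lat/lon axes with half-open
cells ``[lon, lon+res) x [lat, lat+res)``.  Bathymetry is positive-down
metres; ingest of negative-down sources should negate on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KM_PER_DEGREE = 111.32


@dataclass(frozen=True)
class VelocitySample:
    """One (u, v) current sample at a depth level and time."""

    u: float
    v: float
    depth: float = 0.0
    time: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.u) and np.isfinite(self.v)):
            raise ValueError(f"non-finite velocity sample: u={self.u}, v={self.v}")
        if self.depth < 0:
            raise ValueError(f"negative depth {self.depth} (positive-down convention)")


@dataclass
class EnvGrid:
    """Co-registered rasters of depth, T, U and DS on a regular lat/lon grid.

    All layers are 2-D arrays of shape ``(n_lat, n_lon)`` sharing the
    cell-centre axes ``lats`` and ``lons`` (degrees, regular spacing).
    """

    lats: np.ndarray
    lons: np.ndarray
    depth: np.ndarray
    T: np.ndarray
    U: np.ndarray
    DS: np.ndarray
    resolution: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        shape = (self.lats.size, self.lons.size)
        for name in ("depth", "T", "U", "DS"):
            layer = np.asarray(getattr(self, name), dtype=float)
            if layer.shape != shape:
                raise ValueError(
                    f"layer {name!r} has shape {layer.shape}, expected {shape}"
                )
            setattr(self, name, layer)
        if self.resolution == 0.0 and self.lats.size > 1:
            self.resolution = float(abs(self.lats[1] - self.lats[0]))
        ocean = np.isfinite(self.depth)
        if np.any(self.depth[ocean] < 0):
            raise ValueError("negative bathymetry in ocean cells (positive-down)")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lats.size, self.lons.size)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format export: one row per cell with lon, lat and all layers."""
        lon2, lat2 = np.meshgrid(self.lons, self.lats)
        return pd.DataFrame(
            {
                "lon": lon2.ravel(),
                "lat": lat2.ravel(),
                "depth": self.depth.ravel(),
                "T": self.T.ravel(),
                "U": self.U.ravel(),
                "DS": self.DS.ravel(),
            }
        )


def current_magnitude(u, v):
    """Speed of a current sample: the vector sum ``sqrt(u^2 + v^2)``.

    Accepts scalars or arrays; raises on any non-finite input, naming the
    offending sample.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    bad = ~(np.isfinite(u) & np.isfinite(v))
    if np.any(bad):
        idx = int(np.flatnonzero(np.atleast_1d(bad))[0])
        raise ValueError(
            f"non-finite velocity at sample {idx}: "
            f"u={np.atleast_1d(u).ravel()[idx]}, v={np.atleast_1d(v).ravel()[idx]}"
        )
    out = np.hypot(u, v)
    return float(out) if out.ndim == 0 else out


def dynamic_stratification(samples) -> float:
    """DS = sqrt(sd(u)^2 + sd(v)^2) over a pixel's depth/time stack.

    ``samples`` is a sequence of :class:`VelocitySample` or a pair of
    array-likes ``(u, v)``.  Sample (n-1 denominator) standard deviations.
    DS is invariant to adding a constant vector to every sample.
    """
    if isinstance(samples, tuple) and len(samples) == 2:
        u = np.asarray(samples[0], dtype=float)
        v = np.asarray(samples[1], dtype=float)
    else:
        samples = list(samples)
        u = np.array([s.u for s in samples], dtype=float)
        v = np.array([s.v for s in samples], dtype=float)
    if u.size < 2:
        raise ValueError(f"dynamic stratification needs >= 2 samples, got {u.size}")
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise ValueError("non-finite velocity in sample stack")
    return float(np.hypot(np.std(u, ddof=1), np.std(v, ddof=1)))


def water_column_mean(values, depths, depth_range) -> float:
    """Unweighted mean over all (depth, time) entries within ``depth_range``.

    Parameters
    ----------
    values : array, shape (n_depth, ...) — scalar per depth level (and
        optionally time along trailing axes); NaN marks missing.
    depths : level depths (m, positive down), length n_depth.
    depth_range : inclusive (min, max) in metres.

    Depth levels are unweighted even when unevenly spaced (``depth_weighting
    = "none"``); a thickness-weighted variant is intentionally not the
    default.
    """
    values = np.asarray(values, dtype=float)
    depths = np.asarray(depths, dtype=float)
    lo, hi = depth_range
    sel = (depths >= lo) & (depths <= hi)
    if not np.any(sel):
        raise ValueError(
            f"no depth levels in range [{lo}, {hi}] m (levels: {depths.tolist()})"
        )
    subset = values[sel]
    if np.all(np.isnan(subset)):
        raise ValueError(f"all values missing within depth range [{lo}, {hi}] m")
    return float(np.nanmean(subset))


def pixel_area(lat, resolution: float):
    """Area (km^2) of a square lat/lon cell of side ``resolution`` degrees.

    Equirectangular approximation: ``(res * 111.32 km)^2 * cos(lat)``.
    """
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90):
        raise ValueError("latitude outside [-90, 90]")
    area = (resolution * KM_PER_DEGREE) ** 2 * np.cos(np.radians(lat))
    return float(area) if area.ndim == 0 else area
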