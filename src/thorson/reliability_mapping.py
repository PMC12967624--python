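"""Developmental-mode proportion maps and their statistical reliability.

This is the analytical heart of the pipeline.  Per-species occupancy masks
are stacked into per-pixel species richness and developmental-mode
proportions.  Latitudinal structure is then summarised over 5-degree bands
with three methodologies of increasing reliability:

``pooled``
    one proportion per band from the set of species present anywhere in it;
``pixel_mean``
    mean (+/- sd) of per-pixel proportions over all occupied pixels;
``filtered``
    pixel_mean restricted to pixels that are both statistically reliable
    (modelled richness >= N_min) and well surveyed (relative Chao1 < 1.2
    in an independent occurrence database).

N_min is the normal-approximation sample size needed to detect an absolute
deviation ``deltaP`` from a reference proportion P with given power and
two-sided significance:

    N_min = ceil( ((z_{1-alpha/2} + z_{power}) / deltaP)^2 * P (1 - P) )

Survey completeness per 0.5-degree occurrence pixel uses the Chao1 richness
estimator, Chao1 = S_obs + f1^2 / (2 f2) (f1 singletons, f2 doubletons;
fallback f1(f1-1)/2 when f2 = 0); the relative index Chao1/S_obs below 1.2
marks a pixel as well surveyed.  A permutation test checks whether a pixel's
observed non-pelagic proportion deviates from the species-pool reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MODES = ("non_pelagic", "planktotrophic", "lecithotrophic")


@dataclass
class ProportionMap:
    """Per-pixel richness and developmental-mode proportions."""

    richness: np.ndarray
    prop_np: np.ndarray
    prop_pt: np.ndarray
    prop_lc: np.ndarray
    lats: np.ndarray | None = None
    lons: np.ndarray | None = None

    def proportion(self, mode: str) -> np.ndarray:
        return {"non_pelagic": self.prop_np, "planktotrophic": self.prop_pt,
                "lecithotrophic": self.prop_lc}[mode]


@dataclass
class ReliabilityMask:
    """Per-pixel survey-completeness and minimum-richness flags."""

    chao1: np.ndarray
    rel_chao: np.ndarray
    passes_survey: np.ndarray
    passes_nmin: np.ndarray

    @property
    def passes(self) -> np.ndarray:
        return self.passes_survey & self.passes_nmin


class OccurrenceTable:
    """Occurrence records binned into 0.5-degree pixels.

    Holds per-pixel observed richness ``S_obs`` and the singleton/doubleton
    frequencies ``f1``/``f2`` on the same (lat, lon) grid as the proportion
    maps.  Build either from individual records (species, lat, lon) or from
    a per-pixel-per-species count array.
    """

    def __init__(self, counts: np.ndarray, lats: np.ndarray, lons: np.ndarray):
        # counts: (n_species, n_lat, n_lon) detection counts
        counts = np.asarray(counts)
        if np.any(counts < 0):
            raise ValueError("negative detection counts")
        self.counts = counts
        self.lats = np.asarray(lats, dtype=float)
        self.lons = np.asarray(lons, dtype=float)
        self.S_obs = (counts > 0).sum(axis=0)
        self.f1 = (counts == 1).sum(axis=0)
        self.f2 = (counts == 2).sum(axis=0)

    @classmethod
    def from_records(cls, records: pd.DataFrame, lats: np.ndarray,
                     lons: np.ndarray, resolution: float = 0.5) -> "OccurrenceTable":
        """Bin (species, lat, lon) records onto the cell-centred grid.

        Accepts GBIF Darwin-Core column names (``decimalLatitude`` /
        ``decimalLongitude``) as synonyms of ``lat`` / ``lon``.
        """
        df = records.rename(columns={"decimalLatitude": "lat",
                                     "decimalLongitude": "lon"})
        lats = np.asarray(lats, dtype=float)
        lons = np.asarray(lons, dtype=float)
        species = sorted(df["species"].unique())
        sp_index = {s: k for k, s in enumerate(species)}
        counts = np.zeros((len(species), lats.size, lons.size), dtype=int)
        half = resolution / 2.0
        i = np.searchsorted(lats + half, df["lat"].to_numpy(), side="right")
        j = np.searchsorted(lons + half, df["lon"].to_numpy(), side="right")
        k = df["species"].map(sp_index).to_numpy()
        ok = (i >= 0) & (i < lats.size) & (j >= 0) & (j < lons.size)
        np.add.at(counts, (k[ok], i[ok], j[ok]), 1)
        return cls(counts, lats, lons)


def stack_proportions(dists, modes, lats=None, lons=None) -> ProportionMap:
    """Stack per-species occupancy masks into richness and mode proportions.

    ``dists`` is a sequence of boolean masks (or objects with a ``.mask``),
    ``modes`` the matching developmental-mode labels.  Proportions are NaN
    where richness is zero.
    """
    masks = [getattr(d, "mask", d) for d in dists]
    if len(masks) != len(modes):
        raise ValueError("dists and modes must have equal length")
    for k, mode in enumerate(modes):
        if mode not in MODES:
            raise ValueError(f"species {k} has unknown mode {mode!r}")
    stack = np.asarray(masks)
    richness = stack.sum(axis=0)
    modes = np.asarray(modes)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = {}
        for mode in MODES:
            count = stack[modes == mode].sum(axis=0)
            props[mode] = np.where(richness > 0, count / richness, np.nan)
    return ProportionMap(richness=richness, prop_np=props["non_pelagic"],
                         prop_pt=props["planktotrophic"],
                         prop_lc=props["lecithotrophic"],
                         lats=lats, lons=lons)


def reference_proportion(modes, mode: str = "non_pelagic") -> float:
    """Share of the species pool with the given developmental mode."""
    modes = np.asarray(modes)
    if modes.size == 0:
        raise ValueError("empty species pool")
    return float(np.mean(modes == mode))


def n_min(P: float, deltaP: float, alpha: float = 0.05,
          power: float = 0.8) -> int:
    """Minimum species count for a reliable pixel proportion.

    ceil( ((z_{1-alpha/2} + z_{power}) / deltaP)^2 * P(1-P) ); ``deltaP``
    is the absolute detectable deviation.  P of exactly 0 or 1 has zero
    binomial variance and returns 0.
    """
    if deltaP <= 0:
        raise ValueError("deltaP must be positive")
    if not (0 <= P <= 1):
        raise ValueError("P must lie in [0, 1]")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if P in (0.0, 1.0):
        return 0
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    return int(math.ceil((z / deltaP) ** 2 * P * (1 - P)))


def chao1(S_obs, f1, f2):
    """Chao1 expected richness from singleton/doubleton frequencies.

    S_obs + f1^2/(2 f2); when f2 = 0 the classic fallback
    S_obs + f1(f1-1)/2.  Always >= S_obs, with equality iff f1 = 0.
    """
    S_obs = np.asarray(S_obs, dtype=float)
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    if np.any(S_obs < 0) or np.any(f1 < 0) or np.any(f2 < 0):
        raise ValueError("negative counts")
    if np.any(f1 + f2 > S_obs):
        raise ValueError("f1 + f2 exceeds S_obs")
    with np.errstate(divide="ignore", invalid="ignore"):
        est = np.where(f2 > 0, S_obs + f1**2 / (2 * f2),
                       S_obs + f1 * (f1 - 1) / 2.0)
    return float(est) if est.ndim == 0 else est


def chao1_bias_corrected(S_obs, f1, f2):
    """Bias-corrected variant: S_obs + f1(f1-1) / (2 (f2+1))."""
    S_obs = np.asarray(S_obs, dtype=float)
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    est = S_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return float(est) if est.ndim == 0 else est


def reliability_mask(occ: OccurrenceTable, richness: np.ndarray, nmin: int,
                     rel_chao_threshold: float = 1.2) -> ReliabilityMask:
    """Flag pixels as reliable: well surveyed and richness >= N_min.

    A pixel passes the survey test iff its relative Chao1 (Chao1/S_obs) is
    below the threshold; pixels with no occurrence records fail it.  The
    richness map must be co-registered with the occurrence grid.
    """
    if richness.shape != occ.S_obs.shape:
        raise ValueError("richness map not co-registered with occurrence grid")
    est = chao1(occ.S_obs, occ.f1, occ.f2)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(occ.S_obs > 0, est / occ.S_obs, np.inf)
    passes_survey = rel < rel_chao_threshold
    passes_nmin = richness >= nmin
    return ReliabilityMask(chao1=est, rel_chao=rel,
                           passes_survey=passes_survey,
                           passes_nmin=passes_nmin)


def latitude_bands(lat_min: float = 25.0, lat_max: float = 70.0,
                   width: float = 5.0):
    """[(lo, hi), ...] 5-degree latitudinal bands spanning the study area."""
    edges = np.arange(lat_min, lat_max + width / 2, width)
    return [(float(lo), float(hi)) for lo, hi in zip(edges[:-1], edges[1:])]


def band_summary(props: ProportionMap, method: str,
                 dists=None, modes=None, mask: ReliabilityMask | None = None,
                 bands=None) -> pd.DataFrame:
    """Per-band developmental-mode proportions by one of three methods.

    ``pooled`` needs the per-species masks and modes; ``filtered`` needs a
    :class:`ReliabilityMask`.  Bands with no qualifying pixels (or species)
    are reported with NaN proportions rather than dropped.  Returns a tidy
    frame with columns band_lo, band_hi, mode, proportion, sd, n.
    """
    if props.lats is None:
        raise ValueError("ProportionMap lacks latitude axis")
    if bands is None:
        bands = latitude_bands()
    if method not in ("pooled", "pixel_mean", "filtered"):
        raise ValueError(f"unknown method {method!r}")
    if method == "pooled" and (dists is None or modes is None):
        raise ValueError("method 'pooled' needs per-species dists and modes")
    if method == "filtered" and mask is None:
        raise ValueError("method 'filtered' needs a ReliabilityMask")

    rows = []
    lats = props.lats
    for lo, hi in bands:
        in_band = (lats >= lo) & (lats < hi)
        if method == "pooled":
            modes_arr = np.asarray(modes)
            present = np.array([getattr(d, "mask", d)[in_band, :].any()
                                for d in dists])
            n_species = int(present.sum())
            for mode in MODES:
                prop = (float(np.mean(modes_arr[present] == mode))
                        if n_species else np.nan)
                rows.append((lo, hi, mode, prop, np.nan, n_species))
        else:
            occupied = props.richness[in_band, :] > 0
            if method == "filtered":
                occupied &= mask.passes[in_band, :]
            n_pix = int(occupied.sum())
            for mode in MODES:
                vals = props.proportion(mode)[in_band, :][occupied]
                if n_pix:
                    rows.append((lo, hi, mode, float(np.mean(vals)),
                                 float(np.std(vals, ddof=1)) if n_pix > 1 else 0.0,
                                 n_pix))
                else:
                    rows.append((lo, hi, mode, np.nan, np.nan, 0))
    return pd.DataFrame(rows, columns=["band_lo", "band_hi", "mode",
                                       "proportion", "sd", "n"])


def proportion_permutation_test(n_species_at_pixel: int, observed_prop: float,
                                species_pool_modes, n_perm: int = 100,
                                seed=None, mode: str = "non_pelagic") -> float:
    """Permutation p-value for a pixel proportion against the pool reference.

    Draws ``n_perm`` random species subsets of the pixel's size from the
    full pool without replacement; the two-sided p-value is the fraction of
    permuted proportions at least as far from the pool reference proportion
    as the observed one (ties count as extreme).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pool = np.asarray(species_pool_modes)
    n = int(n_species_at_pixel)
    if n > pool.size:
        raise ValueError("pixel richness exceeds pool size")
    if n < 1:
        raise ValueError("pixel must hold at least one species")
    rng = np.random.default_rng(seed)
    is_mode = (pool == mode).astype(float)
    ref = is_mode.mean()
    obs_dev = abs(observed_prop - ref)
    # vectorised draws without replacement: argsort of uniform keys
    keys = rng.random((n_perm, pool.size))
    idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
    perm_props = is_mode[idx].mean(axis=1)
    return float(np.mean(np.abs(perm_props - ref) >= obs_dev - 1e-12))
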