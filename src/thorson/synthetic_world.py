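"""Seeded generator of a complete synthetic study system.

Builds, from a single integer seed, every input the pipeline needs: a
gridded shelf/offshore bathymetry with temperature and AR(1) current
series (so the mean current U and dynamic stratification DS have known
expectations), monthly chlorophyll-a series with tunable seasonal
contingency, a species table with literature-style rectangular ranges,
metabolic-theory life histories and a planted logistic developmental-mode
model on depth and chlorophyll seasonality, plus effort-biased occurrence
records emulating an unevenly sampled biodiversity database.

The default world is engineered to reproduce the sampling-artefact
phenomenon at the heart of the study *without any planted latitudinal
gradient in developmental mode*: the mode model depends only on depth and
chlorophyll contingency (M_CHLA varies zonally, not with latitude), but

* a shallow species-rich shelf strip spans all latitudes,
* a vast deep offshore region is occupied only at high latitudes, by a
  handful of deep-ranged (hence mostly non-pelagic) species, and
* occurrence sampling effort declines exponentially poleward.

Averaged per-pixel proportions then rise poleward (the deep, species-poor,
unsurveyed north is dominated by non-pelagic developers), while the
reliability-filtered method — minimum species count N_min plus relative
Chao1 survey completeness — retains only trustworthy shelf pixels whose
proportions carry no trend.  All draws go through one
``numpy.random.default_rng`` stream per generator call, so regeneration
from (seed, params) is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .chla_seasonality import ChlaSeries, chla_stats, colwell
from .grids_env import EnvGrid, current_magnitude
from .life_history import (
    MetabolicParams,
    developmental_time,
    fecundity,
    embryo_mass,
    growth_ratios,
)
from .ranges_habitat import PotentialDistribution, RangeSpec, potential_habitat, \
    rasterize_range, species_env_means
from .reliability_mapping import OccurrenceTable

#: Planted developmental-mode model: logit P(pelagic) = b0 + b1*depth + b2*M_CHLA.
#: Shaped like the study's binomial mixed model (positive intercept, negative
#: depth and seasonality effects).
DEFAULT_MODE_MODEL = (5.0, -0.0047, -14.2)


@dataclass
class GroundTruth:
    """Everything planted into a synthetic world, for later verification."""

    seed: int
    mode_model: tuple
    reference_prop_np: float
    effort_scale: float
    effort_efolding_deg: float
    richness: np.ndarray
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "mode_model": list(self.mode_model),
            "reference_prop_np": self.reference_prop_np,
            "effort_scale": self.effort_scale,
            "effort_efolding_deg": self.effort_efolding_deg,
            "richness": np.asarray(self.richness).tolist(),
            "params": self.params,
        }
        return json.dumps(payload, indent=2)


def gen_env_grid(seed: int, shape: tuple = (90, 20),
                 lat_range: tuple = (25.0, 70.0), lon_range: tuple = (0.0, 10.0),
                 n_time: int = 40, shelf_cols: int = 4,
                 t_south: float = 22.0, t_north: float = 7.0,
                 current_mean: tuple = (0.03, 0.0),
                 current_sd: tuple = (0.05, 0.05), ar_phi: float = 0.6,
                 ) -> EnvGrid:
    """Synthetic bathymetry, temperature and AR(1)-current summary fields.

    The westernmost ``shelf_cols`` columns form a shallow shelf (~15-60 m)
    at every latitude; offshore cells deepen eastward to several hundred
    metres.  Temperature follows a linear poleward-cooling gradient plus
    smooth noise.  (u, v) series are stationary AR(1) processes with the
    requested means and standard deviations, so the DS field estimates
    ``hypot(sd_u, sd_v)`` and converges to it as ``n_time`` grows.
    """
    ny, nx = shape
    if ny < 10 or nx < 10:
        raise ValueError("grid must be at least 10 x 10")
    if not (0 <= ar_phi < 1):
        raise ValueError("AR(1) coefficient must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    res_lat = (lat_range[1] - lat_range[0]) / ny
    res_lon = (lon_range[1] - lon_range[0]) / nx
    lats = lat_range[0] + res_lat * (np.arange(ny) + 0.5)
    lons = lon_range[0] + res_lon * (np.arange(nx) + 0.5)

    smooth = ndimage.gaussian_filter(rng.standard_normal((ny, nx)), sigma=3)
    depth = np.empty((ny, nx))
    # cross-shelf ramp (~20 -> ~120 m) so shelf species differ in mean depth
    shelf_ramp = 15.0 + (np.arange(shelf_cols) + 0.5) * (110.0 / shelf_cols)
    depth[:, :shelf_cols] = shelf_ramp[None, :] + 8.0 * smooth[:, :shelf_cols]
    # continuous slope: ~160 m at the shelf break deepening to ~900 m east
    n_off = nx - shelf_cols
    slope_ramp = 160.0 + (np.arange(n_off) + 0.5) * (740.0 / n_off)
    depth[:, shelf_cols:] = slope_ramp[None, :] + 50.0 * smooth[:, shelf_cols:]
    depth = np.clip(depth, 10.0, None)

    frac = (lats - lat_range[0]) / (lat_range[1] - lat_range[0])
    T = (t_south + (t_north - t_south) * frac)[:, None] + \
        0.8 * ndimage.gaussian_filter(rng.standard_normal((ny, nx)), sigma=2)

    # stationary AR(1) series per pixel; innovations scaled to hold sd fixed
    mu_u, mu_v = current_mean
    sd_u, sd_v = current_sd
    eps_scale = np.sqrt(1 - ar_phi**2)
    u = np.empty((n_time, ny, nx))
    v = np.empty((n_time, ny, nx))
    u[0] = mu_u + sd_u * rng.standard_normal((ny, nx))
    v[0] = mu_v + sd_v * rng.standard_normal((ny, nx))
    for t in range(1, n_time):
        u[t] = mu_u + ar_phi * (u[t - 1] - mu_u) \
            + sd_u * eps_scale * rng.standard_normal((ny, nx))
        v[t] = mu_v + ar_phi * (v[t - 1] - mu_v) \
            + sd_v * eps_scale * rng.standard_normal((ny, nx))
    U = current_magnitude(u, v).mean(axis=0)
    if n_time >= 2 and (sd_u > 0 or sd_v > 0):
        DS = np.hypot(u.std(axis=0, ddof=1), v.std(axis=0, ddof=1))
    else:
        DS = np.zeros((ny, nx))
    return EnvGrid(lats=lats, lons=lons, depth=depth, T=T, U=U, DS=DS,
                   resolution=res_lat)


def gen_chla(seed: int, n_years: int = 19, seasonal_amplitude: float = 1.5,
             noise_sd: float = 0.35, baseline: float = 0.3) -> ChlaSeries:
    """One pixel's monthly chlorophyll series: sinusoid + lognormal noise.

    ``seasonal_amplitude`` sets the peak-to-trough seasonal cycle (mg/m^3)
    and hence the expected Colwell contingency; ``noise_sd`` is the log-
    scale noise dispersion eroding predictability.  Zero amplitude and zero
    noise give a constant series (P, C, M) = (1, 1, 0).
    """
    if n_years < 2:
        raise ValueError("need at least 2 whole years")
    if seasonal_amplitude < 0:
        raise ValueError("seasonal amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    months = np.arange(12)
    cycle = baseline + seasonal_amplitude * 0.5 * (1 + np.sin(2 * np.pi * months / 12))
    noise = rng.standard_normal((n_years, 12)) * noise_sd
    values = cycle[None, :] * np.exp(noise - noise_sd**2 / 2)
    return ChlaSeries(values=values)


def gen_chla_fields(seed: int, grid: EnvGrid, n_years: int = 19,
                    amplitude_range: tuple = (1.5, 1.5),
                    amplitude_texture: float = 1.0,
                    noise_sd: float = 0.35, baseline: float = 0.3,
                    n_classes: int = 11, centre_cols: int | None = 4) -> dict:
    """Per-pixel chlorophyll summary fields over the grid.

    The seasonal amplitude ramps with *longitude* (west to east over
    ``amplitude_range``) plus a smooth random zonal wiggle that is constant
    along latitude, so M_CHLA has zonal, not meridional, mean structure —
    deliberate, to keep the developmental-mode model latitude-free — and is
    not a monotone function of longitude (decorrelating seasonality from
    the eastward-deepening bathymetry).
    Returns dict of 2-D fields: CHLA_mean, CHLA_max, P_CHLA, C_CHLA, M_CHLA.
    """
    rng = np.random.default_rng(seed)
    ny, nx = grid.shape
    lon_frac = (grid.lons - grid.lons[0]) / max(grid.lons[-1] - grid.lons[0], 1e-9)
    wiggle = ndimage.gaussian_filter1d(rng.standard_normal(nx), sigma=1.5,
                                       mode="wrap")
    # centre over the shelf columns: the shelf pool's mean seasonality is
    # seed-stable, keeping the realised mode mix near the reference share
    wiggle -= wiggle[:centre_cols].mean() if centre_cols else wiggle.mean()
    wiggle /= max(wiggle.std(), 1e-12)  # unit variance, latitude-constant
    amplitude = np.broadcast_to(
        amplitude_range[0]
        + (amplitude_range[1] - amplitude_range[0]) * lon_frac
        + amplitude_texture * wiggle, (ny, nx)).copy()
    amplitude = np.clip(amplitude, 0.0, None)
    months = np.arange(12)
    cycle = 0.5 * (1 + np.sin(2 * np.pi * months / 12))  # shape (12,)
    noise = rng.standard_normal((ny, nx, n_years, 12)) * noise_sd
    values = (baseline + amplitude[:, :, None, None] * cycle[None, None, None, :]) \
        * np.exp(noise - noise_sd**2 / 2)
    fields = {name: np.empty((ny, nx)) for name in
              ("CHLA_mean", "CHLA_max", "P_CHLA", "C_CHLA", "M_CHLA")}
    for i in range(ny):
        for j in range(nx):
            series = ChlaSeries(values=values[i, j])
            mean, mx = chla_stats(series)
            cw = colwell(series, n_classes=n_classes)
            fields["CHLA_mean"][i, j] = mean
            fields["CHLA_max"][i, j] = mx
            fields["P_CHLA"][i, j] = cw.P
            fields["C_CHLA"][i, j] = cw.C
            fields["M_CHLA"][i, j] = cw.M
    return fields


_SUPERFAMILIES = tuple(f"SF{k:02d}" for k in range(12))


def gen_species(seed: int, grid: EnvGrid, env_fields: dict,
                n_species: int = 94, shelf_cols: int = 4,
                mode_model: tuple = DEFAULT_MODE_MODEL,
                deep_frac: float = 0.19, widespread_frac: float = 1.0,
                deep_lat_min_range: tuple = (45.0, 58.0),
                planktotrophic_share: float = 51 / 61,
                superfamily_mode_coupling: float = 0.0,
                shelf_band_max_width: int | None = None,
                metabolic: MetabolicParams = MetabolicParams(a0const=5.796e-10),
                ) -> tuple[pd.DataFrame, list, list]:
    """Species table, range specs and potential distributions.

    Species split into shelf dwellers (shallow strip, ranges spanning all
    or part of the latitudinal extent) and deep offshore dwellers (ranges
    confined to high latitudes).  Developmental mode is drawn Bernoulli
    from the planted logistic model on range-mean depth and M_CHLA;
    pelagic species are split planktotrophic/lecithotrophic at the study
    pool's ratio.  Sizes are lognormal with mode-dependent shifts
    (non-pelagic have the largest initial and juvenile volumes;
    planktotrophic the largest juvenile/initial ratio Gr1), and DT and C
    follow the calibrated metabolic-theory formulas at each species'
    range-mean temperature.  Returns (records, range_specs, distributions).
    """
    if n_species < 10:
        raise ValueError("need at least 10 species")
    b = tuple(mode_model)
    if len(b) != 3 or not all(np.isfinite(b)):
        raise ValueError("mode_model must be 3 finite logistic coefficients")
    rng = np.random.default_rng(seed)
    lat0, lat1 = float(grid.lats[0]), float(grid.lats[-1])
    res_lon = float(grid.lons[1] - grid.lons[0])
    nx = grid.lons.size
    n_deep = max(2, int(round(deep_frac * n_species)))
    n_shelf = n_species - n_deep

    def col_span(a: int, bcol: int) -> tuple[float, float]:
        return (float(grid.lons[a]) - res_lon / 2,
                float(grid.lons[bcol]) + res_lon / 2)

    rows, specs, dists = [], [], []
    layers = {"depth": grid.depth, "T": grid.T, "U": grid.U, "DS": grid.DS,
              **env_fields}
    for k in range(n_species):
        deep = k >= n_shelf
        if deep:
            # narrow offshore column band: deep species differ in mean depth
            a = int(rng.integers(shelf_cols, nx))
            bcol = min(a + int(rng.integers(0, 4)), nx - 1)
            lon_lo, lon_hi_sp = col_span(a, bcol)
            lmin = rng.uniform(*deep_lat_min_range)
            rect = (lmin, lat1 + 1, lon_lo, lon_hi_sp)
            depth_range = (150.0, 5000.0)
        else:
            if shelf_band_max_width is None:
                # whole shelf: every shelf species sees the same environment,
                # so the shelf pool is stationary in both latitude and
                # longitude (the artefact experiment's null condition)
                a, bcol = 0, shelf_cols - 1
            else:
                # narrow cross-shelf band: species differ in mean depth/M
                a = int(rng.integers(0, shelf_cols))
                bcol = min(a + int(rng.integers(0, shelf_band_max_width + 1)),
                           shelf_cols - 1)
            lon_lo, lon_hi_sp = col_span(a, bcol)
            if rng.random() < widespread_frac:
                rect = (lat0 - 1, lat1 + 1, lon_lo, lon_hi_sp)
            else:
                lmin = rng.uniform(lat0, 45.0)
                lmax = min(lat1 + 1, lmin + rng.uniform(10.0, 30.0))
                rect = (lmin, lmax, lon_lo, lon_hi_sp)
            depth_range = (0.0, 150.0)
        spec = RangeSpec(rects=(rect,), depth_range=depth_range)
        mask = rasterize_range(spec, grid, species=f"sp{k:03d}")
        dist = potential_habitat(mask, grid, depth_range=depth_range)
        means = species_env_means(dist, layers)
        eta = b[0] + b[1] * means["depth"] + b[2] * means["M_CHLA"]
        pelagic = rng.random() < special.expit(eta)
        if not pelagic:
            mode = "non_pelagic"
        elif rng.random() < planktotrophic_share:
            mode = "planktotrophic"
        else:
            mode = "lecithotrophic"

        mu_is = {"non_pelagic": 0.0, "planktotrophic": -5.3,
                 "lecithotrophic": -3.9}[mode]
        IS = float(np.exp(rng.normal(mu_is, 1.0)))
        mu_gr1 = {"non_pelagic": np.log(3.0), "planktotrophic": np.log(100.0),
                  "lecithotrophic": np.log(5.0)}[mode]
        Gr1 = float(max(np.exp(rng.normal(mu_gr1, 0.4)), 1.05))  # JS > IS
        JS = IS * Gr1
        Gr2 = float(max(np.exp(rng.normal(np.log(1e4), 1.0)), 1.05))
        AS = JS * Gr2

        if superfamily_mode_coupling > 0 and rng.random() < superfamily_mode_coupling:
            half = len(_SUPERFAMILIES) // 2
            pool_sf = _SUPERFAMILIES[:half] if mode == "non_pelagic" \
                else _SUPERFAMILIES[half:]
        else:
            pool_sf = _SUPERFAMILIES
        superfamily = pool_sf[rng.integers(len(pool_sf))]

        T_k = means["T"] + 273.15
        DT = developmental_time(T_k, JS - IS, metabolic)
        C = fecundity(embryo_mass(IS), embryo_mass(AS), T_k, metabolic)
        gr1, gr2, gr3 = growth_ratios(IS, JS, AS)
        rows.append({
            "species": f"sp{k:03d}", "superfamily": superfamily, "mode": mode,
            "diet": ("carnivore", "omnivore", "herbivore")[
                rng.choice(3, p=[51 / 94, 4 / 94, 39 / 94])],
            "IS": IS, "JS": JS, "AS": AS,
            "Gr1": gr1, "Gr2": gr2, "Gr3": gr3, "DT": DT, "C": C,
            "depth_min": depth_range[0], "depth_max": depth_range[1],
            "area_km2": dist.area, "is_deep": deep,
            **{f"env_{name}": val for name, val in means.items()},
        })
        specs.append(spec)
        dists.append(dist)
    return pd.DataFrame(rows), specs, dists


def gen_effort_field(grid: EnvGrid, effort_scale: float = 6.0,
                     efolding_deg: float = 15.0) -> np.ndarray:
    """Poleward-declining exponential sampling-effort field."""
    if effort_scale < 0:
        raise ValueError("effort must be non-negative")
    lat0 = float(grid.lats[0])
    return np.broadcast_to(
        effort_scale * np.exp(-(grid.lats - lat0) / efolding_deg)[:, None],
        grid.shape).copy()


def gen_occurrences(seed: int, dists, effort_field, lats, lons) -> OccurrenceTable:
    """Effort-biased occurrence sampling of the species' distributions.

    Per pixel and species present there, the detection count is Poisson
    with mean equal to the local sampling effort; low effort yields many
    singletons (inflated relative Chao1), high effort drives the relative
    Chao1 towards 1.
    """
    effort = np.asarray(effort_field, dtype=float)
    if np.any(effort < 0):
        raise ValueError("effort must be non-negative")
    rng = np.random.default_rng(seed)
    masks = np.asarray([getattr(d, "mask", d) for d in dists])
    lam = masks * effort[None, :, :]
    counts = rng.poisson(lam)
    return OccurrenceTable(counts, lats, lons)


@dataclass
class SyntheticWorld:
    """A fully generated study system with its ground truth."""

    grid: EnvGrid
    env_fields: dict
    species: pd.DataFrame
    range_specs: list
    dists: list
    effort: np.ndarray
    occurrences: OccurrenceTable
    truth: GroundTruth


def gen_world(seed: int, shape: tuple = (90, 20), n_species: int = 94,
              mode_model: tuple = DEFAULT_MODE_MODEL,
              effort_scale: float = 6.0, effort_efolding_deg: float = 15.0,
              **kwargs) -> SyntheticWorld:
    """Generate the full default study system from one seed.

    Seeds for the stage generators are derived from ``seed`` through a
    ``SeedSequence`` spawn, so worlds are reproducible and stages are
    independent.
    """
    ss = np.random.SeedSequence(seed)
    s_env, s_chla, s_species, s_occ = [int(s.generate_state(1)[0] % (2**31))
                                       for s in ss.spawn(4)]
    grid = gen_env_grid(s_env, shape=shape,
                        **{k: v for k, v in kwargs.items()
                           if k in ("lat_range", "lon_range", "n_time",
                                    "shelf_cols", "current_mean", "current_sd")})
    env_fields = gen_chla_fields(s_chla, grid)
    species, specs, dists = gen_species(
        s_species, grid, env_fields, n_species=n_species, mode_model=mode_model,
        **{k: v for k, v in kwargs.items()
           if k in ("deep_frac", "widespread_frac", "deep_lat_min_range",
                    "superfamily_mode_coupling", "shelf_band_max_width")})
    effort = gen_effort_field(grid, effort_scale, effort_efolding_deg)
    occ = gen_occurrences(s_occ, dists, effort, grid.lats, grid.lons)
    richness = np.asarray([d.mask for d in dists]).sum(axis=0)
    truth = GroundTruth(seed=seed, mode_model=tuple(mode_model),
                        reference_prop_np=float((species["mode"] ==
                                                 "non_pelagic").mean()),
                        effort_scale=effort_scale,
                        effort_efolding_deg=effort_efolding_deg,
                        richness=richness,
                        params={"shape": list(shape), "n_species": n_species})
    return SyntheticWorld(grid=grid, env_fields=env_fields, species=species,
                          range_specs=specs, dists=dists, effort=effort,
                          occurrences=occ, truth=truth)


def artefact_experiment(seed: int, deltaP: float = 0.30, alpha: float = 0.05,
                        power: float = 0.8, rel_chao_threshold: float = 1.2,
                        **world_kwargs) -> dict:
    """Run the sampling-artefact experiment on one synthetic world.

    Generates a world, stacks the proportion maps, derives N_min from the
    realised species pool, applies the survey-completeness mask, and
    summarises the non-pelagic proportion over 5-degree latitudinal bands
    with the ``pixel_mean`` and ``filtered`` methodologies.  The returned
    dict carries both band tables and the Kendall rank-correlation trend
    test (tau and p) of band proportion against band order for each method
    — the Mann-Kendall statistic for a monotone latitudinal trend.
    """
    from scipy.stats import kendalltau

    from .reliability_mapping import (band_summary, n_min, reference_proportion,
                                      reliability_mask, stack_proportions)

    world = gen_world(seed, **world_kwargs)
    modes = world.species["mode"].to_numpy()
    props = stack_proportions(world.dists, modes,
                              lats=world.grid.lats, lons=world.grid.lons)
    ref = reference_proportion(modes)
    nmin = n_min(ref, deltaP, alpha, power)
    mask = reliability_mask(world.occurrences, props.richness, nmin,
                            rel_chao_threshold)
    out = {"world": world, "n_min": nmin, "reference_prop": ref, "bands": {},
           "trend": {}}
    for method in ("pixel_mean", "filtered"):
        table = band_summary(props, method,
                             mask=mask if method == "filtered" else None)
        np_band = table[table["mode"] == "non_pelagic"].reset_index(drop=True)
        ok = np_band["proportion"].notna()
        tau, p = (np.nan, np.nan)
        if ok.sum() >= 3:
            tau, p = kendalltau(np_band.index[ok], np_band.loc[ok, "proportion"])
            if np.isnan(p):  # constant band proportions: no trend by definition
                tau, p = 0.0, 1.0
        out["bands"][method] = table
        out["trend"][method] = {"tau": float(tau), "p": float(p),
                                "n_bands": int(ok.sum())}
    return out
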