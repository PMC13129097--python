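"""Seeded synthetic landscapes, climate cubes and binary presence cubes.

The generator emulates the shape of stacked, thresholded species distribution
model output on a regular grid: a peninsula-like landmass with a north-eastern
mountain ridge, a latitudinal temperature gradient with elevational lapse,
scenario-dependent warming across four periods, and a warm-skewed species pool
whose Gaussian thermal niches make baseline richness concentrate in warm
coastal lowlands and drive poleward/upslope displacement under warming.

All randomness is controlled by a single integer seed split deterministically
per stage; the same (seed, parameters) always reproduces the same cube
bit-for-bit.  Ground-truth niche parameters are returned as a
:class:`~floradrift.containers.ShiftTruth` so that downstream analyses can be
checked against the constructed shift direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .containers import (
    DEFAULT_PERIODS,
    DEFAULT_SCENARIOS,
    ClimateCube,
    GridLandscape,
    PresenceCube,
    ShiftTruth,
)
from ._utils import rng_from

#: default per-period warming increments (degC per period step) by scenario
DEFAULT_SCENARIO_DELTAS = {"126": 0.3, "370": 0.6, "585": 0.9}


@dataclass
class ReliefParams:
    """Controls of the synthetic landmass and relief field.

    The defaults sketch a mid-latitude peninsula: an elliptical landmass with
    a wavy coastline, lowlands in the south-west/south-east and a mountain
    ridge rising toward the north-east (peak elevation ~1,500 m).
    """

    land_radius_frac: float = 0.46       # ellipse semi-axes as fraction of extent
    coastline_wobble: float = 0.12       # radial boundary perturbation amplitude
    ridge_amp_m: float = 1500.0
    ridge_width: float = 0.18            # gaussian ridge width in normalized x
    base_slope_m: float = 200.0          # gentle south->north rise
    noise_sd_m: float = 30.0
    missing_coast_frac: float = 0.05     # near-coast cells with coast_km masked
    lat0_deg: float = 34.0
    lon0_deg: float = 126.0
    km_per_deg_lat: float = 111.0
    km_per_deg_lon: float = 88.0


@dataclass
class NicheParams:
    """Species-pool sampling controls for :func:`simulate_presence`.

    Optima are drawn warm-skewed: ``optimum = q95(current MAT) - Exp(scale)``,
    so most species centre on the warm end of the landscape and baseline
    richness concentrates in warm coastal lowlands.  Explicit per-species
    arrays override sampling when provided.
    """

    optimum_offset_scale_c: float = 2.0
    breadth_range_c: tuple = (1.5, 3.5)
    moisture_requirement_range_mm: tuple = (800.0, 1300.0)
    moisture_softness_mm: float = 150.0
    threshold_range: tuple = (0.30, 0.50)
    optimum_c: np.ndarray | None = None
    breadth_c: np.ndarray | None = None
    moisture_requirement_mm: np.ndarray | None = None
    threshold: np.ndarray | None = None


def coast_distance_km(x_km, y_km, is_land) -> np.ndarray:
    """Distance from each land-cell center to the nearest sea-cell center.

    Sea cells get 0.  Brute-force pairwise distances; grids used here are
    small enough that this is exact and fast.
    """
    x = np.asarray(x_km, dtype=float)
    y = np.asarray(y_km, dtype=float)
    land = np.asarray(is_land, dtype=bool)
    if not (~land).any():
        raise ValueError("no sea cells: coast distance is undefined")
    pts = np.column_stack([x, y])
    d = np.zeros(len(x))
    d[land] = cdist(pts[land], pts[~land]).min(axis=1)
    return d


def make_landscape(nx: int, ny: int, resolution_km: float = 10.0, seed: int = 0,
                   relief: ReliefParams | None = None,
                   land_mask: np.ndarray | None = None) -> GridLandscape:
    """Generate a complete rectangular lattice with relief and coast distances.

    Parameters
    ----------
    nx, ny : int
        Grid dimensions (>= 8 each).
    resolution_km : float
        Cell size; cell area is ``resolution_km**2``.
    seed : int
        Controls relief noise and which near-coast cells lose their
        ``coast_km`` value (to exercise downstream imputation).
    relief : ReliefParams, optional
    land_mask : array of bool, optional
        Explicit (ny*nx,) land mask in row-major (iy, ix) order, overriding
        the default elliptical landmass.
    """
    if nx < 8 or ny < 8:
        raise ValueError("nx and ny must be >= 8")
    if resolution_km <= 0:
        raise ValueError("resolution_km must be positive")
    relief = relief or ReliefParams()
    rng = rng_from(seed, "landscape")

    iy, ix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    ix = ix.ravel()
    iy = iy.ravel()
    x = (ix + 0.5) * resolution_km
    y = (iy + 0.5) * resolution_km
    xmax, ymax = nx * resolution_km, ny * resolution_km

    if land_mask is not None:
        land = np.asarray(land_mask, dtype=bool).ravel()
        if land.size != nx * ny:
            raise ValueError("land_mask has wrong size")
    else:
        cx, cy = xmax / 2, ymax / 2
        dx, dy = (x - cx) / (relief.land_radius_frac * xmax), (y - cy) / (
            relief.land_radius_frac * ymax)
        theta = np.arctan2(dy, dx)
        phase = rng.uniform(0, 2 * np.pi)
        boundary = 1.0 + relief.coastline_wobble * np.sin(3 * theta + phase)
        land = dx**2 + dy**2 <= boundary**2

    xn, yn = x / xmax, y / ymax
    ridge_center = 0.68 + 0.10 * yn
    ridge = np.exp(-((xn - ridge_center) ** 2) / (2 * relief.ridge_width**2))
    elev = (relief.ridge_amp_m * ridge * yn**1.2
            + relief.base_slope_m * yn
            + rng.normal(0.0, relief.noise_sd_m, size=x.size))
    elev = np.clip(elev, 0.0, None)
    elev[~land] = 0.0

    coast = coast_distance_km(x, y, land)
    coast_col = coast.astype(float)
    coast_col[~land] = np.nan  # coast distance is a land attribute

    # mask a seeded fraction of near-coast land cells to emulate land/sea
    # resampling gaps in real rasters
    if relief.missing_coast_frac > 0:
        land_idx = np.flatnonzero(land)
        near = land_idx[coast[land_idx] <= np.quantile(coast[land_idx], 0.2)]
        n_miss = int(round(relief.missing_coast_frac * land_idx.size))
        n_miss = min(n_miss, max(near.size - 1, 0))
        if n_miss > 0:
            miss = rng.choice(near, size=n_miss, replace=False)
            coast_col[miss] = np.nan

    cells = pd.DataFrame({
        "cell_id": np.arange(nx * ny),
        "ix": ix, "iy": iy,
        "x_km": x, "y_km": y,
        "lon_deg": relief.lon0_deg + x / relief.km_per_deg_lon,
        "lat_deg": relief.lat0_deg + y / relief.km_per_deg_lat,
        "elevation_m": elev,
        "coast_km": coast_col,
        "is_land": land,
        "cell_area_km2": resolution_km**2,
    })
    return GridLandscape(cells=cells, nx=nx, ny=ny, resolution_km=resolution_km)


@dataclass
class ClimateParams:
    """Deterministic structure of the synthetic climate fields."""

    base_mat_c: float = 15.0
    lat_gradient_c_per_deg: float = 1.0
    lapse_rate_c_per_km: float = -6.0
    base_map_mm: float = 1500.0
    coast_dry_mm_per_km: float = 2.5
    orographic_mm_per_m: float = 0.20
    map_trend_mm_per_period_delta: float = 15.0
    pdm_fraction: float = 0.05
    iso_base: float = 0.25
    noise_sd_c: float = 0.3       # static spatial microclimate field (degC)
    noise_sd_mm: float = 40.0     # static spatial precipitation field (mm)


def make_climate(landscape: GridLandscape,
                 scenario_deltas: dict | None = None,
                 lapse_rate: float | None = None,
                 seed: int = 0,
                 params: ClimateParams | None = None,
                 periods=DEFAULT_PERIODS) -> ClimateCube:
    """Build per-scenario x per-period climate fields on the landscape lattice.

    MAT follows a latitudinal gradient with elevational lapse plus a
    per-period scenario warming increment; MAP has a coastal-wet/orographic
    structure with a mild wet-get-wetter trend; noise is a static seeded
    spatial field shared across scenarios and periods, so within-scenario
    warming is exactly monotone by construction.
    """
    p = params or ClimateParams()
    if lapse_rate is not None:
        if lapse_rate > 0:
            raise ValueError("lapse_rate must be <= 0 degC per km of elevation")
        p.lapse_rate_c_per_km = lapse_rate
    deltas = {str(k): float(v) for k, v in
              (scenario_deltas or DEFAULT_SCENARIO_DELTAS).items()}
    scenarios = tuple(sorted(deltas))
    rng = rng_from(seed, "climate")

    cells = landscape.cells
    lat = cells["lat_deg"].to_numpy()
    elev = cells["elevation_m"].to_numpy()
    x = cells["x_km"].to_numpy()
    y = cells["y_km"].to_numpy()
    xmax = landscape.nx * landscape.resolution_km
    ymax = landscape.ny * landscape.resolution_km
    # recompute full coast distances from the mask (no missingness here)
    coast = coast_distance_km(x, y, cells["is_land"].to_numpy(dtype=bool))

    lat0 = lat.min()
    mat0 = (p.base_mat_c - p.lat_gradient_c_per_deg * (lat - lat0)
            + p.lapse_rate_c_per_km * elev / 1000.0)
    map0 = (p.base_map_mm - p.coast_dry_mm_per_km * coast
            + p.orographic_mm_per_m * elev)
    mat_noise = rng.normal(0, p.noise_sd_c, size=lat.size) if p.noise_sd_c else 0.0
    map_noise = rng.normal(0, p.noise_sd_mm, size=lat.size) if p.noise_sd_mm else 0.0
    iso0 = np.clip(p.iso_base + 0.05 * np.sin(2 * np.pi * x / xmax)
                   * np.cos(np.pi * y / ymax), 0.05, 0.60)

    frames = {}
    for scen in scenarios:
        for t, per in enumerate(periods):
            mat = mat0 + mat_noise + t * deltas[scen]
            mp = np.clip(map0 + map_noise
                         + p.map_trend_mm_per_period_delta * t * deltas[scen],
                         200.0, None)
            pdm = np.clip(p.pdm_fraction * mp - 20.0, 0.0, mp)
            iso = np.clip(iso0 + 0.004 * t * deltas[scen], 0.05, 0.60)
            frames[(scen, str(per))] = pd.DataFrame({
                "mat_c": mat, "map_mm": mp, "iso": iso, "pdm_mm": pdm})
    return ClimateCube(frames=frames, scenarios=scenarios,
                       periods=tuple(str(pp) for pp in periods),
                       cell_ids=cells["cell_id"].to_numpy())


def _sample_pool(niche: NicheParams, n_species: int, mat_current: np.ndarray,
                 rng: np.random.Generator):
    if niche.optimum_c is not None:
        opt = np.asarray(niche.optimum_c, dtype=float)
    else:
        warm_edge = np.quantile(mat_current, 0.95)
        opt = warm_edge - rng.exponential(niche.optimum_offset_scale_c, n_species)
    sig = (np.asarray(niche.breadth_c, dtype=float) if niche.breadth_c is not None
           else rng.uniform(*niche.breadth_range_c, n_species))
    req = (np.asarray(niche.moisture_requirement_mm, dtype=float)
           if niche.moisture_requirement_mm is not None
           else rng.uniform(*niche.moisture_requirement_range_mm, n_species))
    thr = (np.asarray(niche.threshold, dtype=float) if niche.threshold is not None
           else rng.uniform(*niche.threshold_range, n_species))
    for name, arr in (("optimum", opt), ("breadth", sig),
                      ("moisture requirement", req), ("threshold", thr)):
        if np.asarray(arr).shape != (n_species,):
            raise ValueError(f"per-species {name} array must have length {n_species}")
    if (sig <= 0).any():
        raise ValueError("thermal breadth must be positive for every species")
    return opt, sig, req, thr


def simulate_presence(landscape: GridLandscape, climate: ClimateCube,
                      n_species: int = 95,
                      niche: NicheParams | None = None,
                      seed: int = 0) -> tuple[PresenceCube, ShiftTruth]:
    """Threshold Gaussian thermal suitability into a binary presence cube.

    Species ``s`` is present in cell ``i`` iff
    ``exp(-(MAT - opt_s)^2 / (2 sigma_s^2)) * moisture(MAP) >= threshold_s``
    and the cell is land, where ``moisture`` is a logistic ramp in annual
    precipitation.  Warming moves each species' suitable band poleward and
    upslope by construction.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    niche = niche or NicheParams()
    rng = rng_from(seed, "species")
    scenarios, periods = climate.scenarios, climate.periods
    land = landscape.land_mask
    mat_current = climate.field("mat_c", scenarios[0], periods[0])[land]
    opt, sig, req, thr = _sample_pool(niche, n_species, mat_current, rng)

    n_cells = len(landscape.cells)
    occ = np.zeros((n_species, n_cells, len(scenarios), len(periods)), dtype=np.uint8)
    for a, scen in enumerate(scenarios):
        for t, per in enumerate(periods):
            mat = climate.field("mat_c", scen, per)
            mp = climate.field("map_mm", scen, per)
            moist = 1.0 / (1.0 + np.exp(-(mp[None, :] - req[:, None])
                                        / niche.moisture_softness_mm))
            suit = np.exp(-((mat[None, :] - opt[:, None]) ** 2)
                          / (2.0 * sig[:, None] ** 2)) * moist
            occ[:, :, a, t] = (suit >= thr[:, None]) & land[None, :]

    cube = PresenceCube(occupancy=occ, species=tuple(f"sp{i:03d}" for i in range(n_species)),
                        cell_ids=landscape.cells["cell_id"].to_numpy(),
                        scenarios=scenarios, periods=periods)
    deltas = {}
    for scen in scenarios:
        m0 = climate.field("mat_c", scen, periods[0]).mean()
        m1 = climate.field("mat_c", scen, periods[1]).mean() if len(periods) > 1 else m0
        deltas[scen] = float(m1 - m0)
    truth = ShiftTruth(thermal_optimum_c=opt, thermal_breadth_c=sig,
                       moisture_requirement_mm=req, suitability_threshold=thr,
                       scenario_delta_c=deltas, seed=seed)
    return cube, truth


def expected_alignment_signs(cube: PresenceCube, labels, scenario: str,
                             rel_change_threshold: float = 0.2) -> pd.DataFrame:
    """Constructed-truth alignment signs per cluster under warming.

    A cluster is *retracting* when its mean richness falls by at least
    ``rel_change_threshold`` (relative) between the first and last period:
    its cells lose thermally marginal species and their composition slides
    toward warmer community types.  Because the fitted latitude vector points
    toward cool/high-latitude community types while warming drags every
    composition the other way, retracting clusters are expected to align
    negatively with the latitude vector and positively with the
    mean-annual-temperature vector.  Returns one row per cluster with
    ``rel_richness_change``, ``retracting`` and the two expected signs (0
    where no strong expectation exists).
    """
    labels = np.asarray(labels, dtype=float)
    first, last = cube.periods[0], cube.periods[-1]
    r0 = cube.richness(scenario, first).astype(float)
    r1 = cube.richness(scenario, last).astype(float)
    rows = []
    for cl in np.unique(labels[~np.isnan(labels)]).astype(int):
        sel = labels == cl
        base = r0[sel].mean()
        rel = (r1[sel].mean() - base) / base if base > 0 else np.inf
        retracting = rel <= -rel_change_threshold
        rows.append({
            "cluster": int(cl),
            "rel_richness_change": float(rel),
            "retracting": bool(retracting),
            "expected_sign_lat": -1 if retracting else 0,
            "expected_sign_mat": 1 if retracting else 0,
        })
    return pd.DataFrame(rows)


def pooled_mean_latitude(cube: PresenceCube, landscape: GridLandscape,
                         scenario: str) -> np.ndarray:
    """Richness-weighted mean latitude of occupied cells, one value per period.

    Direct summation oracle for the constructed poleward shift: under
    warming with zero temporal noise this sequence is non-decreasing.
    """
    lat = landscape.cells["lat_deg"].to_numpy()
    out = []
    for per in cube.periods:
        w = cube.richness(scenario, per).astype(float)
        if w.sum() == 0:
            out.append(np.nan)
        else:
            out.append(float(np.average(lat, weights=w)))
    return np.asarray(out)
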