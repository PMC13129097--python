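"""Richness-weighted kernel density core zones (KDE50).

Per scenario x period, species richness over occupied cells serves as
replication weights in a bivariate Gaussian KDE evaluated on the analysis
lattice itself.  The 50% highest-density region (the KDE50 isopleth, in
raster form) is clipped to land, intersected with the static environmental
clusters, and summarized per cluster: centroid, area, connected-component
count and the distribution of elevation and coast distance over member
cells.  Displacement between periods and cross-scenario agreement counts are
derived from these sets.

Regions are represented as cell sets rather than vector polygons: at one
fixed resolution this matches polygon dissolution up to half-cell
discretization and keeps every downstream decision per-cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._utils import as_2d_points
from .containers import GridLandscape, PresenceCube
from .zoning import impute_coast_distance

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])

# Gaussian-kernel constants for the univariate direct plug-in bandwidth
_RK = 1.0 / (2.0 * np.sqrt(np.pi))          # roughness R(K)
_PHI4_0 = 3.0 / np.sqrt(2.0 * np.pi)        # phi''''(0)
_PHI6_0 = -15.0 / np.sqrt(2.0 * np.pi)      # phi^(6)(0)


def effective_sample_size(weights) -> float:
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / (w**2).sum())


def _weighted_mean_cov(points, weights):
    pts = as_2d_points(points)
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("weights must not all be zero")
    mu = np.average(pts, axis=0, weights=w)
    c = pts - mu
    cov = (w[:, None] * c).T @ c / w.sum()
    return mu, cov


def _phi_deriv(x, order):
    phi = np.exp(-0.5 * x**2) / np.sqrt(2 * np.pi)
    if order == 4:
        return (x**4 - 6 * x**2 + 3) * phi
    if order == 6:
        return (x**6 - 15 * x**4 + 45 * x**2 - 15) * phi
    raise ValueError(order)


def _psi_functional(x, w, g, order):
    # psi_r = sum_ij w_i w_j phi_g^(r)(x_i - x_j) / (sum w)^2
    diff = (x[:, None] - x[None, :]) / g
    ww = np.outer(w, w) / w.sum() ** 2
    return float((ww * _phi_deriv(diff, order)).sum() / g ** (order + 1))


def _plugin_h1d(x, w):
    """Two-stage direct plug-in bandwidth for one coordinate (weighted)."""
    n = effective_sample_size(w)
    sd = np.sqrt(np.average((x - np.average(x, weights=w)) ** 2, weights=w))
    if sd == 0:
        raise ValueError("zero weighted variance: bandwidth undefined")
    psi8 = 105.0 / (32.0 * np.sqrt(np.pi) * sd**9)
    g6 = (-2.0 * _PHI6_0 / (psi8 * n)) ** (1.0 / 9.0)
    psi6 = _psi_functional(x, w, g6, 6)
    g4 = (-2.0 * _PHI4_0 / (psi6 * n)) ** (1.0 / 7.0)
    psi4 = _psi_functional(x, w, g4, 4)
    return (_RK / (psi4 * n)) ** 0.2


def weighted_bandwidth(points, weights, method: str = "normal_scale") -> np.ndarray:
    """Data-driven 2x2 bandwidth matrix for weighted points.

    ``normal_scale`` (default): H = n_eff^(-1/3) * weighted covariance — the
    2-D normal-scale rule (the (4/(d+2))^(2/(d+4)) prefactor equals 1 at
    d = 2) with the effective sample size n_eff = (sum w)^2 / sum(w^2), so
    duplicating points while halving weights leaves H unchanged.

    ``plugin``: diagonal matrix of squared univariate two-stage direct
    plug-in bandwidths, computed coordinate-wise on the weighted sample.
    """
    pts = as_2d_points(points)
    w = np.asarray(weights, dtype=float)
    if pts.shape[0] != w.shape[0]:
        raise ValueError("points and weights length mismatch")
    keep = w > 0
    if len(np.unique(pts[keep], axis=0)) < 2:
        raise ValueError("need at least 2 distinct points with positive weight")
    pts, w = pts[keep], w[keep]
    _, cov = _weighted_mean_cov(pts, w)
    if np.linalg.det(cov) <= 0:
        raise ValueError("degenerate weighted covariance (collinear or "
                         "coincident points)")
    if method == "normal_scale":
        H = effective_sample_size(w) ** (-1.0 / 3.0) * cov
    elif method == "plugin":
        H = np.diag([_plugin_h1d(pts[:, 0], w) ** 2,
                     _plugin_h1d(pts[:, 1], w) ** 2])
    else:
        raise ValueError(f"unknown bandwidth method {method!r}")
    return H


@dataclass
class DensitySurface:
    """Weighted KDE evaluated on the analysis lattice."""

    x_km: np.ndarray
    y_km: np.ndarray
    density: np.ndarray          # km^-2, one value per lattice cell
    bandwidth: np.ndarray        # 2x2 SPD (km^2)
    cell_area_km2: float

    @property
    def cell_mass(self) -> np.ndarray:
        return self.density * self.cell_area_km2

    @property
    def total_mass(self) -> float:
        return float(self.cell_mass.sum())


def weighted_kde(points, weights, H, eval_x, eval_y,
                 cell_area_km2: float) -> DensitySurface:
    """f(x) = sum_i w_i K_H(x - x_i) / sum_i w_i with Gaussian K_H."""
    pts = as_2d_points(points)
    w = np.asarray(weights, dtype=float)
    H = np.asarray(H, dtype=float)
    try:
        L = np.linalg.cholesky(H)
    except np.linalg.LinAlgError as err:
        raise ValueError("bandwidth matrix must be positive-definite") from err
    det = np.linalg.det(H)
    Hinv = np.linalg.inv(H)
    ex = np.asarray(eval_x, dtype=float)
    ey = np.asarray(eval_y, dtype=float)
    out = np.zeros(ex.size)
    norm = 1.0 / (2.0 * np.pi * np.sqrt(det))
    # chunk the evaluation lattice to bound the (m x n) temporary
    step = max(1, int(4e6 // max(pts.shape[0], 1)))
    for s in range(0, ex.size, step):
        dx = ex[s:s + step, None] - pts[None, :, 0]
        dy = ey[s:s + step, None] - pts[None, :, 1]
        q = (Hinv[0, 0] * dx**2 + 2 * Hinv[0, 1] * dx * dy + Hinv[1, 1] * dy**2)
        out[s:s + step] = (np.exp(-0.5 * q) * w[None, :]).sum(axis=1)
    out *= norm / w.sum()
    return DensitySurface(x_km=ex, y_km=ey, density=out, bandwidth=H,
                          cell_area_km2=cell_area_km2)


def kde50_region(surface: DensitySurface, mass: float = 0.5) -> np.ndarray:
    """Indices of the discrete highest-density region holding >= ``mass``.

    Cells are sorted by density descending and accumulated until the target
    mass is reached; all cells tied at the threshold density are included, so
    the result is order-independent.
    """
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    if surface.total_mass <= mass:
        raise ValueError(
            f"kernel mass on the lattice ({surface.total_mass:.3f}) does not "
            f"exceed the requested isopleth mass {mass}; the evaluation "
            "lattice is too small for this bandwidth")
    order = np.argsort(surface.density)[::-1]
    cum = np.cumsum(surface.cell_mass[order])
    cut = int(np.searchsorted(cum, mass))
    thr = surface.density[order[cut]]
    return np.flatnonzero(surface.density >= thr)


class RichnessWeightedKDE:
    """Sklearn-style wrapper around the weighted Gaussian KDE.

    Parameters
    ----------
    bandwidth_method : {'normal_scale', 'plugin'} or 'fixed'
        Selector for the 2x2 bandwidth matrix; with ``'fixed'``,
        ``bandwidth`` must be supplied.
    bandwidth : (2, 2) array, optional
        Explicit SPD bandwidth matrix, used when ``bandwidth_method='fixed'``.

    Attributes
    ----------
    bandwidth_ : (2, 2) selected bandwidth matrix
    points_, weights_ : the fitted weighted sample
    """

    def __init__(self, bandwidth_method: str = "normal_scale", bandwidth=None):
        self.bandwidth_method = bandwidth_method
        self.bandwidth = bandwidth

    def get_params(self, deep=True):
        return {"bandwidth_method": self.bandwidth_method,
                "bandwidth": self.bandwidth}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None, sample_weight=None):
        pts = as_2d_points(X)
        w = (np.ones(len(pts)) if sample_weight is None
             else np.asarray(sample_weight, dtype=float))
        if self.bandwidth_method == "fixed":
            if self.bandwidth is None:
                raise ValueError("bandwidth_method='fixed' requires bandwidth")
            self.bandwidth_ = np.asarray(self.bandwidth, dtype=float)
        else:
            self.bandwidth_ = weighted_bandwidth(pts, w, self.bandwidth_method)
        self.points_, self.weights_ = pts, w
        return self

    def evaluate(self, eval_x, eval_y, cell_area_km2: float) -> DensitySurface:
        return weighted_kde(self.points_, self.weights_, self.bandwidth_,
                            eval_x, eval_y, cell_area_km2)

    def score_samples(self, X):
        pts = as_2d_points(X)
        return self.evaluate(pts[:, 0], pts[:, 1], 1.0).density


@dataclass
class CoreZoneSet:
    """Dissolved KDE50 core zones per cluster for one scenario x period."""

    scenario: str
    period: str
    mass: float
    table: pd.DataFrame
    members: dict = field(default_factory=dict)   # cluster -> cell row indices
    hdr_cells: np.ndarray | None = None           # undissolved KDE50 (pre-clip)
    surface: DensitySurface | None = None
    pooled: dict = field(default_factory=dict)    # all-species merged zone stats


def _summarize_members(idx, landscape_cells):
    sub = landscape_cells.iloc[idx]
    out = {
        "centroid_x_km": float(sub["x_km"].mean()),
        "centroid_y_km": float(sub["y_km"].mean()),
        "centroid_lon_deg": float(sub["lon_deg"].mean()),
        "centroid_lat_deg": float(sub["lat_deg"].mean()),
    }
    for var, tag in (("elevation_m", "elev_m"), ("coast_km", "coast_km")):
        v = sub[var].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
        out[f"mean_{tag}"] = float(v.mean())
        out[f"median_{tag}"] = float(med)
        out[f"iqr_{tag}"] = float(q3 - q1)
    return out


def _component_count(idx, landscape: GridLandscape) -> int:
    mask = np.zeros((landscape.ny, landscape.nx), dtype=bool)
    cells = landscape.cells.iloc[idx]
    mask[cells["iy"].to_numpy(), cells["ix"].to_numpy()] = True
    _, n = ndimage.label(mask, structure=_FOUR_CONN)
    return int(n)


def build_core_zones(cube: PresenceCube, labels, landscape: GridLandscape,
                     scenario: str, period: str, mass: float = 0.5,
                     bandwidth_method: str = "normal_scale",
                     mode: str = "pooled") -> CoreZoneSet:
    """Richness-weighted KDE50 core zones dissolved by cluster.

    ``mode='pooled'`` (default) estimates one richness-weighted KDE from all
    occupied cells, extracts the 50% highest-density region, clips to land
    and intersects with each cluster's footprint.  ``mode='per_cluster'``
    instead fits a separate KDE per cluster from that cluster's occupied
    cells.  ``labels`` is a per-cell vector over the full lattice (NaN on
    sea).
    """
    landscape = impute_coast_distance(landscape)
    cells = landscape.cells
    labels = np.asarray(labels, dtype=float)
    richness = cube.richness(scenario, period).astype(float)
    if richness.sum() == 0:
        raise ValueError("all-zero richness: no occupied cells to estimate from")
    land = landscape.land_mask
    ex = cells["x_km"].to_numpy()
    ey = cells["y_km"].to_numpy()

    cluster_ids = np.unique(labels[~np.isnan(labels)]).astype(int)
    members: dict = {}
    hdr_idx = None
    surface = None
    pooled: dict = {}

    def _clipped_hdr(pts_mask):
        pts = np.column_stack([ex[pts_mask], ey[pts_mask]])
        w = richness[pts_mask]
        H = weighted_bandwidth(pts, w, method=bandwidth_method)
        surf = weighted_kde(pts, w, H, ex, ey, landscape.cell_area_km2)
        return surf, kde50_region(surf, mass=mass)

    if mode == "pooled":
        surface, hdr_idx = _clipped_hdr(richness > 0)
        core = np.zeros(len(cells), dtype=bool)
        core[hdr_idx] = True
        core &= land
        for cl in cluster_ids:
            members[int(cl)] = np.flatnonzero(core & (labels == cl))
        core_idx = np.flatnonzero(core)
        if core_idx.size:
            pooled = _summarize_members(core_idx, cells)
            pooled["area_km2"] = float(core_idx.size * landscape.cell_area_km2)
            pooled["n_components"] = _component_count(core_idx, landscape)
    elif mode == "per_cluster":
        for cl in cluster_ids:
            sel = (richness > 0) & (labels == cl)
            if sel.sum() < 2:
                members[int(cl)] = np.array([], dtype=int)
                continue
            try:
                _, idx = _clipped_hdr(sel)
            except ValueError:
                members[int(cl)] = np.array([], dtype=int)
                continue
            core = np.zeros(len(cells), dtype=bool)
            core[idx] = True
            members[int(cl)] = np.flatnonzero(core & land & (labels == cl))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rows = []
    for cl, idx in members.items():
        if idx.size == 0:
            continue
        row = {"cluster": cl, "scenario": scenario, "period": period,
               "n_cells": int(idx.size),
               "area_km2": float(idx.size * landscape.cell_area_km2),
               "n_components": _component_count(idx, landscape)}
        row.update(_summarize_members(idx, cells))
        rows.append(row)
    cols = ["cluster", "scenario", "period", "n_cells", "area_km2",
            "n_components", "centroid_x_km", "centroid_y_km",
            "centroid_lon_deg", "centroid_lat_deg", "mean_elev_m",
            "median_elev_m", "iqr_elev_m", "mean_coast_km", "median_coast_km",
            "iqr_coast_km"]
    table = (pd.DataFrame(rows, columns=cols).sort_values("cluster")
             .reset_index(drop=True) if rows else pd.DataFrame(columns=cols))
    return CoreZoneSet(scenario=scenario, period=period, mass=mass,
                       table=table, members=members, hdr_cells=hdr_idx,
                       surface=surface, pooled=pooled)


def zone_displacement(a: CoreZoneSet, b: CoreZoneSet) -> pd.DataFrame:
    """Per-cluster centroid and attribute deltas between two core-zone sets.

    Clusters empty in either set are omitted (absent, not zero).
    """
    ta = a.table.set_index("cluster")
    tb = b.table.set_index("cluster")
    common = sorted(set(ta.index) & set(tb.index))
    rows = []
    for cl in common:
        ra, rb = ta.loc[cl], tb.loc[cl]
        dx = rb["centroid_x_km"] - ra["centroid_x_km"]
        dy = rb["centroid_y_km"] - ra["centroid_y_km"]
        rows.append({
            "cluster": cl, "scenario": b.scenario,
            "from_period": a.period, "to_period": b.period,
            "d_lon_deg": float(rb["centroid_lon_deg"] - ra["centroid_lon_deg"]),
            "d_lat_deg": float(rb["centroid_lat_deg"] - ra["centroid_lat_deg"]),
            "d_elev_m": float(rb["mean_elev_m"] - ra["mean_elev_m"]),
            "d_coast_km": float(rb["mean_coast_km"] - ra["mean_coast_km"]),
            "shift_km": float(np.hypot(dx, dy)),
        })
    return pd.DataFrame(rows, columns=[
        "cluster", "scenario", "from_period", "to_period", "d_lon_deg",
        "d_lat_deg", "d_elev_m", "d_coast_km", "shift_km"])


def scenario_agreement(zones_by_scenario: dict, labels,
                       landscape: GridLandscape) -> pd.DataFrame:
    """Per land cell, in how many scenarios it lies in its cluster's KDE50.

    ``zones_by_scenario`` maps scenario label to a :class:`CoreZoneSet` for a
    common period; counts range over 0..len(zones_by_scenario).
    """
    if not zones_by_scenario:
        raise ValueError("no scenarios supplied")
    periods = {z.period for z in zones_by_scenario.values()}
    if len(periods) != 1:
        raise ValueError("core-zone sets span different periods")
    labels = np.asarray(labels, dtype=float)
    land_idx = np.flatnonzero(landscape.land_mask)
    count = np.zeros(len(landscape.cells), dtype=int)
    for zones in zones_by_scenario.values():
        inset = np.zeros(len(landscape.cells), dtype=bool)
        for cl, idx in zones.members.items():
            inset[idx] = True
        count += inset
    return pd.DataFrame({
        "cell_id": landscape.cells["cell_id"].to_numpy()[land_idx],
        "cluster": labels[land_idx].astype(int),
        "period": next(iter(periods)),
        "agreement": count[land_idx],
    })
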