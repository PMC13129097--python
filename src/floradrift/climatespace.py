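"""Climate-space (Whittaker plane) analysis of cluster reorganization.

Each land cell is projected onto the mean-annual-temperature (degC) x annual
precipitation (cm) plane.  Per cluster (or pooled), 50% and 95% bivariate
normal confidence ellipses summarize climate occupancy; area change, ellipse
overlap (Jaccard and minimum-based, via rasterization), k x k cell-level
transition matrices and optional biome-polygon fractions quantify how the
occupied climate space is displaced and restructured between periods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import chi2

from .containers import ClimateCube, GridLandscape


def to_climate_points(climate: ClimateCube, labels, landscape: GridLandscape,
                      scenario: str, period: str,
                      map_in_cm: bool = False) -> pd.DataFrame:
    """One (MAT degC, MAP cm, cluster) record per land cell.

    Cluster labels are the static environmental zones and are reused
    unchanged across periods.  Annual precipitation is converted from mm to
    cm unless ``map_in_cm`` says the cube already stores cm.
    """
    land = landscape.land_mask
    labels = np.asarray(labels, dtype=float)
    mat = climate.field("mat_c", scenario, period)[land]
    mp = climate.field("map_mm", scenario, period)[land]
    return pd.DataFrame({
        "cell_id": landscape.cells["cell_id"].to_numpy()[land],
        "mat_c": mat,
        "map_cm": mp if map_in_cm else mp / 10.0,
        "cluster": labels[land].astype(int),
        "scenario": scenario,
        "period": period,
    })


@dataclass
class ClimateEllipse:
    """Bivariate-normal confidence ellipse in the MAT-MAP plane."""

    center: np.ndarray       # (mean MAT degC, mean MAP cm)
    cov: np.ndarray          # 2x2 sample covariance
    level: float             # confidence level, e.g. 0.95
    cluster: int | str = "all"
    period: str = ""

    @property
    def q(self) -> float:
        """Chi-square(2 df) quantile bounding the ellipse."""
        return float(chi2.ppf(self.level, df=2))

    @property
    def area(self) -> float:
        """Closed-form area pi * q * sqrt(det(cov)), in degC * cm."""
        return float(np.pi * self.q * np.sqrt(np.linalg.det(self.cov)))

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d = pts - self.center
        Sinv = np.linalg.inv(self.cov)
        md2 = np.einsum("ni,ij,nj->n", d, Sinv, d)
        return md2 <= self.q

    def bbox(self):
        half = np.sqrt(self.q * np.diag(self.cov))
        return (self.center - half, self.center + half)


def fit_confidence_ellipse(points, level: float, cluster="all",
                           period: str = "") -> ClimateEllipse:
    """Fit a multivariate-normal confidence ellipse to n >= 3 points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    cov = np.cov(pts, rowvar=False, ddof=1)
    if np.linalg.det(cov) <= 0:
        raise ValueError("singular covariance: points are degenerate")
    return ClimateEllipse(center=pts.mean(axis=0), cov=cov, level=level,
                          cluster=cluster, period=period)


def _raster_masks(e1: ClimateEllipse, e2: ClimateEllipse, raster_n: int):
    lo = np.minimum(e1.bbox()[0], e2.bbox()[0])
    hi = np.maximum(e1.bbox()[1], e2.bbox()[1])
    xs = np.linspace(lo[0], hi[0], raster_n)
    ys = np.linspace(lo[1], hi[1], raster_n)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    return e1.contains(pts), e2.contains(pts)


def ellipse_overlap(e1: ClimateEllipse, e2: ClimateEllipse,
                    method: str = "jaccard", raster_n: int = 500) -> float:
    """Overlap of two ellipses on a shared raster over their joint bbox.

    ``jaccard`` = |intersection| / |union|; ``min`` = |intersection| over the
    smaller ellipse.  Discretization error is O(1/raster_n).
    """
    if raster_n < 100:
        raise ValueError("raster_n must be >= 100 per axis")
    m1, m2 = _raster_masks(e1, e2, raster_n)
    inter = float((m1 & m2).sum())
    if method == "jaccard":
        union = float((m1 | m2).sum())
        return inter / union if union else 0.0
    if method == "min":
        smaller = float(min(m1.sum(), m2.sum()))
        return inter / smaller if smaller else 0.0
    raise ValueError(f"unknown overlap method {method!r}")


def rasterized_area(e: ClimateEllipse, raster_n: int = 500) -> float:
    """Monte-Carlo-free raster estimate of the ellipse area (for validation)."""
    lo, hi = e.bbox()
    xs = np.linspace(lo[0], hi[0], raster_n)
    ys = np.linspace(lo[1], hi[1], raster_n)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
    return float(e.contains(pts).sum() * cell)


def delta_area(current: ClimateEllipse, future: ClimateEllipse):
    """(dArea, percent change) between same-level ellipses."""
    if current.level != future.level:
        raise ValueError("ellipse levels differ")
    d = future.area - current.area
    return d, 100.0 * d / current.area


def assign_climate_labels(points: pd.DataFrame, centroids: pd.DataFrame,
                          scale: tuple | None = None) -> np.ndarray:
    """Nearest-centroid cluster labels in standardized MAT-MAP space.

    ``centroids`` holds columns ``cluster, mat_c, map_cm``; ``scale`` gives
    the (sd_mat, sd_map) used for standardization (defaults to the sd of the
    supplied points).
    """
    pts = points[["mat_c", "map_cm"]].to_numpy(dtype=float)
    cen = centroids[["mat_c", "map_cm"]].to_numpy(dtype=float)
    if scale is None:
        scale = pts.std(axis=0, ddof=0)
    scale = np.asarray(scale, dtype=float)
    d = cdist(pts / scale, cen / scale)
    return centroids["cluster"].to_numpy()[d.argmin(axis=1)]


def transition_matrix(current_labels, future_labels, k: int) -> pd.DataFrame:
    """Row-stochastic k x k matrix P(F|C) of cluster reassignment counts.

    Entry (C, F) is the share of cells currently labelled C that carry future
    label F.  Rows of empty current clusters are NaN.
    """
    cur = np.asarray(current_labels)
    fut = np.asarray(future_labels)
    if cur.shape != fut.shape:
        raise ValueError("label vectors differ in length")
    P = np.full((k, k), np.nan)
    for c in range(1, k + 1):
        sel = cur == c
        if sel.sum() == 0:
            continue
        counts = np.array([(fut[sel] == f).sum() for f in range(1, k + 1)],
                          dtype=float)
        P[c - 1] = counts / sel.sum()
    idx = [f"C{c}" for c in range(1, k + 1)]
    cols = [f"F{f}" for f in range(1, k + 1)]
    return pd.DataFrame(P, index=idx, columns=cols)


def biome_fractions(ellipse: ClimateEllipse, biome_polygons,
                    raster_n: int = 500) -> pd.DataFrame:
    """Fraction of the rasterized ellipse falling in each labelled polygon.

    ``biome_polygons`` is a sequence of (name, shapely polygon) pairs in
    MAT-MAP coordinates; overlaps resolve by input order (first wins) with a
    warning.  The unassigned remainder is reported as ``outside reference``.
    """
    from shapely import contains_xy

    lo, hi = ellipse.bbox()
    xs = np.linspace(lo[0], hi[0], raster_n)
    ys = np.linspace(lo[1], hi[1], raster_n)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = ellipse.contains(pts)
    total = float(inside.sum())
    assigned = np.zeros(pts.shape[0], dtype=bool)
    rows = []
    overlap_warned = False
    for name, poly in biome_polygons:
        hit = inside & contains_xy(poly, pts[:, 0], pts[:, 1])
        if (hit & assigned).any() and not overlap_warned:
            warnings.warn("overlapping biome polygons: precedence by input "
                          "order", stacklevel=2)
            overlap_warned = True
        hit &= ~assigned
        assigned |= hit
        rows.append({"biome": name, "fraction": float(hit.sum()) / total})
    rows.append({"biome": "outside reference",
                 "fraction": float((inside & ~assigned).sum()) / total})
    return pd.DataFrame(rows)


def climate_space_shift(climate: ClimateCube, labels, landscape: GridLandscape,
                        scenario: str, from_period: str, to_period: str,
                        levels=(0.5, 0.95), raster_n: int = 500,
                        pooled: bool = True,
                        label_source: str = "current_vs_future_centroids"):
    """Ellipses, overlaps and the transition matrix between two periods.

    ``label_source`` controls how the future-side labels of the transition
    matrix arise:

    * ``'current_vs_future_centroids'`` (default): each cell's CURRENT
      climate is assigned to the nearest per-cluster centroid of the FUTURE
      climate — the entry P(F|C) then reads "cluster C's present climate
      matches the future climate of cluster F", so under warming the dominant
      off-diagonal flow runs from warm rows toward cooler columns.
    * ``'future_vs_current_centroids'``: each cell's FUTURE climate is
      assigned to the nearest CURRENT-period centroid.
    * ``'static'``: labels never change (identity matrix; a null reference).

    Returns a dict with ``ellipses`` (DataFrame), ``overlap`` (DataFrame) and
    ``transition`` (DataFrame).
    """
    cur = to_climate_points(climate, labels, landscape, scenario, from_period)
    fut = to_climate_points(climate, labels, landscape, scenario, to_period)
    k = int(np.nanmax(np.asarray(labels, dtype=float)))

    ell_rows, overlap_rows = [], []
    groups = [("all", cur, fut)] if pooled else []
    for cl in sorted(cur["cluster"].unique()):
        groups.append((int(cl), cur[cur["cluster"] == cl],
                       fut[fut["cluster"] == cl]))
    ellipses = {}
    for name, c_pts, f_pts in groups:
        for level in levels:
            for tag, pts in (("current", c_pts), ("future", f_pts)):
                if len(pts) < 3:
                    continue
                try:
                    e = fit_confidence_ellipse(
                        pts[["mat_c", "map_cm"]].to_numpy(), level,
                        cluster=name,
                        period=from_period if tag == "current" else to_period)
                except ValueError:
                    continue
                ellipses[(name, level, tag)] = e
                ell_rows.append({
                    "cluster": name, "level": level, "when": tag,
                    "period": e.period, "mat_center_c": e.center[0],
                    "map_center_cm": e.center[1], "area_c_cm": e.area})
            key_c, key_f = (name, level, "current"), (name, level, "future")
            if key_c in ellipses and key_f in ellipses:
                ec, ef = ellipses[key_c], ellipses[key_f]
                da, pct = delta_area(ec, ef)
                overlap_rows.append({
                    "cluster": name, "level": level,
                    "delta_area_c_cm": da, "pct_change": pct,
                    "jaccard": ellipse_overlap(ec, ef, "jaccard", raster_n),
                    "min_overlap": ellipse_overlap(ec, ef, "min", raster_n)})

    cur_centroids = (cur.groupby("cluster")[["mat_c", "map_cm"]].mean()
                     .reset_index())
    fut_centroids = (fut.groupby("cluster")[["mat_c", "map_cm"]].mean()
                     .reset_index())
    scale = cur[["mat_c", "map_cm"]].to_numpy().std(axis=0, ddof=0)
    if label_source == "current_vs_future_centroids":
        new_labels = assign_climate_labels(cur, fut_centroids, scale=scale)
    elif label_source == "future_vs_current_centroids":
        new_labels = assign_climate_labels(fut, cur_centroids, scale=scale)
    elif label_source == "static":
        new_labels = fut["cluster"].to_numpy()
    else:
        raise ValueError(f"unknown label_source {label_source!r}")
    trans = transition_matrix(cur["cluster"].to_numpy(), new_labels, k)

    return {"ellipses": pd.DataFrame(ell_rows),
            "overlap": pd.DataFrame(overlap_rows),
            "transition": trans,
            "current_centroids": cur_centroids,
            "future_centroids": fut_centroids}
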