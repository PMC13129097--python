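"""Scenario-invariant environmental zoning of the landscape.

Land cells are clustered on four static variables — elevation, distance to
coast, latitude and longitude — after z-standardization, using k-means with
silhouette-guided selection of k constrained to k >= 6.  The resulting
clusters are a fixed spatial frame of reference: every downstream analysis
(core zones, trajectories, climate space) is reported per cluster, so labels
are made deterministic by relabelling clusters in order of descending size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.utils.validation import check_is_fitted

from .containers import GridLandscape

STATIC_VARS = ("elevation_m", "coast_km", "lat_deg", "lon_deg")
MIN_K = 6  # minimum cluster count considered ecologically resolvable


def impute_coast_distance(landscape: GridLandscape, n_neighbors: int = 8,
                          power: float = 2.0) -> GridLandscape:
    """Fill missing coast distances by inverse-distance-weighted interpolation.

    Missing values (land cells only) are replaced by the IDW mean of the
    ``n_neighbors`` nearest land cells with observed coast distance; exact
    spatial coincidence falls back to the coincident value.  Observed values
    are never modified.  This is a boundary correction, not an inference step.
    """
    cells = landscape.cells
    coast = cells["coast_km"].to_numpy(dtype=float).copy()
    land = cells["is_land"].to_numpy(dtype=bool)
    missing = land & np.isnan(coast)
    if not missing.any():
        return landscape
    observed = land & ~np.isnan(coast)
    if not observed.any():
        raise ValueError("cannot impute: no observed coast distances")
    xy = cells[["x_km", "y_km"]].to_numpy(dtype=float)
    d = cdist(xy[missing], xy[observed])
    k = min(n_neighbors, observed.sum())
    nn = np.argsort(d, axis=1)[:, :k]
    rows = np.arange(d.shape[0])[:, None]
    dn = d[rows, nn]
    vals = coast[observed][nn]
    # exact spatial coincidence wins outright; otherwise IDW over the donors
    exact = dn == 0
    w = np.zeros_like(dn)
    hit = exact.any(axis=1)
    w[hit] = exact[hit]
    w[~hit] = 1.0 / dn[~hit] ** power
    coast[missing] = (w * vals).sum(axis=1) / w.sum(axis=1)
    out = cells.copy()
    out["coast_km"] = coast
    return GridLandscape(cells=out, nx=landscape.nx, ny=landscape.ny,
                         resolution_km=landscape.resolution_km)


def zstandardize(features) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-transform each column to mean 0, population sd 1.

    Raises on any zero-variance column, naming it.
    """
    X = np.asarray(features, dtype=float)
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
    else:
        names = [f"col{i}" for i in range(X.shape[1])]
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise ValueError(f"zero-variance column(s): {[names[i] for i in zero]}")
    return (X - means) / sds, means, sds


def _relabel_by_size(labels0: np.ndarray, centers: np.ndarray):
    """Map arbitrary k-means labels to 1..k by descending cluster size.

    Ties in size break on lexicographic centroid order, so the relabelling is
    invariant to input row order.
    """
    k = centers.shape[0]
    counts = np.bincount(labels0, minlength=k)
    order = sorted(range(k), key=lambda j: (-counts[j], tuple(centers[j])))
    mapping = np.empty(k, dtype=int)
    for new, old in enumerate(order, start=1):
        mapping[old] = new
    return mapping[labels0], centers[order]


def fit_kmeans(standardized, k: int, seed: int = 0, n_init: int = 10):
    """Best-of-``n_init`` Lloyd k-means with k-means++ starts.

    Returns ``(labels 1..k, centroids, inertia)`` with clusters relabelled by
    descending size.
    """
    X = np.asarray(standardized, dtype=float)
    if k > len(np.unique(X, axis=0)):
        raise ValueError("k exceeds the number of distinct rows")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                random_state=seed, algorithm="lloyd").fit(X)
    labels, centers = _relabel_by_size(km.labels_, km.cluster_centers_)
    return labels, centers, float(km.inertia_)


def select_k(standardized, k_candidates, seed: int = 0, n_init: int = 10,
             plateau_tol: float = 0.01):
    """Mean silhouette per candidate k; pick the silhouette plateau's start.

    Candidates below 6 are rejected: fewer zones are considered too coarse to
    resolve the elevational/coastal gradients the zoning is meant to capture.
    ``k*`` is the smallest candidate whose silhouette is within
    ``plateau_tol`` (relative) of the best.
    """
    k_candidates = sorted(int(k) for k in k_candidates)
    if any(k < MIN_K for k in k_candidates):
        raise ValueError(f"candidate k below {MIN_K} is not allowed "
                         "(zoning requires at least six clusters)")
    X = np.asarray(standardized, dtype=float)
    sil = {}
    for k in k_candidates:
        labels, _, _ = fit_kmeans(X, k, seed=seed, n_init=n_init)
        sil[k] = float(silhouette_score(X, labels))
    best = max(sil.values())
    k_star = next(k for k in k_candidates if sil[k] >= (1 - plateau_tol) * best)
    table = pd.DataFrame({"k": list(sil), "silhouette": list(sil.values())})
    return k_star, table


class EnvironmentalZoner(ClusterMixin, BaseEstimator):
    """Z-standardized k-means zoning of land cells on static geography.

    Parameters
    ----------
    k : int, default 9
        Number of zones.  Ignored when ``k_candidates`` is given.
    k_candidates : sequence of int, optional
        When set, k is chosen by the silhouette-plateau rule over these
        candidates (all must be >= 6).
    n_init : int, default 10
        k-means restarts; best inertia wins.
    random_state : int, default 0

    Attributes
    ----------
    k_ : selected number of clusters
    labels_ : per-row labels in 1..k, relabelled by descending cluster size
    cluster_centers_ : (k, n_features) centroids in z-space, label order
    feature_means_, feature_sds_ : standardization constants (population sd)
    inertia_ : within-cluster sum of squares of the winning fit
    silhouette_by_k_ : DataFrame, only when ``k_candidates`` was used
    """

    def __init__(self, k: int = 9, k_candidates=None, n_init: int = 10,
                 random_state: int = 0, plateau_tol: float = 0.01):
        self.k = k
        self.k_candidates = k_candidates
        self.n_init = n_init
        self.random_state = random_state
        self.plateau_tol = plateau_tol

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (cells x static variables)")
        Z, means, sds = zstandardize(X)
        self.feature_means_ = means
        self.feature_sds_ = sds
        if self.k_candidates is not None:
            k, table = select_k(Z, self.k_candidates, seed=self.random_state,
                                n_init=self.n_init, plateau_tol=self.plateau_tol)
            self.silhouette_by_k_ = table
        else:
            k = int(self.k)
        self.k_ = k
        self.labels_, self.cluster_centers_, self.inertia_ = fit_kmeans(
            Z, k, seed=self.random_state, n_init=self.n_init)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        Z = (np.asarray(X, dtype=float) - self.feature_means_) / self.feature_sds_
        return cdist(Z, self.cluster_centers_).argmin(axis=1) + 1

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def zone_landscape(landscape: GridLandscape, k: int = 9, k_candidates=None,
                   seed: int = 0, n_init: int = 10):
    """Impute coast distance, then fit an :class:`EnvironmentalZoner`.

    Returns ``(zoner, labels)`` where ``labels`` is a per-cell Series over the
    full lattice (NaN on sea cells, 1..k on land).
    """
    landscape = impute_coast_distance(landscape)
    land = landscape.land
    X = land[list(STATIC_VARS)]
    zoner = EnvironmentalZoner(k=k, k_candidates=k_candidates,
                               random_state=seed, n_init=n_init).fit(X)
    labels = pd.Series(np.nan, index=landscape.cells.index, name="cluster")
    labels.loc[land.index] = zoner.labels_
    return zoner, labels


def cluster_profiles(labels: np.ndarray, landscape: GridLandscape) -> pd.DataFrame:
    """Per-cluster raw means and z-score means of the static variables.

    ``labels`` aligns with the land cells of ``landscape`` (after imputation).
    z-scores use the land-wide population mean/sd, so the cell-count-weighted
    mean of cluster z-scores is 0 per variable.
    """
    land = impute_coast_distance(landscape).land
    X = land[list(STATIC_VARS)].to_numpy(dtype=float)
    Z, _, _ = zstandardize(X)
    labels = np.asarray(labels)
    rows = []
    for lab in np.unique(labels):
        sel = labels == lab
        row = {"cluster": int(lab), "n_cells": int(sel.sum()),
               "area_km2": float(sel.sum() * landscape.cell_area_km2)}
        for j, var in enumerate(STATIC_VARS):
            row[f"mean_{var}"] = float(X[sel, j].mean())
            row[f"z_{var}"] = float(Z[sel, j].mean())
        rows.append(row)
    return pd.DataFrame(rows).sort_values("cluster").reset_index(drop=True)
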