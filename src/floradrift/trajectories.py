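"""Compositional trajectory analysis in ordination space.

Binary Bray–Curtis dissimilarities among (cell, period) community vectors are
embedded by principal coordinates analysis with a Lingoes correction for
negative eigenvalues.  Within each environmental cluster, replicates of 20
cells sampled without replacement trace a centroid path across the four
periods; each path is summarized by its length L, directionality D (net
displacement over L) and internal variation V (standard deviation of turning
angles).  Environmental vectors fitted to the ordination plane give, per
replicate and variable, the alignment cos(dtheta) between the trajectory's
net displacement and the gradient, and the scaled alignment L*cos(dtheta).
PERMANOVA (sequential McArdle–Anderson partition) and PERMDISP provide
permutation inference on cluster and period effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.linalg import eigsh
from scipy.spatial.distance import pdist, squareform

from ._utils import rng_from
from .containers import ClimateCube, GridLandscape, PresenceCube

DEFAULT_ENV_VARS = ("lat_deg", "lon_deg", "iso", "pdm_mm")

_STATIC_ENV = ("lat_deg", "lon_deg", "elevation_m", "coast_km",
               "x_km", "y_km")


# ---------------------------------------------------------------------------
# dissimilarity

def bray_curtis_binary(X) -> np.ndarray:
    """Pairwise binary Bray–Curtis distances, d = sum|a-b| / sum(a+b).

    On presence–absence rows this equals the Sørensen dissimilarity
    1 - 2a/(2a+b+c).  Rows must be non-empty; route empty rows through
    :func:`filter_cells` first.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (entities x species)")
    if (X.sum(axis=1) == 0).any():
        raise ValueError("zero-sum row(s): Bray-Curtis is undefined for empty "
                         "communities; drop them with filter_cells")
    return squareform(pdist(X, metric="braycurtis"))


def filter_cells(cube: PresenceCube, scenario: str) -> np.ndarray:
    """Cell positions eligible for trajectories under one scenario.

    Eligible cells have complete predictions and at least one species present
    in every period (Bray–Curtis is undefined on empty communities).
    """
    ok = np.ones(len(cube.cell_ids), dtype=bool)
    for per in cube.periods:
        ok &= cube.richness(scenario, per) >= 1
    return np.flatnonzero(ok)


def subsample_replicates(eligible_by_cluster: dict, n_cells: int = 20,
                         n_reps: int = 30, seed: int = 0) -> dict:
    """Per cluster, ``n_reps`` seeded draws of ``n_cells`` cells w/o replacement.

    Clusters with fewer than ``n_cells`` eligible cells are skipped with a
    warning.  Replicate r of cluster c uses the child stream (seed, c, r), so
    any subset of replicates is reproducible in isolation.
    """
    out = {}
    for cl, cells in sorted(eligible_by_cluster.items()):
        cells = np.asarray(cells)
        if cells.size < n_cells:
            warnings.warn(f"cluster {cl}: only {cells.size} eligible cells "
                          f"(< {n_cells}); skipped", stacklevel=2)
            continue
        out[cl] = [np.sort(rng_from(seed, "subsample", cl, r)
                           .choice(cells, size=n_cells, replace=False))
                   for r in range(n_reps)]
    return out


# ---------------------------------------------------------------------------
# ordination

def _gower_center(D2: np.ndarray) -> np.ndarray:
    n = D2.shape[0]
    A = -0.5 * D2
    rm = A.mean(axis=1, keepdims=True)
    return A - rm - rm.T + A.mean()


class LingoesPCoA:
    """Principal coordinates analysis with Lingoes correction.

    The Gower-centered matrix of ``-d^2/2`` is eigendecomposed; if the
    smallest eigenvalue is below ``-tol`` the Lingoes constant c = -lambda_min
    is added to all squared off-diagonal dissimilarities (d'^2 = d^2 + 2c) and
    the decomposition is redone, making the configuration fully Euclidean.

    Parameters
    ----------
    n_components : int or None
        Retained axes; None keeps every positive-eigenvalue axis (dense
        solver only).
    solver : {'auto', 'dense', 'arpack'}
        'arpack' computes only the extreme eigenpairs and needs
        ``n_components``; 'auto' switches to arpack above 1,200 entities.
    tol : float
        Negative-eigenvalue tolerance.

    Attributes
    ----------
    coordinates_ : (n, m) scores, axes by descending eigenvalue, each axis
        signed so its largest-magnitude entry is positive
    eigenvalues_ : eigenvalues of the (corrected) Gower matrix, descending
    lingoes_c_ : the additive constant applied (0 when none was needed)
    """

    def __init__(self, n_components: int | None = None, solver: str = "auto",
                 tol: float = 1e-8):
        self.n_components = n_components
        self.solver = solver
        self.tol = tol

    def get_params(self, deep=True):
        return {"n_components": self.n_components, "solver": self.solver,
                "tol": self.tol}

    def set_params(self, **p):
        for k, v in p.items():
            setattr(self, k, v)
        return self

    def _decompose(self, G: np.ndarray, dense: bool):
        if dense:
            lam, vec = np.linalg.eigh(G)
            return lam[::-1], vec[:, ::-1]
        k = max(self.n_components + 2, 4)
        lam_hi, vec_hi = eigsh(G, k=min(k, G.shape[0] - 1), which="LA")
        order = np.argsort(lam_hi)[::-1]
        lam_lo = eigsh(G, k=1, which="SA", return_eigenvectors=False)
        return (np.concatenate([lam_hi[order], lam_lo]),
                vec_hi[:, order])

    def fit(self, D):
        D = np.asarray(D, dtype=float)
        n = D.shape[0]
        if D.ndim != 2 or D.shape[1] != n:
            raise ValueError("D must be a square distance matrix")
        if n < 3:
            raise ValueError("need at least 3 entities")
        dense = (self.solver == "dense"
                 or (self.solver == "auto"
                     and (n <= 1200 or self.n_components is None)))
        if not dense and self.n_components is None:
            raise ValueError("arpack solver requires n_components")
        D2 = D**2
        lam, vec = self._decompose(_gower_center(D2), dense)
        c = 0.0
        if lam[-1] < -self.tol:
            c = -float(lam[-1])
            D2c = D2 + 2.0 * c
            np.fill_diagonal(D2c, 0.0)
            lam, vec = self._decompose(_gower_center(D2c), dense)
        self.lingoes_c_ = c
        lam = np.where(np.abs(lam) < self.tol, 0.0, lam)
        self.eigenvalues_ = lam
        pos = np.flatnonzero(lam[: vec.shape[1]] > 0)
        m = len(pos) if self.n_components is None else min(self.n_components,
                                                           len(pos))
        coords = vec[:, pos[:m]] * np.sqrt(lam[pos[:m]])
        # deterministic sign: largest-|value| entry of each axis positive
        for j in range(coords.shape[1]):
            i = np.argmax(np.abs(coords[:, j]))
            if coords[i, j] < 0:
                coords[:, j] = -coords[:, j]
        self.coordinates_ = coords
        return self

    def fit_transform(self, D):
        return self.fit(D).coordinates_


def pcoa_lingoes(D, n_components: int | None = None, solver: str = "auto"):
    """Functional wrapper: returns (coordinates, eigenvalues, lingoes_c)."""
    m = LingoesPCoA(n_components=n_components, solver=solver).fit(D)
    return m.coordinates_, m.eigenvalues_, m.lingoes_c_


# ---------------------------------------------------------------------------
# trajectory geometry

def trajectory_metrics(points) -> tuple[float, float, float]:
    """Length L, directionality D and internal variation V of a path.

    L is the cumulative Euclidean distance over successive points; D the net
    displacement divided by L (NaN when L = 0); V the sample standard
    deviation, in degrees, of the unsigned turning angles between successive
    non-degenerate segments (NaN with fewer than two angles).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 ordered points")
    seg = np.diff(pts, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    L = float(lens.sum())
    net = float(np.linalg.norm(pts[-1] - pts[0]))
    D = net / L if L > 0 else float("nan")
    live = seg[lens > 0]
    angles = []
    for a, b in zip(live[:-1], live[1:]):
        cosang = np.clip(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)),
                         -1.0, 1.0)
        angles.append(np.degrees(np.arccos(cosang)))
    V = float(np.std(angles, ddof=1)) if len(angles) >= 2 else float("nan")
    return L, D, V


def alignment(points, env_direction) -> tuple[float, float]:
    """cos(dtheta) between a path's net displacement and an environmental
    vector, and the scaled alignment A = L * cos(dtheta).

    Positive values mean compositional change proceeds along the gradient,
    negative against it.  Zero net displacement yields NaN with a warning.
    """
    pts = np.asarray(points, dtype=float)
    net = pts[-1] - pts[0]
    norm = np.linalg.norm(net)
    L, _, _ = trajectory_metrics(pts)
    if norm == 0:
        warnings.warn("zero net displacement: alignment undefined", stacklevel=2)
        return float("nan"), float("nan")
    u = np.asarray(env_direction, dtype=float)
    u = u / np.linalg.norm(u)
    cos = float(np.clip(np.dot(net / norm, u), -1.0, 1.0))
    return cos, L * cos


def dominant_driver(scaled_alignments: dict, order=None) -> str | None:
    """Variable with the largest |scaled alignment|; ties break on ``order``."""
    finite = {k: v for k, v in scaled_alignments.items() if np.isfinite(v)}
    if not finite:
        return None
    order = list(order) if order is not None else list(scaled_alignments)
    candidates = [k for k in order if k in finite]
    return max(candidates, key=lambda k: (abs(finite[k]), -order.index(k)))


def interval_turnover(occ_by_period) -> pd.DataFrame:
    """Per-cell Bray–Curtis between consecutive periods.

    ``occ_by_period`` is a sequence of (cells x species) binary matrices with
    identical cell order; returns a long frame with columns
    ``interval, cell, bc``.
    """
    rows = []
    for t in range(len(occ_by_period) - 1):
        a = np.asarray(occ_by_period[t], dtype=float)
        b = np.asarray(occ_by_period[t + 1], dtype=float)
        denom = (a + b).sum(axis=1)
        if (denom == 0).any():
            raise ValueError("empty community pair: Bray-Curtis undefined")
        bc = np.abs(a - b).sum(axis=1) / denom
        rows.append(pd.DataFrame({"interval": t, "cell": np.arange(len(bc)),
                                  "bc": bc}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# envfit

def fit_env_vectors(scores, env: pd.DataFrame, n_perm: int = 999,
                    seed: int = 0) -> pd.DataFrame:
    """Least-squares environmental vectors in the 2-D ordination plane.

    Each variable is regressed on the two axes; the normalized coefficient
    vector is the gradient direction, r² the coefficient of determination and
    the p-value a permutation tail probability (add-one convention) from
    shuffling the variable across entities.  Constant variables are reported
    with r² = 0 and ``degenerate=True``.
    """
    S = np.asarray(scores, dtype=float)[:, :2]
    n = S.shape[0]
    X = np.column_stack([np.ones(n), S])
    Q, _ = np.linalg.qr(X)
    P = Q @ Q.T
    C = P - np.full((n, n), 1.0 / n)   # r2 numerator quadratic form
    rng = rng_from(seed, "envfit")
    rows = []
    for var in env.columns:
        v = env[var].to_numpy(dtype=float)
        sst = float(((v - v.mean()) ** 2).sum())
        if sst == 0:
            rows.append({"variable": var, "dx": 0.0, "dy": 0.0, "r2": 0.0,
                         "p": float("nan"), "degenerate": True})
            continue
        beta = np.linalg.lstsq(X, v, rcond=None)[0]
        direction = beta[1:]
        nrm = np.linalg.norm(direction)
        direction = direction / nrm if nrm > 0 else direction
        r2 = float(v @ C @ v / sst)
        if n_perm > 0:
            perms = np.stack([rng.permutation(v) for _ in range(n_perm)])
            r2p = np.einsum("pn,nm,pm->p", perms, C, perms) / sst
            p = (1.0 + (r2p >= r2 - 1e-12).sum()) / (1.0 + n_perm)
        else:
            p = float("nan")
        rows.append({"variable": var, "dx": float(direction[0]),
                     "dy": float(direction[1]), "r2": r2, "p": p,
                     "degenerate": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# permutation inference

def _dummy(levels: np.ndarray) -> np.ndarray:
    cats = pd.unique(levels)
    return (levels[:, None] == cats[None, :]).astype(float)


def _hat(X: np.ndarray) -> np.ndarray:
    Q, R = np.linalg.qr(X)
    keep = np.abs(np.diag(R)) > 1e-10
    Q = Q[:, keep]
    return Q @ Q.T


def permanova(D, factors: pd.DataFrame, order=None, interaction: bool = False,
              n_perm: int = 9999, seed: int = 0) -> pd.DataFrame:
    """Sequential (Type-I) distance-based PERMANOVA, McArdle–Anderson form.

    ``factors`` holds one column per factor; ``order`` fixes the sequential
    entry order (default: column order).  p-values come from free permutation
    of entities with the add-one convention.  Returns one row per factor plus
    Residual and Total, with columns ``df, ss, r2, pseudo_f, p``.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    order = list(order) if order is not None else list(factors.columns)
    for f in order:
        if factors[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has a single level")
    G = _gower_center(D**2)
    ss_total = float(np.trace(G))

    terms = list(order)
    designs = []
    X = np.ones((n, 1))
    for f in order:
        X = np.column_stack([X, _dummy(factors[f].to_numpy())])
        designs.append(X.copy())
    if interaction:
        if len(order) != 2:
            raise ValueError("interaction requires exactly two factors")
        inter = np.einsum("ni,nj->nij",
                          _dummy(factors[order[0]].to_numpy()),
                          _dummy(factors[order[1]].to_numpy())).reshape(n, -1)
        designs.append(np.column_stack([designs[-1], inter]))
        terms.append(f"{order[0]}:{order[1]}")

    hats = [_hat(X) for X in designs]
    dfs, deltas = [], []
    prev_hat = np.full((n, n), 1.0 / n)
    prev_rank = 1
    for H in hats:
        rank = int(round(np.trace(H)))
        dfs.append(rank - prev_rank)
        deltas.append(H - prev_hat)
        prev_hat, prev_rank = H, rank
    resid_proj = np.eye(n) - hats[-1]
    df_res = n - prev_rank

    def _stats(Gm):
        ss = np.array([float((d * Gm).sum()) for d in deltas])
        ss_res = float((resid_proj * Gm).sum())
        ms_res = ss_res / df_res
        F = (ss / np.array(dfs)) / ms_res
        return ss, ss_res, F

    ss, ss_res, F_obs = _stats(G)
    rng = rng_from(seed, "permanova")
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        p = rng.permutation(n)
        _, _, Fp = _stats(G[np.ix_(p, p)])
        exceed += Fp >= F_obs - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm) if n_perm > 0 else [float("nan")] * len(terms)

    rows = []
    for i, t in enumerate(terms):
        rows.append({"term": t, "df": dfs[i], "ss": ss[i],
                     "r2": ss[i] / ss_total, "pseudo_f": F_obs[i],
                     "p": float(pvals[i])})
    rows.append({"term": "Residual", "df": df_res, "ss": ss_res,
                 "r2": ss_res / ss_total, "pseudo_f": float("nan"),
                 "p": float("nan")})
    rows.append({"term": "Total", "df": n - 1, "ss": ss_total, "r2": 1.0,
                 "pseudo_f": float("nan"), "p": float("nan")})
    return pd.DataFrame(rows)


def permdisp(D, groups, n_perm: int = 999, seed: int = 0):
    """Homogeneity of multivariate dispersions (distance to group centroid).

    Entities are embedded by PCoA keeping real and imaginary axes; per-entity
    distances to the group centroid combine the two parts as
    z^2 = d_real^2 - d_imag^2 (floored at 0).  F is the one-way ANOVA
    statistic on z; the p-value permutes group labels.  Returns
    ``(F, p, dispersions)`` where ``dispersions`` maps group -> mean z.
    A fully degenerate configuration (all z = 0) yields NaN F and p.
    """
    D = np.asarray(D, dtype=float)
    groups = np.asarray(groups)
    labs, counts = np.unique(groups, return_counts=True)
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 entities")
    lam, vec = np.linalg.eigh(_gower_center(D**2))
    lam, vec = lam[::-1], vec[:, ::-1]
    tol = 1e-10 * max(1.0, abs(lam[0]))
    re = vec[:, lam > tol] * np.sqrt(lam[lam > tol])
    im = vec[:, lam < -tol] * np.sqrt(-lam[lam < -tol])

    def _z(lab_vec):
        z2 = np.zeros(len(lab_vec))
        for g in np.unique(lab_vec):
            sel = lab_vec == g
            dr = ((re[sel] - re[sel].mean(axis=0)) ** 2).sum(axis=1)
            di = ((im[sel] - im[sel].mean(axis=0)) ** 2).sum(axis=1) if im.size else 0.0
            z2[sel] = np.maximum(dr - di, 0.0)
        return np.sqrt(z2)

    def _f(z, lab_vec):
        grand = z.mean()
        ssb = ssw = 0.0
        for g in labs:
            sel = lab_vec == g
            ssb += sel.sum() * (z[sel].mean() - grand) ** 2
            ssw += ((z[sel] - z[sel].mean()) ** 2).sum()
        dfb, dfw = len(labs) - 1, len(z) - len(labs)
        if ssw == 0:
            return float("nan")
        return (ssb / dfb) / (ssw / dfw)

    z = _z(groups)
    disp = {g: float(z[groups == g].mean()) for g in labs}
    if np.allclose(z, 0.0, atol=1e-10):   # all entities sit on their centroid
        return float("nan"), float("nan"), disp
    F = _f(z, groups)
    if not np.isfinite(F):
        return float("nan"), float("nan"), disp
    rng = rng_from(seed, "permdisp")
    exceed = 0
    for _ in range(n_perm):
        gp = rng.permutation(groups)
        Fp = _f(_z(gp), gp)
        if np.isfinite(Fp) and Fp >= F - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return float(F), float(p), disp


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class TrajectoryAnalysis:
    """All trajectory outputs for one scenario."""

    scenario: str
    entities: pd.DataFrame          # cell position, cell_id, period per row
    scores: np.ndarray              # entity coordinates in the reference plane
    lingoes_c: float
    env_vectors: pd.DataFrame
    trajectories: pd.DataFrame      # cluster, replicate, L, D, V
    alignments: pd.DataFrame        # cluster, replicate, variable, cos, A, dominant
    turnover: pd.DataFrame          # cluster, replicate, interval, median/iqr
    permanova: pd.DataFrame | None = None
    permdisp: tuple | None = None
    replicate_paths: dict = field(default_factory=dict)


def _entity_env(var, positions, landscape, climate, scenario, period):
    if var in _STATIC_ENV:
        return landscape.cells[var].to_numpy(dtype=float)[positions]
    return climate.field(var, scenario, period)[positions]


def run_trajectory_analysis(cube: PresenceCube, labels, landscape: GridLandscape,
                            climate: ClimateCube, scenario: str,
                            n_cells: int = 20, n_reps: int = 30,
                            env_vars=DEFAULT_ENV_VARS, n_perm_env: int = 999,
                            n_perm_permanova: int = 9999,
                            n_perm_permdisp: int = 999,
                            do_permanova: bool = True, seed: int = 0
                            ) -> TrajectoryAnalysis:
    """End-to-end trajectory analysis for one scenario.

    A single reference PCoA is fitted to the union of all sampled cells
    across the four periods, so every replicate trajectory lives in the same
    plane; per replicate the path is the per-period mean of its cells'
    scores.
    """
    labels = np.asarray(labels, dtype=float)
    eligible = filter_cells(cube, scenario)
    by_cluster = {}
    for cl in np.unique(labels[~np.isnan(labels)]).astype(int):
        cells = eligible[labels[eligible] == cl]
        by_cluster[int(cl)] = cells
    reps = subsample_replicates(by_cluster, n_cells=n_cells, n_reps=n_reps,
                                seed=seed)
    if not reps:
        raise ValueError("no cluster has enough eligible cells")
    union = np.unique(np.concatenate([r for sets in reps.values() for r in sets]))
    periods = cube.periods

    ent_pos, ent_per = [], []
    blocks = []
    for per in periods:
        M = cube.matrix(scenario, per)[union]
        blocks.append(M)
        ent_pos.append(union)
        ent_per.append(np.full(union.size, per, dtype=object))
    occ = np.vstack(blocks)
    positions = np.concatenate(ent_pos)
    entity_periods = np.concatenate(ent_per)
    D = bray_curtis_binary(occ)
    pc = LingoesPCoA(n_components=2, solver="auto").fit(D)
    scores = pc.coordinates_

    env = pd.DataFrame({
        var: np.concatenate([
            _entity_env(var, union, landscape, climate, scenario, per)
            for per in periods])
        for var in env_vars})
    env_std = (env - env.mean()) / env.std(ddof=0)
    vectors = fit_env_vectors(scores, env_std, n_perm=n_perm_env,
                              seed=seed)
    directions = {r.variable: np.array([r.dx, r.dy])
                  for r in vectors.itertuples() if not r.degenerate}

    pos_index = {c: i for i, c in enumerate(union)}
    traj_rows, align_rows, turn_rows = [], [], []
    paths = {}
    for cl, sets in reps.items():
        for r, cells in enumerate(sets):
            rows_idx = np.array([pos_index[c] for c in cells])
            path = np.stack([
                scores[t * union.size + rows_idx].mean(axis=0)
                for t in range(len(periods))])
            paths[(cl, r)] = path
            L, Dm, V = trajectory_metrics(path)
            traj_rows.append({"cluster": cl, "scenario": scenario,
                              "replicate": r, "L": L, "D": Dm, "V": V})
            scaled = {}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for var, u in directions.items():
                    cos, A = alignment(path, u)
                    scaled[var] = A
                    align_rows.append({"cluster": cl, "scenario": scenario,
                                       "replicate": r, "variable": var,
                                       "cos_dtheta": cos,
                                       "scaled_alignment": A})
            dom = dominant_driver(scaled, order=list(env_vars))
            for row in align_rows[-len(directions):]:
                row["dominant"] = row["variable"] == dom
            occ_by_period = [cube.matrix(scenario, per)[cells] for per in periods]
            tv = interval_turnover(occ_by_period)
            for t, grp in tv.groupby("interval"):
                q1, med, q3 = np.percentile(grp["bc"], [25, 50, 75])
                turn_rows.append({
                    "cluster": cl, "scenario": scenario, "replicate": r,
                    "interval": f"{periods[t]}-{periods[t + 1]}",
                    "median_bc": float(med), "iqr_bc": float(q3 - q1)})

    perm_res = None
    disp_res = None
    if do_permanova:
        factors = pd.DataFrame({
            "cluster": labels[positions].astype(int).astype(str),
            "period": entity_periods.astype(str)})
        perm_res = permanova(D, factors, order=["cluster", "period"],
                             n_perm=n_perm_permanova, seed=seed)
        disp_res = permdisp(D, entity_periods.astype(str),
                            n_perm=n_perm_permdisp, seed=seed)

    entities = pd.DataFrame({
        "position": positions,
        "cell_id": cube.cell_ids[positions],
        "period": entity_periods,
        "cluster": labels[positions].astype(int)})
    return TrajectoryAnalysis(
        scenario=scenario, entities=entities, scores=scores,
        lingoes_c=pc.lingoes_c_, env_vectors=vectors,
        trajectories=pd.DataFrame(traj_rows),
        alignments=pd.DataFrame(align_rows),
        turnover=pd.DataFrame(turn_rows),
        permanova=perm_res, permdisp=disp_res, replicate_paths=paths)
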