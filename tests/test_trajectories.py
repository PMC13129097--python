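"""Bray-Curtis, PCoA/Lingoes, trajectory metrics, envfit, PERMANOVA/PERMDISP."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

import floradrift as fd
from floradrift.trajectories import (LingoesPCoA, _gower_center,
                                     bray_curtis_binary, filter_cells,
                                     interval_turnover, subsample_replicates,
                                     trajectory_metrics)


class TestBrayCurtis:
    @pytest.mark.parametrize("a,b,expected", [
        ([1, 1, 0, 0], [1, 0, 1, 0], 0.5),
        ([1, 0, 1], [1, 0, 1], 0.0),
        ([1, 1, 0], [0, 0, 1], 1.0),
    ])
    def test_hand_examples(self, a, b, expected):
        D = bray_curtis_binary(np.array([a, b]))
        assert D[0, 1] == pytest.approx(expected)
        assert D[1, 0] == D[0, 1] and D[0, 0] == 0

    def test_zero_row_errors_with_pointer(self):
        with pytest.raises(ValueError, match="filter_cells"):
            bray_curtis_binary(np.array([[1, 0], [0, 0]]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**30 - 1))
    def test_sorensen_identity_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 2, size=(6, 12))
        X[X.sum(axis=1) == 0, 0] = 1
        D = bray_curtis_binary(X)
        for i in range(6):
            for j in range(i + 1, 6):
                a = int((X[i] & X[j]).sum())
                b = int((X[i] & ~X[j]).sum())
                c = int((~X[i] & X[j]).sum())
                assert D[i, j] == pytest.approx(1 - 2 * a / (2 * a + b + c))


class TestFilterCells:
    def test_cell_with_empty_period_excluded(self, cube):
        eligible = filter_cells(cube, "585")
        r = np.minimum.reduce([cube.richness("585", p) for p in cube.periods])
        np.testing.assert_array_equal(eligible, np.flatnonzero(r >= 1))

    def test_fully_occupied_cube_keeps_all_land(self, landscape):
        occ = np.ones((2, len(landscape.cells), 1, 4), dtype=np.uint8)
        occ[:, ~landscape.land_mask] = 0
        cube = fd.PresenceCube(occ, ("a", "b"),
                               landscape.cells["cell_id"].to_numpy(),
                               scenarios=("585",),
                               periods=("Current", "1140", "4170", "7100"))
        assert len(filter_cells(cube, "585")) == landscape.land_mask.sum()


class TestSubsample:
    def test_exactly_enough_cells_forces_identical_sets(self):
        reps = subsample_replicates({1: np.arange(20)}, n_cells=20, n_reps=5,
                                    seed=0)
        for r in reps[1]:
            np.testing.assert_array_equal(r, np.arange(20))

    def test_no_duplicates_within_replicate(self):
        reps = subsample_replicates({1: np.arange(100)}, n_cells=20,
                                    n_reps=10, seed=1)
        for r in reps[1]:
            assert len(np.unique(r)) == 20

    def test_seed_determinism(self):
        a = subsample_replicates({1: np.arange(50), 2: np.arange(60)}, seed=3)
        b = subsample_replicates({1: np.arange(50), 2: np.arange(60)}, seed=3)
        for cl in a:
            for x, y in zip(a[cl], b[cl]):
                np.testing.assert_array_equal(x, y)

    def test_small_cluster_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            reps = subsample_replicates({1: np.arange(5)}, n_cells=20)
        assert reps == {}


class TestPCoA:
    def test_collinear_points_recover_line(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        D = squareform(pdist(pts))
        m = LingoesPCoA().fit(D)
        assert m.lingoes_c_ == 0.0
        ax1 = m.coordinates_[:, 0]
        assert np.allclose(ax1, [-1, 0, 1]) or np.allclose(ax1, [1, 0, -1])

    def test_euclidean_input_needs_no_correction(self, rng):
        D = squareform(pdist(rng.normal(size=(15, 4))))
        m = LingoesPCoA().fit(D)
        assert m.lingoes_c_ == 0.0

    def test_roundtrip_reproduces_corrected_distances(self, rng):
        X = rng.integers(0, 2, size=(18, 10))
        X[X.sum(axis=1) == 0, 0] = 1
        D = bray_curtis_binary(X)
        m = LingoesPCoA().fit(D)
        emb = squareform(pdist(m.coordinates_))
        target = np.sqrt(D**2 + 2 * m.lingoes_c_)
        np.fill_diagonal(target, 0.0)
        np.testing.assert_allclose(emb, target, atol=1e-8)

    def test_corrected_eigenvalues_non_negative(self, rng):
        X = rng.integers(0, 2, size=(20, 6))
        X[X.sum(axis=1) == 0, 0] = 1
        m = LingoesPCoA().fit(bray_curtis_binary(X))
        assert m.eigenvalues_.min() >= -1e-9

    def test_matches_skbio_on_euclidean_data(self, rng):
        skbio = pytest.importorskip("skbio")
        X = rng.normal(size=(12, 3))
        D = squareform(pdist(X))
        ours = LingoesPCoA().fit(D)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D))
        np.testing.assert_allclose(
            ours.eigenvalues_[:3], ref.eigvals.to_numpy()[:3], atol=1e-8)

    def test_arpack_agrees_with_dense_on_plane(self, rng):
        X = rng.integers(0, 2, size=(40, 8))
        X[X.sum(axis=1) == 0, 0] = 1
        D = bray_curtis_binary(X)
        a = LingoesPCoA(n_components=2, solver="dense").fit(D)
        b = LingoesPCoA(n_components=2, solver="arpack").fit(D)
        np.testing.assert_allclose(np.abs(a.coordinates_),
                                   np.abs(b.coordinates_), atol=1e-7)
        assert a.lingoes_c_ == pytest.approx(b.lingoes_c_, abs=1e-9)

    def test_too_few_entities(self):
        with pytest.raises(ValueError):
            LingoesPCoA().fit(np.zeros((2, 2)))


class TestTrajectoryMetrics:
    def test_straight_path(self):
        L, D, V = trajectory_metrics([(0, 0), (1, 0), (2, 0), (3, 0)])
        assert (L, D, V) == (3.0, 1.0, 0.0)

    def test_l_shaped_path(self):
        L, D, V = trajectory_metrics([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert L == pytest.approx(3.0)
        assert D == pytest.approx(1 / 3)
        assert V == pytest.approx(0.0)  # both turns are 90 degrees

    def test_diagonal_path_oracle(self):
        L, D, V = trajectory_metrics([(0, 0), (1, 0), (2, 1), (3, 1)])
        assert L == pytest.approx(2 + np.sqrt(2))
        assert D == pytest.approx(np.sqrt(10) / (2 + np.sqrt(2)))
        assert V == pytest.approx(0.0)  # 45 degrees twice

    def test_zero_length_segments_skipped(self):
        L, D, V = trajectory_metrics([(0, 0), (0, 0), (1, 0), (2, 0)])
        assert L == 2.0 and D == 1.0
        assert np.isnan(V)  # only one live turning angle

    def test_stationary_path_gives_nan_directionality(self):
        L, D, V = trajectory_metrics([(1, 1), (1, 1), (1, 1)])
        assert L == 0.0 and np.isnan(D)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            trajectory_metrics([(0, 0), (1, 1)])


class TestAlignment:
    def test_parallel_vector(self):
        path = [(0, 0), (1.5, 0), (3, 0)]
        cos, A = fd.alignment(path, (1, 0))
        assert cos == 1.0 and A == pytest.approx(3.0)

    def test_orthogonal_vector(self):
        cos, A = fd.alignment([(0, 0), (0.5, 0), (1, 0)], (0, 1))
        assert cos == pytest.approx(0.0, abs=1e-12)
        assert A == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_hand_trigonometry(self):
        # net (1,1) with total length 3: x + sqrt((1-x)^2+1) = 3 at x = 1.75
        path = [(0, 0), (1.75, 0), (1, 1)]
        cos, A = fd.alignment(path, (1, 0))
        assert cos == pytest.approx(np.sqrt(2) / 2)
        assert A == pytest.approx(3 * np.sqrt(2) / 2)

    def test_zero_net_displacement_warns_nan(self):
        with pytest.warns(UserWarning):
            cos, A = fd.alignment([(0, 0), (1, 0), (0, 0)], (1, 0))
        assert np.isnan(cos) and np.isnan(A)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 2**30 - 1))
    def test_scaled_alignment_bounded_by_length(self, seed):
        rng = np.random.default_rng(seed)
        path = rng.normal(size=(4, 2))
        u = rng.normal(size=2)
        if np.linalg.norm(path[-1] - path[0]) == 0 or np.linalg.norm(u) == 0:
            return
        L, _, _ = trajectory_metrics(path)
        _, A = fd.alignment(path, u)
        assert abs(A) <= L + 1e-12


class TestDominantDriver:
    def test_largest_absolute_wins(self):
        assert fd.dominant_driver({"lat": 2.0, "elev": -2.5}) == "elev"

    def test_single_variable(self):
        assert fd.dominant_driver({"iso": 0.1}) == "iso"

    def test_tie_breaks_on_configured_order(self):
        out = fd.dominant_driver({"a": -1.0, "b": 1.0}, order=["b", "a"])
        assert out == "b"

    def test_all_nan_reports_none(self):
        assert fd.dominant_driver({"a": float("nan")}) is None


class TestIntervalTurnover:
    def test_static_composition_is_zero(self):
        M = np.array([[1, 0, 1], [0, 1, 1]])
        tv = interval_turnover([M, M, M, M])
        assert (tv["bc"] == 0).all()

    def test_complete_replacement_is_one(self):
        a = np.array([[1, 1, 0, 0]])
        b = np.array([[0, 0, 1, 1]])
        tv = interval_turnover([a, b, a])
        assert (tv["bc"] == 1).all()

    def test_single_gain_is_one_third(self):
        tv = interval_turnover([np.array([[1, 0]]), np.array([[1, 1]])])
        assert tv["bc"].iloc[0] == pytest.approx(1 / 3)


class TestEnvfit:
    def test_axis_aligned_variable(self, rng):
        scores = rng.normal(size=(50, 2))
        env = pd.DataFrame({"v": scores[:, 0]})
        out = fd.fit_env_vectors(scores, env, n_perm=49, seed=0).iloc[0]
        assert out["r2"] == pytest.approx(1.0)
        assert (out["dx"], out["dy"]) == pytest.approx((1.0, 0.0), abs=1e-9)

    def test_r2_matches_normal_equations_oracle(self, rng):
        scores = rng.normal(size=(40, 2))
        v = rng.normal(size=40)
        out = fd.fit_env_vectors(scores, pd.DataFrame({"v": v}), n_perm=0)
        X = np.column_stack([np.ones(40), scores])
        beta = np.linalg.solve(X.T @ X, X.T @ v)
        resid = v - X @ beta
        r2 = 1 - resid @ resid / ((v - v.mean()) @ (v - v.mean()))
        assert out["r2"].iloc[0] == pytest.approx(r2, abs=1e-10)

    def test_constant_variable_flagged(self, rng):
        scores = rng.normal(size=(20, 2))
        out = fd.fit_env_vectors(scores, pd.DataFrame({"v": np.ones(20)}),
                                 n_perm=9)
        assert out["degenerate"].iloc[0]
        assert out["r2"].iloc[0] == 0.0


def _toy_partition():
    # 1-D points {0,1} vs {3,4}: SS_total 10, SS_between 9, F 18
    x = np.array([[0.0], [1.0], [3.0], [4.0]])
    D = squareform(pdist(x))
    groups = pd.DataFrame({"g": ["a", "a", "b", "b"]})
    return D, groups


class TestPermanova:
    def test_toy_partition_exact(self):
        D, groups = _toy_partition()
        res = fd.permanova(D, groups, n_perm=99, seed=0).set_index("term")
        assert res.loc["Total", "ss"] == pytest.approx(10.0)
        assert res.loc["g", "ss"] == pytest.approx(9.0)
        assert res.loc["g", "r2"] == pytest.approx(0.9)
        assert res.loc["g", "pseudo_f"] == pytest.approx(18.0)

    def test_r2_partition_sums_to_one(self, rng):
        X = rng.normal(size=(24, 3))
        D = squareform(pdist(X))
        factors = pd.DataFrame({
            "f1": np.repeat(["a", "b", "c"], 8),
            "f2": np.tile(["x", "y"], 12)})
        res = fd.permanova(D, factors, n_perm=49, seed=0)
        terms = res[res["term"] != "Total"]
        assert terms["r2"].sum() == pytest.approx(1.0)
        assert terms["ss"].sum() == pytest.approx(
            res.set_index("term").loc["Total", "ss"])

    def test_p_value_bounds(self, rng):
        X = rng.normal(size=(16, 2))
        D = squareform(pdist(X))
        factors = pd.DataFrame({"g": np.repeat(["a", "b"], 8)})
        res = fd.permanova(D, factors, n_perm=99, seed=1)
        p = res.set_index("term").loc["g", "p"]
        assert 1 / 100 <= p <= 1.0

    def test_single_level_factor_rejected(self):
        D, _ = _toy_partition()
        with pytest.raises(ValueError):
            fd.permanova(D, pd.DataFrame({"g": ["a"] * 4}))

    def test_one_way_f_matches_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        X = rng.normal(size=(21, 4))
        X[7:, 0] += 1.5
        D = squareform(pdist(X))
        groups = np.repeat(["a", "b", "c"], 7)
        ours = fd.permanova(D, pd.DataFrame({"g": groups}), n_perm=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(D), groups.tolist(), permutations=0)
        assert ours.set_index("term").loc["g", "pseudo_f"] == pytest.approx(
            ref["test statistic"], abs=1e-9)

    def test_interaction_term_included(self, rng):
        X = rng.normal(size=(24, 2))
        D = squareform(pdist(X))
        factors = pd.DataFrame({
            "f1": np.repeat(["a", "b"], 12),
            "f2": np.tile(np.repeat(["x", "y"], 6), 2)})
        res = fd.permanova(D, factors, interaction=True, n_perm=19, seed=0)
        assert "f1:f2" in set(res["term"])
        assert res[res["term"] != "Total"]["r2"].sum() == pytest.approx(1.0)


class TestPermdisp:
    def test_duplicated_pairs_degenerate(self):
        X = np.array([[0.0, 0], [0, 0], [5, 5], [5, 5]])
        D = squareform(pdist(X))
        F, p, disp = fd.permdisp(D, ["a", "a", "b", "b"], n_perm=19)
        assert np.isnan(F) and np.isnan(p)

    def test_dispersion_scales_linearly(self, rng):
        base = rng.normal(size=(30, 2))
        base -= base.mean(axis=0)
        X = np.vstack([base, 2 * base + 10])
        D = squareform(pdist(X))
        groups = np.repeat(["a", "b"], 30)
        F, p, disp = fd.permdisp(D, groups, n_perm=99, seed=0)
        assert disp["b"] == pytest.approx(2 * disp["a"], rel=1e-9)
        assert p <= 0.05

    def test_singleton_group_rejected(self):
        D = squareform(pdist(np.arange(3.0)[:, None]))
        with pytest.raises(ValueError):
            fd.permdisp(D, ["a", "a", "b"])

    def test_f_matches_skbio_on_euclidean(self, rng):
        skbio = pytest.importorskip("skbio")
        X = rng.normal(size=(20, 3))
        X[10:] *= 2.5
        D = squareform(pdist(X))
        groups = np.repeat(["a", "b"], 10).tolist()
        F, _, _ = fd.permdisp(D, groups, n_perm=9, seed=0)
        ref = skbio.stats.distance.permdisp(skbio.DistanceMatrix(D), groups,
                                            test="centroid", permutations=9)
        assert F == pytest.approx(ref["test statistic"], rel=1e-6)


@pytest.fixture(scope="module")
def analysis(cube, zoned, landscape, climate):
    _, labels = zoned
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fd.run_trajectory_analysis(
            cube, labels, landscape, climate, "585", n_cells=10,
            n_reps=3, n_perm_env=19, n_perm_permanova=49,
            n_perm_permdisp=19, seed=0)


class TestRunAnalysis:
    def test_replicate_row_counts(self, analysis):
        counts = analysis.trajectories.groupby("cluster").size()
        assert (counts == 3).all()
        n_vars = analysis.alignments["variable"].nunique()
        assert len(analysis.alignments) == len(analysis.trajectories) * n_vars
        assert len(analysis.turnover) == len(analysis.trajectories) * 3

    def test_reference_plane_shared(self, analysis):
        # entities = union cells x 4 periods, scores 2-D
        n = len(analysis.entities)
        assert analysis.scores.shape == (n, 2)
        assert analysis.entities["period"].nunique() == 4

    def test_permanova_terms_present(self, analysis):
        terms = set(analysis.permanova["term"])
        assert {"cluster", "period", "Residual", "Total"} <= terms

    def test_deterministic_under_seed(self, cube, zoned, landscape, climate):
        _, labels = zoned
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kw = dict(n_cells=10, n_reps=2, n_perm_env=0,
                      do_permanova=False, seed=5)
            a = fd.run_trajectory_analysis(cube, labels, landscape, climate,
                                           "370", **kw)
            b = fd.run_trajectory_analysis(cube, labels, landscape, climate,
                                           "370", **kw)
        pd.testing.assert_frame_equal(a.trajectories, b.trajectories)
        np.testing.assert_array_equal(a.scores, b.scores)
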