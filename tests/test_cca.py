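"""CCA against eigen/grid oracles; score methods; network thresholding; ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from ccanet.cca import (
    BipartiteNetwork,
    association_scores,
    build_network,
    cca_fit,
    rank_regulators,
    standardize,
    variable_loadings,
)
from conftest import II4CL_SCORES, fig5b_networks


def eigen_rho(X, Y):
    """Canonical correlations as sqrt eigenvalues of Sxx^-1 Sxy Syy^-1 Syx."""
    Xc = (X - X.mean(0)) / X.std(0, ddof=1)
    Yc = (Y - Y.mean(0)) / Y.std(0, ddof=1)
    n = len(Xc)
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    M = linalg.solve(Sxx, Sxy) @ linalg.solve(Syy, Sxy.T)
    vals = np.sort(np.real(linalg.eigvals(M)))[::-1]
    k = min(X.shape[1], Y.shape[1])
    return np.sqrt(np.clip(vals[:k], 0, 1))


class TestStandardize:
    def test_hand_zscores(self):
        out = standardize(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(out.to_numpy().ravel(), [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(20, 4))
        once = standardize(M)
        twice = standardize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            standardize(df)


class TestCcaFit:
    def test_univariate_anticorrelated_gives_rho_one(self):
        x = np.arange(10.0)[:, None]
        fit = cca_fit(x, -x + 3)
        assert fit.rho[0] == pytest.approx(1.0, abs=1e-12)

    def test_identical_blocks_give_all_rho_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        fit = cca_fit(X, X.copy())
        assert np.allclose(fit.rho, 1.0, atol=1e-8)

    def test_matches_eigen_oracle_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(10, 40))
            p = int(rng.integers(1, 4))
            q = int(rng.integers(1, 4))
            X = rng.normal(size=(n, p))
            Y = rng.normal(size=(n, q)) + 0.5 * X[:, :1]
            fit = cca_fit(X, Y)
            assert np.allclose(fit.rho, eigen_rho(X, Y), atol=1e-8)

    def test_rho1_matches_dense_grid_search(self):
        """rho1 = max corr(Xa, Yb) over unit directions (p = q = 2 grid)."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 2))
        Y = rng.normal(size=(30, 2)) + 0.8 * X @ rng.normal(size=(2, 2))
        fit = cca_fit(X, Y)
        Xz = standardize(X).to_numpy()
        Yz = standardize(Y).to_numpy()
        theta = np.linspace(0, np.pi, 600, endpoint=False)
        A = np.stack([np.cos(theta), np.sin(theta)])  # 2 x 600 unit vectors
        U = Xz @ A
        V = Yz @ A
        U = (U - U.mean(0)) / U.std(0, ddof=1)
        V = (V - V.mean(0)) / V.std(0, ddof=1)
        grid_max = np.abs(U.T @ V / (len(Xz) - 1)).max()
        assert fit.rho[0] == pytest.approx(grid_max, abs=1e-3)

    def test_matches_sklearn_cca_scores(self):
        """Independent cross-check: sklearn's NIPALS CCA score correlations."""
        from sklearn.cross_decomposition import CCA as SkCCA

        rng = np.random.default_rng(21)
        X = rng.normal(size=(40, 3))
        Y = rng.normal(size=(40, 2)) + X[:, :2]
        fit = cca_fit(X, Y)
        U, V = SkCCA(n_components=2, scale=True).fit(X, Y).transform(X, Y)
        sk_rho = [abs(np.corrcoef(U[:, i], V[:, i])[0, 1]) for i in range(2)]
        assert np.allclose(fit.rho, sk_rho, atol=1e-6)

    def test_invariance_under_affine_rescaling(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 3))
        Y = rng.normal(size=(25, 2)) + X[:, :2]
        base = cca_fit(X, Y).rho
        X2 = X * np.array([3.0, 0.2, 11.0]) + np.array([5.0, -2.0, 0.7])
        Y2 = Y * np.array([0.01, 40.0]) - 3.0
        assert np.allclose(cca_fit(X2, Y2).rho, base, atol=1e-8)

    def test_canonical_variable_structure(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 3))
        Y = rng.normal(size=(40, 3)) + X
        fit = cca_fit(X, Y)
        assert np.all(np.diff(fit.rho) <= 1e-12)  # descending
        for M in (fit.U, fit.V):
            assert np.allclose(M.std(0, ddof=1), 1.0, atol=1e-8)
        C = np.corrcoef(fit.U.T)
        assert np.allclose(C - np.diag(np.diag(C)), 0, atol=1e-8)
        for i, r in enumerate(fit.rho):
            assert np.corrcoef(fit.U[:, i], fit.V[:, i])[0, 1] == pytest.approx(r, abs=1e-8)

    def test_sample_starved_fit_requires_ridge(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(5, 8))
        Y = rng.normal(size=(5, 2))
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            cca_fit(X, Y)
        fit = cca_fit(X, Y, ridge=1e-3)
        assert np.all((fit.rho >= 0) & (fit.rho <= 1))

    def test_nan_rejected(self):
        X = np.array([[1.0, 2], [3, np.nan], [2, 1], [0, 4]])
        with pytest.raises(ValueError, match="NaN"):
            cca_fit(X, np.ones((4, 1)) * [[1], [2], [3], [4.0]])


class TestLoadings:
    def test_single_x_variable_loads_fully_on_u1(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(15, 1))
        y = 0.5 * x + rng.normal(size=(15, 1))
        fit = cca_fit(x, y)
        assert abs(fit.x_loadings_U1.iloc[0]) == pytest.approx(1.0, abs=1e-10)

    def test_crossloading_identity_at_p_one(self):
        # corr(x, V1) = rho1 * corr(x, U1) exactly when U1 is a rescaling of x
        rng = np.random.default_rng(8)
        x = rng.normal(size=(20, 1))
        Y = rng.normal(size=(20, 3)) + x
        fit = cca_fit(x, Y)
        assert fit.x_crossloadings_V1.iloc[0] == pytest.approx(
            fit.rho[0] * fit.x_loadings_U1.iloc[0], abs=1e-8
        )

    def test_loadings_equal_column_wise_pearson(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 3))
        Y = rng.normal(size=(30, 2)) + X[:, :2]
        fit = cca_fit(X, Y)
        table = variable_loadings(fit, X, Y)
        for row in table.itertuples(index=False):
            j = int(row.variable[1:])
            v = X[:, j] if row.block == "X" else Y[:, j]
            assert row.corr_U1 == pytest.approx(np.corrcoef(v, fit.U[:, 0])[0, 1], abs=1e-10)
            assert row.corr_V1 == pytest.approx(np.corrcoef(v, fit.V[:, 0])[0, 1], abs=1e-10)


class TestAssociationScores:
    def test_identical_profiles_score_one(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(12, 1))
        sm = association_scores(x, x.copy(), method="direct_pearson")
        assert sm.scores.iloc[0, 0] == pytest.approx(1.0)
        assert sm.method == "direct_pearson"

    def test_methods_agree_on_rankings_for_single_factor_data(self):
        # noise-free single latent factor: all three scores are monotone in
        # the product of loadings, so pair rankings coincide
        rng = np.random.default_rng(11)
        n = 4000
        z = rng.normal(size=n)
        a = np.array([0.9, 0.5])  # planted products well separated
        b = np.array([0.85, 0.55, 0.25])
        X = a[None, :] * z[:, None] + np.sqrt(1 - a**2) * rng.normal(size=(n, 2))
        Y = b[None, :] * z[:, None] + np.sqrt(1 - b**2) * rng.normal(size=(n, 3))
        frames = {
            m: association_scores(X, Y, method=m, cutoff_of_record=0.1).scores
            for m in ("direct_pearson", "loading_product", "cross_loading")
        }
        expected = tuple(np.outer(a, b).ravel().argsort().argsort())
        for m in ("direct_pearson", "loading_product"):
            got = tuple(frames[m].to_numpy().ravel().argsort().argsort())
            assert got == expected, m
        # cross_loading scores each gene once (ties across metabolites passing
        # the record cutoff); its gene-level ordering must match the planted one
        cl = frames["cross_loading"].to_numpy()
        assert np.allclose(cl, cl[:, :1])  # constant within gene
        assert tuple(cl[:, 0].argsort().argsort()) == tuple(a.argsort().argsort())

    def test_loading_product_decomposes(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(25, 3))
        Y = rng.normal(size=(25, 2)) + X[:, :2]
        fit = cca_fit(X, Y)
        sm = association_scores(X, Y, method="loading_product")
        for j in range(3):
            for k in range(2):
                expected = (
                    fit.x_loadings_U1.iloc[j] * fit.rho[0] * fit.y_loadings_V1.iloc[k]
                )
                assert sm.scores.iloc[j, k] == pytest.approx(expected, abs=1e-10)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            association_scores(np.ones((4, 1)), np.ones((4, 1)), method="magic")


class TestBuildNetwork:
    def test_printed_pathway_gene_example(self):
        scores = pd.DataFrame([list(II4CL_SCORES.values())], index=["Ii4CL"],
                              columns=list(II4CL_SCORES))
        net = build_network(scores, cutoff=0.5)
        assert net.edge_set() == {("Ii4CL", "lariciresinol"), ("Ii4CL", "pinoresinol")}
        assert min(abs(w) for _, _, w, _ in net.edges) == pytest.approx(0.6)

    def test_all_zero_scores_no_edges_nodes_kept(self):
        scores = pd.DataFrame(np.zeros((3, 2)), index=list("abc"), columns=["m1", "m2"])
        net = build_network(scores, cutoff=0.5)
        assert net.edges == ()
        assert net.left_nodes == ("a", "b", "c")

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(13)
        scores = pd.DataFrame(rng.uniform(-1, 1, size=(5, 4)),
                              index=[f"g{i}" for i in range(5)],
                              columns=[f"m{k}" for k in range(4)])
        for cutoff in (0.2, 0.5, 0.8):
            net = build_network(scores, cutoff=cutoff)
            expected = {
                (g, m)
                for g in scores.index
                for m in scores.columns
                if abs(scores.at[g, m]) >= cutoff
            }
            assert net.edge_set() == expected

    def test_signed_only_mode_drops_negative(self):
        scores = pd.DataFrame([[0.7, -0.7]], index=["g"], columns=["m1", "m2"])
        assert build_network(scores, 0.5).edge_set() == {("g", "m1"), ("g", "m2")}
        assert build_network(scores, 0.5, signed_only=True).edge_set() == {("g", "m1")}

    def test_cutoff_validated(self):
        with pytest.raises(ValueError):
            build_network(pd.DataFrame([[0.5]]), cutoff=0.0)


class TestRankRegulators:
    def test_published_family_lists_give_four_common_tfs(self):
        met_net, gene_net, labels = fig5b_networks()
        report = rank_regulators(met_net, gene_net, labels)
        assert report.common_union == ("Ii007", "Ii049", "Ii050", "Ii080")
        assert report.common["AP2"] == ("Ii080",)
        assert report.common["DREB"] == ("Ii007",)
        assert report.common["Soloist"] == ("Ii049", "Ii050")
        assert report.common.get("RAV", ()) == ()

    def test_disjoint_networks_empty_intersection(self):
        a = BipartiteNetwork(("t1",), ("m",), (("t1", "m", 0.9, 1),), 0.5)
        b = BipartiteNetwork(("t2",), ("g",), (("t2", "g", 0.9, 1),), 0.5)
        report = rank_regulators(a, b, {"t1": "ERF", "t2": "ERF"})
        assert report.common_union == ()

    def test_matches_brute_force_set_intersection(self):
        rng = np.random.default_rng(14)
        tfs = [f"t{i}" for i in range(12)]
        fams = {t: ("ERF", "DREB", "AP2")[i % 3] for i, t in enumerate(tfs)}

        def random_net(right):
            edges = tuple(
                (t, right, float(rng.uniform(0.5, 1)), 1) for t in tfs if rng.random() < 0.5
            )
            return BipartiteNetwork(tuple(tfs), (right,), edges, 0.5)

        a, b = random_net("m"), random_net("g")
        report = rank_regulators(a, b, fams)
        expected = set()
        for fam in set(fams.values()):
            in_a = {t for t, *_ in a.edges if fams[t] == fam}
            in_b = {t for t, *_ in b.edges if fams[t] == fam}
            expected |= in_a & in_b
        assert set(report.common_union) == expected

    def test_edge_order_permutation_invariant(self):
        met_net, gene_net, labels = fig5b_networks()
        shuffled = BipartiteNetwork(
            met_net.left_nodes, met_net.right_nodes, tuple(reversed(met_net.edges)),
            met_net.cutoff,
        )
        r1 = rank_regulators(met_net, gene_net, labels)
        r2 = rank_regulators(shuffled, gene_net, labels)
        assert r1.common_union == r2.common_union
        assert r1.top_per_entity == r2.top_per_entity

    def test_top_k_ranking_ties_by_id(self):
        edges = (("tB", "m", 0.8, 1), ("tA", "m", 0.8, 1), ("tC", "m", -0.9, -1))
        net = BipartiteNetwork(("tA", "tB", "tC"), ("m",), edges, 0.5)
        empty = BipartiteNetwork((), ("g",), (), 0.5)
        report = rank_regulators(net, empty, {t: "ERF" for t in ("tA", "tB", "tC")}, top_k=2)
        assert report.top_per_entity["m"] == ("tC", "tA")

    def test_missing_family_label_errors(self):
        net = BipartiteNetwork(("t1",), ("m",), (("t1", "m", 0.9, 1),), 0.5)
        with pytest.raises(KeyError, match="t1"):
            rank_regulators(net, net, {})
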