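"""PCA reduction, density-peak clustering, ordering genes and the
branching principal tree."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.decomposition import PCA

import ascpath as ap
from ascpath.trajectory import (
    assign_branches,
    cluster_density_peak,
    embed_2d,
    fit_principal_tree,
    reduce_dims,
    select_ordering_genes,
)


def make_adata(X):
    X = np.asarray(X, dtype=float)
    return ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])]),
        var=pd.DataFrame(index=[f"G{j}" for j in range(X.shape[1])]),
    )


class TestReduceDims:
    def test_rank_one_data_captured_by_first_component(self, rng):
        u = rng.random(50)
        v = rng.random(20)
        X = np.outer(u, v)
        emb = reduce_dims(X, num_dim=3)
        var = emb.var(axis=0)
        assert var[0] / var.sum() > 0.999

    def test_permutation_equivariance(self, rng):
        X = rng.random((40, 15))
        perm = rng.permutation(40)
        a = reduce_dims(X, num_dim=5)
        b = reduce_dims(X[perm], num_dim=5)
        np.testing.assert_allclose(a[perm], b, atol=1e-8)

    def test_reconstruction_error_equals_discarded_eigenvalues(self, rng):
        X = rng.random((30, 12))
        num_dim = 4
        pca = PCA(svd_solver="full").fit(X - X.mean(axis=0))
        emb = reduce_dims(X, num_dim=num_dim)
        # squared reconstruction error per spectral identity
        total = ((X - X.mean(axis=0)) ** 2).sum()
        captured = (emb**2).sum()
        discarded = pca.explained_variance_[num_dim:].sum() * (X.shape[0] - 1)
        np.testing.assert_allclose(total - captured, discarded, rtol=1e-6)

    def test_num_dim_bound(self, rng):
        with pytest.raises(ValueError):
            reduce_dims(rng.random((5, 3)), num_dim=4)


class TestEmbed2d:
    def test_same_seed_deterministic(self, rng):
        X = rng.random((60, 8))
        a, _ = embed_2d(X, seed=3)
        b, _ = embed_2d(X, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_blobs_remain_separated(self, rng):
        a = rng.normal(0, 1, size=(50, 6))
        b = rng.normal(0, 1, size=(50, 6)) + 60
        Y, score = embed_2d(np.vstack([a, b]), seed=1)
        ca, cb = Y[:50].mean(axis=0), Y[50:].mean(axis=0)
        spread = max(Y[:50].std(), Y[50:].std())
        assert np.linalg.norm(ca - cb) > spread
        assert 0 <= score <= 1

    def test_tiny_input_degenerate(self):
        Y, _ = embed_2d(np.eye(3), seed=1)
        assert Y.shape == (3, 2)


class TestDensityPeak:
    def test_single_blob_single_cluster(self, rng):
        cm = cluster_density_peak(rng.normal(0, 1, size=(200, 2)))
        assert cm.n_clusters == 1

    def test_three_blobs(self, rng):
        X = np.vstack(
            [rng.normal(c, 1.0, size=(100, 2)) for c in ([0, 0], [30, 0], [0, 30])]
        )
        cm = cluster_density_peak(X)
        assert cm.n_clusters == 3
        truth = np.repeat([0, 1, 2], 100)
        ct = pd.crosstab(cm.labels.to_numpy(), truth)
        assert (ct.max(axis=0) / ct.sum(axis=0) >= 0.95).all()

    def test_global_maximum_delta_is_max_distance(self, rng):
        X = rng.normal(size=(50, 3))
        cm = cluster_density_peak(X)
        from scipy.spatial.distance import cdist

        rho_order = np.lexsort((np.arange(50), -cm.rho))
        top = rho_order[0]
        assert cm.delta[top] == cdist(X[[top]], X).max()

    def test_identical_cells_single_cluster(self):
        cm = cluster_density_peak(np.ones((20, 3)))
        assert cm.n_clusters == 1

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            cluster_density_peak(np.zeros((5, 2)))


def hand_kruskal(groups):
    """Independent Kruskal-Wallis H for the small-case oracle."""
    all_vals = np.concatenate(groups)
    n = len(all_vals)
    order = np.argsort(all_vals, kind="mergesort")
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    # average ranks for ties
    s = pd.Series(all_vals)
    ranks = s.rank().to_numpy()
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
        start += len(g)
    h *= 12 / (n * (n + 1))
    # tie correction
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie


class TestOrderingGenes:
    def build(self, rng, n_per=25):
        X = rng.random((2 * n_per, 5))
        X[:, 0] = 0.0  # constant gene
        X[n_per:, 1] += 10.0  # perfectly separated gene
        adata = make_adata(X)
        clusters = pd.Series(
            np.repeat([0, 1], n_per), index=adata.obs_names
        )
        return adata, clusters

    def test_constant_gene_never_selected_first(self, rng):
        adata, clusters = self.build(rng)
        table = select_ordering_genes(adata, clusters, n_top=2)
        assert table.loc["G0", "p"] == 1.0
        assert not table.loc["G0", "selected"]

    def test_separated_gene_among_top(self, rng):
        adata, clusters = self.build(rng)
        table = select_ordering_genes(adata, clusters, n_top=1)
        assert table.loc["G1", "selected"]

    def test_statistic_matches_hand_oracle(self, rng):
        adata, clusters = self.build(rng, n_per=12)
        table = select_ordering_genes(adata, clusters, n_top=5)
        col = np.asarray(adata.X[:, 2], float)
        h = hand_kruskal([col[:12], col[12:]])
        np.testing.assert_allclose(table.loc["G2", "statistic"], h, rtol=1e-10)

    def test_n_top_exceeding_gene_count_selects_all_varying(self, rng):
        adata, clusters = self.build(rng)
        table = select_ordering_genes(adata, clusters, n_top=100)
        assert table["selected"].sum() == adata.n_vars

    def test_single_cluster_errors(self, rng):
        adata, _ = self.build(rng)
        ones = pd.Series(1, index=adata.obs_names)
        with pytest.raises(ValueError):
            select_ordering_genes(adata, ones)


def segment_cells(rng, a, b, n, noise=0.05, dim=4):
    t = rng.random(n)[:, None]
    pts = np.asarray(a) + t * (np.asarray(b) - np.asarray(a))
    return pts + rng.normal(0, noise, size=(n, dim)), t.ravel()


class TestPrincipalTree:
    def test_linear_gradient_gives_path_and_ordered_pseudotime(self, rng):
        X, t = segment_cells(rng, [0, 0, 0, 0], [20, 0, 0, 0], 300, noise=0.3)
        adata = make_adata(X)
        cm = cluster_density_peak(X, cell_names=adata.obs_names)
        model = fit_principal_tree(adata, cm.labels, num_dim=4, root_cluster=int(cm.labels.iloc[np.argmin(t)]))
        assert model.branch_points == []
        assert model.n_branches == 1
        rho = spearmanr(model.pseudotime.to_numpy(), t).statistic
        assert abs(rho) >= 0.95
        # orientation: root end has minimal pseudotime
        assert model.pseudotime.to_numpy()[np.argmin(t)] < model.pseudotime.mean()

    def test_root_cells_have_zero_pseudotime(self, rng):
        X, t = segment_cells(rng, [0] * 4, [10, 0, 0, 0], 200, noise=0.1)
        adata = make_adata(X)
        cm = cluster_density_peak(X, cell_names=adata.obs_names)
        root = int(cm.labels.iloc[np.argmin(t)])
        model = fit_principal_tree(adata, cm.labels, num_dim=4, root_cluster=root)
        assert model.pseudotime.min() >= 0
        assert model.pseudotime.min() < 1e-6 or model.pseudotime.min() < 0.05 * model.pseudotime.max()

    def test_y_shape_three_branches(self, rng):
        segs = [
            segment_cells(rng, [0, 0, 0, 0], [10, 0, 0, 0], 150, noise=0.2)[0],
            segment_cells(rng, [10, 0, 0, 0], [20, 8, 0, 0], 150, noise=0.2)[0],
            segment_cells(rng, [10, 0, 0, 0], [20, -8, 0, 0], 150, noise=0.2)[0],
        ]
        X = np.vstack(segs)
        adata = make_adata(X)
        cm = cluster_density_peak(X, cell_names=adata.obs_names)
        model = fit_principal_tree(adata, cm.labels, num_dim=4)
        assert len(model.branch_points) >= 1
        assert model.n_branches == 3
        truth = np.repeat([0, 1, 2], 150)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, model.branch.to_numpy()) > 0.7

    def test_pseudotime_monotone_along_root_to_leaf(self, rng):
        X, t = segment_cells(rng, [0] * 4, [15, 0, 0, 0], 250, noise=0.2)
        adata = make_adata(X)
        cm = cluster_density_peak(X, cell_names=adata.obs_names)
        root = int(cm.labels.iloc[np.argmin(t)])
        model = fit_principal_tree(adata, cm.labels, num_dim=4, root_cluster=root)
        # binned means of pseudotime increase along the true gradient
        bins = pd.qcut(t, 8, labels=False)
        means = pd.Series(model.pseudotime.to_numpy()).groupby(bins).mean()
        assert (np.diff(means.to_numpy()) > 0).all()

    def test_single_cluster_trivial_trajectory(self, rng):
        X = rng.normal(size=(50, 4))
        adata = make_adata(X)
        ones = pd.Series(0, index=adata.obs_names)
        model = fit_principal_tree(adata, ones, num_dim=4)
        assert model.branch_points == []
        assert model.n_branches == 1


class TestAssignBranches:
    def _model_from_edges(self, edges, n_nodes):
        """Synthetic star/path topologies via direct projection geometry."""
        rng = np.random.default_rng(0)
        # place nodes far apart so cells cluster unambiguously
        nodes = rng.normal(0, 50, size=(n_nodes, 3))
        cells = []
        for a, b in edges:
            for t in np.linspace(0.1, 0.9, 20):
                cells.append(nodes[a] + t * (nodes[b] - nodes[a]))
        X = np.asarray(cells)
        adata = make_adata(X)
        labels = pd.Series(
            np.repeat(np.arange(len(edges)), 20), index=adata.obs_names
        )
        return adata, labels

    def test_path_one_branch(self, rng):
        X, t = segment_cells(rng, [0] * 4, [10, 0, 0, 0], 150, noise=0.1)
        adata = make_adata(X)
        cm = cluster_density_peak(X, cell_names=adata.obs_names)
        model = fit_principal_tree(adata, cm.labels, num_dim=4)
        assert assign_branches(model).nunique() == 1

    def test_star_four_leaves(self, rng):
        center = np.zeros(4)
        arms = [np.array([20, 0, 0, 0]), np.array([-20, 0, 0, 0]),
                np.array([0, 20, 0, 0]), np.array([0, -20, 0, 0])]
        X = np.vstack(
            [segment_cells(rng, center, arm, 120, noise=0.2)[0] for arm in arms]
        )
        adata = make_adata(X)
        cm = cluster_density_peak(X, cell_names=adata.obs_names)
        model = fit_principal_tree(adata, cm.labels, num_dim=4)
        assert len(model.branch_points) == 1
        assert model.n_branches == 4
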