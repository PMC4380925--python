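"""Profiling contracts: Z-scores, PCA, clustering, feature selection."""

import numpy as np
import pandas as pd
import pytest

from shapesignal import profiling as prof
from shapesignal import synthetic as syn
from shapesignal.catalog import TF_NODE


def _toy_cells():
    rng = np.random.default_rng(0)
    rows = []
    for well, (a_mu, b_mu) in {"w0": (10, 1), "w1": (20, 2), "w2": (40, 3)}.items():
        for _ in range(5):
            rows.append({"well_id": well, "line_id": "L", "medium": "base",
                         "treatment": "untreated",
                         "fa": a_mu + rng.normal(0, 0.01), "fb": b_mu + rng.normal(0, 0.01)})
    return pd.DataFrame(rows)


class TestWellProfiles:
    def test_z_columns_standardized_with_population_sd(self):
        cells = _toy_cells()
        _, z = prof.well_profiles(cells, ["fa", "fb"])
        assert np.allclose(z.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(z.std(axis=0, ddof=0), 1, atol=1e-9)

    def test_z_values_match_hand_arithmetic(self):
        cells = _toy_cells()
        means, z = prof.well_profiles(cells, ["fa", "fb"])
        col = means.set_index("well_id")["fa"]
        expected = (col - col.mean()) / col.std(ddof=0)
        assert np.allclose(np.sort(z["fa"].to_numpy()), np.sort(expected.to_numpy()),
                           atol=1e-6)

    def test_well_of_identical_cells_mean_equals_value(self):
        cells = pd.DataFrame({"well_id": ["w"] * 4, "fa": [7.0] * 4, "fb": [1.0] * 4})
        means, _ = prof.well_profiles(cells, ["fa"], group_keys=["well_id"])
        assert means["fa"].iloc[0] == 7.0
        assert means["n_cells"].iloc[0] == 4

    def test_zero_variance_column_excluded_with_warning(self):
        cells = _toy_cells()
        cells["const"] = 5.0
        with pytest.warns(UserWarning, match="const"):
            _, z = prof.well_profiles(cells, ["fa", "const"])
        assert "const" not in z.columns


class TestPCA:
    def test_rank_one_matrix_pc1_explains_everything(self):
        v = np.array([[1.0, 2.0, -1.0]])
        X = pd.DataFrame(np.outer([1, 2, 3, 4], v[0]))
        model = prof.pca_scores(X, k=3)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_variance_fractions_non_increasing_and_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((12, 6)))
        model = prof.pca_scores(X, k=5)
        evr = model.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        L = model.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(5), atol=1e-9)

    def test_scores_match_brute_force_eigendecomposition(self):
        X = pd.DataFrame([[1.0, 2.0, 0.5], [0.2, -1.0, 1.5],
                          [2.0, 0.0, -0.5], [-1.0, 1.0, 0.0]])
        model = prof.pca_scores(X, k=2)
        # independent oracle: eigendecomposition of the covariance matrix
        A = X.to_numpy() - X.to_numpy().mean(axis=0)
        cov = A.T @ A / (len(A) - 1)
        w, V = np.linalg.eigh(cov)
        idx = np.argsort(w)[::-1][:2]
        oracle = A @ V[:, idx]
        got = model.scores.to_numpy()
        for j in range(2):  # sign of each PC is a convention
            assert (np.allclose(got[:, j], oracle[:, j], atol=1e-8)
                    or np.allclose(got[:, j], -oracle[:, j], atol=1e-8))

    def test_full_reconstruction_reproduces_z(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((8, 5)))
        model = prof.pca_scores(X, k=5)
        recon = model.scores.to_numpy() @ model.loadings.to_numpy().T + model.mean_
        assert np.linalg.norm(recon - X.to_numpy()) < 1e-8

    def test_k_above_rank_truncated_with_warning(self):
        X = pd.DataFrame(np.outer([1, 2, 3], [1.0, 1.0, 2.0]))
        with pytest.warns(UserWarning, match="rank"):
            model = prof.pca_scores(X, k=3)
        assert model.scores.shape[1] == 1


class TestClustering:
    def test_duplicate_rows_merge_first_at_height_zero(self):
        X = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, -1.0, 0.0]],
                         index=["a", "b", "c"])
        res = prof.cluster_lines(X, n_clusters=2)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert res.flat_clusters["a"] == res.flat_clusters["b"]

    def test_two_planted_groups_recovered_exactly(self):
        rng = np.random.default_rng(3)
        base_a = np.array([1.0, -1.0, 2.0, 0.0, 1.0])
        base_b = np.array([-2.0, 1.0, -1.0, 1.5, -0.5])
        rows, idx = [], []
        for g, base in [("A", base_a), ("B", base_b)]:
            for i in range(4):
                rows.append(base + 0.02 * rng.standard_normal(5))
                idx.append(f"{g}{i}")
        res = prof.cluster_lines(pd.DataFrame(rows, index=idx), n_clusters=2)
        groups = {}
        for label, cl in res.flat_clusters.items():
            groups.setdefault(cl, set()).add(label[0])
        assert sorted(len(v) for v in groups.values()) == [1, 1]

    def test_distance_matrix_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.standard_normal((5, 4)))
        res = prof.cluster_lines(X)
        D = res.distance_matrix.to_numpy()
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)

    def test_row_order_invariance_of_partition(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.standard_normal((6, 4)),
                         index=[f"r{i}" for i in range(6)])
        res1 = prof.cluster_lines(X, n_clusters=3)
        perm = [3, 0, 5, 1, 4, 2]
        res2 = prof.cluster_lines(X.iloc[perm], n_clusters=3)

        def partition(res):
            inv = {}
            for label, cl in res.flat_clusters.items():
                inv.setdefault(cl, set()).add(label)
            return {frozenset(v) for v in inv.values()}

        assert partition(res1) == partition(res2)

    def test_newick_export_contains_all_leaves(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.standard_normal((4, 3)), index=list("wxyz"))
        nwk = prof.cluster_lines(X).to_newick()
        assert nwk.endswith(";")
        for leaf in "wxyz":
            assert leaf in nwk


class TestFeatureSelection:
    @staticmethod
    def _cells_with_planted_shift(n_lines=4, n=1000, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        for li in range(n_lines):
            tf = rng.standard_normal(n)
            frames.append(pd.DataFrame({
                "line_id": f"L{li}",
                "treatment": "untreated",
                TF_NODE: tf,
                # planted: 1-SD mean shift between high and low TF cells
                "shifted": 0.5 * tf + rng.standard_normal(n),
                "null_a": rng.standard_normal(n),
                "null_b": rng.standard_normal(n),
            }))
        return pd.concat(frames, ignore_index=True)

    def test_planted_shift_feature_ranked_first(self):
        cells = self._cells_with_planted_shift()
        selected, votes = prof.select_discriminative_features(
            cells, ["shifted", "null_a", "null_b"], k=2)
        assert selected[0] == "shifted"
        shifted_votes = votes[(votes.feature == "shifted") & votes.significant]
        assert len(shifted_votes) == 4

    def test_identical_feature_never_selected_first(self):
        cells = self._cells_with_planted_shift()
        cells["flat"] = 1.0
        selected, votes = prof.select_discriminative_features(
            cells, ["flat", "shifted"], k=1)
        assert selected == ["shifted"]
        assert not votes[votes.feature == "flat"].significant.any()

    def test_k_larger_than_catalog_returns_all_ordered(self):
        cells = self._cells_with_planted_shift()
        selected, _ = prof.select_discriminative_features(
            cells, ["shifted", "null_a"], k=99)
        assert len(selected) == 2

    def test_invariant_to_line_renaming(self):
        cells = self._cells_with_planted_shift()
        renamed = cells.assign(line_id=cells.line_id.map(lambda s: "zz_" + s))
        s1, _ = prof.select_discriminative_features(cells, ["shifted", "null_a", "null_b"], k=3)
        s2, _ = prof.select_discriminative_features(renamed, ["shifted", "null_a", "null_b"], k=3)
        assert s1 == s2
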