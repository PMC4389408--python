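import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tnbcsub.fuzzy_clustering import (
    FannyConfig,
    FuzzyPartition,
    barycentric_coordinates,
    calinski_harabasz,
    centred_pearson_dissimilarity,
    crisp_assign,
    dunn_index,
    fanny,
    fanny_objective,
    membership_diagnostics,
    validity_indices,
)


def grid_search_objective_k2(D, r, resolution=0.01):
    """Dense-grid oracle for the two-cluster criterion on tiny instances.

    Enumerates every membership matrix whose first-column entries lie on a
    grid of the given resolution (second column is the complement) and
    returns the minimal criterion value.
    """
    n = D.shape[0]
    grid = np.round(np.arange(0.0, 1.0 + 1e-12, resolution), 10)
    meshes = np.meshgrid(*([grid] * n), indexing="ij")
    u1 = np.stack([m.ravel() for m in meshes], axis=1)  # (M, n)
    total = np.zeros(len(u1))
    for w in (u1**r, (1.0 - u1) ** r):
        num = np.einsum("mi,mj,ij->m", w, w, D)
        den = 2.0 * w.sum(axis=1)
        ok = den > 0
        term = np.zeros(len(w))  # an empty cluster contributes nothing
        term[ok] = num[ok] / den[ok]
        total += term
    return float(total.min())


def random_dissimilarity(rng, n):
    X = rng.normal(size=(n, 3))
    D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
    return D


class TestDissimilarity:
    def test_self_and_anticorrelated(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        E = pd.DataFrame({"a": x, "b": -x, "c": x})
        D = centred_pearson_dissimilarity(E)
        assert D.loc["a", "a"] == 0.0
        assert D.loc["a", "c"] == pytest.approx(0.0, abs=1e-12)
        assert D.loc["a", "b"] == pytest.approx(2.0)

    def test_matches_textbook_correlation(self, rng):
        E = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("abcde"))
        D = centred_pearson_dissimilarity(E)
        for i, ci in enumerate(E.columns):
            for j, cj in enumerate(E.columns):
                x, y = E[ci].to_numpy(), E[cj].to_numpy()
                xm, ym = x - x.mean(), y - y.mean()
                rho = (xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym))
                assert D.iloc[i, j] == pytest.approx(1 - rho, abs=1e-12)

    def test_constant_profile_names_sample(self):
        E = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            centred_pearson_dissimilarity(E)

    def test_halved_variant(self, rng):
        E = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("wxyz"))
        full = centred_pearson_dissimilarity(E)
        half = centred_pearson_dissimilarity(E, halved=True)
        np.testing.assert_allclose(half.to_numpy(), full.to_numpy() / 2)


class TestObjective:
    def test_hard_partition_zero_within(self):
        # two tight pairs with zero within-pair dissimilarity
        D = np.array(
            [[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 0], [5, 5, 0, 0]], dtype=float
        )
        u = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        assert fanny_objective(u, D, 2.0) == 0.0

    def test_uniform_membership_hand_value(self):
        # 3 samples, 2 clusters, u = 0.5 everywhere, r = 2:
        # per cluster: (0.5^2 * 0.5^2 * sum_ij d) / (2 * 3 * 0.25)
        D = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        u = np.full((3, 2), 0.5)
        sum_d = D.sum()  # 12, counting both triangle halves
        hand = 2 * ((0.0625 * sum_d) / (2 * 3 * 0.25))
        assert fanny_objective(u, D, 2.0) == pytest.approx(hand)

    def test_label_permutation_invariance(self, rng):
        D = random_dissimilarity(rng, 6)
        u = rng.dirichlet(np.ones(3), size=6)
        perm = u[:, [2, 0, 1]]
        assert fanny_objective(u, D, 1.5) == pytest.approx(
            fanny_objective(perm, D, 1.5)
        )

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="membership rows"):
            fanny_objective(np.full((3, 2), 0.5), np.zeros((4, 4)), 2.0)


class TestFanny:
    def test_k1_closed_form(self, rng):
        D = random_dissimilarity(rng, 5)
        part = fanny(D, FannyConfig(k=1))
        assert np.all(part.u == 1.0)
        assert part.objective == pytest.approx(D.sum() / (2 * 5))

    def test_two_tight_pairs(self):
        # two pairs far apart: each sample strongly members its own pair
        D = np.array(
            [
                [0.0, 0.1, 4.0, 4.1],
                [0.1, 0.0, 4.2, 4.0],
                [4.0, 4.2, 0.0, 0.1],
                [4.1, 4.0, 0.1, 0.0],
            ]
        )
        part = fanny(D, FannyConfig(k=2, r=2.0, seed=0))
        win = part.u.max(axis=1)
        labels = crisp_assign(part)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]
        assert (win > 0.9).all()

    @pytest.mark.parametrize("r", [2.0, 1.5])
    def test_objective_beats_dense_grid_oracle(self, r, rng):
        D = random_dissimilarity(rng, 3)
        part = fanny(D, FannyConfig(k=2, r=r, seed=1, n_restarts=4))
        oracle = grid_search_objective_k2(D, r)
        assert part.objective <= oracle + 1e-9

    def test_row_sums_and_monotone_objective(self, rng):
        for seed in range(3):
            rng_local = np.random.default_rng(seed)
            D = random_dissimilarity(rng_local, 12)
            part = fanny(D, FannyConfig(k=3, seed=seed))
            np.testing.assert_allclose(part.u.sum(axis=1), 1.0, atol=1e-9)
            assert part.objective >= 0

    def test_k_exceeds_samples(self, rng):
        D = random_dissimilarity(rng, 3)
        with pytest.raises(ValueError, match="exceeds"):
            fanny(D, FannyConfig(k=4))

    def test_recovers_planted_clusters(self, cohort):
        from sklearn.metrics import adjusted_rand_score

        from tnbcsub.expression_io import filter_top_variance

        Ef = filter_top_variance(cohort.expression, 0.05)
        D = centred_pearson_dissimilarity(Ef)
        part = fanny(D, FannyConfig(k=3, seed=11))
        ari = adjusted_rand_score(cohort.truth.to_numpy(), crisp_assign(part))
        assert ari >= 0.9


class TestCrispAndDiagnostics:
    def test_crisp_assign_examples(self):
        u = np.array([[0.73, 0.17, 0.10], [0.5, 0.5, 0.0]])
        p = FuzzyPartition(u, 0.0, 1, True)
        labels = crisp_assign(p)
        assert labels[0] == 0  # highest membership wins
        assert labels[1] == 0  # tie broken toward the lowest index

    def test_crisp_assign_matches_row_scan(self, rng):
        u = rng.dirichlet(np.ones(4), size=20)
        p = FuzzyPartition(u, 0.0, 1, True)
        labels = crisp_assign(p)
        for i in range(20):
            best = max(range(4), key=lambda k: (u[i, k], -k))
            assert labels[i] == best

    def test_diagnostics_fixture_values(self):
        # one cluster with winning memberships {0.73, 0.98, 0.99}
        u = np.array([[0.73, 0.27], [0.98, 0.02], [0.99, 0.01], [0.2, 0.8]])
        p = FuzzyPartition(u, 0.0, 1, True)
        d = membership_diagnostics(p, threshold=0.9)["clusters"][0]
        assert d["min"] == pytest.approx(0.73)
        assert d["median"] == pytest.approx(0.98)
        assert d["n_above_threshold"] == 2

    def test_diagnostics_all_ones_and_empty_cluster(self):
        u = np.array([[1.0, 0.0], [1.0, 0.0]])
        p = FuzzyPartition(u, 0.0, 1, True)
        out = membership_diagnostics(p, threshold=0.5)
        assert out["clusters"][0] == {
            "n": 2, "min": 1.0, "median": 1.0, "n_above_threshold": 2
        }
        assert out["clusters"][1]["min"] is None

    def test_gap_summary_matches_recomputation(self, rng):
        u = rng.dirichlet(np.ones(3), size=15)
        p = FuzzyPartition(u, 0.0, 1, True)
        out = membership_diagnostics(p, gap_pair=(0, 1), gap_threshold=0.2)
        labels = crisp_assign(p)
        mask = (labels == 0) | (labels == 1)
        gaps = np.abs(u[mask, 0] - u[mask, 1])
        np.testing.assert_allclose(out["gap"]["gaps"], gaps)
        assert out["gap"]["n_below_gap_threshold"] == int((gaps < 0.2).sum())


class TestValidityIndices:
    def _blobs(self, rng, n_centers, n_per, n_features=8, sd=0.3, scale=4.0):
        # centers are random direction vectors: separable both in Euclidean
        # space and under the mean-removing correlation distance
        centers = rng.normal(0.0, scale, size=(n_centers, n_features))
        X, labels = [], []
        for c in range(n_centers):
            X.append(centers[c] + rng.normal(0.0, sd, size=(n_per, n_features)))
            labels += [c] * n_per
        return np.vstack(X), np.array(labels)

    def test_ch_maximal_at_two_blobs(self, rng):
        X, _ = self._blobs(rng, 2, n_per=10)
        E = pd.DataFrame(X.T, columns=[f"s{i}" for i in range(20)])
        D = centred_pearson_dissimilarity(E)
        vi = validity_indices(E, D, range(2, 6), FannyConfig(seed=0))
        ch = vi.set_index("k")["calinski_harabasz"]
        assert ch.idxmax() == 2

    def test_indices_match_direct_formula(self, rng):
        X, labels = self._blobs(rng, 3, n_per=2, n_features=5)
        D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        # Dunn by definition on the 6-sample instance
        dn = dunn_index(D, labels)
        inter = min(
            D[i, j]
            for i in range(6)
            for j in range(6)
            if labels[i] != labels[j]
        )
        intra = max(
            D[i, j]
            for i in range(6)
            for j in range(6)
            if labels[i] == labels[j]
        )
        assert dn == pytest.approx(inter / intra)
        # Calinski-Harabasz against sklearn's reference implementation
        from sklearn.metrics import calinski_harabasz_score

        assert calinski_harabasz(X, labels) == pytest.approx(
            calinski_harabasz_score(X, labels)
        )

    def test_dunn_degenerate_duplicated_points(self):
        D = np.zeros((4, 4))
        labels = np.array([0, 0, 1, 1])
        assert dunn_index(D, labels) is None


class TestBarycentric:
    def test_vertices_and_centroid(self):
        vertices = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 1.0]])
        u = np.array([[1.0, 0.0, 0.0], [1 / 3, 1 / 3, 1 / 3]])
        p = FuzzyPartition(u, 0.0, 1, True)
        xy = barycentric_coordinates(p, vertices)
        np.testing.assert_allclose(xy[0], vertices[0])
        np.testing.assert_allclose(xy[1], vertices.mean(axis=0))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_weighted_sum(self, seed):
        rng = np.random.default_rng(seed)
        u = rng.dirichlet(np.ones(3), size=6)
        vertices = rng.normal(size=(3, 2))
        p = FuzzyPartition(u, 0.0, 1, True)
        xy = barycentric_coordinates(p, vertices)
        for i in range(6):
            expected = sum(u[i, k] * vertices[k] for k in range(3))
            np.testing.assert_allclose(xy[i], expected, atol=1e-12)

    def test_vertex_count_mismatch(self):
        p = FuzzyPartition(np.array([[0.5, 0.5]]), 0.0, 1, True)
        with pytest.raises(ValueError, match="vertex"):
            barycentric_coordinates(p, np.zeros((3, 2)))
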