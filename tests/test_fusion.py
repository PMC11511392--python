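"""PCA / LDA / CCA / MCCA numerics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from physioid import fusion

from oracles import cca_whitened_svd, mcca_dense_eig


class TestPca:
    def test_full_rank_reconstruction_is_lossless(self, rng):
        X = rng.normal(size=(40, 6))
        model = fusion.pca_fit(X)
        np.testing.assert_allclose(model.reconstruct(model.transform(X)), X,
                                   atol=1e-8)

    def test_zero_variance_coordinate_carries_no_loading(self, rng):
        X = rng.normal(size=(100, 5))
        X[:, 2] = 7.0
        model = fusion.pca_fit(X, k=4)
        assert np.all(np.abs(model.components[2, :]) < 1e-8)

    def test_components_orthonormal(self, rng):
        model = fusion.pca_fit(rng.normal(size=(60, 8)))
        gram = model.components.T @ model.components
        assert np.max(np.abs(gram - np.eye(8))) < 1e-8

    def test_cumulative_threshold_selection(self, rng):
        base = rng.normal(size=(500, 3)) @ np.diag([10.0, 1.0, 0.1])
        X = np.hstack([base, 0.01 * rng.normal(size=(500, 2))])
        model = fusion.pca_fit(X, cum_threshold=0.99)
        assert 1 <= model.k < 5
        assert model.cumulative_rates[model.k - 1] >= 0.99

    def test_oversized_k_rejected(self, rng):
        with pytest.raises(ValueError, match="k must"):
            fusion.pca_fit(rng.normal(size=(10, 4)), k=5)

    def test_matches_sklearn_principal_axes(self, rng):
        from sklearn.decomposition import PCA
        X = rng.normal(size=(80, 6)) @ rng.normal(size=(6, 6))
        ours = fusion.pca_fit(X, k=3)
        ref = PCA(n_components=3).fit(X)
        for j in range(3):
            a, b = ours.components[:, j], ref.components_[j]
            assert min(np.linalg.norm(a - b), np.linalg.norm(a + b)) < 1e-8
        np.testing.assert_allclose(ours.eigenvalues[:3] * len(X) / (len(X) - 1),
                                   ref.explained_variance_, rtol=1e-8)


class TestContributionReport:
    def test_isotropic_rates_roughly_equal(self, rng):
        model = fusion.pca_fit(rng.normal(size=(10_000, 5)))
        assert np.allclose(model.contribution_rates, 0.2, atol=0.01)

    def test_rates_sum_to_one_and_sorted(self, rng):
        model = fusion.pca_fit(rng.normal(size=(50, 7)) @ rng.normal(size=(7, 7)))
        report = fusion.contribution_report(model)
        assert report["contribution_rate"].sum() == pytest.approx(1.0, abs=1e-10)
        assert report["cumulative_rate"].iloc[-1] == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(report["contribution_rate"]) <= 1e-12)
        assert np.all(np.diff(report["cumulative_rate"]) >= -1e-12)


class TestLda:
    def test_separated_classes_perfectly_ordered(self, rng):
        a = rng.normal(size=(100, 2))
        b = rng.normal(size=(100, 2)) + np.array([10.0, 10.0])
        X = np.vstack([a, b])
        y = np.repeat([0, 1], 100)
        model = fusion.lda_fit(X, y, k=1)
        z = model.transform(X).ravel()
        assert z[y == 0].max() < z[y == 1].min() or z[y == 1].max() < z[y == 0].min()

    def test_eigenvalues_are_rayleigh_quotients(self, rng):
        X = rng.normal(size=(120, 8))
        y = rng.integers(0, 4, size=120)
        model = fusion.lda_fit(X, y, k=3)
        for lam, w in zip(model.eigenvalues, model.W.T):
            quotient = (w @ model.Sb @ w) / (w @ model.Sw @ w)
            assert abs(lam - quotient) < 1e-8

    def test_sample_order_invariance_up_to_sign(self, rng):
        X = rng.normal(size=(90, 5))
        y = rng.integers(0, 3, size=90)
        perm = rng.permutation(90)
        W1 = fusion.lda_fit(X, y, k=2).W
        W2 = fusion.lda_fit(X[perm], y[perm], k=2).W
        np.testing.assert_allclose(W1, W2, atol=1e-8)

    def test_rank_bound_enforced(self, rng):
        X = rng.normal(size=(60, 10))
        y = rng.integers(0, 3, size=60)
        with pytest.raises(ValueError, match="n_classes - 1"):
            fusion.lda_fit(X, y, k=3)


class TestCca:
    def test_identical_sets_fully_correlated(self, rng):
        X = rng.normal(size=(200, 4))
        model = fusion.cca_fit(X, X.copy(), k=2)
        assert model.correlations[0] == pytest.approx(1.0, abs=1e-8)

    def test_independent_sets_nearly_uncorrelated(self, rng):
        X = rng.normal(size=(10_000, 3))
        Y = rng.normal(size=(10_000, 3))
        model = fusion.cca_fit(X, Y, k=3)
        assert np.all(model.correlations < 0.1)

    def test_matches_whitened_svd_oracle(self, rng):
        X = rng.normal(size=(300, 5)) @ rng.normal(size=(5, 5))
        Y = X @ rng.normal(size=(5, 5)) + 0.5 * rng.normal(size=(300, 5))
        k = 5
        model = fusion.cca_fit(X, Y, k=k)
        _, _, s = cca_whitened_svd(X, Y, k)
        np.testing.assert_allclose(model.correlations, s, atol=1e-8)
        U, V = model.transform(X, Y)
        for j in range(k):
            r = np.corrcoef(U[:, j], V[:, j])[0, 1]
            assert abs(r - s[j]) < 1e-6

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="row mismatch"):
            fusion.cca_fit(rng.normal(size=(10, 3)), rng.normal(size=(11, 3)), k=1)


class TestMcca:
    def _random_sets(self, rng, n_sets=3, n=200, d=4):
        base = rng.normal(size=(n, d))
        return [base @ rng.normal(size=(d, d)) + 0.3 * rng.normal(size=(n, d))
                for _ in range(n_sets)]

    def test_two_set_problem_reduces_to_cca(self, rng):
        X, Y = self._random_sets(rng, n_sets=2, d=5)
        k = 5
        model = fusion.mcca_fit([X, Y], k=k)
        _, _, s = cca_whitened_svd(X, Y, k)
        # Eigenvalue convention: lambda = 1 + rho for two sets.
        np.testing.assert_allclose(model.eigenvalues - 1.0, s, atol=1e-8)

    def test_copies_of_one_set_project_identically(self, rng):
        X = rng.normal(size=(150, 4))
        model = fusion.mcca_fit([X, X.copy(), X.copy()], k=1)
        p1, p2, p3 = model.transform_sets([X, X, X])
        for a, b in ((p1, p2), (p1, p3)):
            r = np.corrcoef(a.ravel(), b.ravel())[0, 1]
            assert r == pytest.approx(1.0, abs=1e-8)

    def test_stationarity_conditions_hold(self, rng):
        Xs = self._random_sets(rng)
        model = fusion.mcca_fit(Xs, k=4)
        S = model.S
        for j in range(model.k):
            lam = model.eigenvalues[j]
            for i in range(3):
                lhs = sum(S[i][m] @ model.directions[m][:, j] for m in range(3))
                rhs = lam * (S[i][i] @ model.directions[i][:, j])
                assert np.linalg.norm(lhs - rhs) <= 1e-6

    def test_normalization_constraint(self, rng):
        Xs = self._random_sets(rng)
        model = fusion.mcca_fit(Xs, k=3)
        for j in range(3):
            total = sum(model.directions[i][:, j] @ model.S[i][i]
                        @ model.directions[i][:, j] for i in range(3))
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_objective_nonincreasing_over_directions(self, rng):
        model = fusion.mcca_fit(self._random_sets(rng), k=4)
        assert np.all(np.diff(model.eigenvalues) <= 1e-10)

    def test_agrees_with_dense_generalized_eig_oracle(self, rng):
        for trial in range(5):
            n_sets = int(rng.integers(2, 5))
            d = int(rng.integers(2, 7))
            Xs = self._random_sets(rng, n_sets=n_sets, d=d)
            k = min(3, d)
            model = fusion.mcca_fit(Xs, k=k)
            lam, parts = mcca_dense_eig(Xs, k=k, ridge=model.ridge)
            np.testing.assert_allclose(model.eigenvalues, lam, atol=1e-8)
            for i in range(n_sets):
                np.testing.assert_allclose(model.directions[i], parts[i],
                                           atol=1e-8)

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="equal row"):
            fusion.mcca_fit([rng.normal(size=(10, 3)),
                             rng.normal(size=(12, 3))], k=1)


class TestSerialParallel:
    def test_serial_dims_add(self, rng):
        fused = fusion.serial_fuse(rng.normal(size=(7, 10)),
                                   rng.normal(size=(7, 10)))
        assert fused.X.shape == (7, 20)
        assert fused.source_dims == (10, 10)

    def test_empty_set_is_neutral(self, rng):
        X = rng.normal(size=(5, 4))
        fused = fusion.serial_fuse(X, np.empty((5, 0)))
        np.testing.assert_array_equal(fused.X, X)

    def test_serial_order_is_column_permutation(self, rng):
        X, Y = rng.normal(size=(6, 3)), rng.normal(size=(6, 2))
        ab = fusion.serial_fuse(X, Y).X
        ba = fusion.serial_fuse(Y, X).X
        np.testing.assert_array_equal(np.sort(ab, axis=1), np.sort(ba, axis=1))

    def test_parallel_zero_imaginary_part_is_identity(self, rng):
        X = rng.normal(size=(8, 5))
        fused = fusion.parallel_fuse(X, np.zeros_like(X))
        np.testing.assert_array_equal(fused.X[:, :5], X)
        assert np.all(fused.X[:, 5:] == 0)

    def test_parallel_modulus_pythagorean(self):
        fused = fusion.parallel_fuse(np.array([[3.0]]), np.array([[4.0]]),
                                     mode="modulus")
        assert fused.X[0, 0] == pytest.approx(5.0)

    def test_parallel_pads_shorter_set(self, rng):
        fused = fusion.parallel_fuse(rng.normal(size=(4, 10)),
                                     rng.normal(size=(4, 8)))
        assert fused.X.shape == (4, 20)

    @given(st.integers(2, 9), st.integers(1, 6), st.integers(1, 6))
    def test_serial_row_and_dim_contract(self, n, da, db):
        rng = np.random.default_rng(n * 100 + da * 10 + db)
        fused = fusion.serial_fuse(rng.normal(size=(n, da)),
                                   rng.normal(size=(n, db)))
        assert fused.X.shape == (n, da + db)


class TestCascade:
    def _class_data(self, rng, n_classes=5, per_class=30, d=12):
        Xs, y = {}, []
        centers = {m: rng.normal(scale=3.0, size=(n_classes, d))
                   for m in ("A", "B", "C")}
        y = np.repeat(np.arange(n_classes), per_class)
        for m in ("A", "B", "C"):
            Xs[m] = centers[m][y] + rng.normal(size=(y.size, d))
        return Xs, y

    def test_default_output_dimension(self, rng):
        Xs, y = self._class_data(rng, n_classes=8)
        cfg = fusion.FusionConfig(pca_k=10, lda_k=6, mcca_k=6)
        train, _, pipe = fusion.fuse_pipeline(Xs, y, config=cfg)
        assert train.X.shape[1] == 18

    def test_no_leakage_from_test_rows(self, rng):
        Xs, y = self._class_data(rng)
        # Stratified split so every class appears in the training rows.
        train_idx = np.flatnonzero(np.arange(150) % 30 < 24)
        test_idx = np.flatnonzero(np.arange(150) % 30 >= 24)
        cfg = fusion.FusionConfig(pca_k=8, lda_k=4, mcca_k=4)
        pipe = fusion.FusionPipeline(cfg).fit(
            {m: X[train_idx] for m, X in Xs.items()}, y[train_idx])
        fused_test = pipe.transform({m: X[test_idx] for m, X in Xs.items()})
        pipe_all = fusion.FusionPipeline(cfg).fit(Xs, y)
        fused_test_leaky = pipe_all.transform(
            {m: X[test_idx] for m, X in Xs.items()})
        assert not np.allclose(fused_test, fused_test_leaky)

    def test_modality_order_permutes_columns_only(self, rng):
        Xs, y = self._class_data(rng)
        cfg = fusion.FusionConfig(pca_k=8, lda_k=4, mcca_k=4)
        pipe1 = fusion.FusionPipeline(cfg).fit(Xs, y)
        rev = {m: Xs[m] for m in reversed(list(Xs))}
        pipe2 = fusion.FusionPipeline(cfg).fit(rev, y)
        f1, f2 = pipe1.transform(Xs), pipe2.transform(rev)
        k = cfg.mcca_k
        blocks1 = {m: f1[:, i * k:(i + 1) * k]
                   for i, m in enumerate(pipe1.modalities_)}
        blocks2 = {m: f2[:, i * k:(i + 1) * k]
                   for i, m in enumerate(pipe2.modalities_)}
        for m in Xs:
            np.testing.assert_allclose(blocks1[m], blocks2[m], atol=1e-8)

    def test_supervised_cascade_beats_plain_pca_separation(self, rng):
        Xs, y = self._class_data(rng)
        cfg = fusion.FusionConfig(pca_k=10, lda_k=4, mcca_k=4)
        fused, _, _ = fusion.fuse_pipeline(Xs, y, config=cfg)
        concat = np.hstack([Xs[m] for m in Xs])
        pca = fusion.pca_fit(fusion.Standardizer().fit_transform(concat),
                             k=fused.X.shape[1])
        plain = pca.transform(fusion.Standardizer().fit_transform(concat))

        def scatter_ratio(Z):
            overall = Z.mean(axis=0)
            sw = sb = 0.0
            for c in np.unique(y):
                Zc = Z[y == c]
                sw += np.sum((Zc - Zc.mean(axis=0)) ** 2)
                sb += Zc.shape[0] * np.sum((Zc.mean(axis=0) - overall) ** 2)
            return sb / sw

        assert scatter_ratio(fused.X) > scatter_ratio(plain)

    def test_label_misalignment_rejected(self, rng):
        Xs, y = self._class_data(rng)
        with pytest.raises(ValueError, match="misaligned"):
            fusion.FusionPipeline().fit(Xs, y[:-1])
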