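import numpy as np
import pytest

from lacto2d import svm
from lacto2d.exceptions import ConfigError, Lacto2dError


def _two_blobs(rng, n=30, gap=6.0, dim=2):
    X = np.vstack([rng.normal(size=(n, dim)), rng.normal(size=(n, dim)) + gap])
    y = np.array(["A"] * n + ["B"] * n)
    return X, y


class TestKernelEval:
    def test_rbf_at_zero_distance_is_one(self, rng):
        x = rng.normal(size=7)
        for g in (0.01, 3.59, 100.0):
            cfg = svm.SVMConfig(kernel="rbf", G_gamma=g)
            assert svm.kernel_eval(cfg, x, x) == 1.0

    def test_linear_dot_product(self):
        cfg = svm.SVMConfig(kernel="linear")
        assert svm.kernel_eval(cfg, np.array([1.0, 2.0]), np.array([3.0, 4.0])) == 11.0

    def test_rbf_hand_evaluated(self):
        """rbf with the reported optimum G = 3.59 on a fixed pair."""
        cfg = svm.SVMConfig(kernel="rbf", G_gamma=3.59)
        x = np.array([0.3, -0.1])
        y = np.array([0.1, 0.4])
        expected = np.exp(-3.59 * ((0.2) ** 2 + (0.5) ** 2))
        assert svm.kernel_eval(cfg, x, y) == pytest.approx(expected, rel=1e-12)

    def test_all_kernels_match_sklearn_pairwise(self, rng):
        from sklearn.metrics.pairwise import pairwise_kernels

        x = rng.normal(size=(1, 5))
        y = rng.normal(size=(1, 5))
        cases = [
            (svm.SVMConfig(kernel="linear"), "linear", {}),
            (svm.SVMConfig(kernel="polynomial", G_gamma=0.7, coef0=1.2, poly_degree=3),
             "poly", dict(gamma=0.7, coef0=1.2, degree=3)),
            (svm.SVMConfig(kernel="rbf", G_gamma=0.7), "rbf", dict(gamma=0.7)),
            (svm.SVMConfig(kernel="sigmoid", G_gamma=0.7, coef0=0.2),
             "sigmoid", dict(gamma=0.7, coef0=0.2)),
        ]
        for cfg, name, kwargs in cases:
            ours = svm.kernel_eval(cfg, x[0], y[0])
            ref = pairwise_kernels(x, y, metric=name, **kwargs)[0, 0]
            assert ours == pytest.approx(ref, rel=1e-10)

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            svm.SVMConfig(kernel="rbf", G_gamma=-1.0)
        with pytest.raises(ConfigError):
            svm.SVMConfig(kernel="wavelet")
        with pytest.raises(ConfigError):
            svm.SVMConfig(C_penalty=0.0)
        with pytest.raises(Lacto2dError):
            svm.kernel_eval(svm.SVMConfig(), np.ones(3), np.ones(4))

    def test_rbf_gram_matrix_symmetric_psd(self, rng):
        X = rng.normal(size=(15, 4))
        cfg = svm.SVMConfig(kernel="rbf", G_gamma=0.5)
        K = np.array([[svm.kernel_eval(cfg, a, b) for b in X] for a in X])
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() >= -1e-10


class TestTraining:
    def test_separable_data_fit_perfectly(self, rng):
        X, y = _two_blobs(rng)
        model = svm.train_svm(X, y, svm.SVMConfig(kernel="linear", C_penalty=100.0))
        assert np.mean(model.predict(X) == y) == 1.0
        assert model.support_count >= 2

    def test_xor_needs_nonlinear_kernel(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array(["A", "A", "B", "B"])
        model = svm.train_svm(
            X, y, svm.SVMConfig(kernel="rbf", C_penalty=100.0, G_gamma=2.0)
        )
        assert np.mean(model.predict(X) == y) == 1.0

    def test_training_is_deterministic(self, rng):
        X, y = _two_blobs(rng, gap=2.0)
        probe = rng.normal(size=(20, 2)) + 1.0
        cfg = svm.SVMConfig(kernel="rbf", C_penalty=5.0, G_gamma=0.3, seed=3)
        p1 = svm.train_svm(X, y, cfg).predict(probe)
        p2 = svm.train_svm(X, y, cfg).predict(probe)
        assert list(p1) == list(p2)


class TestCrossValidation:
    def test_separable_scores_one(self, rng):
        X, y = _two_blobs(rng, gap=10.0)
        cfg = svm.SVMConfig(kernel="linear", C_penalty=10.0, cv_folds=5)
        assert svm.cross_val_accuracy(X, y, cfg) == 1.0

    def test_permuted_labels_score_at_chance(self):
        """Three balanced classes with shuffled labels: accuracy near 1/3."""
        scores = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 5))
            y = np.array(["A", "B", "C"] * 20)
            rng.shuffle(y)
            cfg = svm.SVMConfig(kernel="rbf", C_penalty=1.0, G_gamma=0.2,
                                cv_folds=5, seed=seed)
            scores.append(svm.cross_val_accuracy(X, y, cfg))
        assert abs(np.mean(scores) - 1.0 / 3.0) < 0.1

    def test_deterministic_for_fixed_seed(self, rng):
        X, y = _two_blobs(rng, gap=1.5)
        cfg = svm.SVMConfig(kernel="rbf", C_penalty=2.0, G_gamma=0.5, seed=11)
        assert svm.cross_val_accuracy(X, y, cfg) == svm.cross_val_accuracy(X, y, cfg)

    def test_class_smaller_than_folds_rejected(self, rng):
        X = rng.normal(size=(7, 2))
        y = np.array(["A"] * 4 + ["B"] * 3)
        with pytest.raises(Lacto2dError):
            svm.cross_val_accuracy(X, y, svm.SVMConfig(cv_folds=5))


class TestGridSearch:
    def test_single_point_grid(self, rng):
        X, y = _two_blobs(rng)
        res = svm.grid_search(
            X, y, svm.SVMConfig(kernel="rbf", cv_folds=3),
            log2C_range=(2.0, 2.0), log2G_range=(-3.0, -3.0),
        )
        assert res.best_C == 4.0 and res.best_G == 0.125
        assert res.surface.shape == (1, 3)

    def test_surface_is_exhaustive_and_unique(self, rng):
        X, y = _two_blobs(rng, n=15)
        res = svm.grid_search(
            X, y, svm.SVMConfig(kernel="rbf", cv_folds=3),
            log2C_range=(-2.0, 2.0), log2G_range=(-4.0, 0.0), step=2.0,
        )
        pts = {(row[0], row[1]) for row in res.surface}
        assert len(pts) == len(res.surface) == 9

    def test_best_point_tops_the_surface(self, rng):
        X, y = _two_blobs(rng, gap=2.0, n=25)
        res = svm.grid_search(
            X, y, svm.SVMConfig(kernel="rbf", cv_folds=3),
            log2C_range=(-5.0, 9.0), log2G_range=(-9.0, 1.0), step=2.0,
        )
        assert res.best_score >= np.percentile(res.surface[:, 2], 95)
        assert res.best_score == res.surface[:, 2].max()


class TestPSO:
    def test_global_best_trace_is_non_decreasing(self, rng):
        X, y = _two_blobs(rng, gap=2.0, n=20)
        pso = svm.PSOConfig(swarm_size=6, iterations=8, seed=0,
                            log2C_bounds=(-3.0, 7.0), log2G_bounds=(-7.0, 1.0))
        res = svm.pso_optimize(X, y, svm.SVMConfig(kernel="rbf", cv_folds=3), pso)
        assert np.all(np.diff(res.trace) >= 0)

    def test_degenerate_bounds_return_that_point(self, rng):
        X, y = _two_blobs(rng)
        pso = svm.PSOConfig(swarm_size=4, iterations=3,
                            log2C_bounds=(1.0, 1.0), log2G_bounds=(-2.0, -2.0))
        with pytest.warns(UserWarning):
            res = svm.pso_optimize(X, y, svm.SVMConfig(kernel="rbf", cv_folds=3), pso)
        assert res.best_C == 2.0 and res.best_G == 0.25

    def test_deterministic_for_fixed_seed(self, rng):
        X, y = _two_blobs(rng, gap=2.0, n=15)
        pso = svm.PSOConfig(swarm_size=5, iterations=5, seed=7,
                            log2C_bounds=(-3.0, 5.0), log2G_bounds=(-7.0, 1.0))
        cfg = svm.SVMConfig(kernel="rbf", cv_folds=3)
        r1 = svm.pso_optimize(X, y, cfg, pso)
        r2 = svm.pso_optimize(X, y, cfg, pso)
        assert r1.best_C == r2.best_C and r1.best_G == r2.best_G
        np.testing.assert_array_equal(r1.trace, r2.trace)


def test_regularization_sweep_shows_over_and_underfitting():
    """Training accuracy rises with C while CV accuracy peaks at interior C."""
    rng = np.random.default_rng(5)
    X = np.vstack([rng.normal(0, 1.5, size=(40, 2)), rng.normal(2.0, 1.5, size=(40, 2))])
    y = np.array(["A"] * 40 + ["B"] * 40)
    log2cs = np.arange(-9.0, 13.0, 2.0)
    train_accs, cv_accs = [], []
    for lc in log2cs:
        cfg = svm.SVMConfig(kernel="rbf", C_penalty=2.0 ** lc, G_gamma=4.0,
                            cv_folds=5, seed=1)
        model = svm.train_svm(X, y, cfg)
        train_accs.append(float(np.mean(model.predict(X) == y)))
        cv_accs.append(svm.cross_val_accuracy(X, y, cfg))
    # training accuracy trend: end above start, no big local drops
    assert train_accs[-1] >= train_accs[0]
    assert all(b >= a - 0.05 for a, b in zip(train_accs, train_accs[1:]))
    # CV accuracy peaks strictly inside the sweep
    best = int(np.argmax(cv_accs))
    assert 0 < best < len(log2cs) - 1
    assert max(cv_accs) > cv_accs[0] and max(cv_accs) > cv_accs[-1]
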