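import numpy as np
import pytest
from scipy.optimize import minimize

import netstrat as ns
from netstrat.classifier import FittedElasticNet
from netstrat.errors import ConfigurationError, DataError


@pytest.fixture(scope="module")
def three_class_toy():
    """Well-separated 3-class problem, 10 samples per class, 6 features."""
    rng = np.random.default_rng(0)
    X = rng.normal(0, 0.3, size=(30, 6))
    y = np.repeat([1, 2, 3], 10)
    for c in range(3):
        X[y == c + 1, 2 * c] += 3.0
    return X, y


class TestFitElasticNet:
    def test_huge_lambda_shrinks_everything_to_majority(self, three_class_toy):
        X, y = three_class_toy
        y = np.concatenate([y[:25], [1, 1, 1, 1, 1]])  # class 1 is the majority
        fit = ns.fit_elastic_net(X, y, alpha=1.0, lam=1e4)
        assert np.allclose(fit.coef, 0.0)
        assert (fit.predict(X) == 1).all()

    def test_separable_classes_fit_perfectly_at_small_lambda(self, three_class_toy):
        X, y = three_class_toy
        fit = ns.fit_elastic_net(X, y, alpha=0.5, lam=1e-4)
        assert (fit.predict(X) == y).mean() == 1.0

    def test_ridge_limit_matches_direct_optimizer(self):
        """alpha=0 keeps the objective smooth, so a generic optimizer on the
        penalized multinomial likelihood must find the same coefficients."""
        rng = np.random.default_rng(1)
        n, p, k = 45, 3, 3
        X = rng.normal(size=(n, p))
        score = X[:, 0] + 0.5 * rng.normal(size=n)
        y = np.digitize(score, np.quantile(score, [1 / 3, 2 / 3]))
        lam = 0.05
        cfg = ns.ElasticNetConfig(standardize=False, tol=1e-10, max_iter=50000)
        fit = ns.fit_elastic_net(X, y, alpha=0.0, lam=lam, config=cfg)

        def objective(theta):
            W = theta[: k * p].reshape(k, p)
            b = theta[k * p:]
            scores = X @ W.T + b
            scores -= scores.max(axis=1, keepdims=True)
            logp = scores - np.log(np.exp(scores).sum(axis=1, keepdims=True))
            nll = -logp[np.arange(n), y].sum() / n
            return nll + lam * 0.5 * (W ** 2).sum()

        res = minimize(objective, np.zeros(k * p + k), method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 5000})
        W_opt = res.x[: k * p].reshape(k, p)
        # sklearn's symmetric parameterization: compare class-contrast coefficients
        contrast_ours = fit.coef[1] - fit.coef[0]
        contrast_oracle = W_opt[1] - W_opt[0]
        assert np.abs(contrast_ours - contrast_oracle).max() < 1e-4

    def test_singleton_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        with pytest.raises(DataError, match="single sample"):
            ns.fit_elastic_net(X, np.array([1, 1, 1, 1, 2]), alpha=0.5, lam=0.1)

    def test_nonzero_count_non_increasing_in_lambda(self, three_class_toy):
        X, y = three_class_toy
        small = ns.fit_elastic_net(X, y, alpha=1.0, lam=0.01)
        large = ns.fit_elastic_net(X, y, alpha=1.0, lam=0.1)
        assert (large.coef != 0).sum() <= (small.coef != 0).sum()


class TestJackknifeTune:
    def test_separable_toy_reaches_zero_error(self, three_class_toy):
        X, y = three_class_toy
        cfg = ns.ElasticNetConfig(alpha_grid=(1.0,), lambda_path=(0.1, 0.001))
        model = ns.jackknife_tune(X, y, cfg)
        assert model.jackknife_error == 0.0

    def test_uninformative_features_never_beat_chance(self):
        """With labels independent of features the leave-one-out error cannot
        be better than chance. It is typically worse: holding out a sample
        of one class tilts the training majority to the other class, a
        well-known pessimistic bias of leave-one-out on balanced data."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 5))
        y = np.repeat([0, 1], 20)
        cfg = ns.ElasticNetConfig(alpha_grid=(0.5,), lambda_path=(0.05,))
        model = ns.jackknife_tune(X, y, cfg)
        assert model.jackknife_error >= 0.45

    def test_matches_independent_loo_reimplementation(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 4))
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2])
        X[y == 1, 0] += 2.0
        X[y == 2, 1] += 2.0
        cfg = ns.ElasticNetConfig(alpha_grid=(0.5, 1.0), lambda_path=(0.1, 0.01))
        model = ns.jackknife_tune(X, y, cfg)
        for (alpha, lam), err in model.grid_errors.items():
            wrong = 0
            for i in range(12):
                keep = [j for j in range(12) if j != i]
                fit = ns.fit_elastic_net(X[keep], y[keep], alpha, lam, cfg)
                wrong += int(fit.predict(X[i:i + 1])[0] != y[i])
            assert err == wrong / 12

    def test_error_invariant_to_sample_order(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(14, 3))
        y = (X[:, 0] > 0).astype(int)
        if min((y == 0).sum(), (y == 1).sum()) < 2:
            y[:2] = [0, 1]
        cfg = ns.ElasticNetConfig(alpha_grid=(1.0,), lambda_path=(0.05,))
        m1 = ns.jackknife_tune(X, y, cfg)
        perm = rng.permutation(14)
        m2 = ns.jackknife_tune(X[perm], y[perm], cfg)
        assert m1.jackknife_error == pytest.approx(m2.jackknife_error)

    def test_tie_break_prefers_larger_lambda(self, three_class_toy):
        X, y = three_class_toy
        cfg = ns.ElasticNetConfig(alpha_grid=(0.5, 1.0), lambda_path=(0.01, 0.001))
        model = ns.jackknife_tune(X, y, cfg)
        zero_error = [g for g, e in model.grid_errors.items() if e == model.jackknife_error]
        best_lam = max(l for _, l in zero_error)
        assert model.chosen_lambda == best_lam

    def test_too_few_samples_rejected(self):
        with pytest.raises(ConfigurationError):
            ns.jackknife_tune(np.ones((5, 2)), np.array([0, 0, 1, 1, 1]))


class TestBiomarkers:
    def _model(self, coef, classes=(1, 2, 3), names=None):
        p = coef.shape[1]
        fit = FittedElasticNet(coef=coef, intercept=np.zeros(len(classes)),
                               classes=np.array(classes), alpha=1.0, lam=0.1,
                               mean=np.zeros(p), scale=np.ones(p))
        return ns.SubtypeModel(fit=fit, chosen_alpha=1.0, chosen_lambda=0.1,
                               jackknife_error=0.1,
                               feature_names=names or [f"g{j}" for j in range(p)])

    def test_all_zero_coefficients_give_empty_lists(self):
        out = ns.extract_biomarkers(self._model(np.zeros((3, 4))))
        assert all(len(v) == 0 for v in out["per_subtype"].values())
        assert out["union_size"] == 0

    def test_known_supports_exact_set_algebra(self):
        coef = np.array([[1.0, 0.0, 2.0, 0.0],   # class 1: g0, g2
                         [0.0, 3.0, 2.0, 0.0],   # class 2: g1, g2
                         [0.0, 0.0, 0.0, 4.0]])  # class 3: g3
        out = ns.extract_biomarkers(self._model(coef))
        assert out["per_subtype"] == {1: ["g0", "g2"], 2: ["g1", "g2"], 3: ["g3"]}
        assert out["union_size"] == 4
        assert out["pairwise_overlap"] == {(1, 2): 1, (1, 3): 0, (2, 3): 0}

    def test_identical_supports_fully_overlap(self):
        coef = np.tile(np.array([1.0, 0.0, 1.0]), (3, 1))
        out = ns.extract_biomarkers(self._model(coef))
        assert all(v == 2 for v in out["pairwise_overlap"].values())


class TestTopNSweep:
    def test_one_row_per_n_and_determinism(self, smoothed_small, small_cohort):
        labels = small_cohort.true_labels[
            [small_cohort.mutation_matrix.patients.index(p) for p in smoothed_small.patients]]
        cfg = ns.ElasticNetConfig(alpha_grid=(1.0,), lambda_path=(0.05,))
        table = ns.top_n_sweep(smoothed_small, labels, n_values=(20, 30, 30), config=cfg)
        assert set(table) == {20, 30}
        again = ns.top_n_sweep(smoothed_small, labels, n_values=(30,), config=cfg)
        assert table[30] == again[30]

    def test_strong_signal_keeps_accuracy_high(self, smoothed_small, small_cohort):
        labels = small_cohort.true_labels[
            [small_cohort.mutation_matrix.patients.index(p) for p in smoothed_small.patients]]
        cfg = ns.ElasticNetConfig(alpha_grid=(1.0,), lambda_path=(0.05,))
        table = ns.top_n_sweep(smoothed_small, labels, n_values=(30, 60), config=cfg)
        assert all(acc >= 0.9 for acc in table.values())
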