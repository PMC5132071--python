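"""Imputation, penalized logistic fitting, tuning, cutoff and CV-AUC."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from tolsig import (
    ConfigError,
    ValidationError,
    cross_validated_auc,
    fit_elastic_net_logistic,
    fit_signature,
    knn_impute,
    predict_probability,
    select_cutoff,
    tune_signature,
)
from tolsig.signature import ToleranceSignature, default_grid, lambda_max


def _frame(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(values,
                        index=[f"{prefix}{i}" for i in range(values.shape[0])],
                        columns=[f"s{j}" for j in range(values.shape[1])])


class TestKnnImpute:
    def test_mean_of_two_nearest(self):
        # s1/s2 are nearest to s0 on the observed gene; their values 3 and 5
        expr = _frame([[np.nan, 3.0, 5.0, 40.0],
                       [0.0, 0.1, -0.1, 9.0]])
        out = knn_impute(expr, k=2)
        assert out.iloc[0, 0] == pytest.approx(4.0)

    def test_complete_matrix_unchanged(self, rng):
        expr = _frame(rng.normal(size=(6, 5)))
        pd.testing.assert_frame_equal(knn_impute(expr, k=2), expr)

    def test_matches_exhaustive_neighbor_search(self, rng):
        X = rng.normal(size=(15, 10))
        holes = rng.random(X.shape) < 0.05
        expr = _frame(np.where(holes, np.nan, X))
        k = 3
        out = knn_impute(expr, k=k)
        vals = expr.to_numpy()

        def dist(i, j):
            a, b = vals[:, i], vals[:, j]
            m = ~np.isnan(a) & ~np.isnan(b)
            return np.sqrt(((a[m] - b[m]) ** 2).mean()) if m.any() else np.inf

        for gi, si in zip(*np.where(np.isnan(vals))):
            donors = sorted((j for j in range(vals.shape[1])
                             if not np.isnan(vals[gi, j])),
                            key=lambda j: dist(si, j))
            expected = np.mean([vals[gi, j] for j in donors[:k]])
            assert out.iloc[gi, si] == pytest.approx(expected, abs=1e-12)

    def test_gene_missing_everywhere_errors(self):
        expr = _frame([[np.nan, np.nan], [1.0, 2.0]])
        with pytest.raises(ValidationError, match="g0"):
            knn_impute(expr, k=1)

    def test_k_too_large_errors(self):
        expr = _frame([[1.0, 2.0], [3.0, np.nan]])
        with pytest.raises(ConfigError):
            knn_impute(expr, k=2)


class TestElasticNetLogistic:
    def _data(self, rng, n=80, p=5):
        X = rng.normal(size=(n, p))
        y = (X[:, 0] + 0.4 * rng.normal(size=n) > 0).astype(int)
        return X, y

    def test_fully_penalized_limit(self, rng):
        X, y = self._data(rng)
        coef, b0 = fit_elastic_net_logistic(X, y, alpha=0.5, lam=50.0)
        assert np.all(coef == 0.0)
        assert b0 == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-12)

    def test_unpenalized_matches_mle(self, rng):
        X, y = self._data(rng, n=120)
        coef, b0 = fit_elastic_net_logistic(X, y, alpha=0.5, lam=0.0)
        mle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.abs(np.r_[b0, coef] - mle.params).max() < 1e-4

    def test_ridge_symmetry_for_duplicated_column(self, rng):
        X, y = self._data(rng, p=3)
        Xdup = np.column_stack([X, X[:, 0]])
        coef, _ = fit_elastic_net_logistic(Xdup, y, alpha=0.0, lam=0.1)
        assert abs(coef[0] - coef[3]) < 1e-6

    def test_l1_produces_exact_zeros(self, rng):
        X, y = self._data(rng, p=10)
        coef, _ = fit_elastic_net_logistic(X, y, alpha=1.0, lam=0.08)
        assert (coef == 0.0).sum() >= 5

    def test_single_class_rejected(self, rng):
        X, _ = self._data(rng)
        with pytest.raises(ValidationError):
            fit_elastic_net_logistic(X, np.ones(len(X), int), 0.5, 0.1)

    def test_lasso_path_monotone_on_orthonormal_design(self, rng):
        # on an orthonormalized design the lasso support shrinks with lambda
        # (soft-threshold behavior); check gene counts never increase
        n, p = 64, 8
        Q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        X = Q * np.sqrt(n)
        eta = X[:, :3] @ np.array([1.2, -1.0, 0.8])
        y = (rng.random(n) < expit(eta)).astype(int)
        Xs = (X - X.mean(0)) / X.std(0)
        lams = np.logspace(np.log10(lambda_max(Xs, y, 1.0)), -3, 12)
        counts = []
        for lam in lams:
            coef, _ = fit_elastic_net_logistic(Xs, y, alpha=1.0, lam=lam)
            counts.append(int((coef != 0).sum()))
        assert all(a <= b for a, b in zip(counts, counts[1:]))


class TestPredict:
    def _sig(self, genes, coef, intercept, center=None, scale=None, **kw):
        p = len(genes)
        return ToleranceSignature(
            genes=genes, coef=np.asarray(coef, float), intercept=intercept,
            alpha=0.5, lam=0.1,
            center=np.zeros(p) if center is None else np.asarray(center, float),
            scale=np.ones(p) if scale is None else np.asarray(scale, float),
            **kw)

    def test_null_model_gives_half(self, rng):
        expr = _frame(rng.normal(size=(3, 4)))
        sig = self._sig(list(expr.index), [0.0, 0.0, 0.0], 0.0)
        assert np.allclose(predict_probability(sig, expr), 0.5)

    def test_training_mean_gives_inverse_logit_intercept(self):
        expr = _frame([[2.0], [7.0]])
        sig = self._sig(["g0", "g1"], [1.0, -2.0], 0.7, center=[2.0, 7.0])
        assert predict_probability(sig, expr).iloc[0] == pytest.approx(expit(0.7))

    def test_matches_dot_product_oracle(self, rng):
        expr = _frame(rng.normal(size=(5, 7)))
        coef = rng.normal(size=5)
        center = rng.normal(size=5)
        scale = rng.uniform(0.5, 2.0, size=5)
        sig = self._sig(list(expr.index), coef, -0.3, center, scale)
        probs = predict_probability(sig, expr)
        for j, s in enumerate(expr.columns):
            eta = -0.3 + sum(
                coef[i] * (expr.iloc[i, j] - center[i]) / scale[i]
                for i in range(5))
            assert abs(probs[s] - expit(eta)) < 1e-12

    def test_affine_rescaling_invariance(self, rng):
        # rescaling gene units with adjusted constants leaves predictions fixed
        expr = _frame(rng.normal(size=(4, 6)))
        coef = rng.normal(size=4)
        center, scale = rng.normal(size=4), rng.uniform(0.5, 2, size=4)
        sig = self._sig(list(expr.index), coef, 0.2, center, scale)
        a, b = 3.0, -1.5
        sig2 = self._sig(list(expr.index), coef, 0.2, a * center + b, a * scale)
        pd.testing.assert_series_equal(predict_probability(sig, expr),
                                       predict_probability(sig2, a * expr + b))

    def test_missing_gene_listed(self, rng):
        expr = _frame(rng.normal(size=(2, 3)))
        sig = self._sig(["g0", "ABSENT"], [1.0, 1.0], 0.0)
        with pytest.raises(ValidationError, match="ABSENT"):
            predict_probability(sig, expr)


class TestSelectCutoff:
    def test_perfect_separation(self):
        probs = np.array([0.9, 0.9, 0.1, 0.1])
        res = select_cutoff(probs, [1, 1, 0, 0])
        assert res.cutoff == pytest.approx(0.5)
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        probs = rng.random(10)
        y = (rng.random(10) < 0.4).astype(int)
        if y.sum() in (0, 10):
            y[0] = 1 - y[0]
        res = select_cutoff(probs, y, spec_min=0.5, sens_min=0.3)
        uniq = np.unique(probs)
        best = None
        for c in (uniq[:-1] + uniq[1:]) / 2:
            pred = probs >= c
            sens = (pred & (y == 1)).sum() / max((y == 1).sum(), 1)
            spec = (~pred & (y == 0)).sum() / max((y == 0).sum(), 1)
            if spec >= 0.5 and sens >= 0.3:
                key = (spec, sens, -c)
                if best is None or key > best[0]:
                    best = (key, c)
        if best is None:
            assert not res.feasible
        else:
            assert res.feasible and res.cutoff == pytest.approx(best[1])

    def test_infeasible_reported_not_silently_fixed(self):
        # labels anti-correlated with probabilities: constraints unreachable
        res = select_cutoff([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert not res.feasible
        assert res.cutoff is None


class TestTuning:
    def _signal_frame(self, rng, n=120, p=20, informative=4):
        y = np.r_[np.ones(n // 4, int), np.zeros(n - n // 4, int)]
        X = rng.normal(size=(p, n))
        X[:informative, y == 1] += 2.0
        expr = _frame(X)
        labels = pd.Series(y, index=expr.columns)
        return expr, labels

    def test_recovers_informative_genes(self, rng):
        expr, labels = self._signal_frame(rng)
        grid = [(1.0, lam) for lam in (0.2, 0.05, 0.01)]
        _, sig = tune_signature(expr, labels, grid=grid, n_iter=12, seed=0)
        selected = set(sig.genes)
        assert {"g0", "g1", "g2", "g3"} <= selected

    def test_gene_cap_enforced(self, rng):
        expr, labels = self._signal_frame(rng)
        grid = [(1.0, 0.05), (1.0, 0.01), (0.1, 1e-4)]
        _, sig = tune_signature(expr, labels, grid=grid, n_iter=8,
                                max_genes=6, seed=0)
        assert sig.n_genes <= 6

    def test_no_feasible_grid_point_errors(self, rng):
        expr, labels = self._signal_frame(rng)
        with pytest.raises(ConfigError, match="lambda"):
            tune_signature(expr, labels, grid=[(0.1, 1e-6)], n_iter=5,
                           max_genes=1, seed=0)

    def test_same_seed_identical_result(self, rng):
        expr, labels = self._signal_frame(rng, n=60, p=8)
        grid = [(0.5, 0.1), (0.5, 0.02)]
        r1, s1 = tune_signature(expr, labels, grid=grid, n_iter=6, seed=3)
        r2, s2 = tune_signature(expr, labels, grid=grid, n_iter=6, seed=3)
        pd.testing.assert_frame_equal(r1.grid, r2.grid, check_exact=True)
        assert s1.genes == s2.genes
        assert np.array_equal(s1.coef, s2.coef)

    def test_default_grid_shape(self, rng):
        expr, labels = self._signal_frame(rng, n=40, p=6)
        X = expr.to_numpy().T
        Xs = (X - X.mean(0)) / X.std(0)
        grid = default_grid(Xs, labels.to_numpy(), n_lambda=7)
        assert len(grid) == 10 * 7
        lams = [l for a, l in grid if a == 1.0]
        assert lams == sorted(lams, reverse=True)
        coef, _ = fit_elastic_net_logistic(Xs, labels.to_numpy(), 1.0, lams[0])
        assert np.all(coef == 0.0)


class TestCrossValidatedAuc:
    def test_null_features_near_half(self):
        # fresh dataset per replicate: a single finite dataset keeps its
        # chance association in every fold, so the null must average over
        # independent draws
        aucs = []
        for rep in range(6):
            local = np.random.default_rng(900 + rep)
            expr = _frame(local.normal(size=(10, 100)))
            y = pd.Series(np.r_[np.ones(30, int), np.zeros(70, int)],
                          index=expr.columns)
            aucs.append(cross_validated_auc(expr, y, alpha=0.5, lam=0.05,
                                            n_iter=10, seed=rep)[0])
        assert 0.42 <= np.mean(aucs) <= 0.58

    def test_strong_signal_high_auc(self, rng):
        X = rng.normal(size=(8, 90))
        y = np.r_[np.ones(30, int), np.zeros(60, int)]
        X[:4, y == 1] += 4.0
        expr = _frame(X)
        labels = pd.Series(y, index=expr.columns)
        auc, rep = cross_validated_auc(expr, labels, alpha=0.5, lam=0.02,
                                       n_iter=15, seed=1)
        assert auc >= 0.95
        assert rep["n_used"] == 15

    def test_apparent_auc_bounds_cv_auc(self, rng):
        from tolsig import roc_auc
        wins = 0
        for rep in range(8):
            local = np.random.default_rng(100 + rep)
            X = local.normal(size=(12, 70))
            y = np.r_[np.ones(20, int), np.zeros(50, int)]
            X[:2, y == 1] += 0.8
            expr = _frame(X)
            labels = pd.Series(y, index=expr.columns)
            sig = fit_signature(expr, labels, alpha=0.5, lam=0.02)
            apparent = roc_auc(predict_probability(sig, expr), labels)
            cv, _ = cross_validated_auc(expr, labels, 0.5, 0.02,
                                        n_iter=10, seed=rep)
            wins += int(apparent >= cv)
        assert wins >= 7
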