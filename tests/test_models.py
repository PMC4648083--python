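"""The five prediction methods against independent numerical oracles."""

import numpy as np
import pytest

from peagp.datatypes import GenotypeMatrix
from peagp.models import (
    GBLUP,
    BayesMarkerRegression,
    KernelPLS,
    MarkerLasso,
    _kernel_coefs,
    _pls1_kernel,
    _pls1_nipals,
    fit_gblup,
    make_model,
    predict_gebv,
    tune_by_cv,
)


def _toy(n, p, seed, n_qtl=None, h2=0.8):
    rng = np.random.default_rng(seed)
    X = rng.choice([0.0, 2.0], size=(n, p))
    nq = n_qtl if n_qtl is not None else max(2, p // 3)
    beta = np.zeros(p)
    beta[rng.choice(p, nq, replace=False)] = rng.normal(0, 1, nq)
    g = (X - X.mean(0)) @ beta
    ve = g.var() * (1 - h2) / h2 if h2 < 1 else 0.0
    y = 5.0 + g + (rng.normal(0, np.sqrt(ve), n) if ve > 0 else 0.0)
    return X, y, beta


class TestGBLUP:
    def test_constant_response_degenerates_to_intercept(self):
        X, _, _ = _toy(12, 8, 0)
        est = GBLUP().fit(X, np.full(12, 3.5))
        assert est.mu_ == 3.5
        np.testing.assert_allclose(est.gebv_, 0.0)
        np.testing.assert_allclose(est.predict(X), 3.5)

    def test_fixed_lambda_equals_closed_form_ridge_oracle(self):
        """GEBVs at fixed lambda match direct mixed-model matrix inversion."""
        X, y, _ = _toy(12, 30, 1)
        lam = 0.7
        est = GBLUP(ratio=lam).fit(X, y)
        # oracle: brute-force GLS intercept + BLUP through explicit inverses
        p = X.mean(0) / 2
        poly = (p > 0) & (p < 1)
        W = (X - 2 * p)[:, poly]
        G = W @ W.T / (2 * np.sum(p[poly] * (1 - p[poly])))
        V = G + lam * np.eye(len(y))
        ones = np.ones(len(y))
        mu = (ones @ np.linalg.solve(V, y)) / (ones @ np.linalg.solve(V, ones))
        gebv = G @ np.linalg.solve(V, y - mu)
        np.testing.assert_allclose(est.gebv_, gebv, atol=1e-8)
        np.testing.assert_allclose(est.predict(X), mu + gebv, atol=1e-8)

    def test_marker_form_equals_kinship_form_on_disjoint_test_set(self):
        X, y, _ = _toy(40, 60, 2)
        Xtr, Xte, ytr = X[:30], X[30:], y[:30]
        est = GBLUP().fit(Xtr, ytr)
        np.testing.assert_allclose(
            est.predict(Xte), est.predict_kinship(Xte, Xtr), atol=1e-8
        )

    def test_reml_recovers_heritability(self):
        """Genomic h2 from REML tracks the simulated broad-sense target."""
        from peagp import simdata

        for h2 in (0.98, 0.71):
            errs = []
            for s in range(5):
                mm = simdata.simulate_map(simdata.SimMapConfig(n_markers=600, seed=s))
                gm, _ = simdata.simulate_panel(
                    mm, simdata.PanelSimConfig(n_accessions=200, seed=s + 50)
                )
                ph, _ = simdata.simulate_trait(
                    gm, simdata.TraitSimConfig(n_qtl=360, h2=h2, seed=s, trait_name="t")
                )
                y = ph.values_for("t", 2007, gm.individuals)
                errs.append(GBLUP().fit(gm.codes.astype(float), y).h2_ - h2)
            assert abs(np.mean(errs)) < 0.1


class TestBayes:
    def test_near_one_pi_shrinks_everything(self):
        X, y, _ = _toy(60, 40, 3)
        est = BayesMarkerRegression(
            pi=0.9999, n_iter=1500, burnin=500, random_state=1
        ).fit(X, y)
        assert np.abs(est.coef_).max() < 0.05
        np.testing.assert_allclose(est.predict(X), y.mean(), atol=0.3)

    def test_dominant_qtl_recovered(self):
        rng = np.random.default_rng(4)
        n, p = 200, 300
        X = rng.choice([0.0, 2.0], size=(n, p))
        beta = np.zeros(p)
        beta[37] = 1.0
        g = X @ beta
        y = g + rng.normal(0, np.sqrt(g.var() / 9), n)
        for pi in (0.0, 0.95):
            est = BayesMarkerRegression(
                pi=pi, n_iter=3000, burnin=1000, random_state=7
            ).fit(X, y)
            assert est.coef_[37] == pytest.approx(1.0, rel=0.2)
            if pi > 0:
                assert est.inclusion_[37] > 0.9

    def test_bayesa_chains_agree_across_seeds(self):
        X, y, _ = _toy(80, 120, 5, h2=0.9)
        preds = []
        for seed in (1, 2):
            est = BayesMarkerRegression(
                pi=0.0, n_iter=3000, burnin=1000, random_state=seed
            ).fit(X, y)
            preds.append(est.predict(X))
        assert np.corrcoef(preds[0], preds[1])[0, 1] > 0.98

    def test_residual_variance_calibrated(self):
        """Posterior sigma_e^2 near truth on polygenic simulations."""
        rel_errs = []
        for s in range(8):
            rng = np.random.default_rng(s)
            n, p = 150, 200
            X = rng.choice([0.0, 2.0], size=(n, p))
            beta = rng.normal(0, 0.2, p)
            g = (X - X.mean(0)) @ beta
            s2e = g.var() * 0.5
            y = 10 + g + rng.normal(0, np.sqrt(s2e), n)
            est = BayesMarkerRegression(
                pi=0.0, n_iter=3000, burnin=1000, random_state=s
            ).fit(X, y)
            rel_errs.append(est.var_e_ / s2e - 1)
        assert abs(np.mean(rel_errs)) < 0.3

    def test_rejects_bad_settings(self):
        X, y, _ = _toy(20, 10, 6)
        with pytest.raises(ValueError):
            BayesMarkerRegression(pi=1.0).fit(X, y)
        with pytest.raises(ValueError):
            BayesMarkerRegression(n_iter=100, burnin=200).fit(X, y)


class TestLasso:
    def test_full_shrinkage_at_t_max(self):
        X, y, _ = _toy(40, 25, 7)
        n = len(y)
        W = X - X.mean(0)
        t_max = np.max(np.abs(W.T @ (y - y.mean()))) / n
        est = MarkerLasso(t=t_max * 1.01).fit(X, y)
        assert (est.coef_ == 0).all()
        np.testing.assert_allclose(est.predict(X), y.mean())

    def test_tiny_penalty_approaches_least_squares(self):
        X, y, _ = _toy(50, 5, 8, n_qtl=5, h2=0.95)
        est = MarkerLasso(t=1e-8).fit(X, y)
        W = X - X.mean(0)
        beta_ols = np.linalg.solve(W.T @ W, W.T @ (y - y.mean()))
        np.testing.assert_allclose(est.coef_, beta_ols, atol=1e-4)

    def test_kkt_conditions_hold(self):
        X, y, _ = _toy(60, 90, 9, h2=0.7)
        est = MarkerLasso(random_state=0).fit(X, y)
        n = len(y)
        W = X - X.mean(0)
        r = (y - y.mean()) - W @ est.coef_
        grad = W.T @ r / n
        t = est.t_
        active = est.coef_ != 0
        # active: gradient equals t * sign(beta); inactive: |gradient| <= t
        np.testing.assert_allclose(
            grad[active], t * np.sign(est.coef_[active]), atol=1e-6
        )
        assert (np.abs(grad[~active]) <= t + 1e-6).all()

    def test_l1_norm_nonincreasing_along_penalty(self):
        X, y, _ = _toy(50, 70, 10, h2=0.7)
        W = X - X.mean(0)
        yc = y - y.mean()
        n = len(y)
        t_max = np.max(np.abs(W.T @ yc)) / n
        grid = np.geomspace(t_max, t_max * 1e-3, 40)
        betas = MarkerLasso()._path(W, yc, grid)
        norms = np.abs(betas).sum(axis=1)
        assert (np.diff(norms) >= -1e-8).all()  # decreasing t -> growing norm


class TestKernelPLS:
    def test_full_rank_equals_least_squares(self):
        X, y, _ = _toy(50, 5, 11, n_qtl=5, h2=0.9)
        est = KernelPLS(n_components=5).fit(X, y)
        W = X - X.mean(0)
        beta_ols = np.linalg.solve(W.T @ W, W.T @ (y - y.mean()))
        np.testing.assert_allclose(est.coef_, beta_ols, atol=1e-6)

    def test_single_marker_equals_simple_regression(self):
        rng = np.random.default_rng(12)
        x = rng.choice([0.0, 2.0], 30)
        y = 1.5 * x + rng.normal(0, 0.1, 30)
        est = KernelPLS(n_components=1).fit(x[:, None], y)
        xc = x - x.mean()
        slope = xc @ (y - y.mean()) / (xc @ xc)
        assert est.coef_[0] == pytest.approx(slope, rel=1e-10)

    def test_kernel_algorithm_matches_nipals_and_sklearn(self):
        """Same fitted values from the kernel recursion, explicit NIPALS
        deflation, and sklearn's PLSRegression."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(13)
        W = rng.normal(size=(20, 50))
        W -= W.mean(axis=0)  # sklearn centers internally; compare like with like
        yc = rng.normal(size=20)
        yc -= yc.mean()
        for k in (1, 3, 7):
            bk = _kernel_coefs(W, *_pls1_kernel(W, yc, k))[-1]
            bn = _pls1_nipals(W, yc, k)
            np.testing.assert_allclose(W @ bk, W @ bn, atol=1e-8)
            sk = PLSRegression(n_components=k, scale=False).fit(W, yc)
            np.testing.assert_allclose(W @ bk, sk.predict(W).ravel(), atol=1e-8)

    def test_rejects_zero_variance_response(self):
        X, _, _ = _toy(20, 10, 14)
        with pytest.raises(ValueError):
            KernelPLS().fit(X, np.ones(20))


class TestTuneByCV:
    def test_single_candidate_selected(self):
        X, y, _ = _toy(30, 10, 15)
        res = tune_by_cv(lambda k, Xt, yt: KernelPLS(n_components=k).fit(Xt, yt), y, X, [2])
        assert res.selected == 2

    def test_exact_tie_goes_to_earlier_grid_entry(self):
        X, y, _ = _toy(30, 10, 16)

        class Mean:
            def fit(self, Xt, yt):
                self.m = yt.mean()
                return self

            def predict(self, Xt):
                return np.full(len(Xt), self.m)

        res = tune_by_cv(lambda c, Xt, yt: Mean().fit(Xt, yt), y, X, [5.0, 1.0])
        assert res.selected == 5.0
        assert res.msep[0] == res.msep[1]

    def test_deterministic_given_seed(self):
        X, y, _ = _toy(40, 20, 17)
        fit_fn = lambda k, Xt, yt: KernelPLS(n_components=k).fit(Xt, yt)
        a = tune_by_cv(fit_fn, y, X, [1, 2, 3], seed=5)
        b = tune_by_cv(fit_fn, y, X, [1, 2, 3], seed=5)
        np.testing.assert_array_equal(a.msep, b.msep)
        assert a.selected == b.selected

    def test_noiseless_trait_prefers_richer_model(self):
        X, y, _ = _toy(60, 15, 18, n_qtl=10, h2=1.0)
        fit_fn = lambda k, Xt, yt: KernelPLS(n_components=k).fit(Xt, yt)
        res = tune_by_cv(fit_fn, y, X, [1, 2, 4, 8], seed=0)
        msep_k1 = res.msep[0]
        assert min(res.msep) <= msep_k1
        assert res.selected > 1

    def test_empty_grid_rejected(self):
        X, y, _ = _toy(20, 5, 19)
        with pytest.raises(ValueError):
            tune_by_cv(lambda c, Xt, yt: None, y, X, [])


class TestPredictGEBV:
    def _gm(self, X, prefix):
        return GenotypeMatrix(
            [f"{prefix}{i}" for i in range(X.shape[0])],
            [f"m{j}" for j in range(X.shape[1])],
            X.astype(np.int8),
        )

    def test_training_set_consistency_and_marker_alignment(self):
        X, y, _ = _toy(30, 20, 20)
        gm = self._gm(X, "tr")
        model = fit_gblup(y, gm)
        np.testing.assert_allclose(
            predict_gebv(model, gm), model.estimator.predict(X), atol=1e-12
        )
        # shuffled + extra markers in the test set are handled by id
        rng = np.random.default_rng(0)
        order = rng.permutation(20)
        X2 = np.column_stack([X[:, order], rng.choice([0, 2], size=(30, 3))])
        gm2 = GenotypeMatrix(
            [f"te{i}" for i in range(30)],
            [f"m{j}" for j in order] + ["x1", "x2", "x3"],
            X2.astype(np.int8),
        )
        np.testing.assert_allclose(
            predict_gebv(model, gm2), model.estimator.predict(X), atol=1e-12
        )

    def test_missing_model_marker_raises(self):
        X, y, _ = _toy(25, 10, 21)
        model = fit_gblup(y, self._gm(X, "tr"))
        gm_te = self._gm(X[:, :8], "te")
        with pytest.raises(KeyError, match="m8"):
            predict_gebv(model, gm_te)

    def test_zero_effect_model_predicts_constant(self):
        X, y, _ = _toy(30, 10, 22)
        gm = self._gm(X, "i")
        model = fit_gblup(np.full(30, 2.0), gm)
        np.testing.assert_allclose(predict_gebv(model, gm), 2.0)


def test_make_model_tags():
    assert isinstance(make_model("gblup"), GBLUP)
    assert make_model("bayesb").pi == 0.95
    assert make_model("bayesa").pi == 0.0
    assert isinstance(make_model("lasso"), MarkerLasso)
    assert isinstance(make_model("kplsr"), KernelPLS)
    with pytest.raises(ValueError):
        make_model("ridge")


def test_high_heritability_trait_predicted_better():
    """With identical architecture, the h2=0.98 trait beats the h2=0.71 one."""
    from peagp import simdata
    from peagp.evalx import CVDesign, run_size_series
    from peagp.evalx import adjust_phenotypes

    mm = simdata.simulate_map(simdata.SimMapConfig(n_markers=400, seed=31))
    gm, _ = simdata.simulate_panel(mm, simdata.PanelSimConfig(n_accessions=200, seed=32))
    import pandas as pd

    frames = []
    for name, h2 in (("hi", 0.98), ("lo", 0.71)):
        ph, _ = simdata.simulate_trait(
            gm, simdata.TraitSimConfig(n_qtl=80, h2=h2, seed=33, trait_name=name)
        )
        frames.append(ph.table)
    pheno = adjust_phenotypes(
        simdata.PhenotypeTable(pd.concat(frames, ignore_index=True))
    )
    design = CVDesign(n_repetitions=8, test_size=50, train_sizes=(140,), seed=34)
    res = run_size_series(gm, pheno, design, methods=("gblup",))
    means = res.groupby("trait")["accuracy"].mean()
    assert means["hi"] > means["lo"]
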