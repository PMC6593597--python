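import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

import twiner as tw
from tests.conftest import make_dataset


def _sklearn_enet(ds, alpha, lam, tol=1e-12):
    """Independent reference: sklearn saga on the equivalent objective.

    Our objective (1/n)NLL + lam[a||b||1 + (1-a)||b||2^2] maps onto
    sklearn's sum-NLL + (1/C)[r||b||1 + (1-r)/2 ||b||2^2] via
    r = a / (a + 2(1-a)) and C = r / (n lam a).
    """
    n = ds.n_samples
    r = alpha / (alpha + 2 * (1 - alpha))
    C = r / (n * lam * alpha)
    sk = LogisticRegression(
        solver="saga", l1_ratio=r, C=C, max_iter=1_000_000, tol=tol
    )
    sk.fit(ds.values, ds.labels)
    return sk.intercept_[0], sk.coef_[0]


def _naive_objective(ds, b0, beta, lam, alpha, w):
    """Direct summation oracle for the penalized negative log-likelihood."""
    eta = b0 + ds.values @ beta
    p = 1 / (1 + np.exp(-eta))
    y = ds.labels
    ll = np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
    pen = lam * (alpha * np.sum(np.abs(w * beta)) + (1 - alpha) * np.sum((w * beta) ** 2))
    return -ll / ds.n_samples + pen


class TestObjective:
    def test_null_model_penalty_free(self, small_dataset):
        ds = small_dataset
        ybar = ds.labels.mean()
        b0 = np.log(ybar / (1 - ybar))
        pen = tw.PenaltySpec(0.9, 1.0)
        obj = tw.negative_penalized_loglik(ds, b0, np.zeros(ds.n_genes), pen)
        null = -np.mean(
            ds.labels * np.log(ybar) + (1 - ds.labels) * np.log(1 - ybar)
        )
        assert obj == pytest.approx(null, abs=1e-12)

    def test_zero_weights_remove_penalty(self, small_dataset):
        ds = small_dataset
        rng = np.random.default_rng(1)
        beta = rng.normal(size=ds.n_genes)
        pen0 = tw.PenaltySpec(0.9, 5.0, np.zeros(ds.n_genes))
        obj = tw.negative_penalized_loglik(ds, 0.3, beta, pen0)
        assert obj == pytest.approx(
            _naive_objective(ds, 0.3, beta, 0.0, 0.9, np.zeros(ds.n_genes)), abs=1e-10
        )

    def test_matches_naive_summation(self):
        ds = make_dataset(seed=4, n=30, p=5)
        rng = np.random.default_rng(2)
        beta, w = rng.normal(size=5), rng.uniform(0.1, 1, 5)
        pen = tw.PenaltySpec(0.7, 0.3, w)
        got = tw.negative_penalized_loglik(ds, -0.2, beta, pen)
        assert got == pytest.approx(
            _naive_objective(ds, -0.2, beta, 0.3, 0.7, w), abs=1e-10
        )

    def test_nonfinite_coefficients_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="finite"):
            tw.negative_penalized_loglik(
                small_dataset,
                0.0,
                np.full(small_dataset.n_genes, np.inf),
                tw.PenaltySpec(0.9, 1.0),
            )


class TestFit:
    def test_full_shrinkage_limit(self, small_dataset):
        ds = small_dataset
        fit = tw.fit_weighted_enet(ds, tw.PenaltySpec(0.9, 1e6))
        assert fit.n_selected == 0
        ybar = ds.labels.mean()
        assert fit.intercept == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_unit_weights_match_reference_solver(self, seed):
        ds = make_dataset(seed=seed, n=50, p=10)
        alpha = 0.9
        lam = 0.3 * tw.lambda_max(ds.values, ds.labels.astype(float), alpha, np.ones(10))
        fit = tw.fit_weighted_enet(ds, tw.PenaltySpec(alpha, lam), tol=1e-9)
        _, sk_beta = _sklearn_enet(ds, alpha, lam)
        np.testing.assert_allclose(fit.coefficients, sk_beta, atol=1e-6)

    @pytest.mark.parametrize("seed", list(range(10)))
    def test_reparameterization_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(3, 13))
        ds = make_dataset(seed=seed + 100, n=int(rng.integers(30, 61)), p=p)
        w = rng.uniform(0.15, 1.5, p)
        w[rng.integers(0, p)] = 0.0  # exercise the unpenalized-feature path
        alpha = float(rng.uniform(0.3, 1.0))
        lam = 0.05 + float(rng.uniform(0, 0.2))
        pen = tw.PenaltySpec(alpha, lam, w)
        direct = tw.fit_weighted_enet(ds, pen, tol=1e-10, method="direct")
        rescaled = tw.fit_weighted_enet(ds, pen, tol=1e-10, method="rescale")
        assert abs(direct.objective_value - rescaled.objective_value) < 1e-8
        np.testing.assert_allclose(
            direct.coefficients, rescaled.coefficients, atol=1e-5
        )

    def test_kkt_residual_reported_below_tolerance(self, small_dataset):
        fit = tw.fit_weighted_enet(small_dataset, tw.PenaltySpec(0.9, 0.05))
        assert fit.converged and fit.kkt_residual < 1e-6

    def test_weighted_fit_dominates_unit_fit_objective(self):
        ds = make_dataset(seed=12, n=40, p=3)
        w = np.array([0.2, 1.0, 1.0])
        pen = tw.PenaltySpec(0.9, 0.08, w)
        fit_w = tw.fit_weighted_enet(ds, pen)
        fit_u = tw.fit_weighted_enet(ds, tw.PenaltySpec(0.9, 0.08))
        assert fit_w.kkt_residual < 1e-6
        # unit-weight coefficients evaluated under the weighted penalty
        # cannot beat the weighted optimum
        other = tw.negative_penalized_loglik(ds, fit_u.intercept, fit_u.coefficients, pen)
        assert fit_w.objective_value <= other + 1e-12

    def test_lambda_max_is_tight(self):
        for seed in (5, 6, 7):
            ds = make_dataset(seed=seed, n=40, p=6)
            lm = tw.lambda_max(ds.values, ds.labels.astype(float), 0.9, np.ones(6))
            at_max = tw.fit_weighted_enet(ds, tw.PenaltySpec(0.9, lm * 1.000001))
            below = tw.fit_weighted_enet(ds, tw.PenaltySpec(0.9, lm * 0.999))
            assert at_max.n_selected == 0
            assert below.n_selected >= 1

    def test_penalty_monotonicity_in_single_weight(self):
        ds = make_dataset(seed=8, n=50, p=4)
        alpha, lam = 0.9, 0.05
        base_w = np.ones(4)
        for j in range(4):
            prev = np.inf
            for wj in (0.2, 0.5, 1.0, 2.0, 5.0):
                w = base_w.copy()
                w[j] = wj
                fit = tw.fit_weighted_enet(ds, tw.PenaltySpec(alpha, lam, w), tol=1e-9)
                assert abs(fit.coefficients[j]) <= prev + 1e-8
                prev = abs(fit.coefficients[j])

    def test_objective_beats_random_perturbations(self, small_dataset):
        ds = small_dataset
        pen = tw.PenaltySpec(0.8, 0.1, np.linspace(0.2, 1.0, ds.n_genes))
        fit = tw.fit_weighted_enet(ds, pen)
        rng = np.random.default_rng(0)
        for _ in range(100):
            db = rng.normal(scale=0.05, size=ds.n_genes)
            d0 = rng.normal(scale=0.05)
            perturbed = tw.negative_penalized_loglik(
                ds, fit.intercept + d0, fit.coefficients + db, pen
            )
            assert perturbed >= fit.objective_value - 1e-10

    def test_separable_data_converges_finite(self):
        # complete separation: penalty keeps the optimum finite
        X = np.linspace(-1, 1, 20).reshape(-1, 1)
        y = (X[:, 0] > 0).astype(int)
        ds = tw.ExpressionDataset(X, [f"s{i}" for i in range(20)], ["g"], y)
        fit = tw.fit_weighted_enet(ds, tw.PenaltySpec(0.9, 0.01))
        assert fit.converged and np.isfinite(fit.coefficients).all()


class TestCV:
    def test_strong_feature_always_selected(self):
        hits = 0
        for seed in range(20):
            beta = np.zeros(5)
            beta[0] = 3.0
            ds = make_dataset(seed=seed, n=80, p=5, beta=beta)
            pen = tw.PenaltySpec(0.9)
            lam_opt, _ = tw.cv_lambda(ds, pen, k=5, seed=seed, n_lambda=40)
            fit = tw.fit_weighted_enet(ds, pen.with_lambda(lam_opt))
            hits += "g0" in fit.selected_genes
        assert hits >= 19

    def test_pure_noise_picks_heavy_shrinkage(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 8))
        y = rng.integers(0, 2, 60)
        ds = tw.ExpressionDataset(
            X, [f"s{i}" for i in range(60)], [f"g{j}" for j in range(8)], y
        )
        lam_opt, table = tw.cv_lambda(ds, tw.PenaltySpec(0.9), k=5, seed=0, n_lambda=40)
        rank = int(np.where(table["lambda"].to_numpy() == lam_opt)[0][0])
        assert rank < len(table) / 4  # top (largest-lambda) quartile of the path

    def test_leave_one_out_boundary(self):
        ds = make_dataset(seed=9, n=10, p=3)
        lam_opt, table = tw.cv_lambda(ds, tw.PenaltySpec(0.9), k=10, seed=0, n_lambda=20)
        assert np.isfinite(lam_opt)
        assert np.isfinite(table["cv_mse"]).all()

    def test_cv_alpha_evaluates_candidate_list(self, small_dataset):
        alphas = [0.5, 0.9]
        a_opt, lam_opt, table = tw.cv_alpha(
            small_dataset, alphas, k=4, seed=1, n_lambda=20
        )
        assert a_opt in alphas
        assert len(table) == 2 and np.isfinite(table["cv_mse"]).all()
        # the chosen pair achieves the best held-out score in the table
        assert table["cv_mse"].min() == pytest.approx(
            float(table.loc[table["alpha"] == a_opt, "cv_mse"].iloc[0])
        )
        with pytest.raises(ValueError, match="empty"):
            tw.cv_alpha(small_dataset, [], k=4)

    def test_cv_deterministic_in_seed(self, small_dataset):
        a = tw.cv_lambda(small_dataset, tw.PenaltySpec(0.9), k=5, seed=42, n_lambda=30)
        b = tw.cv_lambda(small_dataset, tw.PenaltySpec(0.9), k=5, seed=42, n_lambda=30)
        assert a[0] == b[0]
        assert a[1].equals(b[1])


class TestPredict:
    def test_zero_model_gives_half(self, small_dataset):
        fit = tw.PenalizedFit(
            0.0, np.zeros(small_dataset.n_genes), list(small_dataset.gene_ids),
            tw.PenaltySpec(0.9, 1.0), 0.0, True, 0,
        )
        np.testing.assert_array_equal(
            tw.predict_prob(fit, small_dataset), 0.5
        )

    def test_extreme_intercept_no_overflow(self, small_dataset):
        fit = tw.PenalizedFit(
            1000.0, np.zeros(small_dataset.n_genes), list(small_dataset.gene_ids),
            tw.PenaltySpec(0.9, 1.0), 0.0, True, 0,
        )
        probs = tw.predict_prob(fit, small_dataset)
        assert np.all(probs <= 1.0) and np.all(probs > 0.999)

    def test_matches_direct_formula(self, small_dataset):
        rng = np.random.default_rng(4)
        beta = rng.normal(size=small_dataset.n_genes)
        fit = tw.PenalizedFit(
            0.3, beta, list(small_dataset.gene_ids), tw.PenaltySpec(0.9, 1.0),
            0.0, True, 0,
        )
        expected = np.exp(0.3 + small_dataset.values @ beta)
        expected = expected / (1 + expected)
        np.testing.assert_allclose(
            tw.predict_prob(fit, small_dataset), expected, atol=1e-12
        )

    def test_misaligned_genes_rejected(self, small_dataset):
        fit = tw.PenalizedFit(
            0.0, np.zeros(2), ["x", "y"], tw.PenaltySpec(0.9, 1.0), 0.0, True, 0
        )
        with pytest.raises(ValueError, match="genes"):
            tw.predict_prob(fit, small_dataset)
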