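import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from xprediction.core_io import (
    AlignedDataset,
    DependencyScreenMatrix,
    DrugSensitivityTable,
    GeneExpressionMatrix,
)
from xprediction.network_profiler import (
    KernelWeights,
    PenaltyConfig,
    estimate_all_networks,
    estimate_sample_network,
    fit_weighted_elastic_net,
    gaussian_kernel,
    kernel_weights,
    lambda_max,
    load_network_stack,
    save_network_stack,
    select_bandwidth,
)


def elastic_net_objective(X, y, w, beta, lam, mixing):
    resid = y - X @ beta
    return (0.5 * np.sum(w * resid**2)
            + lam * (mixing * np.abs(beta).sum() + 0.5 * (1 - mixing) * np.sum(beta**2)))


def make_dataset(X, Y_targets, m, regulator_ids=None, target_ids=None):
    """Assemble an AlignedDataset from raw arrays (X: n x J, Y: n x L)."""
    n, J = X.shape
    L = Y_targets.shape[1]
    regulator_ids = regulator_ids or [f"r{j}" for j in range(J)]
    target_ids = target_ids or [f"t{l}" for l in range(L)]
    samples = [f"s{i:03d}" for i in range(n)]
    genes = regulator_ids + target_ids
    expr = GeneExpressionMatrix(np.vstack([X.T, Y_targets.T]), genes, samples)
    sens = DrugSensitivityTable(m[:, None], samples, ["dM"])
    dep = DependencyScreenMatrix(np.zeros((1, n)), ["gdep"], samples)
    return AlignedDataset(expr, sens, dep, regulator_ids, target_ids)


class TestGaussianKernel:
    def test_zero_distance(self):
        assert gaussian_kernel(1.7, 1.7, 0.3) == 1.0

    def test_exp_minus_one_point(self):
        b = 0.49
        assert gaussian_kernel(np.sqrt(b), 0.0, b) == pytest.approx(np.exp(-1), abs=1e-12)

    def test_large_bandwidth_limit_monotone(self):
        vals = [gaussian_kernel(2.0, 0.0, b) for b in (1, 10, 100, 1e4, 1e8)]
        assert all(v2 > v1 for v1, v2 in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(1.0, abs=1e-6)

    def test_bad_bandwidth(self):
        with pytest.raises(ValueError):
            gaussian_kernel(0.0, 0.0, 0.0)

    @given(m1=st.floats(-5, 5), m2=st.floats(-5, 5), b=st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, m1, m2, b):
        assert gaussian_kernel(m1, m2, b) == gaussian_kernel(m2, m1, b)

    def test_kernel_weights_anchor_is_one(self):
        m = np.array([0.0, 1.0, -2.0, 0.5])
        kw = kernel_weights(m, 2, 1.5, "sX")
        assert kw.weights[2] == 1.0
        assert np.all(kw.weights <= 1.0) and np.all(kw.weights > 0.0)


class TestFitWeightedElasticNet:
    def test_lambda_zero_matches_wls(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            X = rng.standard_normal((20, 5))
            y = rng.standard_normal(20)
            w = rng.uniform(0.2, 1.0, 20)
            beta = fit_weighted_elastic_net(X, y, w, PenaltyConfig(lam=0.0, tol=1e-10))
            beta_wls = np.linalg.solve(X.T @ np.diag(w) @ X, X.T @ (w * y))
            np.testing.assert_allclose(beta, beta_wls, atol=1e-8)

    def test_lambda_max_gives_zero_vector(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((15, 4))
        y = rng.standard_normal(15)
        w = np.ones(15)
        lmax = lambda_max(X, y, w, 0.5)
        beta = fit_weighted_elastic_net(X, y, w, PenaltyConfig(lam=lmax * 1.001, mixing=0.5))
        np.testing.assert_array_equal(beta, np.zeros(4))

    def test_objective_matches_numerical_minimizer(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        w = rng.uniform(0.5, 1.0, 20)
        lam, mixing = 0.1, 0.5
        beta = fit_weighted_elastic_net(X, y, w, PenaltyConfig(lam=lam, mixing=mixing, tol=1e-10))
        obj = elastic_net_objective(X, y, w, beta, lam, mixing)
        res = optimize.minimize(lambda b: elastic_net_objective(X, y, w, b, lam, mixing),
                                np.zeros(5), method="Powell",
                                options={"xtol": 1e-12, "ftol": 1e-14, "maxiter": 10000})
        assert abs(obj - res.fun) < 1e-6

    def test_all_zero_weights_error(self):
        with pytest.raises(ValueError, match="zero"):
            fit_weighted_elastic_net(np.ones((3, 2)), np.ones(3), np.zeros(3),
                                     PenaltyConfig(lam=0.1))

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            fit_weighted_elastic_net(np.ones((1, 2)), np.ones(1), np.ones(1),
                                     PenaltyConfig(lam=0.1))

    def test_accepts_kernel_weights_object(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((10, 3))
        y = rng.standard_normal(10)
        kw = KernelWeights(np.full(10, 0.5), "s0", 1.0)
        b1 = fit_weighted_elastic_net(X, y, kw, PenaltyConfig(lam=0.05))
        b2 = fit_weighted_elastic_net(X, y, np.full(10, 0.5), PenaltyConfig(lam=0.05))
        np.testing.assert_array_equal(b1, b2)


class TestPenaltyConfig:
    def test_fixed_requires_lam(self):
        with pytest.raises(ValueError):
            PenaltyConfig(selection="fixed", lam=None)

    def test_bad_mixing(self):
        with pytest.raises(ValueError):
            PenaltyConfig(lam=0.1, mixing=1.5)

    def test_bad_rule(self):
        with pytest.raises(ValueError):
            PenaltyConfig(lam=0.1, cv_rule="2se")


class TestSelectBandwidth:
    def _constant_data(self, rng, n=50, J=4):
        m = rng.standard_normal(n)
        X = rng.standard_normal((n, J))
        beta = np.array([1.0, -0.8, 0.0, 0.5])
        y = X @ beta + 0.2 * rng.standard_normal(n)
        return m, X, y

    def _switching_data(self, rng, n=80, J=4):
        m = rng.standard_normal(n)
        X = rng.standard_normal((n, J))
        beta0 = np.array([1.5, -1.5, 1.0, -1.0])
        sign = np.where(m > 0, 1.0, -1.0)
        y = (X @ beta0) * sign + 0.2 * rng.standard_normal(n)
        return m, X, y

    def test_single_candidate(self):
        rng = np.random.default_rng(0)
        m, X, y = self._constant_data(rng)
        assert select_bandwidth(m, [2.5], X, y, PenaltyConfig(lam=0.01)) == 2.5

    def test_empty_candidates(self):
        with pytest.raises(ValueError):
            select_bandwidth(np.zeros(5), [], np.zeros((5, 2)), np.zeros(5),
                             PenaltyConfig(lam=0.1))

    def test_constant_coefficients_prefer_pooling(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            m, X, y = self._constant_data(rng)
            cands = [0.25, 1.0, 16.0]
            b = select_bandwidth(m, cands, X, y, PenaltyConfig(lam=0.01))
            wins += b == 16.0
        assert wins >= 14

    def test_switching_coefficients_prefer_local(self):
        below = 0
        for seed in range(20):
            rng = np.random.default_rng(seed + 100)
            m, X, y = self._switching_data(rng)
            cands = [0.25, 1.0, 16.0]
            b = select_bandwidth(m, cands, X, y, PenaltyConfig(lam=0.01))
            below += b < 16.0
        assert below >= 16


class TestEstimateSampleNetwork:
    def test_noiseless_constant_recovery(self):
        rng = np.random.default_rng(4)
        n, J = 60, 5
        X = rng.standard_normal((n, J))
        beta_true = np.array([1.2, 0.0, -0.7, 0.0, 0.4])
        Y = (X @ beta_true)[:, None]
        m = rng.standard_normal(n)
        ds = make_dataset(X, Y, m)
        row = estimate_sample_network(ds, "dM", "t0", "s000",
                                      PenaltyConfig(lam=1e-4), bandwidth=100.0)
        assert np.abs(row - beta_true).max() < 0.05

    def test_empty_true_regulator_set_estimates_zero(self):
        zero_rows = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, J = 50, 6
            X = rng.standard_normal((n, J))
            Y = rng.standard_normal((n, 1))  # no regulator signal at all
            m = rng.standard_normal(n)
            ds = make_dataset(X, Y, m)
            row = estimate_sample_network(ds, "dM", "t0", "s000",
                                          PenaltyConfig(selection="grid_cv", n_lambdas=20),
                                          bandwidth=4.0)
            zero_rows += bool(np.all(row == 0.0))
        assert zero_rows >= 18

    def test_self_regulation_excluded(self):
        rng = np.random.default_rng(6)
        n = 40
        X = rng.standard_normal((n, 2))
        y = X @ np.array([1.0, 0.5]) + 0.1 * rng.standard_normal(n)
        m = rng.standard_normal(n)
        samples = [f"s{i:03d}" for i in range(n)]
        # the target gene is also listed as a candidate regulator
        expr = GeneExpressionMatrix(np.vstack([X.T, y]), ["r0", "r1", "t0"], samples)
        sens = DrugSensitivityTable(m[:, None], samples, ["dM"])
        dep = DependencyScreenMatrix(np.zeros((1, n)), ["gdep"], samples)
        ds = AlignedDataset(expr, sens, dep, ["r0", "r1", "t0"], ["t0"])
        row = estimate_sample_network(ds, "dM", "t0", "s000",
                                      PenaltyConfig(lam=1e-3), bandwidth=50.0)
        assert row[2] == 0.0  # own coefficient forced to zero
        assert abs(row[0] - 1.0) < 0.1  # real regulators still recovered

    def test_extreme_anchor_weights_concentrate(self):
        m = np.linspace(-3, 3, 30)
        kw = kernel_weights(m, 0, 1.0)
        assert kw.weights[0] == 1.0
        assert np.all(np.diff(kw.weights) < 0)  # decays with modulator distance
        assert kw.weights.sum() < 30 / 2  # effective sample size well below n


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(8)
    n, J, L = 12, 4, 2
    X = rng.standard_normal((n, J))
    B = np.array([[1.0, 0.0, -0.5, 0.0], [0.0, 0.8, 0.0, 0.0]])
    Y = X @ B.T + 0.1 * rng.standard_normal((n, L))
    m = rng.standard_normal(n)
    m[3] = m[7]  # two samples share a modulator value
    return make_dataset(X, Y, m)


class TestEstimateAllNetworks:
    def test_matches_sequential_loop(self, toy):
        penalty = PenaltyConfig(lam=0.05)
        stack = estimate_all_networks(toy, "dM", penalty=penalty, bandwidth=1.0)
        assert stack.shape == (12, 2, 4)
        for a, s in enumerate(toy.sample_ids):
            for l, t in enumerate(toy.target_ids):
                row = estimate_sample_network(toy, "dM", t, s, penalty, 1.0)
                np.testing.assert_allclose(stack.coefficients[a, l], row, atol=1e-12)

    def test_equal_modulator_identical_rows(self, toy):
        stack = estimate_all_networks(toy, "dM", penalty=PenaltyConfig(lam=0.05),
                                      bandwidth=1.0)
        np.testing.assert_array_equal(stack.coefficients[3], stack.coefficients[7])

    def test_parallel_bit_identical(self, toy):
        penalty = PenaltyConfig(lam=0.05)
        s1 = estimate_all_networks(toy, "dM", penalty=penalty, bandwidth=1.0, n_jobs=1)
        s2 = estimate_all_networks(toy, "dM", penalty=penalty, bandwidth=1.0, n_jobs=2)
        np.testing.assert_array_equal(s1.coefficients, s2.coefficients)

    def test_empty_target_list(self, toy):
        with pytest.raises(ValueError):
            estimate_all_networks(toy, "dM", targets=[], penalty=PenaltyConfig(lam=0.1))

    def test_stack_round_trip(self, toy, tmp_path):
        stack = estimate_all_networks(toy, "dM", penalty=PenaltyConfig(lam=0.05),
                                      bandwidth=1.0)
        save_network_stack(stack, tmp_path / "stack")
        back = load_network_stack(tmp_path / "stack")
        np.testing.assert_allclose(back.coefficients, stack.coefficients, atol=1e-12)
        assert back.sample_ids == stack.sample_ids
        assert back.bandwidths == stack.bandwidths
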