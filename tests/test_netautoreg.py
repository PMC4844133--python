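"""ML estimation of the network-disturbances model.

The independent oracles here are (a) direct evaluation of the multivariate
normal density with covariance sigma^2 (I-W)^-1 (I-W)^-T on tiny systems and
(b) dense grid search over rho on a single-matrix toy.
"""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import culturenet as cn
from culturenet.netautoreg import (
    DegenerateDesignError,
    StabilityDomainError,
    bic,
    concentrated_loglik,
    full_loglik,
)
from culturenet.synthetic_data import ring_lattice_weights

from conftest import toy_nodes


def random_affinity(n, seed):
    rng = np.random.default_rng(seed)
    d = rng.random((n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    return cn.distance_to_affinity(
        cn.DistanceMatrix(nodes=toy_nodes(n), values=d), label="A"
    )


def random_adjacency(n, seed, p=0.5):
    rng = np.random.default_rng(seed)
    a = (rng.random((n, n)) < p).astype(float)
    a = np.maximum(a, a.T)
    np.fill_diagonal(a, 0)
    return cn.row_normalize(a, toy_nodes(n), label="B")


def mvn_oracle_loglik(model, rho):
    """Brute-force: profile beta/sigma2, then evaluate the MVN density."""
    n = model.n
    A = np.eye(n)
    for r, w in zip(np.atleast_1d(rho), model.w_list):
        A -= r * w.values
    yt, Xt = A @ model.y, A @ model.X
    beta = np.linalg.lstsq(Xt, yt, rcond=None)[0]
    resid = yt - Xt @ beta
    sigma2 = resid @ resid / n
    Ainv = np.linalg.inv(A)
    cov = sigma2 * Ainv @ Ainv.T
    return multivariate_normal.logpdf(model.y, mean=model.X @ beta, cov=cov)


class TestConcentratedLoglik:
    @pytest.mark.parametrize("n", [4, 5, 6])
    @pytest.mark.parametrize("rho", [(0.0, 0.0), (0.3, -0.2), (-0.5, 0.4)])
    def test_matches_mvn_oracle(self, n, rho):
        rng = np.random.default_rng(n)
        w1 = random_affinity(n, seed=n)
        w2 = random_adjacency(n, seed=n + 1)
        y = rng.normal(size=n)
        m = cn.DisturbanceModel.intercept_only(y, w_list=(w1, w2))
        assert concentrated_loglik(m, rho) == pytest.approx(
            mvn_oracle_loglik(m, rho), abs=1e-8
        )

    def test_rho_zero_is_ols_gaussian_loglik(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=20)
        m = cn.DisturbanceModel.intercept_only(y, w_list=(random_adjacency(20, 5),))
        s2 = y.var()  # biased MLE variance
        expected = -10 * np.log(2 * np.pi * s2) - 10
        assert concentrated_loglik(m, [0.0]) == pytest.approx(expected, abs=1e-10)

    def test_outcome_shift_leaves_rho_profile_shape(self):
        rng = np.random.default_rng(9)
        w = random_adjacency(15, 2)
        y = rng.normal(size=15)
        m1 = cn.DisturbanceModel.intercept_only(y, w_list=(w,))
        m2 = cn.DisturbanceModel.intercept_only(y + 100.0, w_list=(w,))
        grid = np.linspace(-0.8, 0.8, 9)
        p1 = [concentrated_loglik(m1, [r]) for r in grid]
        p2 = [concentrated_loglik(m2, [r]) for r in grid]
        assert np.allclose(p1, p2, atol=1e-7)

    def test_singular_operator_rejected(self):
        w = random_adjacency(6, 1)
        y = np.arange(6.0)
        m = cn.DisturbanceModel.intercept_only(y, w_list=(w,))
        # row-normalized: I - W is exactly singular at rho = 1 (constant
        # null vector), surfacing as a singular operator or design
        with pytest.raises((StabilityDomainError, DegenerateDesignError)):
            concentrated_loglik(m, [1.0])


class TestFit:
    def test_grid_search_oracle_single_matrix(self):
        w = ring_lattice_weights(30, 4)
        y = cn.sample_disturbance_outcome([w], [0.4], seed=21)
        m = cn.DisturbanceModel.intercept_only(y, w_list=(w,))
        res = cn.fit(m)
        grid = np.arange(-1.5, 1.5, 1e-4)
        vals = np.full(grid.size, -np.inf)
        for i, r in enumerate(grid):
            try:
                vals[i] = concentrated_loglik(m, [r])
            except StabilityDomainError:
                pass
        assert res.rho[0] == pytest.approx(grid[np.argmax(vals)], abs=1e-3)

    def test_parameter_recovery_single_matrix(self, ring100):
        est = []
        for s in range(200):
            y = cn.sample_disturbance_outcome([ring100], [0.5], seed=s)
            est.append(cn.fit(cn.DisturbanceModel.intercept_only(y, w_list=(ring100,))).rho[0])
        est = np.asarray(est)
        mc_se = est.std(ddof=1) / np.sqrt(est.size)
        assert abs(est.mean() - 0.5) < 3 * mc_se + 0.05

    def test_type_i_error_near_nominal(self, ring100):
        rng = np.random.default_rng(77)
        rejections = 0
        reps = 200
        for _ in range(reps):
            y = rng.standard_normal(100)
            res = cn.fit(cn.DisturbanceModel.intercept_only(y, w_list=(ring100,)))
            if res.converged and np.isfinite(res.rho_p[0]) and res.rho_p[0] < 0.05:
                rejections += 1
        # binomial 3-sigma band around 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert rejections / reps < 0.05 + 3 * se + 0.02

    def test_ols_limit_beta_sigma2(self):
        rng = np.random.default_rng(5)
        y = rng.normal(2.0, 1.5, size=50)
        res = cn.fit(cn.DisturbanceModel.intercept_only(y))  # no matrices
        assert res.beta[0] == pytest.approx(y.mean(), abs=1e-10)
        assert res.sigma2 == pytest.approx(y.var(), abs=1e-10)

    def test_monotone_likelihood_nested_models(self, small_world):
        y = cn.sample_disturbance_outcome(
            [small_world.networks["S_adj"]], [0.5], seed=13)
        nets = small_world.networks
        sub = cn.fit(cn.DisturbanceModel.intercept_only(y, w_list=(nets["S_adj"],)))
        sup = cn.fit(cn.DisturbanceModel.intercept_only(
            y, w_list=(nets["S_adj"], nets["L_adj"])))
        assert sup.loglik >= sub.loglik - 1e-6

    def test_constant_outcome_rejected(self):
        with pytest.raises(DegenerateDesignError):
            cn.fit(cn.DisturbanceModel.intercept_only(np.ones(10)))

    def test_serialization_round_trip(self, ring100):
        import json
        y = cn.sample_disturbance_outcome([ring100], [0.3], seed=1)
        res = cn.fit(cn.DisturbanceModel.intercept_only(y, w_list=(ring100,)))
        payload = json.loads(res.to_json())
        assert payload["rho"]["ring"] == pytest.approx(res.rho[0])
        assert payload["n"] == 100 and payload["k_params"] == 3


class TestBic:
    def test_null_model_closed_form(self):
        y = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        res = cn.fit(cn.DisturbanceModel.intercept_only(y))
        n, s2 = 10, y.var()
        loglik = -0.5 * n * np.log(2 * np.pi * s2) - 0.5 * n
        assert res.loglik == pytest.approx(loglik, abs=1e-10)
        assert res.bic == pytest.approx(-2 * loglik + 2 * np.log(n), abs=1e-10)

    def test_extra_matrix_with_zero_rho_costs_ln_n(self, ring100):
        # identical loglik + one extra parameter = BIC penalty of exactly ln n
        from culturenet.netautoreg import FitResult
        base = dict(beta=np.array([0.0]), sigma2=1.0, loglik=-120.0, bic=np.nan,
                    n=100, converged=True)
        f1 = FitResult(rho=np.zeros(0), rho_se=np.zeros(0), rho_p=np.zeros(0),
                       k_params=2, labels=(), **base)
        f2 = FitResult(rho=np.zeros(1), rho_se=np.zeros(1), rho_p=np.ones(1),
                       k_params=3, labels=("ring",), **base)
        assert bic(f2) - bic(f1) == pytest.approx(np.log(100))

    def test_bic_difference_invariant_to_outcome_shift(self, ring100):
        y = cn.sample_disturbance_outcome([ring100], [0.4], seed=3)
        def gaps(vec):
            f0 = cn.fit(cn.DisturbanceModel.intercept_only(vec))
            f1 = cn.fit(cn.DisturbanceModel.intercept_only(vec, w_list=(ring100,)))
            return f1.bic - f0.bic
        assert gaps(y) == pytest.approx(gaps(y + 57.0), abs=1e-5)


def test_full_loglik_consistent_with_concentrated(ring100):
    y = cn.sample_disturbance_outcome([ring100], [0.3], seed=8)
    m = cn.DisturbanceModel.intercept_only(y, w_list=(ring100,))
    res = cn.fit(m)
    assert full_loglik(m, res.beta, res.sigma2, res.rho) == pytest.approx(
        res.loglik, abs=1e-8
    )
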