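import numpy as np
import pytest
from scipy.optimize import approx_fprime

from oagncc import (
    SeparationError,
    SetDesign,
    ZeroCellError,
    conditional_loglik,
    fit_clogit,
    marginal_or,
    wald_interval,
)


def brute_loglik(beta, sets):
    """Direct enumeration oracle: sum over sets of log softmax at the case."""
    total = 0.0
    for X in sets:
        scores = np.exp(X @ beta)
        total += np.log(scores[0] / scores.sum())
    return total


def random_sets(rng, n_sets=10, set_size=None, p=2):
    sets = []
    for _ in range(n_sets):
        m = set_size or int(rng.integers(2, 8))
        sets.append(rng.integers(0, 2, size=(m, p)).astype(float))
    return sets


class TestConditionalLoglik:
    def test_null_beta_uniform_probability(self):
        sets = [np.zeros((11, 1)) for _ in range(10)]
        ll, _, _ = conditional_loglik(np.zeros(1), sets)
        assert ll == pytest.approx(-10 * np.log(11), abs=1e-12)

    def test_single_pair_closed_form(self):
        sets = [np.array([[1.0], [0.0]])]
        ll, _, _ = conditional_loglik(np.array([np.log(2.0)]), sets)
        assert ll == pytest.approx(np.log(2 / 3), abs=1e-12)

    def test_matches_enumeration_and_finite_differences(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            sets = random_sets(rng, n_sets=6, p=3)
            beta = rng.normal(0, 0.8, size=3)
            ll, grad, hess = conditional_loglik(beta, sets)
            assert ll == pytest.approx(brute_loglik(beta, sets), abs=1e-10)
            num_grad = approx_fprime(beta, lambda b: brute_loglik(b, sets), 1e-7)
            assert np.allclose(grad, num_grad, atol=1e-5)
            for k in range(3):
                num_hess_k = approx_fprime(
                    beta, lambda b: conditional_loglik(b, sets)[1][k], 1e-7
                )
                assert np.allclose(hess[k], num_hess_k, atol=1e-5)

    def test_score_at_null_is_case_minus_set_mean(self):
        rng = np.random.default_rng(3)
        sets = random_sets(rng, n_sets=15, p=2)
        _, grad, _ = conditional_loglik(np.zeros(2), sets)
        expected = sum(X[0] - X.mean(axis=0) for X in sets)
        assert np.allclose(grad, expected, atol=1e-12)

    def test_hessian_negative_semidefinite(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            sets = random_sets(rng, n_sets=8, p=3)
            beta = rng.normal(0, 1.5, size=3)
            _, _, hess = conditional_loglik(beta, sets)
            assert np.linalg.eigvalsh(hess).max() < 1e-9

    def test_non_finite_covariates_rejected(self):
        with pytest.raises(ValueError):
            conditional_loglik(np.zeros(1), [np.array([[np.nan], [0.0]])])

    def test_set_design_wrapper(self):
        sd = SetDesign(0, np.array([1.0]), np.array([[0.0], [0.0]]))
        ll, _, _ = conditional_loglik(np.zeros(1), [sd])
        assert ll == pytest.approx(-np.log(3))


class TestFit:
    def test_discordant_pairs_closed_form(self):
        # 20 case-exposed-only pairs, 10 control-exposed-only, 15 concordant
        sets = (
            [np.array([[1.0], [0.0]])] * 20
            + [np.array([[0.0], [1.0]])] * 10
            + [np.array([[1.0], [1.0]])] * 15
        )
        res = fit_clogit(sets, ["exposure"])
        t = res.term("exposure")
        assert t.or_point == pytest.approx(2.0, abs=1e-7)  # n10/n01
        assert res.converged

    def test_matches_independent_optimizer(self):
        from scipy.optimize import minimize

        rng = np.random.default_rng(7)
        for _ in range(10):
            sets = random_sets(rng, n_sets=30, p=2)
            res = fit_clogit(sets, ["a", "b"])
            if not all(t.informative for t in res.terms):
                continue
            opt = minimize(
                lambda b: -brute_loglik(b, sets), np.zeros(2), method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
            )
            ours = np.array([t.beta for t in res.terms])
            assert np.allclose(ours, opt.x, atol=1e-5)

    def test_separation_raises(self):
        # case is the only exposed member of every set
        sets = [np.vstack([[1.0], np.zeros((5, 1))]) for _ in range(12)]
        with pytest.raises(SeparationError):
            fit_clogit(sets, ["exposure"])

    def test_zero_variation_term_flagged(self):
        rng = np.random.default_rng(8)
        sets = [np.column_stack([rng.integers(0, 2, 4), np.ones(4)]).astype(float) for _ in range(10)]
        res = fit_clogit(sets, ["exposure", "constant"])
        t = res.term("constant")
        assert not t.informative and np.isinf(t.se) and t.beta == 0.0

    def test_invariant_to_control_order_and_set_relabeling(self):
        rng = np.random.default_rng(9)
        sets = random_sets(rng, n_sets=12, p=2)
        res1 = fit_clogit(sets, ["a", "b"])
        shuffled = []
        for X in sets[::-1]:
            controls = X[1:][rng.permutation(len(X) - 1)]
            shuffled.append(np.vstack([X[:1], controls]))
        res2 = fit_clogit(shuffled, ["a", "b"])
        for n in ("a", "b"):
            assert res1.term(n).beta == pytest.approx(res2.term(n).beta, abs=1e-10)
            assert res1.term(n).se == pytest.approx(res2.term(n).se, abs=1e-10)


class TestWaldInterval:
    def test_reference_values(self):
        from scipy.stats import norm

        z = norm.ppf(0.975)
        lo, hi = wald_interval(0.0, 0.1)
        assert lo == pytest.approx(np.exp(-z * 0.1), abs=1e-12)  # 0.822
        assert hi == pytest.approx(np.exp(z * 0.1), abs=1e-12)  # 1.217

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wald_interval(0.0, 0.0)

    def test_monotone_widening_in_se(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            beta = rng.normal()
            s1, s2 = sorted(rng.uniform(0.01, 2.0, size=2))
            w1 = np.subtract(*wald_interval(beta, s1)[::-1])
            w2 = np.subtract(*wald_interval(beta, s2)[::-1])
            assert w2 >= w1

    def test_collapses_as_se_vanishes(self):
        lo, hi = wald_interval(0.5, 1e-12)
        assert lo == pytest.approx(hi, rel=1e-6) == pytest.approx(np.exp(0.5), rel=1e-6)


class TestMarginalOr:
    def test_balanced_table_is_null(self):
        or_, (lo, hi) = marginal_or(10, 10, 10, 10)
        assert or_ == 1.0 and lo < 1.0 < hi

    def test_zero_cell_raises_unless_corrected(self):
        with pytest.raises(ZeroCellError):
            marginal_or(0, 10, 10, 10)
        or_, _ = marginal_or(0, 10, 10, 10, haldane=True)
        assert 0 < or_ < 1
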