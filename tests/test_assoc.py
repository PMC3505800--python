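"""Weighted score tests against independent contingency-table and
exhaustive-permutation oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from linkscore import (CaseControlData, WeightScheme, make_link, marginal_test,
                       permutation_pvalue, stratified_test, two_df_test)

# ---------------------------------------------------------------------------
# independent oracles


def mantel_trend_oracle(y, x):
    """Cochran-Armitage/Mantel trend chi-squared from the 2xk contingency
    table, hypergeometric (conditional) variance with the N-1 denominator."""
    scores = np.unique(x)
    n_j = np.array([(x == s).sum() for s in scores], dtype=float)
    r_j = np.array([y[x == s].sum() for s in scores], dtype=float)
    N, R = n_j.sum(), r_j.sum()
    T = (scores * r_j).sum() - R / N * (scores * n_j).sum()
    var = (R * (N - R) / (N * (N - 1))) * ((scores ** 2 * n_j).sum()
                                           - (scores * n_j).sum() ** 2 / N)
    return T, var, T * T / var


def exhaustive_permutation_U(y, z, x, weights):
    """Mean and variance of the weighted stratified score over ALL
    within-stratum orderings, stratum by stratum (permutations across strata
    are independent, so moments add)."""
    mean, var = 0.0, 0.0
    for s in np.unique(z):
        m = z == s
        xs, ys, w = x[m], y[m], weights[s]
        vals = []
        for perm in itertools.permutations(xs):
            p = np.array(perm)
            vals.append(w * float((p - p.mean()) @ (ys - ys.mean())))
        vals = np.asarray(vals)
        mean += vals.mean()
        var += vals.var()
    return mean, var


def _random_dataset(rng, n_strata=2, n_min=4, n_max=7):
    while True:
        y, z, x = [], [], []
        for s in range(n_strata):
            n = rng.integers(n_min, n_max + 1)
            ys = rng.integers(0, 2, n)
            xs = rng.integers(0, 3, n)
            y.append(ys); z.append(np.full(n, s)); x.append(xs)
        y, z, x = map(np.concatenate, (y, z, x))
        if all(np.ptp(y[z == s]) > 0 and np.ptp(x[z == s]) > 0
               for s in np.unique(z)):
            return CaseControlData(y=y, z=z, x=x.astype(float))


# ---------------------------------------------------------------------------


class TestStratifiedAgainstOracles:
    def test_single_stratum_equals_cochran_armitage(self):
        data = CaseControlData(y=[0, 0, 0, 1, 1, 1], z=[0] * 6,
                               x=[0, 1, 2, 0, 1, 2])
        res = stratified_test(data, WeightScheme.unit([0]))
        U, V, chi2 = mantel_trend_oracle(data.y, data.x)
        assert res.U == pytest.approx(U, abs=1e-12)
        assert res.V == pytest.approx(V, abs=1e-12)
        assert res.chi2 == pytest.approx(chi2, abs=1e-12)

    def test_twenty_random_single_stratum_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            data = _random_dataset(rng, n_strata=1, n_min=6, n_max=12)
            res = stratified_test(data, WeightScheme.unit(data.strata))
            _, _, chi2 = mantel_trend_oracle(data.y, data.x)
            assert res.chi2 == pytest.approx(chi2, abs=1e-10)

    def test_exhaustive_permutation_variance(self):
        """Formula variance == enumeration over every within-stratum ordering
        (unit and non-unit weights, strata of <= 7 subjects)."""
        rng = np.random.default_rng(5)
        for k in range(6):
            data = _random_dataset(rng, n_strata=2)
            w = {0: 1.0, 1: 1.0} if k < 3 else {0: 0.7, 1: 2.3}
            res = stratified_test(data, WeightScheme(w, "test"))
            mean, var = exhaustive_permutation_U(data.y, data.z, data.x, w)
            assert mean == pytest.approx(0.0, abs=1e-10)
            assert res.V == pytest.approx(var, abs=1e-10)

    def test_constant_genotype_gives_null_result(self):
        data = CaseControlData(y=[0, 1, 0, 1], z=[0, 0, 1, 1], x=[1, 1, 1, 1])
        res = stratified_test(data, WeightScheme.unit([0, 1]))
        assert res.U == 0.0 and res.chi2 == 0.0 and res.p_asymptotic == 1.0
        assert res.warnings

    def test_singleton_strata_contribute_nothing(self):
        base = CaseControlData(y=[0, 0, 1, 1], z=[0] * 4, x=[0., 1, 1, 2])
        plus = CaseControlData(y=[0, 0, 1, 1, 1], z=[0, 0, 0, 0, 9],
                               x=[0., 1, 1, 2, 2])
        r1 = stratified_test(base, WeightScheme.unit([0]))
        r2 = stratified_test(plus, WeightScheme.unit([0, 9]))
        assert r2.chi2 == pytest.approx(r1.chi2, abs=1e-14)

    def test_missing_weight_raises(self):
        data = CaseControlData(y=[0, 1], z=[0, 0], x=[0., 1])
        with pytest.raises(ValueError, match="stratum"):
            stratified_test(data, WeightScheme({1: 1.0}, "wrong"))


class TestMarginal:
    def test_unit_weights_equal_pooled_cochran_armitage(self):
        rng = np.random.default_rng(3)
        data = _random_dataset(rng, n_strata=3, n_min=5, n_max=7)
        res = marginal_test(data, WeightScheme.unit(data.strata))
        _, _, chi2 = mantel_trend_oracle(data.y, data.x)  # strata disregarded
        assert res.chi2 == pytest.approx(chi2, abs=1e-10)

    def test_direct_reweighted_indicator_formula(self):
        """Statistic equals a from-scratch computation on ytil = w_z * y."""
        rng = np.random.default_rng(4)
        data = _random_dataset(rng, n_strata=3, n_min=5, n_max=7)
        mu = data.stratum_case_fractions()
        w = WeightScheme.from_link(make_link("power_odds", 0.5), 1.0, mu)
        res = marginal_test(data, w)
        ytil = np.array([w.weights[s] for s in data.z]) * data.y
        x = data.x
        n = len(x)
        U = float((x - x.mean()) @ (ytil - ytil.mean()))
        V = n * n / (n - 1) * x.var() * ytil.var()
        assert res.U == pytest.approx(U, abs=1e-12)
        assert res.chi2 == pytest.approx(U * U / V, abs=1e-12)

    def test_equal_stratum_means_make_tests_coincide(self):
        """When xbar_z is identical across strata (and weights unit), the
        stratified and marginal scores are exactly equal."""
        y = np.array([0, 1, 0, 1, 0, 1, 0, 1.])
        z = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        x = np.array([0, 2, 1, 1, 0, 2, 1, 1.])  # xbar = 1 in both strata
        data = CaseControlData(y=y, z=z, x=x)
        u = WeightScheme.unit([0, 1])
        assert marginal_test(data, u).U == pytest.approx(
            stratified_test(data, u).U, abs=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(scale=st.floats(0.01, 100.0), seed=st.integers(0, 10 ** 6))
def test_global_weight_rescaling_is_invariant(scale, seed):
    """chi2 and p are unchanged when every stratum weight is multiplied by c > 0."""
    rng = np.random.default_rng(seed)
    data = _random_dataset(rng, n_strata=2, n_min=5, n_max=7)
    base = {0: 0.6, 1: 1.9}
    scaled = {s: scale * w for s, w in base.items()}
    for test in (stratified_test, marginal_test):
        r1 = test(data, WeightScheme(base, "a"))
        r2 = test(data, WeightScheme(scaled, "b"))
        assert r1.chi2 == pytest.approx(r2.chi2, rel=1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(a=st.floats(-5, 5), b=st.floats(0.1, 10.0), seed=st.integers(0, 10 ** 6))
def test_affine_genotype_recoding_is_invariant(a, b, seed):
    rng = np.random.default_rng(seed)
    data = _random_dataset(rng)
    recoded = CaseControlData(y=data.y, z=data.z, x=a + b * data.x)
    u = WeightScheme.unit(data.strata)
    assert stratified_test(data, u).chi2 == pytest.approx(
        stratified_test(recoded, u).chi2, rel=1e-9)


class TestTwoDf:
    @staticmethod
    def _indicator_data(rng, n=60, n_strata=2):
        z = rng.integers(0, n_strata, n)
        g = rng.integers(0, 3, n)
        y = rng.integers(0, 2, n)
        return CaseControlData(y=y, z=z, x=(g == 1).astype(float),
                               x2=(g == 2).astype(float))

    def test_degenerate_second_indicator_reduces_to_1df(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 40)
        z = np.zeros(40, dtype=int)
        x1 = rng.integers(0, 2, 40).astype(float)
        data = CaseControlData(y=y, z=z, x=x1, x2=np.zeros(40))
        u = WeightScheme.unit([0])
        r2 = two_df_test(data, u, mode="stratified")
        r1 = stratified_test(CaseControlData(y=y, z=z, x=x1), u)
        assert r2.df == 1
        assert r2.chi2 == pytest.approx(r1.chi2, abs=1e-10)

    def test_rank_zero_returns_p_one(self):
        data = CaseControlData(y=[0, 1, 0, 1], z=[0] * 4,
                               x=np.ones(4), x2=np.ones(4))
        res = two_df_test(data, WeightScheme.unit([0]), mode="stratified")
        assert res.p_asymptotic == 1.0 and res.warnings

    def test_matches_glm_score_test(self):
        """Unit-weight stratified 2-df statistic vs the Rao score test from a
        logistic regression with stratum factors (statsmodels fit)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(15)
        n = 2000
        z = rng.integers(0, 3, n)
        g = rng.integers(0, 3, n)
        eta = -0.5 + 0.45 * z + 0.3 * (g == 1) + 0.5 * (g == 2)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        data = CaseControlData(y=y, z=z, x=(g == 1).astype(float),
                               x2=(g == 2).astype(float))
        res = two_df_test(data, WeightScheme.unit([0, 1, 2]), mode="stratified")

        Z = np.column_stack([np.ones(n), z == 1, z == 2]).astype(float)
        null = sm.GLM(y, Z, family=sm.families.Binomial()).fit()
        muhat = null.mu
        X = np.column_stack([(g == 1), (g == 2)]).astype(float)
        W = muhat * (1 - muhat)
        U = X.T @ (y - muhat)
        I_xx = (X * W[:, None]).T @ X
        I_xz = (X * W[:, None]).T @ Z
        I_zz = (Z * W[:, None]).T @ Z
        V = I_xx - I_xz @ np.linalg.solve(I_zz, I_xz.T)
        score_stat = float(U @ np.linalg.solve(V, U))
        assert res.chi2 == pytest.approx(score_stat, rel=0.02)


class TestPermutationPvalue:
    def test_zero_statistic_gives_p_one(self):
        # perfectly balanced: U = 0
        data = CaseControlData(y=[0, 0, 1, 1], z=[0] * 4, x=[0., 2, 0, 2])
        res = permutation_pvalue(data, WeightScheme.unit([0]), "stratified",
                                 n_perm=200, seed=1)
        assert res.p_permutation == 1.0

    def test_determinism_and_modes(self):
        rng = np.random.default_rng(21)
        data = _random_dataset(rng, n_strata=2, n_min=6, n_max=7)
        u = WeightScheme.unit(data.strata)
        for mode in ("stratified", "marginal"):
            p1 = permutation_pvalue(data, u, mode, n_perm=500, seed=7).p_permutation
            p2 = permutation_pvalue(data, u, mode, n_perm=500, seed=7).p_permutation
            assert p1 == p2

    def test_agrees_with_asymptotic_on_moderate_sample(self):
        # the permutation null is discrete; agreement tightens as n grows
        rng = np.random.default_rng(2)
        n = 2000
        z = rng.integers(0, 2, n)
        x = rng.integers(0, 3, n).astype(float)
        y = rng.integers(0, 2, n)
        data = CaseControlData(y=y, z=z, x=x)
        u = WeightScheme.unit([0, 1])
        res = permutation_pvalue(data, u, "marginal", n_perm=4000, seed=3)
        se = res.permutation_se
        assert abs(res.p_permutation - res.p_asymptotic) < 3 * se + 0.02
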