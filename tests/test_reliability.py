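"""Weighted kappa, ICC(2,1) and the sample-size calculators."""

import numpy as np
import pytest

from discmorph import (
    ReliabilityResult,
    bonett_icc_n,
    icc_2_1,
    kappa_sample_size,
    weighted_kappa,
)
from discmorph.reliability import crosstab


def brute_force_weighted_kappa(table, weights="linear"):
    """Exhaustive double-loop oracle for K_w on a contingency table."""
    table = np.asarray(table, dtype=float)
    m = table.shape[0]
    n = table.sum()
    po = pe = 0.0
    for i in range(m):
        for j in range(m):
            if weights == "linear":
                w = 1.0 - abs(i - j) / (m - 1)
            else:
                w = 1.0 - (abs(i - j) / (m - 1)) ** 2
            po += w * table[i, j] / n
            pe += w * (table[i, :].sum() / n) * (table[:, j].sum() / n)
    return (po - pe) / (1.0 - pe)


def anova_oracle_icc21(x):
    """From-scratch two-way ANOVA decomposition by explicit loops."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    ssr = ssc = sse = 0.0
    for i in range(n):
        ri = sum(x[i, :]) / k
        ssr += k * (ri - grand) ** 2
    for j in range(k):
        cj = sum(x[:, j]) / n
        ssc += n * (cj - grand) ** 2
    for i in range(n):
        ri = sum(x[i, :]) / k
        for j in range(k):
            cj = sum(x[:, j]) / n
            sse += (x[i, j] - ri - cj + grand) ** 2
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def _pairs_from_table(table):
    m = len(table)
    return [
        (i, j) for i in range(m) for j in range(m) for _ in range(int(table[i][j]))
    ]


class TestWeightedKappa:
    def test_perfect_agreement(self):
        res = weighted_kappa([(2, 2), (3, 3), (1, 1), (4, 4)], categories=[1, 2, 3, 4])
        assert res.estimate == pytest.approx(1.0)

    def test_matches_brute_force_on_toy_table(self, rng):
        table = [[5, 2, 0], [1, 7, 3], [0, 2, 9]]
        for w in ("linear", "quadratic"):
            mine = weighted_kappa(_pairs_from_table(table), categories=range(3),
                                  weights=w)
            assert mine.estimate == pytest.approx(
                brute_force_weighted_kappa(table, w), abs=1e-12
            )

    def test_independent_choices_near_zero(self, rng):
        a = rng.integers(1, 5, size=5000)
        b = rng.integers(1, 5, size=5000)
        res = weighted_kappa(list(zip(a, b)), categories=[1, 2, 3, 4])
        assert abs(res.estimate) < 0.05
        assert res.ci_lower <= 0.0 <= res.ci_upper or abs(res.estimate) < 0.03

    def test_category_order_reversal_invariance(self, rng):
        a = rng.integers(1, 5, size=100)
        b = np.clip(a + rng.integers(-1, 2, size=100), 1, 4)
        fwd = weighted_kappa(list(zip(a, b)), categories=[1, 2, 3, 4])
        rev = weighted_kappa(list(zip(a, b)), categories=[4, 3, 2, 1])
        assert fwd.estimate == pytest.approx(rev.estimate, abs=1e-12)

    def test_two_categories_quadratic_equals_unweighted(self, rng):
        a = rng.integers(0, 2, size=200)
        b = np.where(rng.random(200) < 0.8, a, 1 - a)
        pairs = list(zip(a, b))
        quad = weighted_kappa(pairs, categories=[0, 1], weights="quadratic")
        lin = weighted_kappa(pairs, categories=[0, 1], weights="linear")
        # with 2 categories every weight scheme is the identity/zero matrix
        table, _ = crosstab(pairs, [0, 1])
        po = np.trace(table) / table.sum()
        pr, pc = table.sum(1) / table.sum(), table.sum(0) / table.sum()
        pe = float((pr * pc).sum())
        unweighted = (po - pe) / (1 - pe)
        assert quad.estimate == pytest.approx(unweighted, abs=1e-12)
        assert lin.estimate == pytest.approx(unweighted, abs=1e-12)

    def test_degenerate_single_cell_is_error(self):
        with pytest.raises(ValueError, match="undefined"):
            weighted_kappa([(2, 2)] * 10, categories=[1, 2, 3])

    def test_asymptotic_ci_matches_statsmodels(self, rng):
        from statsmodels.stats.inter_rater import cohens_kappa

        table = rng.integers(0, 12, size=(4, 4)).astype(float)
        table[0, 0] += 5
        res = weighted_kappa(_pairs_from_table(table), categories=range(4))
        sm = cohens_kappa(table, wt="ca")
        assert res.estimate == pytest.approx(sm.kappa, abs=1e-10)
        se_mine = (res.ci_upper - res.estimate) / 1.959963984540054
        assert se_mine == pytest.approx(np.sqrt(sm.var_kappa), abs=1e-8)

    def test_bootstrap_ci_is_seeded_and_sane(self, rng):
        a = rng.integers(1, 5, size=80)
        b = np.clip(a + rng.integers(-1, 2, size=80), 1, 4)
        pairs = list(zip(a, b))
        r1 = weighted_kappa(pairs, categories=[1, 2, 3, 4],
                            ci_method="bootstrap", seed=5, n_boot=300)
        r2 = weighted_kappa(pairs, categories=[1, 2, 3, 4],
                            ci_method="bootstrap", seed=5, n_boot=300)
        assert (r1.ci_lower, r1.ci_upper) == (r2.ci_lower, r2.ci_upper)
        assert r1.ci_lower <= r1.estimate <= r1.ci_upper


class TestIcc21:
    def test_identical_raters_with_subject_variance(self):
        col = np.array([1.0, 2.0, 5.0, 9.0])
        res = icc_2_1(np.column_stack([col, col]))
        assert res.estimate == pytest.approx(1.0)
        assert res.ci_lower == res.ci_upper == 1.0

    def test_matches_anova_oracle_on_toy_table(self):
        x = np.array([[9.0, 2.0], [4.5, 4.0], [8.0, 7.0], [6.0, 6.5]])
        assert icc_2_1(x).estimate == pytest.approx(anova_oracle_icc21(x), abs=1e-12)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        x = rng.normal(size=(15, 3)) + rng.normal(size=(15, 1)) * 2 + [0.0, 0.4, 0.9]
        df = pd.DataFrame({
            "s": np.repeat(range(15), 3), "r": list(range(3)) * 15, "y": x.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="s", raters="r", ratings="y")
        ref = ref.set_index("Type").loc["ICC(A,1)"]
        mine = icc_2_1(x)
        assert mine.estimate == pytest.approx(float(ref["ICC"]), abs=1e-10)

    def test_variance_component_recovery(self, rng):
        n = 2000
        subj = rng.normal(0, 3.0, size=(n, 1))          # sigma_s^2 = 9
        biases = np.array([-0.35355339, 0.35355339])    # rater component 0.25
        x = subj + biases + rng.normal(0, 1.0, size=(n, 2))
        res = icc_2_1(x)
        assert res.estimate == pytest.approx(9 / 10.25, abs=0.02)

    def test_shift_and_column_permutation_invariance(self, rng):
        x = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1))
        base = icc_2_1(x).estimate
        assert icc_2_1(x + 17.3).estimate == pytest.approx(base, abs=1e-10)
        assert icc_2_1(x[:, [2, 0, 1]]).estimate == pytest.approx(base, abs=1e-10)

    def test_ci_contains_estimate_and_shrinks_with_n(self, rng):
        def width(n):
            subj = rng.normal(0, 2.0, size=(n, 1))
            x = subj + rng.normal(0, 1.0, size=(n, 2))
            r = icc_2_1(x)
            assert r.ci_lower <= r.estimate <= r.ci_upper
            return r.ci_upper - r.ci_lower

        assert width(400) < width(12)

    def test_degenerate_constant_table_is_error(self):
        with pytest.raises(ValueError, match="undefined"):
            icc_2_1(np.zeros((5, 2)))

    def test_incomplete_table_rejected(self):
        x = np.ones((4, 2))
        x[1, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            icc_2_1(x)


class TestSampleSizes:
    @pytest.mark.parametrize("k,expected", [(2, 8), (3, 18), (4, 32)])
    def test_kappa_rule(self, k, expected):
        assert kappa_sample_size(k) == expected

    def test_bonett_reference_case(self):
        assert bonett_icc_n(rho=0.9, alpha=0.05, width=0.2, k_raters=2) == 15

    def test_bonett_matches_symbolic_rederivation(self):
        import sympy

        rho, w, k = sympy.Rational(7, 10), sympy.Rational(1, 5), 2
        z = 1.959963984540054
        n = 8 * z**2 * (1 - rho) ** 2 * (1 + (k - 1) * rho) ** 2 / (
            k * (k - 1) * w**2
        ) + 1
        assert bonett_icc_n(0.7, 0.05, 0.2, 2) == int(np.ceil(float(n) - 1e-9))

    def test_bonett_monotone_in_rho(self):
        ns = [bonett_icc_n(r) for r in (0.5, 0.6, 0.7, 0.8, 0.9, 0.95)]
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            kappa_sample_size(1)
        with pytest.raises(ValueError):
            bonett_icc_n(rho=1.2)
        with pytest.raises(ValueError):
            bonett_icc_n(rho=0.9, width=0.0)


def test_result_invariant_enforced():
    with pytest.raises(ValueError):
        ReliabilityResult(estimate=0.9, ci_lower=0.95, ci_upper=1.0, method="x", n=5)
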