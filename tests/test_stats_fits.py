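import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st
from scipy import stats as sps

from hfovbench.stats_fits import (
    fit_exponential,
    fit_linear,
    fit_power,
    fit_quadratic,
    one_way_anova_tukey,
    significance_band,
)


def normal_equations(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Brute-force OLS oracle: solve X'X beta = X'y directly."""
    return np.linalg.solve(design.T @ design, design.T @ y)


def anova_f_oracle(groups):
    """Brute-force F from explicit sums of squares."""
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
    ssw = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values())
    k = len(groups)
    n = len(all_vals)
    return (ssb / (k - 1)) / (ssw / (n - k))


class TestFitLinear:
    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_linear(x, 2 * x + 1)
        assert fit.coefficients["slope"] == pytest.approx(2.0)
        assert fit.coefficients["intercept"] == pytest.approx(1.0)
        assert fit.correlation == pytest.approx(1.0)
        assert fit.p_value == pytest.approx(0.0, abs=1e-12)

    def test_negative_correlation(self):
        x = np.array([1.0, 2.0, 3.0])
        fit = fit_linear(x, -x)
        assert fit.correlation == pytest.approx(-1.0)

    def test_against_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        x = np.array([1.0, 3.0, 4.0, 7.0, 9.0])
        y = 0.8 * x + 2.0 + rng.normal(0, 0.3, 5)
        fit = fit_linear(x, y)
        beta = normal_equations(np.column_stack([x, np.ones(5)]), y)
        assert fit.coefficients["slope"] == pytest.approx(beta[0], rel=1e-9)
        assert fit.coefficients["intercept"] == pytest.approx(beta[1], rel=1e-9)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_linear([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_min_points(self):
        with pytest.raises(ValueError):
            fit_linear([1.0, 2.0], [1.0, 2.0])


class TestFitPower:
    def test_exact_power(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        fit = fit_power(x, 2.0 * x**1.5)
        assert fit.coefficients["exponent"] == pytest.approx(1.5)
        assert fit.coefficients["amplitude"] == pytest.approx(2.0)
        assert fit.correlation == pytest.approx(1.0)

    def test_constant_y(self):
        fit = fit_power([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert fit.coefficients["exponent"] == pytest.approx(0.0)
        assert fit.coefficients["amplitude"] == pytest.approx(5.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_power([1.0, 2.0, 3.0], [1.0, -1.0, 2.0])

    @given(scale=st.floats(min_value=0.1, max_value=100.0))
    @hyp_settings(max_examples=30)
    def test_rescale_equivariance(self, scale):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        y = 3.0 * x**1.2
        a = fit_power(x, y)
        b = fit_power(x, scale * y)
        assert b.coefficients["exponent"] == pytest.approx(
            a.coefficients["exponent"], rel=1e-9
        )
        assert b.coefficients["amplitude"] == pytest.approx(
            scale * a.coefficients["amplitude"], rel=1e-9
        )


class TestFitExponential:
    def test_exact_decay(self):
        x = np.array([0.5, 1.0, 2.0, 3.0, 4.0])
        fit = fit_exponential(x, 7.54 * np.exp(-0.3 * x))
        assert fit.coefficients["y_intercept"] == pytest.approx(7.54)
        assert fit.coefficients["rate"] == pytest.approx(0.3)
        assert fit.correlation == pytest.approx(-1.0)

    def test_constant_y_zero_rate(self):
        fit = fit_exponential([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])
        assert fit.coefficients["rate"] == pytest.approx(0.0)

    def test_nonpositive_y_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_exponential([1.0, 2.0, 3.0], [1.0, 0.0, 2.0])

    @given(scale=st.floats(min_value=0.1, max_value=100.0))
    @hyp_settings(max_examples=30)
    def test_rescale_equivariance(self, scale):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = 5.0 * np.exp(-0.4 * x)
        a = fit_exponential(x, y)
        b = fit_exponential(x, scale * y)
        assert b.coefficients["rate"] == pytest.approx(a.coefficients["rate"], rel=1e-9)
        assert b.coefficients["y_intercept"] == pytest.approx(
            scale * a.coefficients["y_intercept"], rel=1e-9
        )


class TestFitQuadratic:
    def test_exact_square(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        fit = fit_quadratic(x, x**2)
        assert fit.coefficients["a2"] == pytest.approx(1.0)
        assert fit.coefficients["a1"] == pytest.approx(0.0, abs=1e-12)
        assert fit.coefficients["a0"] == pytest.approx(0.0, abs=1e-12)
        assert fit.correlation == pytest.approx(1.0)

    def test_linear_data_zero_quadratic_term(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        fit = fit_quadratic(x, 3.0 * x + 1.0)
        assert fit.coefficients["a2"] == pytest.approx(0.0, abs=1e-10)

    def test_against_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        x = np.array([0.0, 1.0, 2.0, 4.0, 6.0, 9.0])
        y = 0.5 * x**2 - x + 3 + rng.normal(0, 0.2, 6)
        fit = fit_quadratic(x, y)
        beta = normal_equations(np.column_stack([x**2, x, np.ones(6)]), y)
        assert fit.coefficients["a2"] == pytest.approx(beta[0], rel=1e-8)
        assert fit.coefficients["a1"] == pytest.approx(beta[1], rel=1e-8)
        assert fit.coefficients["a0"] == pytest.approx(beta[2], rel=1e-8)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_quadratic([1.0, 1.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0])


class TestExactFitProperty:
    def test_each_family_reproduces_generator(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        cases = [
            (fit_linear, 2 * x - 1),
            (fit_power, 0.5 * x**1.8),
            (fit_exponential, 4.0 * np.exp(-0.2 * x)),
            (fit_quadratic, x**2 + x + 1),
        ]
        for fitter, y in cases:
            fit = fitter(x, y)
            assert abs(fit.correlation) == pytest.approx(1.0)
            np.testing.assert_allclose(fit.predict(x), y, rtol=1e-8)


class TestAnovaTukey:
    def test_identical_groups_degenerate(self):
        res = one_way_anova_tukey({"a": [5.0, 5.0], "b": [5.0, 5.0], "c": [5.0, 5.0]})
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0
        assert res.degenerate

    def test_well_separated_groups(self):
        rng = np.random.default_rng(0)
        groups = {
            "lo": rng.normal(0.0, 1.0, 5),
            "hi": rng.normal(100.0, 1.0, 5),
        }
        res = one_way_anova_tukey(groups)
        assert res.p_value < 0.001
        assert res.tukey_pairs[0].band == "<0.001"

    def test_f_against_brute_force_and_scipy(self):
        rng = np.random.default_rng(3)
        groups = {
            "a": rng.normal(0.0, 1.0, 5),
            "b": rng.normal(1.0, 1.0, 5),
            "c": rng.normal(2.5, 1.0, 5),
        }
        res = one_way_anova_tukey(groups)
        assert res.f_statistic == pytest.approx(anova_f_oracle(groups), rel=1e-10)
        f_sp, p_sp = sps.f_oneway(*groups.values())
        assert res.f_statistic == pytest.approx(f_sp, rel=1e-10)
        assert res.p_value == pytest.approx(p_sp, rel=1e-10)

    def test_f_against_permutation_oracle(self):
        rng = np.random.default_rng(4)
        groups = {
            "a": rng.normal(0.0, 1.0, 5),
            "b": rng.normal(0.8, 1.0, 5),
            "c": rng.normal(1.6, 1.0, 5),
        }
        res = one_way_anova_tukey(groups)
        pooled = np.concatenate(list(groups.values()))
        observed = res.f_statistic
        count = 0
        n_perm = 4000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            shuffled = {"a": perm[:5], "b": perm[5:10], "c": perm[10:]}
            if anova_f_oracle(shuffled) >= observed:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
        assert p_perm == pytest.approx(res.p_value, abs=0.03)

    def test_tukey_against_scipy(self):
        rng = np.random.default_rng(8)
        samples = [rng.normal(mu, 1.0, 5) for mu in (0.0, 1.0, 3.0)]
        res = one_way_anova_tukey({"a": samples[0], "b": samples[1], "c": samples[2]})
        sp = sps.tukey_hsd(*samples)
        idx = {("a", "b"): (0, 1), ("a", "c"): (0, 2), ("b", "c"): (1, 2)}
        for pair in res.tukey_pairs:
            i, j = idx[(pair.group_a, pair.group_b)]
            assert pair.p_adj == pytest.approx(sp.pvalue[i, j], abs=1e-8)

    def test_pair_count(self):
        rng = np.random.default_rng(1)
        for k in (2, 3, 4, 5):
            groups = {f"g{i}": rng.normal(i, 1.0, 5) for i in range(k)}
            res = one_way_anova_tukey(groups)
            assert len(res.tukey_pairs) == k * (k - 1) // 2

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        groups = {g: rng.normal(i, 1.0, 5) for i, g in enumerate("abc")}
        shifted = {g: np.asarray(v) + 37.5 for g, v in groups.items()}
        a = one_way_anova_tukey(groups)
        b = one_way_anova_tukey(shifted)
        assert a.f_statistic == pytest.approx(b.f_statistic, rel=1e-9)
        for pa, pb in zip(a.tukey_pairs, b.tukey_pairs):
            assert pa.p_adj == pytest.approx(pb.p_adj, rel=1e-6)

    def test_band_symmetry_in_group_order(self):
        rng = np.random.default_rng(6)
        g1 = rng.normal(0, 1, 5)
        g2 = rng.normal(2, 1, 5)
        a = one_way_anova_tukey({"x": g1, "y": g2})
        b = one_way_anova_tukey({"y": g2, "x": g1})
        assert a.tukey_pairs[0].p_adj == pytest.approx(b.tukey_pairs[0].p_adj)
        assert a.tukey_pairs[0].band == b.tukey_pairs[0].band

    def test_validation(self):
        with pytest.raises(ValueError):
            one_way_anova_tukey({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            one_way_anova_tukey({"a": [1.0, 2.0], "b": [1.0]})


def test_significance_bands():
    assert significance_band(0.2) == "ns"
    assert significance_band(0.04) == "<0.05"
    assert significance_band(0.005) == "<0.01"
    assert significance_band(0.0005) == "<0.001"
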