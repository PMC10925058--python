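"""Model zoo, BIC, likelihood-ratio test, KDE two-sample test."""

import math

import numpy as np
import pandas as pd
import pytest

from pulmopet.coupling_stats import (MODEL_FORMS, best_fit, bic, fit_form,
                                     fit_model_zoo, fit_stratified_linear,
                                     kde_two_sample_test, likelihood_ratio_test,
                                     plugin_bandwidth)
from pulmopet.phantom import PhantomConfig, sample_coupling_cloud


def _cloud(condition, seed):
    x, y = sample_coupling_cloud(PhantomConfig(), condition,
                                 np.random.default_rng(seed))
    return np.column_stack([x, y])


class TestFitForm:
    def test_exact_line_is_interpolated(self):
        x = np.linspace(0.3, 1.8, 40)
        y = 0.32 + 0.690 * x
        f = fit_form("y=a+bx", x, y)
        assert f.rss < 1e-20
        assert f.coefficients == pytest.approx((0.32, 0.690), abs=1e-10)

    def test_through_origin_hand_ols(self):
        # a = sum(xy)/sum(x^2) = 17/14; RSS = 5/14
        f = fit_form("y=ax", np.array([0.0, 1, 2, 3]), np.array([0.0, 1, 2, 4]))
        assert f.coefficients[0] == pytest.approx(17 / 14)
        assert f.rss == pytest.approx(0.35714285, abs=1e-6)

    @pytest.mark.parametrize("form", ["y=ax", "y=a+bx", "y=ax+bx^2", "y=a+bx+cx^2"])
    def test_polynomials_match_normal_equations(self, form):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.2, 2.0, 60)
        y = 0.3 + 0.7 * x - 0.2 * x**2 + rng.normal(0, 0.1, 60)
        f = fit_form(form, x, y)
        X = MODEL_FORMS[form].design(x)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(f.coefficients, beta, atol=1e-10)
        assert f.rss == pytest.approx(float(np.sum((y - X @ beta) ** 2)), abs=1e-10)

    def test_exponential_recovery(self):
        x = np.linspace(0.1, 1.9, 80)
        f = fit_form("y=ae^(bx)", x, 0.503 * np.exp(0.650 * x))
        assert f.coefficients == pytest.approx((0.503, 0.650), abs=1e-6)
        f1 = fit_form("y=e^(ax)", x, np.exp(0.4 * x))
        assert f1.coefficients[0] == pytest.approx(0.4, abs=1e-8)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            fit_form("y=a+bx", np.ones(20), np.arange(20.0))

    def test_zoo_covers_six_forms_and_orientations(self):
        X = _cloud("baseline", 0)
        fits = fit_model_zoo(X[:, 0], X[:, 1])
        assert len(fits) == 12
        assert {f.orientation for f in fits} == {"F_bn~Q_n", "Q_n~F_bn"}

    def test_zoo_requires_ten_points(self):
        with pytest.raises(ValueError, match="10"):
            fit_model_zoo(np.arange(5.0), np.arange(5.0))


class TestBic:
    def test_hand_value(self):
        # n*ln(RSS/n) + (k+1)*ln(n) at n=4, RSS=5/14, k=1
        val = bic(4, 5 / 14, 1)
        assert val == pytest.approx(4 * math.log((5 / 14) / 4) + 2 * math.log(4))
        assert val == pytest.approx(-6.891, abs=1e-3)

    def test_monotone_in_rss(self):
        assert bic(100, 1.0, 2) < bic(100, 2.0, 2)

    def test_sample_size_scaling(self):
        # doubling n at fixed RSS/n and k shifts BIC by the n*ln term
        b1, b2 = bic(100, 100 * 0.04, 2), bic(200, 200 * 0.04, 2)
        assert b2 - b1 == pytest.approx(100 * math.log(0.04)
                                        + 3 * (math.log(200) - math.log(100)))

    def test_exact_fit_rejected(self):
        with pytest.raises(ValueError, match="exact"):
            bic(10, 0.0, 1)

    def test_conventions_agree_on_ordering(self):
        a1 = bic(50, 2.0, 1) - bic(50, 1.0, 2)
        a2 = (bic(50, 2.0, 1, "full_gaussian") - bic(50, 1.0, 2, "full_gaussian"))
        assert a1 == pytest.approx(a2)

    def test_tie_break_prefers_smaller_model(self):
        f_small = fit_form("y=ax", np.array([1.0, 2, 3, 4]) * 1.0,
                           np.array([1.0, 2, 3, 4.1]))
        f_big = f_small.__class__("y=a+bx", (0.0, 1.0), f_small.orientation,
                                  f_small.n, 2, f_small.rss, f_small.loglik,
                                  f_small.bic)
        assert best_fit([f_big, f_small]).form == "y=ax"


class TestLrt:
    def _fits(self, y):
        x = np.linspace(0.2, 1.8, 100)
        return (fit_form("y=a+bx", x, y(x)), fit_form("y=a+bx+cx^2", x, y(x)))

    def test_identical_rss_gives_zero(self):
        lin = fit_form("y=a+bx", np.linspace(0, 1, 50),
                       0.3 + 0.5 * np.linspace(0, 1, 50))
        out = likelihood_ratio_test(lin, fit_form(
            "y=a+bx+cx^2", np.linspace(0, 1, 50), 0.3 + 0.5 * np.linspace(0, 1, 50)))
        assert out.chi_square == pytest.approx(0.0, abs=1e-6)
        assert out.p_value == pytest.approx(1.0, abs=1e-3)

    def test_formula(self):
        # chi2 = n*ln(RSS_red/RSS_full): ratio e at n=100 -> 100
        red = fit_form("y=ax", np.array([0.0, 1, 2, 3]), np.array([0.0, 1, 2, 4]))
        full = red.__class__("y=ax+bx^2", red.coefficients + (0.0,),
                             red.orientation, 100, 2, red.rss / math.e,
                             red.loglik, red.bic)
        red = red.__class__(red.form, red.coefficients, red.orientation, 100,
                            1, red.rss, red.loglik, red.bic)
        out = likelihood_ratio_test(red, full)
        assert out.chi_square == pytest.approx(100.0)
        assert out.df == 1

    def test_non_nested_rejected(self):
        x = np.linspace(0.1, 2, 30)
        f1 = fit_form("y=e^(ax)", x, np.exp(0.3 * x))
        f2 = fit_form("y=a+bx", x, np.exp(0.3 * x))
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(f1, f2)

    def test_injury_curvature_detected(self):
        """Linear-vs-quadratic on injury-type clouds rejects at alpha=0.001
        in nearly every replicate."""
        cfg = PhantomConfig()
        rng = np.random.default_rng(17)
        rej = 0
        n = 60
        for _ in range(n):
            x, y = sample_coupling_cloud(cfg, "injury", rng)
            out = likelihood_ratio_test(fit_form("y=a+bx", x, y),
                                        fit_form("y=a+bx+cx^2", x, y))
            rej += out.p_value < 0.001
        assert rej >= 0.95 * n


class TestKdeTest:
    def test_symmetry(self):
        X, Y = _cloud("baseline", 1), _cloud("injury", 2)
        r1, r2 = kde_two_sample_test(X, Y), kde_two_sample_test(Y, X)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_affine_invariance_permutation(self):
        X, Y = _cloud("baseline", 3), _cloud("injury", 4)
        A = np.array([[2.0, 0.3], [0.1, 0.5]])
        b = np.array([1.0, -2.0])
        r1 = kde_two_sample_test(X, Y, method="permutation", seed=11,
                                 n_permutations=199)
        r2 = kde_two_sample_test(X @ A + b, Y @ A + b, method="permutation",
                                 seed=11, n_permutations=199)
        assert abs(r1.p_value - r2.p_value) < 1e-6

    def test_distinct_clouds_detected(self):
        r = kde_two_sample_test(_cloud("baseline", 5), _cloud("injury", 6))
        assert r.p_value < 0.001

    def test_asymptotic_and_permutation_agree(self):
        """Median |p_asym - p_perm| over 50 null replicates stays below 0.02."""
        cfg = PhantomConfig()
        rng = np.random.default_rng(29)
        diffs = []
        for i in range(50):
            x1, y1 = sample_coupling_cloud(cfg, "baseline", rng)
            x2, y2 = sample_coupling_cloud(cfg, "baseline", rng)
            X, Y = np.column_stack([x1, y1]), np.column_stack([x2, y2])
            pa = kde_two_sample_test(X, Y).p_value
            pp = kde_two_sample_test(X, Y, method="permutation", seed=i,
                                     n_permutations=999).p_value
            diffs.append(abs(pa - pp))
        assert np.median(diffs) < 0.02

    def test_bandwidth_is_spd(self):
        H = plugin_bandwidth(_cloud("baseline", 7))
        assert np.allclose(H, H.T)
        assert np.all(np.linalg.eigvalsh(H) > 0)

    def test_small_or_degenerate_samples_rejected(self):
        with pytest.raises(ValueError, match="20"):
            kde_two_sample_test(np.zeros((5, 2)), np.zeros((25, 2)))
        X = _cloud("baseline", 8)
        Y = X.copy()
        Y[:, 1] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            kde_two_sample_test(X, Y)


class TestStratified:
    def _table(self, y_fn, n=150):
        rng = np.random.default_rng(0)
        h = rng.uniform(0, 1, n)
        x = 0.3 + 1.5 * (1 - h) + rng.normal(0, 0.05, n)
        return pd.DataFrame({"height_fraction": h, "Q_n": x, "F_bn": y_fn(x)})

    def test_global_linear_gives_identical_slopes(self):
        tab = self._table(lambda x: 0.2 + 0.8 * x)
        fits = fit_stratified_linear(tab, 3)
        slopes = [f.coefficients[1] for _, f in fits]
        assert np.allclose(slopes, 0.8, atol=1e-9)

    def test_concave_curve_gives_decreasing_slopes(self):
        # strata are dependent-to-nondependent, i.e. decreasing Q_n
        tab = self._table(lambda x: 1.684 * x - 0.538 * x**2)
        fits = fit_stratified_linear(tab, 3)
        slopes = [f.coefficients[1] for _, f in fits]
        # stratum 0 (low height) has the highest Q_n -> smallest local slope
        assert slopes[0] < slopes[1] < slopes[2]

    def test_single_stratum_equals_global_fit(self):
        tab = self._table(lambda x: 0.2 + 0.8 * x)
        (_, f1), = fit_stratified_linear(tab, 1)
        f2 = fit_form("y=a+bx", tab["Q_n"], tab["F_bn"])
        assert f1.coefficients == pytest.approx(f2.coefficients)

    def test_small_stratum_listed_in_error(self):
        tab = self._table(lambda x: x, n=12)
        with pytest.raises(ValueError, match="strata"):
            fit_stratified_linear(tab, 4)
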