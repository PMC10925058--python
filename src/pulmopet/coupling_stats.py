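"""Statistics of the perfusion-blood-volume coupling.

This module carries the inferential layer applied to pooled (Q_n, F_bn)
point clouds:

* a six-model least-squares zoo (``y=ax``, ``y=a+bx``, ``y=ax+bx^2``,
  ``y=a+bx+cx^2``, ``y=e^(ax)``, ``y=ae^(bx)``) ranked by the Bayesian
  information criterion, fitted in either variable orientation;
* likelihood-ratio tests between nested forms;
* a nonparametric two-sample test for equality of two bivariate
  distributions based on the integrated squared difference of Gaussian
  kernel density estimates with unconstrained plug-in bandwidth matrices;
* piecewise-linear fits stratified by lung height.

All fits assume i.i.d. Gaussian residuals, so the maximized log-likelihood
is ``-n/2 * (ln(2*pi*RSS/n) + 1)`` and the default BIC convention counts the
error variance as one extra parameter: ``BIC = n*ln(RSS/n) + (k+1)*ln(n)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from scipy.optimize import least_squares, minimize

__all__ = [
    "MODEL_FORMS",
    "ModelFit",
    "KdeTestResult",
    "LrtResult",
    "fit_form",
    "fit_model_zoo",
    "best_fit",
    "bic",
    "gaussian_loglik",
    "likelihood_ratio_test",
    "plugin_bandwidth",
    "kde_two_sample_test",
    "fit_stratified_linear",
]


# ---------------------------------------------------------------------------
# model zoo
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelForm:
    name: str
    k: int                      # number of mean-function parameters
    design: Callable | None     # linear-in-parameters design matrix, or None
    predict: Callable           # predict(coef, x)


def _exp1_predict(c, x):
    return np.exp(np.clip(c[0] * x, -700, 700))


def _exp2_predict(c, x):
    return c[0] * np.exp(np.clip(c[1] * x, -700, 700))


MODEL_FORMS: dict[str, ModelForm] = {
    "y=ax": ModelForm("y=ax", 1, lambda x: x[:, None],
                      lambda c, x: c[0] * x),
    "y=a+bx": ModelForm("y=a+bx", 2, lambda x: np.column_stack([np.ones_like(x), x]),
                        lambda c, x: c[0] + c[1] * x),
    "y=ax+bx^2": ModelForm("y=ax+bx^2", 2, lambda x: np.column_stack([x, x**2]),
                           lambda c, x: c[0] * x + c[1] * x**2),
    "y=a+bx+cx^2": ModelForm("y=a+bx+cx^2", 3,
                             lambda x: np.column_stack([np.ones_like(x), x, x**2]),
                             lambda c, x: c[0] + c[1] * x + c[2] * x**2),
    "y=e^(ax)": ModelForm("y=e^(ax)", 1, None, _exp1_predict),
    "y=ae^(bx)": ModelForm("y=ae^(bx)", 2, None, _exp2_predict),
}

#: (reduced, full) pairs for which the likelihood-ratio test is defined
_NESTED: frozenset[tuple[str, str]] = frozenset({
    ("y=ax", "y=a+bx"),
    ("y=ax", "y=ax+bx^2"),
    ("y=ax", "y=a+bx+cx^2"),
    ("y=a+bx", "y=a+bx+cx^2"),
    ("y=ax+bx^2", "y=a+bx+cx^2"),
    ("y=e^(ax)", "y=ae^(bx)"),
})


@dataclass(frozen=True)
class ModelFit:
    form: str
    coefficients: tuple[float, ...]
    orientation: str
    n: int
    k: int
    rss: float
    loglik: float
    bic: float
    converged: bool = True

    def predict(self, x: np.ndarray) -> np.ndarray:
        return MODEL_FORMS[self.form].predict(np.asarray(self.coefficients),
                                              np.asarray(x, dtype=float))


def gaussian_loglik(n: int, rss: float) -> float:
    """Maximized Gaussian log-likelihood given the residual sum of squares."""
    if rss <= 0:
        return math.inf
    return -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)


def bic(fit_or_n, rss: float | None = None, k: int | None = None,
        convention: str = "variance_counted") -> float:
    """BIC of a Gaussian least-squares fit.

    ``variance_counted`` (default): ``n*ln(RSS/n) + (k+1)*ln(n)``, counting the
    error variance as a fitted parameter. ``full_gaussian`` keeps the additive
    Gaussian constants: ``-2*logLik + (k+1)*ln(n)``. Both orderings agree.
    """
    if isinstance(fit_or_n, ModelFit):
        n, rss, k = fit_or_n.n, fit_or_n.rss, fit_or_n.k
    else:
        n = int(fit_or_n)
        if rss is None or k is None:
            raise TypeError("bic(n, rss, k) requires rss and k")
    if rss == 0:
        raise ValueError("RSS is exactly zero (exact fit): BIC undefined; "
                         "handle exact interpolation separately")
    if rss < 0:
        raise ValueError("RSS must be non-negative")
    if convention == "variance_counted":
        return n * math.log(rss / n) + (k + 1) * math.log(n)
    if convention == "full_gaussian":
        return -2.0 * gaussian_loglik(n, rss) + (k + 1) * math.log(n)
    raise ValueError(f"unknown BIC convention: {convention!r}")


def _fit_exponential(form: ModelForm, x: np.ndarray, y: np.ndarray
                     ) -> tuple[np.ndarray, float, bool]:
    """Original-space nonlinear least squares with log-space initialization."""
    ylog = np.log(np.clip(y, 1e-8, None))
    if form.name == "y=e^(ax)":
        sx2 = float(np.sum(x * x))
        a0 = float(np.sum(x * ylog) / sx2) if sx2 > 0 else 0.0
        x0, lo, hi = np.array([a0]), np.array([-50.0]), np.array([50.0])
    else:  # y = a*e^(bx)
        X = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(X, ylog, rcond=None)
        x0 = np.array([math.exp(np.clip(coef[0], -20, 20)), coef[1]])
        lo, hi = np.array([1e-12, -50.0]), np.array([1e12, 50.0])
    x0 = np.clip(x0, lo, hi)
    sol = least_squares(lambda c: form.predict(c, x) - y, x0, bounds=(lo, hi),
                        method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                        max_nfev=2000)
    return sol.x, float(np.sum(sol.fun**2)), bool(sol.status > 0)


def fit_form(form_name: str, x: Sequence[float], y: Sequence[float],
             orientation: str = "y~x",
             bic_convention: str = "variance_counted") -> ModelFit:
    """Least-squares fit of one model form."""
    form = MODEL_FORMS[form_name]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    n = x.size
    converged = True
    if form.design is not None:
        X = form.design(x)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"singular design for form {form_name!r} "
                             "(constant or degenerate x)")
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        rss = float(resid @ resid)
    else:
        if np.allclose(x, x[0]):
            raise ValueError(f"singular design for form {form_name!r} (constant x)")
        coef, rss, converged = _fit_exponential(form, x, y)
    ll = gaussian_loglik(n, rss)
    b = bic(n, rss, form.k, bic_convention) if rss > 0 else -math.inf
    return ModelFit(form.name, tuple(float(c) for c in coef), orientation,
                    n, form.k, rss, ll, b, converged)


def fit_model_zoo(x: Sequence[float], y: Sequence[float],
                  x_name: str = "Q_n", y_name: str = "F_bn",
                  both_orientations: bool = True,
                  bic_convention: str = "variance_counted") -> list[ModelFit]:
    """Fit all six candidate forms, optionally in both variable orientations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 points for the model comparison")
    fits = [fit_form(name, x, y, orientation=f"{y_name}~{x_name}",
                     bic_convention=bic_convention) for name in MODEL_FORMS]
    if both_orientations:
        fits += [fit_form(name, y, x, orientation=f"{x_name}~{y_name}",
                          bic_convention=bic_convention) for name in MODEL_FORMS]
    return fits


def best_fit(fits: Iterable[ModelFit], within_orientation: str | None = None
             ) -> ModelFit:
    """Lowest-BIC fit; BIC ties within 1e-6 go to the smaller model."""
    pool = [f for f in fits
            if within_orientation is None or f.orientation == within_orientation]
    if not pool:
        raise ValueError("no fits to rank")
    return min(pool, key=lambda f: (round(f.bic / 1e-6) * 1e-6, f.k))


@dataclass(frozen=True)
class LrtResult:
    chi_square: float
    df: int
    p_value: float


def likelihood_ratio_test(fit_reduced: ModelFit, fit_full: ModelFit) -> LrtResult:
    """Chi-square LRT between nested Gaussian least-squares fits.

    chi^2 = 2*(logLik_full - logLik_reduced) = n*ln(RSS_reduced/RSS_full).
    """
    if (fit_reduced.form, fit_full.form) not in _NESTED:
        raise ValueError(f"{fit_reduced.form!r} is not nested in {fit_full.form!r}")
    if fit_reduced.n != fit_full.n or fit_reduced.orientation != fit_full.orientation:
        raise ValueError("LRT requires fits on identical data and orientation")
    if fit_full.rss <= 0:
        raise ValueError("full-model RSS must be positive")
    chi2 = max(0.0, fit_reduced.n * math.log(fit_reduced.rss / fit_full.rss))
    df = fit_full.k - fit_reduced.k
    return LrtResult(chi2, df, float(_stats.chi2.sf(chi2, df)))


# ---------------------------------------------------------------------------
# two-sample kernel density test
# ---------------------------------------------------------------------------

def _gauss_kernel_sums(diff: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """phi_Sigma evaluated at an (m, d) array of differences."""
    d = Sigma.shape[0]
    Sinv = np.linalg.inv(Sigma)
    det = np.linalg.det(Sigma)
    q = np.einsum("ij,jk,ik->i", diff, Sinv, diff)
    return np.exp(-0.5 * q) / ((2.0 * math.pi) ** (d / 2) * math.sqrt(det))


def _phi0(Sigma: np.ndarray) -> float:
    d = Sigma.shape[0]
    return 1.0 / ((2.0 * math.pi) ** (d / 2) * math.sqrt(np.linalg.det(Sigma)))


def _pairwise_diff(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return (A[:, None, :] - B[None, :, :]).reshape(-1, A.shape[1])


def _psi_hat(A: np.ndarray, B: np.ndarray, Sigma: np.ndarray) -> float:
    """V-statistic (1/(nA*nB)) * sum_ij phi_Sigma(A_i - B_j)."""
    vals = _gauss_kernel_sums(_pairwise_diff(A, B), Sigma)
    return float(vals.sum() / (A.shape[0] * B.shape[0]))


def plugin_bandwidth(X: np.ndarray) -> np.ndarray:
    """Unconstrained two-stage plug-in bandwidth matrix for a 2-D sample.

    The sample is pre-whitened by its covariance; fourth-order integrated
    density-derivative functionals are estimated there with an isotropic
    normal-scale-order pilot, the asymptotic MISE criterion is minimized over
    all symmetric positive-definite matrices, and the result is mapped back.
    Falls back to the normal-scale matrix if the minimization degenerates.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if d != 2:
        raise ValueError("plugin_bandwidth is implemented for 2-D samples")
    S = np.cov(X.T)
    if np.linalg.det(S) <= 0:
        raise ValueError("degenerate sample (singular covariance)")
    evals, evecs = np.linalg.eigh(S)
    S_half = evecs @ np.diag(np.sqrt(evals)) @ evecs.T
    S_ihalf = evecs @ np.diag(evals ** -0.5) @ evecs.T
    Z = X @ S_ihalf

    h_ns2 = (4.0 / ((d + 2) * n)) ** (2.0 / (d + 4))  # normal-scale (whitened)

    # stage 1: psi_r, |r| = 4, isotropic pilot on whitened data
    g = n ** (-1.0 / (d + 6))
    diff = _pairwise_diff(Z, Z) / g
    u, v = diff[:, 0], diff[:, 1]
    phi = np.exp(-0.5 * (u * u + v * v)) / (2.0 * math.pi * g * g)
    he = {1: lambda t: t, 2: lambda t: t * t - 1.0,
          3: lambda t: t**3 - 3.0 * t, 4: lambda t: t**4 - 6.0 * t * t + 3.0}

    def psi(r1: int, r2: int) -> float:
        f1 = he[r1](u) if r1 else 1.0
        f2 = he[r2](v) if r2 else 1.0
        return float(np.sum(f1 * f2 * phi) / (n * n * g ** 4))

    p40, p31, p22, p13, p04 = psi(4, 0), psi(3, 1), psi(2, 2), psi(1, 3), psi(0, 4)

    def pi_crit(p: np.ndarray) -> float:
        l11, l21, l22 = math.exp(p[0]), p[1], math.exp(p[2])
        h11 = l11 * l11
        h12 = l11 * l21
        h22 = l21 * l21 + l22 * l22
        det = (l11 * l22) ** 2
        var_term = (4.0 * math.pi) ** (-d / 2) / (n * math.sqrt(det))
        bias = (h11 * h11 * p40 + 4.0 * h11 * h12 * p31
                + (2.0 * h11 * h22 + 4.0 * h12 * h12) * p22
                + 4.0 * h12 * h22 * p13 + h22 * h22 * p04)
        return var_term + 0.25 * bias

    p0 = np.array([0.5 * math.log(h_ns2), 0.0, 0.5 * math.log(h_ns2)])
    Hw = np.array([[h_ns2, 0.0], [0.0, h_ns2]])
    if p40 > 0 and p04 > 0:
        res = minimize(pi_crit, p0, method="Nelder-Mead",
                       options={"maxiter": 600, "xatol": 1e-8, "fatol": 1e-12})
        l11, l21, l22 = math.exp(res.x[0]), res.x[1], math.exp(res.x[2])
        cand = np.array([[l11 * l11, l11 * l21],
                         [l11 * l21, l21 * l21 + l22 * l22]])
        # reject degenerate optima (criterion running away)
        ev = np.linalg.eigvalsh(cand)
        if res.success and ev.min() > 1e-8 * h_ns2 and ev.max() < 1e4 * h_ns2:
            Hw = cand
    return S_half @ Hw @ S_half


@dataclass(frozen=True)
class KdeTestResult:
    statistic: float
    null_mean: float
    null_var: float
    z: float
    p_value: float
    H1: np.ndarray
    H2: np.ndarray
    method: str
    n1: int
    n2: int
    n_permutations: int = 0


def kde_two_sample_test(X: np.ndarray, Y: np.ndarray,
                        method: str = "asymptotic",
                        H1: np.ndarray | None = None,
                        H2: np.ndarray | None = None,
                        n_permutations: int = 999,
                        seed: int | None = None) -> KdeTestResult:
    """Two-sample test of distributional equality for bivariate clouds.

    The statistic is the integrated squared difference of the two Gaussian
    kernel density estimates, available in closed form through convolution
    kernels over all sample pairs::

        T = psi11(2*H1) + psi22(2*H2) - 2*psi12(H1 + H2)

    ``method='asymptotic'`` compares T against its normal limit under the
    null, with moments estimated from the pooled sample; ``'permutation'``
    relabels the pooled sample (bandwidths held fixed) and is exact up to
    Monte-Carlo error.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != 2 or Y.shape[1] != 2:
        raise ValueError("X and Y must be (n, 2) arrays")
    n1, n2 = X.shape[0], Y.shape[0]
    if n1 < 20 or n2 < 20:
        raise ValueError("need at least 20 points per sample")
    for name, A in (("X", X), ("Y", Y)):
        if np.any(np.std(A, axis=0) <= 0):
            raise ValueError(f"degenerate sample {name} (zero variance)")
    d = 2
    if H1 is None:
        H1 = plugin_bandwidth(X)
    if H2 is None:
        H2 = plugin_bandwidth(Y)
    S11, S22, S12 = 2.0 * H1, 2.0 * H2, H1 + H2

    Z = np.vstack([X, Y])
    N = Z.shape[0]
    # pooled kernel matrices, reused by both inference routes
    K11 = _gauss_kernel_sums(_pairwise_diff(Z, Z), S11).reshape(N, N)
    K22 = _gauss_kernel_sums(_pairwise_diff(Z, Z), S22).reshape(N, N)
    K12 = _gauss_kernel_sums(_pairwise_diff(Z, Z), S12).reshape(N, N)

    def t_stat(idx1: np.ndarray, idx2: np.ndarray) -> float:
        a = K11[np.ix_(idx1, idx1)].sum() / (n1 * n1)
        b = K22[np.ix_(idx2, idx2)].sum() / (n2 * n2)
        c = K12[np.ix_(idx1, idx2)].sum() / (n1 * n2)
        return a + b - 2.0 * c

    i1 = np.arange(n1)
    i2 = np.arange(n1, N)
    T = t_stat(i1, i2)

    # Null moments estimated on the pooled sample. The mean keeps the O(1)
    # smoothing-mismatch term, which does not cancel when H1 != H2:
    #   E[T] = phi_{2H1}(0)/n1 + phi_{2H2}(0)/n2
    #        + (1-1/n1)*theta11 + (1-1/n2)*theta22 - 2*theta12,
    # with theta_ab = E[K_{Sab}(Z - Z')]. Variance and third cumulant come
    # from the degenerate (double-centered) kernels; the null is
    # approximated by a gamma matched to (mean, variance, skewness), which
    # captures the right skew of the quadratic form at moderate n.
    offmask = ~np.eye(N, dtype=bool)
    th11 = float(K11[offmask].mean())
    th22 = float(K22[offmask].mean())
    th12 = float(K12[offmask].mean())
    mu = (_phi0(S11) / n1 + _phi0(S22) / n2
          + (1.0 - 1.0 / n1) * th11 + (1.0 - 1.0 / n2) * th22 - 2.0 * th12)

    def dcenter(K: np.ndarray) -> np.ndarray:
        M = K.copy()
        np.fill_diagonal(M, 0.0)
        rm = M.sum(axis=1) / (N - 1)
        gm = M.sum() / (N * (N - 1))
        C = M - rm[:, None] - rm[None, :] + gm
        np.fill_diagonal(C, 0.0)
        return C

    C11, C22, C12 = dcenter(K11), dcenter(K22), dcenter(K12)
    e11 = float((C11**2)[offmask].mean())
    e22 = float((C22**2)[offmask].mean())
    e12 = float((C12**2)[offmask].mean())
    var = (2.0 * (n1 - 1) / n1**3 * e11 + 2.0 * (n2 - 1) / n2**3 * e22
           + 4.0 / (n1 * n2) * e12)

    # third cumulant: triangle terms per sample-membership type plus the
    # smaller same-pair-cubed terms; triangles on a subsample if N is large
    if N > 400:
        sub = np.linspace(0, N - 1, 400).astype(int)
    else:
        sub = np.arange(N)
    m = sub.size
    A11, A22, A12 = C11[np.ix_(sub, sub)], C22[np.ix_(sub, sub)], C12[np.ix_(sub, sub)]
    denom = m * (m - 1) * (m - 2)

    def tri(Pa: np.ndarray, Pb: np.ndarray, Pc: np.ndarray) -> float:
        return float(np.sum((Pa @ Pb) * Pc) / denom)

    t111 = tri(A11, A11, A11)
    t112 = tri(A11, A12, A12)
    t122 = tri(A12, A22, A12)
    t222 = tri(A22, A22, A22)
    f111 = float((C11**3)[offmask].mean())
    f222 = float((C22**3)[offmask].mean())
    f123 = float((C12**3)[offmask].mean())

    def comb(n: int, r: int) -> float:
        return math.comb(n, r)

    kappa3 = 6.0 * (comb(n1, 3) * 8.0 / n1**6 * t111
                    + comb(n1, 2) * n2 * 8.0 / (n1**4 * n2**2) * t112
                    + n1 * comb(n2, 2) * 8.0 / (n1**2 * n2**4) * t122
                    + comb(n2, 3) * 8.0 / n2**6 * t222)
    kappa3 += (comb(n1, 2) * 8.0 / n1**6 * f111
               + comb(n2, 2) * 8.0 / n2**6 * f222
               - n1 * n2 * 8.0 / (n1**3 * n2**3) * f123)

    z = (T - mu) / math.sqrt(var) if var > 0 else math.inf
    if method == "asymptotic":
        skew = kappa3 / var**1.5 if var > 0 else 0.0
        if skew > 1e-8:
            shape = 4.0 / skew**2
            scale = math.sqrt(var) * skew / 2.0
            loc = mu - 2.0 * math.sqrt(var) / skew
            p = float(_stats.gamma.sf(T, shape, loc=loc, scale=scale))
        else:
            p = float(_stats.norm.sf(z))
        nperm = 0
    elif method == "permutation":
        if n_permutations < 99:
            raise ValueError("use at least 99 permutations")
        rng = np.random.default_rng(seed)
        count = 0
        idx = np.arange(N)
        for _ in range(n_permutations):
            rng.shuffle(idx)
            if t_stat(idx[:n1], idx[n1:]) >= T - 1e-15:
                count += 1
        p = (1.0 + count) / (1.0 + n_permutations)
        nperm = n_permutations
    else:
        raise ValueError(f"unknown method: {method!r}")
    return KdeTestResult(float(T), float(mu), float(var), float(z), p,
                         H1, H2, method, n1, n2, nperm)


# ---------------------------------------------------------------------------
# stratified piecewise-linear fits
# ---------------------------------------------------------------------------

def fit_stratified_linear(table: pd.DataFrame, n_strata: int,
                          x_col: str = "Q_n", y_col: str = "F_bn",
                          strata_col: str = "height_fraction",
                          min_points: int = 5) -> list[tuple[int, ModelFit]]:
    """Independent ``y=a+bx`` fits within height strata.

    Strata are defined by quantiles of ``strata_col``; the piecewise-linear
    view shows how the local slope of the coupling varies along the vertical
    gradient. Returns ``(stratum_index, fit)`` pairs, stratum 0 most dependent.
    """
    if n_strata < 1:
        raise ValueError("n_strata must be >= 1")
    h = table[strata_col].to_numpy(dtype=float)
    edges = np.quantile(h, np.linspace(0, 1, n_strata + 1))
    labels = np.clip(np.searchsorted(edges, h, side="right") - 1, 0, n_strata - 1)
    sizes = {s: int(np.sum(labels == s)) for s in range(n_strata)}
    small = [s for s, c in sizes.items() if c < min_points]
    if small:
        raise ValueError(f"strata below {min_points} points: {small} (sizes {sizes})")
    out = []
    for s in range(n_strata):
        sel = labels == s
        fit = fit_form("y=a+bx", table.loc[sel, x_col], table.loc[sel, y_col],
                       orientation=f"{y_col}~{x_col}")
        out.append((s, fit))
    return out
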