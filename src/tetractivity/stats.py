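"""The 11 per-subset statistical criteria.

Five correlation tests between activity x and feature f — linear
(Pearson), Spearman rank, Kendall rank, and two dichotomous tests
(chi-square and Fisher exact on the median-split 2x2 table) — plus six
regression-applicability diagnostics:

1. uniformity of x (Kolmogorov-Smirnov against Uniform(min x, max x)),
2. uniformity of f (same),
3. normality of the residuals of the f-on-x regression (KS against a
   normal with the residuals' mean and sd),
4. independence of those residuals (Wald-Wolfowitz runs test on the
   residual signs ordered by x),
5.-6. the same two checks for the x-on-f regression.

Each test returns a significance level alpha.  For the correlation
tests a small alpha is favourable (a correlation exists); for the
applicability diagnostics a small alpha is unfavourable (an assumption
of regression analysis is violated).  Degenerate inputs (constant
vectors, zero-variance residuals, empty 2x2 margins) yield alpha = 1 by
convention: no evidence either way.  Alphas are floored at 1e-10 so the
downstream log-scale utility mapping stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

ALPHA_FLOOR = 1e-10

#: stable ids of the 11 criteria, correlation tests first.
CRITERIA: tuple[str, ...] = (
    "pearson", "spearman", "kendall", "chi2", "fisher",
    "unif_x", "unif_f", "norm_fx", "indep_fx", "norm_xf", "indep_xf",
)
#: ids whose small alpha is favourable (evidence FOR a usable correlation)
FAVOURABLE = frozenset({"pearson", "spearman", "kendall", "chi2", "fisher"})


@dataclass(frozen=True)
class TestResult:
    criterion_id: str
    statistic: float
    alpha: float
    direction: str  # "favourable" | "unfavourable"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha out of (0, 1]: {self.alpha}")


def _result(cid: str, stat: float, alpha: float) -> TestResult:
    alpha = float(min(1.0, max(ALPHA_FLOOR, alpha)))
    direction = "favourable" if cid in FAVOURABLE else "unfavourable"
    return TestResult(cid, float(stat), alpha, direction)


def _as_arrays(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    return x, y


def pearson(x, y) -> TestResult:
    """Linear correlation; two-sided alpha from the t distribution."""
    x, y = _as_arrays(x, y)
    if x.size < 3:
        raise ValueError("need n >= 3 for correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return _result("pearson", 0.0, 1.0)
    r, p = sps.pearsonr(x, y)
    return _result("pearson", r, p)


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with average ranks for ties."""
    x, y = _as_arrays(x, y)
    if x.size < 3:
        raise ValueError("need n >= 3 for correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return _result("spearman", 0.0, 1.0)
    rho, p = sps.spearmanr(x, y)
    if np.isnan(rho):
        return _result("spearman", 0.0, 1.0)
    return _result("spearman", rho, p)


def kendall(x, y) -> TestResult:
    """Kendall tau-b with the normal approximation for alpha."""
    x, y = _as_arrays(x, y)
    if x.size < 3:
        raise ValueError("need n >= 3 for correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return _result("kendall", 0.0, 1.0)
    tau, p = sps.kendalltau(x, y, method="asymptotic")
    if np.isnan(tau):
        return _result("kendall", 0.0, 1.0)
    return _result("kendall", tau, p)


def median_split_table(x, y) -> np.ndarray:
    """2x2 contingency table from median dichotomization.

    Values strictly above the median count as "high"; ties at the median
    go to the "low" group (deterministic).
    """
    x, y = _as_arrays(x, y)
    hx = x > np.median(x)
    hy = y > np.median(y)
    return np.array(
        [
            [np.sum(~hx & ~hy), np.sum(~hx & hy)],
            [np.sum(hx & ~hy), np.sum(hx & hy)],
        ],
        dtype=int,
    )


def dichotomous_tests(x, y) -> tuple[TestResult, TestResult]:
    """Chi-square (no continuity correction) and two-sided Fisher exact
    on the shared median-split table."""
    x, y = _as_arrays(x, y)
    if x.size < 4:
        raise ValueError("need n >= 4 for dichotomous tests")
    table = median_split_table(x, y)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return _result("chi2", 0.0, 1.0), _result("fisher", 0.0, 1.0)
    chi2_stat, chi2_p, _, _ = sps.chi2_contingency(table, correction=False)
    odds, fisher_p = sps.fisher_exact(table, alternative="two-sided")
    return _result("chi2", chi2_stat, chi2_p), _result("fisher", odds, fisher_p)


def _ks_uniform(cid: str, v: np.ndarray) -> TestResult:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return _result(cid, 0.0, 1.0)
    stat, p = sps.kstest(v, "uniform", args=(lo, hi - lo))
    return _result(cid, stat, p)


def _ks_normal_residuals(cid: str, resid: np.ndarray) -> TestResult:
    sd = resid.std(ddof=1)
    if sd == 0:
        return _result(cid, 0.0, 1.0)
    stat, p = sps.kstest(resid, "norm", args=(resid.mean(), sd))
    return _result(cid, stat, p)


def runs_test(signs: np.ndarray) -> tuple[float, float]:
    """Wald-Wolfowitz runs test on a boolean sequence.

    Returns (z, two-sided alpha) under the normal approximation.  With
    fewer than two of either symbol the test is uninformative and
    (0, 1) is returned.
    """
    signs = np.asarray(signs, dtype=bool)
    n1 = int(signs.sum())
    n2 = int(signs.size - n1)
    if n1 == 0 or n2 == 0:
        return 0.0, 1.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n1 + n2
    mean = 1 + 2 * n1 * n2 / n
    var = 2 * n1 * n2 * (2 * n1 * n2 - n) / (n**2 * (n - 1))
    if var <= 0:
        return 0.0, 1.0
    z = (runs - mean) / np.sqrt(var)
    return float(z), float(2 * sps.norm.sf(abs(z)))


def _residual_checks(
    regressor: np.ndarray, response: np.ndarray, norm_id: str, indep_id: str
) -> tuple[TestResult, TestResult]:
    """Normality + independence of least-squares residuals of
    response-on-regressor, ordered by the regressor."""
    if np.ptp(regressor) == 0:
        return _result(norm_id, 0.0, 1.0), _result(indep_id, 0.0, 1.0)
    slope, intercept = np.polyfit(regressor, response, 1)
    resid = response - (slope * regressor + intercept)
    if np.allclose(resid, 0):
        return _result(norm_id, 0.0, 1.0), _result(indep_id, 0.0, 1.0)
    normality = _ks_normal_residuals(norm_id, resid)
    order = np.argsort(regressor, kind="stable")
    z, p = runs_test(resid[order] >= 0)
    return normality, _result(indep_id, z, p)


@dataclass(frozen=True)
class RegressionDiagnostics:
    """Both directed least-squares fits between activity and feature."""

    slope_fx: float  # lambda: feature-on-activity
    intercept_fx: float  # mu
    residuals_fx: np.ndarray
    slope_xf: float  # phi: activity-on-feature
    intercept_xf: float  # psi
    residuals_xf: np.ndarray


def regression_diagnostics(x, f) -> RegressionDiagnostics:
    """Fit f = lambda*x + mu and x = phi*f + psi, returning both residual
    vectors (in input order)."""
    x, f = _as_arrays(x, f)
    lam, mu = np.polyfit(x, f, 1)
    phi, psi = np.polyfit(f, x, 1)
    return RegressionDiagnostics(
        slope_fx=float(lam), intercept_fx=float(mu), residuals_fx=f - (lam * x + mu),
        slope_xf=float(phi), intercept_xf=float(psi), residuals_xf=x - (phi * f + psi),
    )


def applicability_criteria(x, f) -> list[TestResult]:
    """The six regression-applicability diagnostics for (activity x,
    feature f), in the order unif_x, unif_f, norm_fx, indep_fx,
    norm_xf, indep_xf."""
    x, f = _as_arrays(x, f)
    if x.size < 5:
        raise ValueError("need n >= 5 for applicability diagnostics")
    out = [_ks_uniform("unif_x", x), _ks_uniform("unif_f", f)]
    out.extend(_residual_checks(x, f, "norm_fx", "indep_fx"))
    out.extend(_residual_checks(f, x, "norm_xf", "indep_xf"))
    return out


def all_criteria(x, f) -> list[TestResult]:
    """All 11 criteria on one (activity, feature) pair, in the canonical
    :data:`CRITERIA` order.

    Subsets too small for a given test yield alpha = 1 for it rather
    than an error, so the 7 x 11 grid is always complete.
    """
    x, f = _as_arrays(x, f)
    results: list[TestResult] = []

    def safe(fn, cid, *args):
        try:
            return fn(*args)
        except ValueError:
            return _result(cid, 0.0, 1.0)

    results.append(safe(pearson, "pearson", x, f))
    results.append(safe(spearman, "spearman", x, f))
    results.append(safe(kendall, "kendall", x, f))
    try:
        chi2_r, fisher_r = dichotomous_tests(x, f)
    except ValueError:
        chi2_r, fisher_r = _result("chi2", 0.0, 1.0), _result("fisher", 0.0, 1.0)
    results.extend([chi2_r, fisher_r])
    try:
        results.extend(applicability_criteria(x, f))
    except ValueError:
        results.extend(
            _result(cid, 0.0, 1.0)
            for cid in ("unif_x", "unif_f", "norm_fx", "indep_fx", "norm_xf", "indep_xf")
        )
    return results
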