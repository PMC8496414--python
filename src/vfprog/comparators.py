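"""Benchmark progression methods: simple linear regression and PoPLR.

Simple (ordinary least squares) linear regression of sensitivity on time is
applied at three levels — global mean sensitivity (MS), cluster MS, and
pointwise — with a one-sided p-value for a negative slope (worsening).

PoPLR (Permutation analyses Of Pointwise Linear Regression) combines the 52
pointwise one-sided slope p-values of a series into the Truncated Product
Method statistic S = sum of -ln(p) over p <= tau, and refers S to a
series-specific null distribution obtained by permuting the order of the VF
tests (whole tests are shuffled, times stay fixed, so the within-test spatial
correlation is preserved).  Both S itself and its permutation p-value are used
as progression statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as _all_permutations

import numpy as np
from scipy.stats import t as _student_t

from .grid import Grid24_2, load_grid
from .io import VFSeries, VFTest

__all__ = [
    "PLRResult",
    "PoPLRResult",
    "mean_sensitivity",
    "plr",
    "pointwise_plr_pvalues",
    "tpm_statistic",
    "poplr",
]

_P_EPS = 1e-300  # keeps p-values inside (0, 1) for degenerate exact fits


@dataclass(frozen=True)
class PLRResult:
    """OLS trend of one unit (global MS, cluster MS, or a location)."""

    slope: float  # dB/year
    intercept: float  # dB
    p_value: float  # one-sided, H1: slope < 0


@dataclass(frozen=True)
class PoPLRResult:
    s: float  # observed truncated-product statistic, >= 0
    p_value: float  # (1 + #{S_perm >= S_obs}) / (1 + n_perm)
    n_perm: int


def mean_sensitivity(test: VFTest, scope="global", grid: Grid24_2 | None = None):
    """Mean sensitivity over the informative locations in scope.

    ``scope`` is ``"global"`` or a cluster id 1..6.  Blind-spot locations are
    never included.
    """
    grid = grid or load_grid()
    if scope == "global":
        mask = grid.informative
    else:
        mask = grid.cluster_id == int(scope)
        if not mask.any():
            raise ValueError(f"empty scope {scope!r}")
    return float(test.sensitivities[mask].mean())


def _ols_one_sided(t, y):
    """Slope, intercept and one-sided p (slope < 0) of y on t."""
    n = len(t)
    tbar = t.mean()
    tc = t - tbar
    sxx = float(tc @ tc)
    if sxx <= 0:
        raise ValueError("need >= 2 distinct times")
    slope = float(tc @ y) / sxx
    intercept = float(y.mean() - slope * tbar)
    if n < 3:
        raise ValueError("p-value undefined with fewer than 3 tests")
    sse = max(float(np.sum((y - intercept - slope * t) ** 2)), 0.0)
    se = math.sqrt(sse / (n - 2) / sxx)
    if se == 0.0:
        p = _P_EPS if slope < 0 else (0.5 if slope == 0 else 1 - _P_EPS)
    else:
        p = float(_student_t.cdf(slope / se, df=n - 2))
    return slope, intercept, min(max(p, _P_EPS), 1 - _P_EPS)


def plr(series: VFSeries, scope="global", grid: Grid24_2 | None = None) -> PLRResult:
    """Simple linear regression of a summary (or pointwise) trend.

    ``scope``: ``"global"`` (global MS), a cluster id 1..6 (cluster MS), or
    ``("location", location_id)`` for a single location's sensitivities.
    """
    grid = grid or load_grid()
    t = series.times
    if isinstance(scope, tuple) and scope[0] == "location":
        lid = int(scope[1])
        if grid.is_blind_spot[lid - 1]:
            raise ValueError(f"location {lid} is a blind-spot location")
        y = series.values[:, lid - 1].astype(float)
    else:
        y = np.array([mean_sensitivity(tst, scope, grid) for tst in series.tests])
    slope, intercept, p = _ols_one_sided(t, y)
    return PLRResult(slope, intercept, p)


def _pointwise_pvalues_matrix(t, Y):
    """One-sided pointwise slope p-values, vectorised over trailing axes.

    ``Y`` has shape (..., n, L) with time along the second-to-last axis.
    Uses the sufficient-statistic identity SSE = Syy - slope^2 * Sxx, which is
    what makes whole-series permutation nulls cheap: Syy is permutation
    invariant.
    """
    n = len(t)
    tc = t - t.mean()
    sxx = float(tc @ tc)
    slope = np.einsum("n,...nl->...l", tc, Y) / sxx
    ybar = Y.mean(axis=-2)
    syy = ((Y - ybar[..., None, :]) ** 2).sum(axis=-2)
    sse = np.maximum(syy - slope**2 * sxx, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = slope / np.sqrt(sse / (n - 2) / sxx)
    tstat = np.where(np.isnan(tstat), 0.0, tstat)  # flat series: slope 0, se 0
    p = _student_t.cdf(np.where(np.isinf(tstat), np.sign(tstat) * 1e9, tstat),
                       df=n - 2)
    return np.clip(p, _P_EPS, 1 - _P_EPS)


def pointwise_plr_pvalues(series: VFSeries, grid: Grid24_2 | None = None):
    """(52,) one-sided p-values of the pointwise slopes (informative locations)."""
    grid = grid or load_grid()
    if series.n_tests < 3:
        raise ValueError("pointwise p-values need >= 3 tests")
    Y = series.values[:, grid.informative].astype(float)
    return _pointwise_pvalues_matrix(series.times, Y)


def tpm_statistic(pvals, tau: float = 0.05) -> float:
    """Truncated Product Method statistic: S = sum of -ln(p) over p <= tau."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    sel = p <= tau
    return float(-np.log(p[sel]).sum()) if sel.any() else 0.0


def poplr(
    series: VFSeries,
    n_perm: int = 5000,
    tau: float = 0.05,
    seed: int = 0,
    grid: Grid24_2 | None = None,
) -> PoPLRResult:
    """PoPLR: truncated-product combination of pointwise slopes with a
    permutation null.

    Whole VF tests are permuted within the series (visit times fixed), the 52
    pointwise one-sided p-values and S are recomputed for each ordering, and
    the p-value uses the add-one estimator p = (1 + #{S_perm >= S_obs}) /
    (1 + n_perm).  When the series is short enough that all orderings fit the
    budget, the null is exhaustive (every ordering except the identity), which
    makes the estimator exactly the enumeration p-value #{S >= S_obs} / n!.
    """
    n = series.n_tests
    if n < 4:
        raise ValueError("PoPLR requires >= 4 tests")
    grid = grid or load_grid()
    t = series.times
    Y = series.values[:, grid.informative].astype(float)

    s_obs = tpm_statistic(_pointwise_pvalues_matrix(t, Y), tau)

    n_orderings = math.factorial(n)
    if n_orderings <= n_perm:
        perms = np.array(
            [p for p in _all_permutations(range(n)) if p != tuple(range(n))]
        )
    else:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 987654321]))
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    pmat = _pointwise_pvalues_matrix(t, Y[perms])  # (n_perm, 52)
    trunc = pmat <= tau
    s_perm = np.where(trunc, -np.log(pmat), 0.0).sum(axis=1)
    count = int(np.sum(s_perm >= s_obs))
    m = len(perms)
    return PoPLRResult(s=s_obs, p_value=(1 + count) / (1 + m), n_perm=m)
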