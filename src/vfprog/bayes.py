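"""Hierarchical Bayesian models of pointwise visual-field progression.

Three variants of one mixed-effect model are fitted per eye by MCMC:

* ``hi_linear``   — Gaussian errors, censoring ignored;
* ``hi_censored`` — Gaussian errors left-censored at the 0 dB floor (Tobit-style);
* ``hi_hsk``      — censored errors whose SD is tied to the estimated
  sensitivity through the capped bilinear variability model.

The linear predictor for location l in cluster c(l) at time t is

    mu_l(t) = (b0 + u0_c + w0_l) + (b1 + u1_c + w1_l) * t

with global fixed effects (b0, b1), cluster random effects (u0_c, u1_c) on the
six optic-nerve-head sectors, and location random effects (w0_l, w1_l) nested
within clusters.  Random-effect pairs are zero-mean bivariate normal with
inverse-Wishart covariance hyperpriors; fixed-effect priors are wide normals
centred on a fast maximum-likelihood initialisation.

Sampler.  Censored observations are data-augmented with latent values below
0 dB, which makes the homoskedastic variants fully conjugate: the entire
118-dimensional coefficient vector (fixed plus random effects) is redrawn
jointly from its Gaussian full conditional each sweep — a blocked Gibbs update
that side-steps the slow mixing of one-at-a-time updates caused by the
intercept/slope sum redundancy across levels of the hierarchy (the location
blocks are marginalised via a Schur complement, so no large matrix is ever
factorised).  ``hi_hsk``, whose error SD depends on the linear predictor
itself, uses the centred parameterisation: the per-location lines are updated
in parallel by Metropolis-Hastings with their exact Gaussian conditionals
under the current SD field as proposals, and the cluster/global lines given
the location lines are all-Gaussian and drawn jointly and exactly.
Convergence is assessed with the split Gelman-Rubin diagnostic on every
monitored parameter across two (or more) parallel chains, with automatic
doubling of the iteration budget when the threshold is exceeded.

Progression evidence is summarised by the P-score: the posterior ECDF of a
slope evaluated at 0 dB/year.  Values near 1 indicate worsening; a perfectly
stable series yields 0.5 in expectation.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
from scipy.linalg.lapack import dpotrf, dpotrs, dtrtrs
from scipy.special import log_ndtr, ndtr, ndtri

from .grid import Grid24_2, load_grid
from .io import VFSeries
from .variability import VariabilityModel

__all__ = [
    "ModelSpec",
    "MLInit",
    "BayesFit",
    "PScoreSet",
    "VARIANTS",
    "ml_initialise",
    "log_likelihood",
    "pscore",
    "fit",
    "fit_single_location",
    "split_rhat",
]

VARIANTS = ("hi_linear", "hi_censored", "hi_hsk")

# fixed-effect prior SDs (dB, dB/year): far wider than any physiological range
_PRIOR_SD_INTERCEPT = 100.0
_PRIOR_SD_SLOPE = 10.0
# inverse-Wishart hyperprior for the 2x2 random-effect covariances
_IW_DF0 = 2.0
_IW_SCALE0 = 0.001
# inverse-gamma hyperprior for the residual variance
_IG_A0 = 0.01
_IG_B0 = 0.01


@dataclass(frozen=True)
class ModelSpec:
    """Model variant plus MCMC settings.

    Defaults (2 chains, 1000 warmup, 2000 draws) target routine per-eye fits;
    bulk simulation studies use reduced settings.  When the split Gelman-Rubin
    statistic exceeds ``rhat_threshold`` the fit is rerun with a doubled
    iteration budget, up to ``max_doublings`` times (4x the original budget).
    """

    variant: str = "hi_censored"
    variability: VariabilityModel | None = None
    n_chains: int = 2
    warmup: int = 1000
    draws: int = 2000
    thin: int = 1
    seed: int = 0
    rhat_threshold: float = 1.2
    max_doublings: int = 2

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "hi_hsk" and self.variability is None:
            raise ValueError("hi_hsk requires a VariabilityModel")
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")


@dataclass(frozen=True)
class MLInit:
    """Fast frequentist initialisation: fixed effects, residual SD and
    method-of-moments random-effect starts."""

    beta0: float
    beta1: float
    sigma: float
    Sigma_u: np.ndarray  # (2, 2)
    Sigma_w: np.ndarray
    cluster_dev: np.ndarray  # (6, 2) per-cluster OLS deviations
    location_dev: np.ndarray  # (52, 2)


@dataclass(frozen=True)
class PScoreSet:
    """Posterior ECDF-at-zero progression scores at the three levels."""

    global_: float
    cluster: np.ndarray  # (6,)
    location: np.ndarray  # (52,)


def _ols_line(t, y):
    """Slope/intercept of y on t for stacked observations; None if singular."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    tbar = t.mean()
    sxx = np.sum((t - tbar) ** 2)
    if sxx <= 0:
        return None
    b = np.sum((t - tbar) * (y - y.mean())) / sxx
    a = y.mean() - b * tbar
    return a, b


def ml_initialise(series: VFSeries, grid: Grid24_2 | None = None) -> MLInit:
    """Homoskedastic, uncensored initialisation of the hierarchy.

    Fixed effects come from the pooled OLS of all pointwise values on time —
    identical to the mixed-model ML fixed effects under the balanced per-eye
    design (every informative location observed at every visit).  Random-effect
    covariance starts are method-of-moments: the covariance of per-cluster and
    per-location OLS deviations from the global line.  Degenerate designs fall
    back to a flat pooled fit with a warning.
    """
    if series.n_tests < 2:
        raise ValueError(f"eye {series.eye_id}: need >= 2 tests")
    grid = grid or load_grid()
    info = grid.informative
    cl = grid.informative_cluster_index
    t = series.times
    Y = series.values[:, info].astype(float)  # (n, 52)
    n, n_loc = Y.shape
    tt = np.repeat(t, n_loc)

    line = _ols_line(tt, Y.ravel())
    if line is None:
        warnings.warn(
            f"eye {series.eye_id}: singular design; pooled-mean fallback"
        )
        a, b = float(Y.mean()), 0.0
    else:
        a, b = line
    resid = Y - (a + b * t[:, None])
    sigma = max(float(resid.std()), 0.5)

    loc_dev = np.zeros((n_loc, 2))
    for l in range(n_loc):
        ln = _ols_line(t, Y[:, l])
        if ln is not None:
            loc_dev[l] = [ln[0] - a, ln[1] - b]
    clu_dev = np.zeros((6, 2))
    for c in range(6):
        sel = cl == c
        ln = _ols_line(np.repeat(t, sel.sum()), Y[:, sel].ravel())
        if ln is not None:
            clu_dev[c] = [ln[0] - a, ln[1] - b]
    loc_dev -= clu_dev[cl]

    def _mom_cov(dev):
        c = np.cov(dev.T) if len(dev) > 1 else np.eye(2)
        c = np.atleast_2d(c)
        # keep starts comfortably positive definite
        return c + np.diag([0.25, 0.01])

    return MLInit(
        beta0=float(a), beta1=float(b), sigma=sigma,
        Sigma_u=_mom_cov(clu_dev), Sigma_w=_mom_cov(loc_dev),
        cluster_dev=clu_dev, location_dev=loc_dev,
    )


def log_likelihood(variant, y, mu, sigma=None, variability=None):
    """Pointwise observation log-likelihood of the three model variants.

    ``hi_linear`` uses the Gaussian density everywhere; the censored variants
    replace the density at recorded 0 dB with the lower-tail log-probability
    log P(Y* <= 0).  For ``hi_hsk`` the SD is taken from the bilinear
    variability model evaluated at ``mu`` (the ``sigma`` argument is unused).
    Returns an array matching the broadcast shape (scalar for scalar input).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    if variant == "hi_hsk":
        if variability is None:
            raise ValueError("hi_hsk requires a VariabilityModel")
        sigma = variability.sd(mu, form="bilinear")
    else:
        sigma = np.asarray(sigma, float)
        if np.any(sigma <= 0):
            raise ValueError("sigma must be > 0")
    dens = -np.log(sigma) - 0.5 * ((y - mu) / sigma) ** 2 - 0.5 * np.log(2 * np.pi)
    if variant == "hi_linear":
        out = dens
    else:
        out = np.where(y == 0, log_ndtr((0.0 - mu) / sigma), dens)
    return float(out) if out.ndim == 0 else out


def pscore(slope_draws) -> float:
    """Posterior ECDF of a slope at 0 dB/year; draws exactly at zero get
    half weight so a symmetric posterior scores exactly 0.5."""
    d = np.asarray(slope_draws, float).ravel()
    if d.size == 0:
        raise ValueError("empty slope draws")
    return float((np.sum(d < 0) + 0.5 * np.sum(d == 0)) / d.size)


def split_rhat(x: np.ndarray) -> np.ndarray:
    """Split Gelman-Rubin diagnostic.

    ``x`` has shape (chains, draws, ...); each chain is split in half, and the
    usual between/within variance ratio is computed over the 2*chains halves.
    Returns the statistic for each trailing parameter dimension.
    """
    m, n = x.shape[:2]
    half = n // 2
    halves = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    mean = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean(axis=0)
    B = half * mean.var(axis=0, ddof=1)
    var_plus = (half - 1) / half * W + B / half
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / W)
    return np.where(W > 0, rhat, 1.0)


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------


def _trunc_normal_below_zero(rng, mu, sd):
    """Draws from N(mu, sd) truncated to (-inf, 0], vectorised and tail-safe."""
    pa = ndtr(-mu / sd)
    u = rng.random(mu.shape)
    arg = np.clip(u * pa, 1e-300, 1.0)
    z = mu + sd * ndtri(arg)
    return np.minimum(z, -1e-12)


def _inv2(a):
    """Closed-form inverse of a symmetric 2x2 matrix."""
    det = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
    return np.array([[a[1, 1], -a[0, 1]], [-a[1, 0], a[0, 0]]]) / det


def _inv_wishart_2x2(rng, df, psi):
    """IW(df, psi) draw via the Bartlett factorisation of Wishart(df, psi^-1).

    Closed-form 2x2 algebra: psi^-1 = L L' with L lower triangular, the
    Bartlett factor has chi-square diagonals and one standard-normal entry.
    """
    pinv = _inv2(psi)
    l11 = np.sqrt(pinv[0, 0])
    l21 = pinv[1, 0] / l11
    l22 = np.sqrt(pinv[1, 1] - l21 * l21)
    a11 = np.sqrt(rng.chisquare(df))
    a21 = rng.normal()
    a22 = np.sqrt(rng.chisquare(df - 1))
    # B = L @ A (both lower triangular)
    b11 = l11 * a11
    b21 = l21 * a11 + l22 * a21
    b22 = l22 * a22
    w = np.array([[b11 * b11, b11 * b21],
                  [b11 * b21, b21 * b21 + b22 * b22]])
    return _inv2(w)


class _EyeData:
    """Per-eye design quantities shared across sweeps."""

    def __init__(self, series, grid):
        self.t = series.times
        info = grid.informative
        self.cl = grid.informative_cluster_index
        self.Y = series.values[:, info].astype(float)
        self.cens = self.Y == 0.0
        self.n, self.n_loc = self.Y.shape
        self.n_clu = 6
        self.n_per_cluster = np.bincount(self.cl, minlength=6)


def _gauss_draw(rng, H, r):
    """Sample from N(H^-1 r, H^-1); returns the draw and the mean."""
    L, info = dpotrf(H, lower=1, clean=1)
    if info != 0:
        raise np.linalg.LinAlgError("posterior precision not positive definite")
    mean, _ = dpotrs(L, r, lower=1)
    noise, _ = dtrtrs(L, rng.standard_normal(len(r)), lower=1, trans=1)
    return mean + noise, mean


def _loc_moments(t, w, Z):
    """Per-location weighted design moments.

    Returns (a, b, d, m0, m1): the components of X' W_l X (a = sum w,
    b = sum w t, d = sum w t^2) and of X' W_l z, per location.
    """
    wt = w * t[:, None]
    return (w.sum(0), wt.sum(0), (wt * t[:, None]).sum(0),
            (w * Z).sum(0), (wt * Z).sum(0))


def _draw_coefficients(rng, ed, w, Z, prior_prec_beta, prior_mean_beta,
                       inv_su, inv_sw):
    """Joint Gaussian draw of (beta, U, W) given latents, weights, covariances.

    The location effects are marginalised analytically (a Schur complement of
    their block-diagonal 2x2 precisions), (beta, U) is drawn from the reduced
    14-dimensional Gaussian, and the W_l are then drawn from their independent
    2x2 conditionals — an exact blocked draw of the full conditional that
    never forms the 118x118 precision matrix.
    """
    t, cl = ed.t, ed.cl
    a, b, d, m0, m1 = _loc_moments(t, w, Z)
    iwa, iwb, iwd = inv_sw[0, 0], inv_sw[0, 1], inv_sw[1, 1]
    pa, pb, pd = a + iwa, b + iwb, d + iwd
    detp = pa * pd - pb * pb
    # Q = P^-1 M, S = M P^-1 M (Schur correction), v = M P^-1 m
    q11 = (pd * a - pb * b) / detp
    q12 = (pd * b - pb * d) / detp
    q21 = (pa * b - pb * a) / detp
    q22 = (pa * d - pb * b) / detp
    s11 = a * q11 + b * q21
    s12 = a * q12 + b * q22
    s22 = b * q12 + d * q22
    u0 = (pd * m0 - pb * m1) / detp
    u1 = (pa * m1 - pb * m0) / detp
    v0 = a * u0 + b * u1
    v1 = b * u0 + d * u1

    e11, e12, e22 = a - s11, b - s12, d - s22
    f0, f1 = m0 - v0, m1 - v1
    c11 = np.bincount(cl, e11, minlength=6)
    c12 = np.bincount(cl, e12, minlength=6)
    c22 = np.bincount(cl, e22, minlength=6)
    g0 = np.bincount(cl, f0, minlength=6)
    g1 = np.bincount(cl, f1, minlength=6)

    H = np.zeros((14, 14))
    H[0, 0] = c11.sum() + prior_prec_beta[0, 0]
    H[0, 1] = H[1, 0] = c12.sum()
    H[1, 1] = c22.sum() + prior_prec_beta[1, 1]
    r = np.zeros(14)
    r[0] = g0.sum() + prior_prec_beta[0, 0] * prior_mean_beta[0]
    r[1] = g1.sum() + prior_prec_beta[1, 1] * prior_mean_beta[1]
    for c in range(6):
        i = 2 + 2 * c
        blk = np.array([[c11[c], c12[c]], [c12[c], c22[c]]])
        H[i : i + 2, i : i + 2] = blk + inv_su
        H[0:2, i : i + 2] = blk
        H[i : i + 2, 0:2] = blk
        r[i] = g0[c]
        r[i + 1] = g1[c]
    theta_bu, _ = _gauss_draw(rng, H, r)
    beta = theta_bu[:2]
    U = theta_bu[2:].reshape(6, 2)

    # W_l | beta, U: N(P_l^-1 (m_l - M_l h_l), P_l^-1), h_l = beta + U_c(l)
    h0 = beta[0] + U[cl, 0]
    h1 = beta[1] + U[cl, 1]
    r0 = m0 - (a * h0 + b * h1)
    r1 = m1 - (b * h0 + d * h1)
    mw0 = (pd * r0 - pb * r1) / detp
    mw1 = (pa * r1 - pb * r0) / detp
    l11 = np.sqrt(pa)
    l21 = pb / l11
    l22 = np.sqrt(pd - l21 * l21)
    z0 = rng.standard_normal(ed.n_loc)
    z1 = rng.standard_normal(ed.n_loc)
    x1 = z1 / l22
    x0 = (z0 - l21 * x1) / l11
    W = np.column_stack([mw0 + x0, mw1 + x1])
    return beta, U, W


def _mu_from_gamma(t, gamma):
    return gamma[:, 0][None, :] + np.outer(t, gamma[:, 1])


def _quad2(inv_s, d0, d1):
    """Batched quadratic form d' inv_s d for 2-vectors."""
    return (inv_s[0, 0] * d0 * d0 + 2.0 * inv_s[0, 1] * d0 * d1
            + inv_s[1, 1] * d1 * d1)


def _gamma_mh_update(rng, ed, var_model, Z, gamma, mu, sd, alpha_of_loc, inv_sw):
    """Batched per-location MH update of the centred location lines.

    The proposal for each location is its exact Gaussian conditional computed
    with the current SD field; the accept step corrects for the SD's
    dependence on the proposed linear predictor (the heteroskedastic link).
    All 52 locations are updated in parallel — their conditionals are
    independent given the cluster lines.
    """
    t = ed.t
    w = 1.0 / sd**2
    a, b, d, m0, m1 = _loc_moments(t, w, Z)
    p0, p1 = alpha_of_loc[:, 0], alpha_of_loc[:, 1]
    iwa, iwb, iwd = inv_sw[0, 0], inv_sw[0, 1], inv_sw[1, 1]

    def conditional(a_, b_, d_, m0_, m1_):
        pa, pb, pd = a_ + iwa, b_ + iwb, d_ + iwd
        detp = pa * pd - pb * pb
        r0 = m0_ + iwa * p0 + iwb * p1
        r1 = m1_ + iwb * p0 + iwd * p1
        mean0 = (pd * r0 - pb * r1) / detp
        mean1 = (pa * r1 - pb * r0) / detp
        l11 = np.sqrt(pa)
        l21 = pb / l11
        l22 = np.sqrt(pd - l21 * l21)
        return mean0, mean1, l11, l21, l22

    def logq(mean0, mean1, l11, l21, l22, x0, x1):
        d0, d1 = x0 - mean0, x1 - mean1
        q1 = l11 * d0 + l21 * d1
        q2 = l22 * d1
        return np.log(l11) + np.log(l22) - 0.5 * (q1 * q1 + q2 * q2)

    mean0, mean1, l11, l21, l22 = conditional(a, b, d, m0, m1)
    z1 = rng.standard_normal(ed.n_loc)
    z0 = rng.standard_normal(ed.n_loc)
    x1 = z1 / l22
    x0 = (z0 - l21 * x1) / l11
    g0p = mean0 + x0
    g1p = mean1 + x1

    mu_p = g0p[None, :] + np.outer(t, g1p)
    sd_p = var_model.sd(mu_p, form="bilinear")
    w_p = 1.0 / sd_p**2
    ll_cur = (-np.log(sd) - 0.5 * w * (Z - mu) ** 2).sum(0)
    ll_prop = (-np.log(sd_p) - 0.5 * w_p * (Z - mu_p) ** 2).sum(0)
    lp_cur = -0.5 * _quad2(inv_sw, gamma[:, 0] - p0, gamma[:, 1] - p1)
    lp_prop = -0.5 * _quad2(inv_sw, g0p - p0, g1p - p1)

    ap, bp, dp, m0p, m1p = _loc_moments(t, w_p, Z)
    rmean0, rmean1, rl11, rl21, rl22 = conditional(ap, bp, dp, m0p, m1p)
    log_alpha = (
        ll_prop + lp_prop - ll_cur - lp_cur
        + logq(rmean0, rmean1, rl11, rl21, rl22, gamma[:, 0], gamma[:, 1])
        - logq(mean0, mean1, l11, l21, l22, g0p, g1p)
    )
    accept = np.log(rng.random(ed.n_loc)) < log_alpha
    gamma = gamma.copy()
    gamma[accept, 0] = g0p[accept]
    gamma[accept, 1] = g1p[accept]
    mu = np.where(accept[None, :], mu_p, mu)
    sd = np.where(accept[None, :], sd_p, sd)
    return gamma, mu, sd, accept



def _px_scale(rng, resid, E, t, sig2):
    """Gibbs draw of the 2-vector of expansion scales of one random-effect
    layer.

    ``E`` holds the unscaled effects mapped to the 52 locations (cluster
    effects are expanded through the cluster index), so the regression of the
    residual on the covariates (E_l0, E_l1 * t_i) with known noise variance
    gives the exact Gaussian conditional of the scales; the prior is standard
    normal per component (order-unity scales, as usual for this expansion).
    """
    n = len(t)
    st, stt = float(t.sum()), float(t @ t)
    e00 = float(E[:, 0] @ E[:, 0])
    e01 = float(E[:, 0] @ E[:, 1])
    e11 = float(E[:, 1] @ E[:, 1])
    r0 = float(E[:, 0] @ resid.sum(axis=0))
    r1 = float(E[:, 1] @ (t @ resid))
    P = np.array([[n * e00, st * e01], [st * e01, stt * e11]]) / sig2
    P += np.eye(2)
    b = np.array([r0, r1]) / sig2
    a, _ = _gauss_draw(rng, P, b)
    # keep the reparameterisation numerically invertible
    return np.where(np.abs(a) < 1e-8, 1e-8, a)


def _run_chain(ed, spec, init, var_model, rng, n_iter, keep_from):
    """One MCMC chain; returns stacked draws of the monitored parameters.

    Homoskedastic variants use a fully conjugate blocked Gibbs sweep on a
    parameter-expanded model: the random effects of each layer carry a
    redundant multiplicative 2-vector of scales (a scaled inverse-Wishart
    construction for the covariances), whose extra Gibbs step breaks the
    funnel-shaped coupling between effects and covariance that otherwise
    mixes very slowly on heavily censored series.  hi_hsk uses the centred
    parameterisation (location lines gamma_l, cluster lines alpha_c, global
    line beta) where only the gamma_l blocks need an MH correction for the
    sensitivity-dependent SD.
    """
    hsk = spec.variant == "hi_hsk"
    censored = spec.variant != "hi_linear"

    prior_prec_beta = np.diag(
        [1.0 / _PRIOR_SD_INTERCEPT**2, 1.0 / _PRIOR_SD_SLOPE**2]
    )
    prior_mean_beta = np.array([init.beta0, init.beta1])
    psi0 = _IW_SCALE0 * np.eye(2)

    # overdispersed chain starts around the ML initialisation; the location
    # lines start at their OLS values (only lightly jittered) because the MH
    # correction of the heteroskedastic variant cannot make large jumps from
    # a data-contradicting start
    beta = prior_mean_beta + rng.normal(0, [1.0, 0.2])
    U = init.cluster_dev + rng.normal(0, [0.2, 0.05], size=(6, 2))
    W = init.location_dev + rng.normal(0, [0.3, 0.05], size=(init.location_dev.shape[0], 2))
    sig2 = (init.sigma * np.exp(rng.normal(0, 0.3))) ** 2
    jit = np.exp(rng.normal(0, 0.3, size=2))
    Sigma_u = init.Sigma_u * jit[0]
    Sigma_w = init.Sigma_w * jit[1]
    a_u = np.ones(2)
    a_w = np.ones(2)
    t, cl = ed.t, ed.cl

    if hsk:
        alpha = beta[None, :] + U
        # location lines start at their OLS fits regardless of the beta jitter
        gamma = (prior_mean_beta[None, :] + init.cluster_dev[cl]
                 + init.location_dev
                 + rng.normal(0, [0.2, 0.03], size=W.shape))
        mu = _mu_from_gamma(t, gamma)
        sd = var_model.sd(mu, form="bilinear")
    else:
        gm = beta[None, :] + U[cl] + W
        mu = _mu_from_gamma(t, gm)

    Z = ed.Y.copy()
    n_keep = (n_iter - keep_from + spec.thin - 1) // spec.thin
    out_theta = np.empty((n_keep, 2 * (1 + ed.n_clu + ed.n_loc)))
    out_sig = np.empty(n_keep)
    out_su = np.empty((n_keep, 3))
    out_sw = np.empty((n_keep, 3))
    k = 0

    for it in range(n_iter):
        inv_su = _inv2(Sigma_u)
        inv_sw = _inv2(Sigma_w)

        # --- latent censored values
        if censored:
            s_c = sd[ed.cens] if hsk else np.sqrt(sig2)
            Z[ed.cens] = _trunc_normal_below_zero(rng, mu[ed.cens], s_c)

        if not hsk:
            # --- joint conjugate draw of the *effective* coefficients
            w = np.full_like(Z, 1.0 / sig2)
            beta, U, W = _draw_coefficients(
                rng, ed, w, Z, prior_prec_beta, prior_mean_beta, inv_su, inv_sw
            )
            # --- expansion-scale Gibbs steps (one per random-effect layer)
            base = beta[0] + beta[1] * t[:, None]
            U_t = U / a_u  # unscaled effects of the expanded model
            W_t = W / a_w
            r_u = Z - base - (W[None, :, 0] + np.outer(t, W[:, 1]))
            a_u = _px_scale(rng, r_u, U_t[cl], t, sig2)
            U = a_u * U_t
            r_w = Z - base - (U[cl, 0][None, :] + np.outer(t, U[cl, 1]))
            a_w = _px_scale(rng, r_w, W_t, t, sig2)
            W = a_w * W_t
            # --- covariances: inverse-Wishart on the unscaled effects,
            # mapped back through the expansion scales
            Sigma_u = np.outer(a_u, a_u) * _inv_wishart_2x2(
                rng, _IW_DF0 + ed.n_clu, psi0 + U_t.T @ U_t)
            Sigma_w = np.outer(a_w, a_w) * _inv_wishart_2x2(
                rng, _IW_DF0 + ed.n_loc, psi0 + W_t.T @ W_t)
            gm = beta[None, :] + U[cl] + W
            mu = _mu_from_gamma(t, gm)
            # --- residual variance
            sse = float(np.sum((Z - mu) ** 2))
            sig2 = (_IG_B0 + 0.5 * sse) / rng.gamma(_IG_A0 + 0.5 * Z.size)
        else:
            # --- centred sweep with batched MH on the location lines
            gamma, mu, sd, _ = _gamma_mh_update(
                rng, ed, var_model, Z, gamma, mu, sd, alpha[cl], inv_sw
            )
            gsum = np.column_stack([
                np.bincount(cl, gamma[:, 0], minlength=6),
                np.bincount(cl, gamma[:, 1], minlength=6),
            ])
            # joint exact draw of (beta, alpha_1..6) | gamma — all-Gaussian
            # chain beta -> alpha -> gamma with gamma held fixed
            H = np.zeros((14, 14))
            r = np.zeros(14)
            H[0:2, 0:2] = 6.0 * inv_su + prior_prec_beta
            r[0:2] = prior_prec_beta @ prior_mean_beta
            for c in range(6):
                i = 2 + 2 * c
                H[i : i + 2, i : i + 2] = ed.n_per_cluster[c] * inv_sw + inv_su
                H[0:2, i : i + 2] = -inv_su
                H[i : i + 2, 0:2] = -inv_su
                r[i : i + 2] = inv_sw @ gsum[c]
            ba, _ = _gauss_draw(rng, H, r)
            beta = ba[:2]
            alpha = ba[2:].reshape(6, 2)
            U = alpha - beta[None, :]
            W = gamma - alpha[cl]
            # --- random-effect covariances
            Sigma_u = _inv_wishart_2x2(rng, _IW_DF0 + ed.n_clu, psi0 + U.T @ U)
            Sigma_w = _inv_wishart_2x2(rng, _IW_DF0 + ed.n_loc, psi0 + W.T @ W)

        if it >= keep_from and (it - keep_from) % spec.thin == 0:
            out_theta[k, :2] = beta
            out_theta[k, 2:14] = U.ravel()
            out_theta[k, 14:] = W.ravel()
            out_sig[k] = np.sqrt(sig2) if not hsk else np.nan
            out_su[k] = [Sigma_u[0, 0], Sigma_u[1, 1], Sigma_u[0, 1]]
            out_sw[k] = [Sigma_w[0, 0], Sigma_w[1, 1], Sigma_w[0, 1]]
            k += 1

    return out_theta[:k], out_sig[:k], out_su[:k], out_sw[:k]


@dataclass
class BayesFit:
    """Posterior draws and diagnostics of one per-eye hierarchical fit.

    Draw arrays are (chains, draws, ...): ``beta`` (…, 2) global
    intercept/slope, ``u`` (…, 6, 2) cluster and ``w`` (…, 52, 2) location
    random-effect pairs, ``Sigma_u``/``Sigma_w`` (…, 3) covariance components
    (var-int, var-slope, cov) and ``sigma`` residual SD (NaN for hi_hsk).
    """

    variant: str
    beta: np.ndarray
    u: np.ndarray
    w: np.ndarray
    sigma: np.ndarray
    Sigma_u: np.ndarray
    Sigma_w: np.ndarray
    rhat: dict
    converged: bool
    ml_init: MLInit
    cluster_index: np.ndarray
    eye_id: str

    @property
    def max_rhat(self) -> float:
        return float(max(self.rhat.values()))

    @property
    def global_slope_draws(self) -> np.ndarray:
        return self.beta[..., 1].ravel()

    @property
    def cluster_slope_draws(self) -> np.ndarray:
        """(total draws, 6): b1 + u1_c."""
        return (self.beta[..., 1:2] + self.u[..., 1]).reshape(-1, 6)

    @property
    def location_slope_draws(self) -> np.ndarray:
        """(total draws, 52): b1 + u1_c(l) + w1_l."""
        cs = self.beta[..., None, 1] + self.u[..., 1][..., self.cluster_index]
        return (cs + self.w[..., 1]).reshape(-1, len(self.cluster_index))

    def pscores(self) -> PScoreSet:
        loc = self.location_slope_draws
        clu = self.cluster_slope_draws
        return PScoreSet(
            global_=pscore(self.global_slope_draws),
            cluster=np.array([pscore(clu[:, c]) for c in range(clu.shape[1])]),
            location=np.array([pscore(loc[:, l]) for l in range(loc.shape[1])]),
        )

    def predict(self, times) -> np.ndarray:
        """Posterior-mean pointwise prediction at future times.

        Returns (len(times), 52) dB clamped to the 0-50 instrument range
        (negative extrapolations are reported as 0 dB).
        """
        times = np.atleast_1d(np.asarray(times, float))
        if np.any(times < 0):
            raise ValueError("prediction times before series baseline")
        b = self.beta.reshape(-1, 2).mean(axis=0)
        u = self.u.reshape(-1, 6, 2).mean(axis=0)
        w = self.w.reshape(-1, len(self.cluster_index), 2).mean(axis=0)
        a_l = b[0] + u[self.cluster_index, 0] + w[:, 0]
        b_l = b[1] + u[self.cluster_index, 1] + w[:, 1]
        mu = a_l[None, :] + np.outer(times, b_l)
        return np.clip(mu, 0.0, 50.0)


def _eye_seed(master_seed: int, eye_id: str, attempt: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        [int(master_seed) % (2**31), zlib.crc32(eye_id.encode()), attempt]
    )


def fit(series: VFSeries, spec: ModelSpec, grid: Grid24_2 | None = None) -> BayesFit:
    """Fit one hierarchical model to one eye's series by MCMC.

    Blind-spot locations are excluded.  Runs ``spec.n_chains`` parallel chains
    from overdispersed starts; if any monitored parameter has split
    Gelman-Rubin above the threshold, the whole fit is rerun with a doubled
    iteration budget (fresh derived seeds), up to ``spec.max_doublings``
    times.  Non-converged fits are returned with ``converged=False`` — the
    caller decides what to do with them.
    """
    if series.n_tests < 2:
        raise ValueError(f"eye {series.eye_id}: need >= 2 tests")
    grid = grid or load_grid()
    ed = _EyeData(series, grid)
    init = ml_initialise(series, grid)

    for attempt in range(spec.max_doublings + 1):
        mult = 2**attempt
        warmup, draws = spec.warmup * mult, spec.draws * mult
        ss = _eye_seed(spec.seed, series.eye_id, attempt)
        chains = []
        for cs in ss.spawn(spec.n_chains):
            rng = np.random.default_rng(cs)
            chains.append(
                _run_chain(ed, spec, init, spec.variability, rng,
                           warmup + draws, warmup)
            )
        theta = np.stack([c[0] for c in chains])  # (chains, keep, dim)
        sig = np.stack([c[1] for c in chains])
        su = np.stack([c[2] for c in chains])
        sw = np.stack([c[3] for c in chains])

        monitored = {"theta": theta, "Sigma_u": su, "Sigma_w": sw}
        if spec.variant != "hi_hsk":
            monitored["sigma"] = sig[..., None]
        rhat = {}
        for name, arr in monitored.items():
            r = split_rhat(arr)
            for idx, val in np.ndenumerate(r):
                rhat[f"{name}[{','.join(map(str, idx))}]"] = float(val)
        converged = max(rhat.values()) <= spec.rhat_threshold
        if converged:
            break

    nb = 1 + ed.n_clu + ed.n_loc
    th = theta.reshape(theta.shape[0], theta.shape[1], nb, 2)
    return BayesFit(
        variant=spec.variant,
        beta=th[:, :, 0],
        u=th[:, :, 1 : 1 + ed.n_clu],
        w=th[:, :, 1 + ed.n_clu :],
        sigma=sig,
        Sigma_u=su,
        Sigma_w=sw,
        rhat=rhat,
        converged=converged,
        ml_init=init,
        cluster_index=ed.cl,
        eye_id=series.eye_id,
    )


def fit_single_location(t, y, warmup=1000, draws=4000, seed=0):
    """Censored (Tobit) simple linear regression of one location by Gibbs.

    Effectively flat priors on intercept/slope and a Jeffreys-style prior on
    the variance; latent values are imputed below 0 dB for censored
    observations.  Returns a dict with ``slope``/``intercept``/``sigma``
    posterior draws and the joint posterior ``mode`` (intercept, slope, sigma)
    — the highest-log-posterior draw polished by a local optimiser, which
    under these flat priors is the censored maximum-likelihood point.  Used
    for oracle checks of the censored machinery on single-location data.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = len(t)
    if n < 3:
        raise ValueError("need >= 3 observations")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 12345]))
    X = np.column_stack([np.ones(n), t])
    XtX = X.T @ X
    cens = y == 0.0
    Z = y.copy()
    Z[cens] = -0.5
    coef = np.linalg.lstsq(X, Z, rcond=None)[0]
    sig2 = max(float(np.var(Z - X @ coef)), 0.25)

    out = np.empty((draws, 3))
    for it in range(warmup + draws):
        mu = X @ coef
        if cens.any():
            Z[cens] = _trunc_normal_below_zero(rng, mu[cens], np.sqrt(sig2))
        H = XtX / sig2 + 1e-8 * np.eye(2)
        r = X.T @ Z / sig2
        coef, _ = _gauss_draw(rng, H, r)
        sse = float(np.sum((Z - X @ coef) ** 2))
        sig2 = (0.001 + 0.5 * sse) / rng.gamma(0.001 + 0.5 * n)
        if it >= warmup:
            out[it - warmup] = [coef[0], coef[1], np.sqrt(sig2)]

    def logpost(p):
        a, b, s = p
        if s <= 0.05:
            return -np.inf
        mu = a + b * t
        ll = np.where(y == 0, log_ndtr(-mu / s),
                      -np.log(s) - 0.5 * ((y - mu) / s) ** 2)
        return float(ll.sum())

    lp = np.array([logpost(p) for p in out])
    from scipy.optimize import minimize as _minimize

    res = _minimize(lambda p: -logpost(p), x0=out[np.argmax(lp)],
                    method="Nelder-Mead",
                    options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
    return {"intercept": out[:, 0], "slope": out[:, 1], "sigma": out[:, 2],
            "mode": tuple(res.x)}
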