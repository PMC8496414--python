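"""Test-retest variability of perimetric sensitivity.

Pointwise perimetric thresholds become markedly more variable as sensitivity
falls, and the 0 dB instrument floor censors the lower tail of the test-retest
distribution.  This module fits the two-part variability model used throughout
the package:

* a *censored heteroskedastic* Gaussian fitted by maximum likelihood, where the
  mean of each observation is fixed at the location's best available estimate
  (BAE, the median of the test-retest values — robust to censoring, unlike the
  mean) and log(SD) is a cubic polynomial in sensitivity;
* a *bilinear approximation* of the same log(SD) relationship — linear in
  sensitivity with a maximum capping value below a breakpoint (broken stick
  with the lower slope fixed at zero) — used inside the heteroskedastic
  Bayesian progression model for speed.

A recorded 0 dB contributes the censored likelihood term P(Y* <= 0); locations
whose test-retest median is itself 0 dB are excluded, because no usable central
estimate of the true threshold exists there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import log_ndtr

from .grid import load_grid
from .io import TestRetestSet

__all__ = [
    "VariabilityModel",
    "VariabilityFitError",
    "best_available_estimate",
    "testretest_observations",
    "censored_hetero_fit",
    "fit_bilinear_approximation",
    "naive_vs_censored_sd",
    "default_variability_model",
]

SD_FLOOR = 0.1  # dB; below any plausible perimetric SD, keeps likelihoods proper
LOG_SD_FLOOR = np.log(SD_FLOOR)


class VariabilityFitError(RuntimeError):
    """Maximum-likelihood fit of the variability model failed to converge."""


@dataclass(frozen=True)
class VariabilityModel:
    """Fitted mapping sensitivity (dB) -> log test-retest SD (dB).

    ``poly_coeffs`` are (c0, c1, c2, c3): log SD = c0 + c1 s + c2 s^2 + c3 s^3.
    The bilinear form is log SD = b0 + b1 s for s >= breakpoint, constant
    (capped) below it; b1 <= 0 so the cap is the maximum SD.
    """

    poly_coeffs: tuple | None = None
    b0: float | None = None
    b1: float | None = None
    breakpoint: float | None = None
    source: str = "fitted"
    loglik: float | None = None

    @property
    def cap_log_sd(self) -> float:
        return self.b0 + self.b1 * self.breakpoint

    def log_sd(self, sensitivity, form="bilinear"):
        s = np.asarray(sensitivity, dtype=float)
        if form == "polynomial":
            if self.poly_coeffs is None:
                raise ValueError("model has no polynomial part")
            c = self.poly_coeffs
            out = c[0] + c[1] * s + c[2] * s**2 + c[3] * s**3
        elif form == "bilinear":
            if self.b0 is None:
                raise ValueError("model has no bilinear part")
            out = self.b0 + self.b1 * np.maximum(s, self.breakpoint)
        else:
            raise ValueError(f"unknown form {form!r}")
        return np.maximum(out, LOG_SD_FLOOR)

    def sd(self, sensitivity, form="bilinear"):
        """SD (dB) at a sensitivity; strictly positive, floored at 0.1 dB."""
        return np.exp(self.log_sd(sensitivity, form))

    def sd_at(self, sensitivity, form="bilinear"):
        """Range-checked scalar/array SD lookup on the 0-50 dB scale."""
        s = np.asarray(sensitivity, dtype=float)
        if np.any(s < 0) or np.any(s > 50):
            raise ValueError("sensitivity outside the 0-50 dB instrument range")
        return self.sd(s, form)

    def to_dict(self) -> dict:
        return {
            "poly_coeffs": list(self.poly_coeffs) if self.poly_coeffs else None,
            "bilinear": {"b0": self.b0, "b1": self.b1, "breakpoint": self.breakpoint},
            "source": self.source,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VariabilityModel":
        bl = d.get("bilinear") or {}
        pc = d.get("poly_coeffs")
        return cls(
            poly_coeffs=tuple(pc) if pc is not None else None,
            b0=bl.get("b0"),
            b1=bl.get("b1"),
            breakpoint=bl.get("breakpoint"),
            source=d.get("source", "user"),
        )


def best_available_estimate(tr: TestRetestSet) -> pd.DataFrame:
    """Per-location BAE (median of repeats) with exclusion flags.

    Returns a frame with columns ``location_id``, ``bae``, ``excluded``;
    a location is excluded iff its median is 0 dB (the central estimate is
    swallowed by the censoring floor).  Even repeat counts use the standard
    mean-of-middle-two median.
    """
    vals = tr.values  # (n_repeats, 54)
    med = np.median(vals, axis=0)
    return pd.DataFrame(
        {
            "location_id": np.arange(1, vals.shape[1] + 1),
            "bae": med,
            "excluded": med == 0.0,
        }
    )


def testretest_observations(tr_sets, grid=None):
    """Flatten test-retest sets into paired (BAE offset, observed dB) arrays.

    Blind-spot locations and locations with BAE 0 dB are dropped.  The offset
    (the location's BAE) acts as the fixed mean of each observation in the
    censored heteroskedastic fit; only the SD is modelled.
    """
    grid = grid or load_grid()
    keep_grid = grid.informative
    offsets, observed = [], []
    for tr in tr_sets:
        bae = best_available_estimate(tr)
        keep = keep_grid & ~bae["excluded"].to_numpy()
        m = bae["bae"].to_numpy()[keep]
        for t in tr.tests:
            offsets.append(m)
            observed.append(t.sensitivities[keep])
    return np.concatenate(offsets), np.concatenate(observed).astype(float)


def _censored_negll(log_sd, offsets, observed):
    """Negative log-likelihood of observations with fixed means and given log SD."""
    log_sd = np.maximum(log_sd, LOG_SD_FLOOR)
    sd = np.exp(log_sd)
    z = (observed - offsets) / sd
    cens = observed == 0
    ll = np.where(
        cens,
        log_ndtr(-offsets / sd),
        -log_sd - 0.5 * z**2 - 0.5 * np.log(2 * np.pi),
    )
    return -float(ll.sum())


def censored_hetero_fit(offsets, observed, return_loglik=False):
    """ML fit of log(SD) as a cubic in sensitivity under 0 dB left-censoring.

    Parameters
    ----------
    offsets, observed : arrays of BAE means and recorded dB values, as produced
        by :func:`testretest_observations`.

    Returns a :class:`VariabilityModel` carrying the polynomial part (and the
    maximised log-likelihood).  Raises :class:`VariabilityFitError`, reporting
    the final gradient norm, if the optimiser does not converge.
    """
    offsets = np.asarray(offsets, float)
    observed = np.asarray(observed, float)
    resid = observed[observed > 0] - offsets[observed > 0]
    s0 = np.log(max(np.std(resid), 0.2)) if resid.size else 0.0
    z = offsets / 10.0  # scaled basis keeps the simplex steps comparable

    def nll(d):
        return _censored_negll(d[0] + d[1] * z + d[2] * z**2 + d[3] * z**3,
                               offsets, observed)

    res = minimize(nll, x0=[s0, 0.0, 0.0, 0.0], method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
    if not res.success:
        eps = 1e-5
        g = np.array([
            (nll(res.x + eps * e) - nll(res.x - eps * e)) / (2 * eps)
            for e in np.eye(4)
        ])
        raise VariabilityFitError(
            f"censored heteroskedastic fit did not converge "
            f"(final gradient norm {np.linalg.norm(g):.3g})"
        )
    c = tuple(res.x[k] / 10.0**k for k in range(4))
    model = VariabilityModel(poly_coeffs=c, loglik=-res.fun)
    return (model, -res.fun) if return_loglik else model


def _broken_stick_negll(params, k, offsets, observed, fix_lower=False):
    if fix_lower:
        a, b_high = params
        b_low = 0.0
    else:
        a, b_low, b_high = params
    d = offsets - k
    log_sd = a + b_low * np.minimum(d, 0.0) + b_high * np.maximum(d, 0.0)
    return _censored_negll(log_sd, offsets, observed)


def fit_bilinear_approximation(offsets, observed, scan_grid=None):
    """Broken-stick (capped bilinear) fit of log(SD) vs sensitivity.

    The breakpoint is scanned over an integer grid (default 1..30 dB), fitting
    a free lower-segment slope at each candidate; the breakpoint is taken where
    that slope crosses zero (linear interpolation between grid points, scanning
    down from the top), after which the lower segment is fixed constant — the
    cap.  If the lower slope never changes sign on the grid the breakpoint is
    pinned to the nearest grid boundary with a warning.
    """
    offsets = np.asarray(offsets, float)
    observed = np.asarray(observed, float)
    grid = np.arange(1, 31) if scan_grid is None else np.asarray(scan_grid)

    resid = observed[observed > 0] - offsets[observed > 0]
    a0 = np.log(max(np.std(resid), 0.2)) if resid.size else 0.0

    lower_slopes = np.empty(len(grid))
    x0 = [a0, 0.0, -0.05]
    for i, k in enumerate(grid):
        res = minimize(_broken_stick_negll, x0=x0, args=(k, offsets, observed),
                       method="Nelder-Mead",
                       options={"maxiter": 2000, "xatol": 1e-5, "fatol": 1e-7})
        lower_slopes[i] = res.x[1]
        x0 = list(res.x)

    # scan downward: lower slope is negative while the candidate breakpoint
    # sits above the true one, ~zero once the lower segment is all plateau
    k_star = None
    for i in range(len(grid) - 1, 0, -1):
        lo, hi = lower_slopes[i - 1], lower_slopes[i]
        if hi < 0.0 <= lo:
            k_star = grid[i - 1] + (0.0 - lo) / (hi - lo) * (grid[i] - grid[i - 1])
            break
    if k_star is None:
        k_star = float(grid[0]) if lower_slopes[-1] < 0 else float(grid[-1])
        warnings.warn(
            "lower-segment slope has no zero crossing on the scan grid; "
            f"breakpoint pinned to {k_star} dB"
        )

    res = minimize(_broken_stick_negll, x0=[a0, -0.05],
                   args=(k_star, offsets, observed, True), method="Nelder-Mead",
                   options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-8})
    a, b_high = res.x
    return VariabilityModel(
        b0=a - b_high * k_star, b1=b_high, breakpoint=float(k_star),
        loglik=-res.fun,
    )


def naive_vs_censored_sd(offsets, observed, min_obs=2) -> pd.DataFrame:
    """Per-sensitivity-level naive vs censored-ML test-retest SD.

    Observations are grouped by their rounded BAE (round-half-to-even).  The
    naive SD is the sample SD of the deviations from the BAE; the censored SD
    maximises the left-censored Gaussian likelihood for the same level.  The
    naive estimate underestimates variability wherever the 0 dB floor truncates
    the lower tail.  Levels with fewer than ``min_obs`` observations are
    skipped with a warning.
    """
    offsets = np.asarray(offsets, float)
    observed = np.asarray(observed, float)
    levels = np.round(offsets).astype(int)
    rows = []
    for lev in np.unique(levels):
        sel = levels == lev
        n = int(sel.sum())
        if n < min_obs:
            warnings.warn(f"level {lev} dB has {n} observation(s); skipped")
            continue
        dev = observed[sel] - offsets[sel]
        naive = float(np.sqrt(np.sum(dev**2) / (n - 1)))
        res = minimize_scalar(
            lambda ls: _censored_negll(ls, offsets[sel], observed[sel]),
            bounds=(LOG_SD_FLOOR, np.log(25.0)), method="bounded",
            options={"xatol": 1e-6},
        )
        rows.append(
            {"level": int(lev), "n": n, "naive_sd": naive,
             "censored_sd": float(np.exp(res.x))}
        )
    return pd.DataFrame(rows)


def default_variability_model() -> VariabilityModel:
    """Packaged default variability model.

    The bilinear part is the ground truth of the synthetic test-retest
    generator — Henson-like values: SD ~1.2 dB at 35 dB rising to a cap of
    ~4.9 dB below 12 dB.  The cubic part is a least-squares fit to the same
    log(SD) curve so both forms describe one relationship.  User-fitted
    coefficients (from :func:`censored_hetero_fit` on real test-retest data)
    should replace these defaults whenever such data exist.
    """
    b0, b1, bp = 2.3, -0.06, 12.0
    s = np.linspace(0.0, 50.0, 101)
    y = b0 + b1 * np.maximum(s, bp)
    c = np.polynomial.polynomial.polyfit(s, y, 3)
    return VariabilityModel(
        poly_coeffs=tuple(c), b0=b0, b1=b1, breakpoint=bp, source="default"
    )
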