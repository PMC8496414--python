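"""Evaluation harness: bias, detection, time-to-progression, prediction error.

Four experiments compare the hierarchical Bayesian variants with the benchmark
methods on synthetic cohorts:

* **Bias** — series with little censoring are shifted down by 10/20 dB (with
  variability inflated to match the lower sensitivities, then re-censored at
  0 dB); an unbiased model estimates the same slopes on the shifted series as
  on the originals.
* **Detection** — hit-rate (HR) curves versus specificity, where specificity is
  measured on stable series built by permuting test-retest sets; partial AUC is
  taken over the specificity band [0.9, 1.0].
* **Time to progression** — earliest truncation length (4..10 tests) at which a
  method's statistic crosses a specificity-calibrated cutoff; Kaplan-Meier
  medians, with pairwise method comparison by Cox proportional hazards using an
  eye-level cluster term and Holm-adjusted p-values.
* **Prediction error** — fit the first k tests (k = 4..9), predict tests
  k+1..10 pointwise; mean absolute error against the no-change baseline (the
  pointwise average of the first two tests).

Every method is reduced to one scalar *progression score* per eye, oriented so
that larger means stronger evidence of worsening (P-scores for the Bayesian
models, S for PoPLR, 1-p for the regression p-values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bayes, comparators
from .grid import Grid24_2, load_grid
from .io import VFSeries, VFTest
from .variability import VariabilityModel

__all__ = [
    "ShiftedSeriesPair",
    "HRCurve",
    "SurvivalResult",
    "PredictionErrorResult",
    "BAYES_METHODS",
    "ALL_METHODS",
    "unit_counts",
    "score_series",
    "score_cohort",
    "select_low_censoring",
    "shift_and_inflate",
    "bias_experiment",
    "stable_series_permutations",
    "calibrate_cutoff",
    "hr_fpr_curve",
    "time_to_progression",
    "survival_compare",
    "prediction_error",
]

BAYES_METHODS = ("hi_linear", "hi_censored", "hi_hsk")
ALL_METHODS = BAYES_METHODS + ("plr_global", "poplr_p", "poplr_s")


def unit_counts(n_eyes: int, grid: Grid24_2 | None = None) -> dict:
    """Total cluster and location units a cohort contributes to pooled
    detection statistics (6 and 52 per eye)."""
    grid = grid or load_grid()
    return {
        "eyes": n_eyes,
        "clusters": n_eyes * grid.n_clusters,
        "locations": n_eyes * grid.n_informative,
    }


# ---------------------------------------------------------------------------
# progression scores
# ---------------------------------------------------------------------------


def score_series(
    series: VFSeries,
    method: str,
    var_model: VariabilityModel | None = None,
    mcmc: dict | None = None,
    seed: int = 0,
    grid: Grid24_2 | None = None,
) -> float:
    """One scalar progression score for one eye; larger = more progression.

    Bayesian methods return the global P-score; ``plr_global`` and ``poplr_p``
    return 1 - p; ``poplr_s`` returns the S statistic.
    """
    if method in BAYES_METHODS:
        spec = bayes.ModelSpec(
            variant=method,
            variability=var_model if method == "hi_hsk" else None,
            seed=seed,
            **(mcmc or {}),
        )
        f = bayes.fit(series, spec, grid=grid)
        if not f.converged:
            # conservative: treat as non-progressing evidence of exactly no trend
            warnings.warn(f"eye {series.eye_id}: non-converged {method} fit")
        return f.pscores().global_
    if method == "plr_global":
        return 1.0 - comparators.plr(series, "global", grid=grid).p_value
    if method == "poplr_s":
        # the observed S does not need the permutation null
        return comparators.tpm_statistic(
            comparators.pointwise_plr_pvalues(series, grid=grid)
        )
    if method == "poplr_p":
        return 1.0 - comparators.poplr(series, seed=seed, grid=grid).p_value
    raise ValueError(f"unknown method {method!r}")


def score_cohort(series_list, method, truncation=None, **kw) -> np.ndarray:
    """Vector of per-eye progression scores, optionally on truncated series."""
    out = np.empty(len(series_list))
    for i, s in enumerate(series_list):
        if truncation is not None:
            s = s.truncate(min(truncation, s.n_tests))
        out[i] = score_series(s, **({"method": method} | kw))
    return out


# ---------------------------------------------------------------------------
# bias experiment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShiftedSeriesPair:
    original: VFSeries
    shifted: VFSeries
    shift_db: float


def select_low_censoring(series_list, max_zero_frac: float = 0.30,
                         grid: Grid24_2 | None = None) -> list:
    """Series in which 0 dB values make up less than ``max_zero_frac`` of the
    observations at every informative location — series whose trends a simple
    uncensored regression can describe accurately."""
    grid = grid or load_grid()
    info = grid.informative
    out = []
    for s in series_list:
        zero_frac = (s.values[:, info] == 0).mean(axis=0)
        if np.all(zero_frac < max_zero_frac):
            out.append(s)
    return out


def shift_and_inflate(
    series: VFSeries,
    shift_db: float,
    var_model: VariabilityModel,
    seed: int = 0,
    grid: Grid24_2 | None = None,
) -> ShiftedSeriesPair:
    """Shift a series down and inflate its noise to match the new sensitivity.

    Each observation is moved by ``shift_db`` and receives additional zero-mean
    Gaussian noise with SD sqrt(max(0, SD_poly(shifted)^2 - SD_poly(original)^2))
    — the variance top-up that makes the total variability appropriate for the
    lower sensitivity level (polynomial form of the variability model).  The
    result is rounded to integer dB and censored at 0.
    """
    if var_model is None:
        raise ValueError("shift_and_inflate requires a variability model")
    grid = grid or load_grid()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 55221]))
    info = grid.informative
    tests = []
    for t in series.tests:
        orig = t.sensitivities.astype(float)
        new_level = orig + shift_db
        sd_orig = var_model.sd(np.clip(orig, 0, 50), form="polynomial")
        sd_new = var_model.sd(np.clip(new_level, 0, 50), form="polynomial")
        extra = np.sqrt(np.maximum(sd_new**2 - sd_orig**2, 0.0))
        vals = new_level + np.where(extra > 0, rng.normal(size=54) * extra, 0.0)
        vals[~info] = orig[~info]  # blind spot untouched
        tests.append(VFTest(t.time_years, np.clip(np.round(vals), 0, 50)))
    return ShiftedSeriesPair(series, VFSeries(series.eye_id, tests), shift_db)


def _slope_estimates(fit: bayes.BayesFit) -> dict:
    """Posterior-mean slopes at the three levels of the hierarchy."""
    return {
        "global": np.array([fit.global_slope_draws.mean()]),
        "cluster": fit.cluster_slope_draws.mean(axis=0),
        "location": fit.location_slope_draws.mean(axis=0),
    }


def bias_experiment(
    series_list,
    variants=BAYES_METHODS,
    shifts=(-10.0, -20.0),
    var_model: VariabilityModel | None = None,
    mcmc: dict | None = None,
    seed: int = 0,
    grid: Grid24_2 | None = None,
) -> pd.DataFrame:
    """Slope bias of each model under artificial downward shifts.

    For every eye and shift, each model is fitted to the original and to the
    shifted-and-inflated series; the bias is the shifted-minus-original slope
    estimate, averaged within (variant, shift, level, original-slope sign).
    Ideally zero: the shift changes sensitivities, not trends.  Non-converged
    fits are dropped and counted in ``df.attrs["n_nonconverged"]``.
    """
    grid = grid or load_grid()
    rows = []
    n_noncvg = 0
    for i, s in enumerate(series_list):
        pairs = {sh: shift_and_inflate(s, sh, var_model, seed=seed + i, grid=grid)
                 for sh in shifts}
        for variant in variants:
            spec = bayes.ModelSpec(
                variant=variant,
                variability=var_model if variant == "hi_hsk" else None,
                seed=seed,
                **(mcmc or {}),
            )
            f0 = bayes.fit(s, spec, grid=grid)
            if not f0.converged:
                n_noncvg += 1
                continue
            est0 = _slope_estimates(f0)
            for sh, pair in pairs.items():
                f1 = bayes.fit(pair.shifted, spec, grid=grid)
                if not f1.converged:
                    n_noncvg += 1
                    continue
                est1 = _slope_estimates(f1)
                for level in ("global", "cluster", "location"):
                    d = est1[level] - est0[level]
                    sign = np.where(est0[level] < 0, "negative", "positive")
                    for di, si in zip(d, sign):
                        rows.append(
                            {"eye_id": s.eye_id, "variant": variant,
                             "shift_db": sh, "level": level,
                             "original_sign": si, "bias": di}
                        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["variant", "shift_db", "level", "original_sign"])["bias"]
        .agg(["mean", "count"])
        .rename(columns={"mean": "mean_bias", "count": "n_units"})
        .reset_index()
    )
    out.attrs["n_nonconverged"] = n_noncvg
    return out


# ---------------------------------------------------------------------------
# stable series and detection
# ---------------------------------------------------------------------------


def stable_series_permutations(testretest_sets, clinical_series, seed=0) -> list:
    """One stable series per clinical eye from permuted test-retest sets.

    Each clinical eye is paired with a random test-retest eye; the repeats are
    randomly permuted, the first 10 (or as many as the clinical series has
    visits) retained and assigned the clinical eye's visit times.  Because the
    repeats are exchangeable, any true time trend is destroyed: the series are
    stable by construction and carry realistic test-retest noise.
    """
    short = [tr.eye_id for tr in testretest_sets if tr.n_repeats < 10]
    if short:
        raise ValueError(
            f"test-retest sets need >= 10 repeats for stable permutation; "
            f"too few in: {short}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 424242]))
    out = []
    for s in clinical_series:
        tr = testretest_sets[rng.integers(len(testretest_sets))]
        n_keep = min(10, s.n_tests, tr.n_repeats)
        order = rng.permutation(tr.n_repeats)[:n_keep]
        times = s.times[:n_keep]
        tests = [
            VFTest(times[k], tr.tests[order[k]].sensitivities)
            for k in range(n_keep)
        ]
        out.append(VFSeries(f"stable_{s.eye_id}", tests))
    return out


def calibrate_cutoff(stable_scores, specificity: float) -> float:
    """Cutoff at the requested specificity: the empirical quantile (midpoint
    interpolation) of the stable-series score distribution.  Detection uses
    score > cutoff."""
    return float(np.quantile(np.asarray(stable_scores, float), specificity,
                             method="midpoint"))


@dataclass
class HRCurve:
    """Hit-rate curve against specificity, with pAUC over [spec_floor, 1]."""

    cutoffs: np.ndarray
    specificity: np.ndarray
    hit_rate: np.ndarray
    spec_floor: float
    pauc: float
    pauc_ci: tuple | None
    hr_at: dict  # specificity level -> (hr, lo, hi)


def _curve_points(clin, stable):
    cuts = np.concatenate([np.unique(np.concatenate([clin, stable])), [np.inf]])
    # score >= cutoff counts as flagged: ties handled identically on both arms
    fpr = np.array([(stable >= c).mean() for c in cuts])
    hr = np.array([(clin >= c).mean() for c in cuts])
    spec = 1.0 - fpr
    order = np.argsort(spec, kind="stable")
    return cuts[order], spec[order], hr[order]


def _pauc(spec, hr, floor):
    """Trapezoidal area of the HR curve over specificity in [floor, 1].

    At a tied specificity only the best achievable hit-rate counts (the usual
    ROC convention for vertical segments).
    """
    spec_u = np.unique(spec)
    hr_u = np.array([hr[spec == s].max() for s in spec_u])
    s = np.concatenate([[0.0], spec_u]) if spec_u[0] > 0 else spec_u
    h = np.concatenate([[1.0], hr_u]) if spec_u[0] > 0 else hr_u
    grid_s = np.union1d(s, [floor])
    grid_s = grid_s[grid_s >= floor]
    grid_h = np.interp(grid_s, s, h)
    return float(np.trapezoid(grid_h, grid_s))


def _hr_at_specificity(clin, stable, level):
    cut = calibrate_cutoff(stable, level)
    return float((clin > cut).mean())


def hr_fpr_curve(
    clin_scores,
    stable_scores,
    spec_floor: float = 0.90,
    levels=(0.975, 0.95, 0.90),
    n_boot: int = 2000,
    seed: int = 0,
) -> HRCurve:
    """ROC-style hit-rate curve of one method.

    ``clin_scores`` and ``stable_scores`` hold one progression score per eye
    for the clinical-like and stable cohorts.  The hit-rate is read at the
    requested specificity levels (cutoff at the stable-score quantile), the
    partial AUC integrates the curve over specificity in [spec_floor, 1]
    (unnormalised, so the maximum is 1 - spec_floor), and eye-resampling
    bootstrap gives percentile CIs.
    """
    clin = np.asarray(clin_scores, float)
    stable = np.asarray(stable_scores, float)
    if clin.size == 0 or stable.size == 0:
        raise ValueError("empty cohort")
    cuts, spec, hr = _curve_points(clin, stable)
    pauc = _pauc(spec, hr, spec_floor)
    hr_pt = {lv: _hr_at_specificity(clin, stable, lv) for lv in levels}

    pauc_ci = None
    hr_at = {lv: (hr_pt[lv], None, None) for lv in levels}
    if n_boot:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7070]))
        bp = np.empty(n_boot)
        bh = {lv: np.empty(n_boot) for lv in levels}
        for b in range(n_boot):
            c = clin[rng.integers(len(clin), size=len(clin))]
            s = stable[rng.integers(len(stable), size=len(stable))]
            _, sp, h = _curve_points(c, s)
            bp[b] = _pauc(sp, h, spec_floor)
            for lv in levels:
                bh[lv][b] = _hr_at_specificity(c, s, lv)
        pauc_ci = tuple(np.quantile(bp, [0.025, 0.975]))
        hr_at = {
            lv: (hr_pt[lv], *np.quantile(bh[lv], [0.025, 0.975])) for lv in levels
        }
    return HRCurve(cuts, spec, hr, spec_floor, pauc, pauc_ci, hr_at)


# ---------------------------------------------------------------------------
# time to progression
# ---------------------------------------------------------------------------


@dataclass
class SurvivalResult:
    """Per-eye (time, event) pairs and the Kaplan-Meier summary."""

    table: pd.DataFrame  # eye_id, time, event
    km_median: float
    km_median_ci: tuple


def time_to_progression(stats: pd.DataFrame, cutoffs) -> SurvivalResult:
    """Earliest detection time over growing truncations of each series.

    ``stats`` has one row per (eye_id, n_tests) with columns ``score`` and
    ``time_years`` (time of the truncation's last test).  ``cutoffs`` maps
    n_tests -> cutoff (or is a single scalar), calibrated on stable series at
    the desired specificity.  An eye progresses at the earliest truncation
    whose score exceeds the cutoff; otherwise it is censored at its last
    truncation time.  Detection is single and unconfirmed.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.utils import median_survival_times

    if np.isscalar(cutoffs):
        cutoffs = {int(n): float(cutoffs) for n in stats["n_tests"].unique()}
    rows = []
    for eye, g in stats.groupby("eye_id", sort=True):
        g = g.sort_values("n_tests")
        hit = g[g.apply(lambda r: r["score"] > cutoffs[int(r["n_tests"])], axis=1)]
        if len(hit):
            rows.append({"eye_id": eye, "time": hit.iloc[0]["time_years"],
                         "event": 1})
        else:
            rows.append({"eye_id": eye, "time": g.iloc[-1]["time_years"],
                         "event": 0})
    table = pd.DataFrame(rows)
    kmf = KaplanMeierFitter().fit(table["time"], table["event"])
    med = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return SurvivalResult(table, med, (lo, hi))


def survival_compare(results: dict) -> pd.DataFrame:
    """Pairwise Cox proportional-hazards comparison of methods.

    ``results`` maps method name -> :class:`SurvivalResult` computed on the
    same eyes.  Each pair is compared with a Cox model on the stacked (time,
    event) data with a method indicator and an eye-level cluster term (robust
    variance), and p-values are Holm-adjusted across pairs.
    """
    from itertools import combinations

    from lifelines import CoxPHFitter
    from statsmodels.stats.multitest import multipletests

    rows = []
    for a, b in combinations(results.keys(), 2):
        df = pd.concat(
            [
                results[a].table.assign(is_b=0),
                results[b].table.assign(is_b=1),
            ],
            ignore_index=True,
        )
        cph = CoxPHFitter()
        cph.fit(df[["time", "event", "is_b", "eye_id"]], "time", "event",
                cluster_col="eye_id", robust=True)
        rows.append(
            {"method_a": a, "method_b": b,
             "hazard_ratio": float(np.exp(cph.params_["is_b"])),
             "p_value": float(cph.summary.loc["is_b", "p"])}
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p_value"], method="holm")[1]
    return out


# ---------------------------------------------------------------------------
# prediction error
# ---------------------------------------------------------------------------


@dataclass
class PredictionErrorResult:
    """MAE table plus stratified signed errors (all pointwise, in dB)."""

    table: pd.DataFrame  # method, n_fit, mae, sd_abs_error, n_points
    by_baseline_change: pd.DataFrame  # signed error vs change-from-baseline bin
    by_baseline_level: pd.DataFrame  # MAE vs baseline-sensitivity bin
    n_skipped: int


def _plr_predict(series: VFSeries, times, grid) -> np.ndarray:
    """Pointwise OLS prediction, clamped to the instrument range."""
    t = series.times
    Y = series.values[:, grid.informative].astype(float)
    tc = t - t.mean()
    sxx = float(tc @ tc)
    slope = tc @ Y / sxx
    intercept = Y.mean(axis=0) - slope * t.mean()
    mu = intercept[None, :] + np.outer(np.asarray(times, float), slope)
    return np.clip(mu, 0.0, 50.0)


def prediction_error(
    series_list,
    variants=BAYES_METHODS,
    var_model: VariabilityModel | None = None,
    mcmc: dict | None = None,
    truncations=range(4, 10),
    seed: int = 0,
    grid: Grid24_2 | None = None,
    change_bins=(-30, -15, -9, -3, 3, 9, 15, 30),
    level_bins=(0, 10, 16, 22, 28, 34, 51),
) -> PredictionErrorResult:
    """Pointwise prediction of future tests from truncated series.

    Uses the first 10 tests of each eligible series: fit the first k
    (k in ``truncations``), predict tests k+1..10 at every informative
    location.  Methods: the Bayesian variants (posterior-mean prediction),
    pointwise simple linear regression (0/50 dB clamped), and the no-change
    baseline — the pointwise average of the first two tests.  Series with
    fewer than 10 tests are skipped and counted.
    """
    grid = grid or load_grid()
    info = grid.informative
    n_skipped = 0
    recs = []
    for s in series_list:
        if s.n_tests < 10:
            n_skipped += 1
            continue
        s10 = s.truncate(10)
        Y = s10.values[:, info].astype(float)
        t = s10.times
        baseline = Y[:2].mean(axis=0)
        for k in truncations:
            fit_s = s10.truncate(k)
            future_t = t[k:10]
            actual = Y[k:10]
            preds = {"no_change": np.tile(baseline, (len(future_t), 1)),
                     "plr": _plr_predict(fit_s, future_t, grid)}
            for variant in variants:
                spec = bayes.ModelSpec(
                    variant=variant,
                    variability=var_model if variant == "hi_hsk" else None,
                    seed=seed,
                    **(mcmc or {}),
                )
                preds[variant] = bayes.fit(fit_s, spec, grid=grid).predict(future_t)
            for method, pred in preds.items():
                err = (pred - actual).ravel()
                recs.append(
                    {"method": method, "n_fit": k, "err": err,
                     "change": (actual - baseline[None, :]).ravel(),
                     "level": np.tile(baseline, (len(future_t), 1)).ravel()}
                )
    if not recs:
        raise ValueError("no series with >= 10 tests")

    long = pd.DataFrame(
        {
            "method": np.repeat([r["method"] for r in recs],
                                [len(r["err"]) for r in recs]),
            "n_fit": np.repeat([r["n_fit"] for r in recs],
                               [len(r["err"]) for r in recs]),
            "err": np.concatenate([r["err"] for r in recs]),
            "change": np.concatenate([r["change"] for r in recs]),
            "level": np.concatenate([r["level"] for r in recs]),
        }
    )
    long["abs_err"] = long["err"].abs()
    table = (
        long.groupby(["method", "n_fit"])["abs_err"]
        .agg(mae="mean", sd_abs_error="std", n_points="count")
        .reset_index()
    )
    long["change_bin"] = pd.cut(long["change"], bins=list(change_bins))
    by_change = (
        long.groupby(["method", "change_bin"], observed=True)["err"]
        .mean()
        .reset_index()
        .rename(columns={"err": "mean_signed_error"})
    )
    long["level_bin"] = pd.cut(long["level"], bins=list(level_bins))
    by_level = (
        long.groupby(["method", "level_bin"], observed=True)["abs_err"]
        .mean()
        .reset_index()
        .rename(columns={"abs_err": "mae"})
    )
    return PredictionErrorResult(table, by_change, by_level, n_skipped)
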