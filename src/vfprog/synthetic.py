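"""Synthetic visual-field cohorts with the statistical structure of clinic data.

The generator is the exact generative mirror of the heteroskedastic censored
hierarchical model: per eye it draws a global intercept/slope, cluster- and
location-level random-effect pairs, builds the latent linear predictor
mu_l(t) = (b0 + u0_c + w0_l) + (b1 + u1_c + w1_l) t, adds Gaussian noise with
SD given by the variability model evaluated at mu, rounds to integer dB (the
instrument reports integers) and censors at the 0 dB floor (clipping at the
50 dB ceiling).  Test-retest sets are generated the same way around fixed true
sensitivities.

Three presets loosely emulate the damage ranges of typical glaucoma-clinic,
trial and test-retest populations; the longitudinal preset is scaled down 10x
by default for desk-scale runs (the full size is a flag away).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .grid import load_grid
from .io import TestRetestSet, VFSeries, VFTest
from .variability import VariabilityModel, default_variability_model

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "generate_testretest",
    "preset",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic longitudinal cohort.

    Baseline mean sensitivity and its spread are calibrated loosely to a
    moderately damaged glaucoma-clinic population (median MD about -6 dB on a
    ~30 dB normal field).  Progressing eyes receive a diffuse negative global
    slope (dB/year) plus a *focal* component: an extra decline concentrated in
    a few randomly chosen optic-nerve-head sectors, mirroring the
    bundle-shaped defects in which glaucomatous loss typically deepens.
    Stable eyes are truly stable (zero slope at every level), which is what
    specificity calibration on permuted test-retest series assumes.
    """

    n_eyes: int = 100
    n_visits: int = 10
    followup_years: tuple = (4.0, 10.0)  # uniform total duration
    baseline_mean: float = 23.5  # dB, global intercept
    baseline_sd: float = 3.0
    fraction_progressing: float = 0.5
    slope_mean: float = -0.25  # diffuse dB/year for progressors (truncated at 0)
    slope_sd: float = 0.15
    focal_slope_mean: float = -0.6  # extra dB/year in the affected sectors
    focal_slope_sd: float = 0.3
    n_focal_clusters: tuple = (1, 3)  # uniform over this inclusive range
    cluster_intercept_sd: float = 2.5
    location_intercept_sd: float = 3.5
    cluster_slope_sd: float = 0.1
    location_slope_sd: float = 0.2
    variability: VariabilityModel | None = None
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.fraction_progressing <= 1.0):
            raise ValueError("fraction_progressing must be in [0, 1]")
        for name in ("baseline_sd", "slope_sd", "cluster_intercept_sd",
                     "location_intercept_sd", "cluster_slope_sd",
                     "location_slope_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_eyes < 1 or self.n_visits < 2:
            raise ValueError("need n_eyes >= 1 and n_visits >= 2")


def _visit_times(rng, spec) -> np.ndarray:
    duration = rng.uniform(*spec.followup_years)
    gaps = rng.uniform(0.5, 1.5, size=spec.n_visits - 1)
    t = np.concatenate([[0.0], np.cumsum(gaps)])
    t *= duration / t[-1]
    return np.round(t, 3)


def _record(latent, rng=None) -> np.ndarray:
    """Instrument output: integer dB, censored at 0, clipped at 50."""
    return np.clip(np.round(latent), 0, 50).astype(int)


def generate_cohort(spec: CohortSpec) -> list:
    """Draw a cohort of :class:`VFSeries`; byte-reproducible from the seed."""
    grid = load_grid()
    var = spec.variability or default_variability_model()
    info = grid.informative
    cl = grid.informative_cluster_index  # (52,)
    n_loc = int(info.sum())
    master = np.random.SeedSequence(spec.seed)
    out = []
    for i, ss in enumerate(master.spawn(spec.n_eyes)):
        rng = np.random.default_rng(ss)
        t = _visit_times(rng, spec)
        b0 = rng.normal(spec.baseline_mean, spec.baseline_sd)
        progressing = rng.random() < spec.fraction_progressing
        if progressing:
            b1 = min(rng.normal(spec.slope_mean, spec.slope_sd), 0.0)
            u1 = rng.normal(0.0, spec.cluster_slope_sd, size=6)
            if spec.focal_slope_mean < 0:
                lo, hi = spec.n_focal_clusters
                k = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
                if k:
                    focal = rng.choice(6, size=k, replace=False)
                    u1[focal] += np.minimum(
                        rng.normal(spec.focal_slope_mean, spec.focal_slope_sd,
                                   size=k), 0.0)
            w1 = rng.normal(0.0, spec.location_slope_sd, size=n_loc)
        else:
            b1 = 0.0
            u1 = np.zeros(6)
            w1 = np.zeros(n_loc)
        u0 = rng.normal(0.0, spec.cluster_intercept_sd, size=6)
        w0 = rng.normal(0.0, spec.location_intercept_sd, size=n_loc)
        a = b0 + u0[cl] + w0  # (52,)
        b = b1 + u1[cl] + w1
        mu = a[None, :] + np.outer(t, b)  # (n_visits, 52)
        latent = mu + rng.normal(size=mu.shape) * var.sd(mu)
        vals = np.zeros((spec.n_visits, 54), dtype=int)
        vals[:, info] = _record(latent)
        # blind spot: low uninformative responses, excluded from all fits
        vals[:, ~info] = _record(rng.normal(2.0, 3.0, size=(spec.n_visits, 2)))
        tests = [VFTest(t[k], vals[k]) for k in range(spec.n_visits)]
        out.append(VFSeries(f"eye{i + 1:04d}", tests))
    return out


def generate_testretest(
    n_eyes: int,
    n_repeats: int,
    seed: int = 0,
    var_model: VariabilityModel | None = None,
    true_mean: float = 25.0,
    true_sd: float = 8.0,
    true_range: tuple = (0.0, 38.0),
) -> list:
    """Draw short-interval test-retest sets around fixed true sensitivities.

    True pointwise sensitivities are clipped-normal per location; repeats are
    i.i.d. censored heteroskedastic around them.  Times hold the repeat index.
    """
    if n_repeats < 3:
        raise ValueError("test-retest requires n_repeats >= 3")
    if n_eyes < 1:
        raise ValueError("n_eyes must be >= 1")
    grid = load_grid()
    var = var_model or default_variability_model()
    info = grid.informative
    n_loc = int(info.sum())
    master = np.random.SeedSequence(seed)
    out = []
    for i, ss in enumerate(master.spawn(n_eyes)):
        rng = np.random.default_rng(ss)
        true = np.clip(rng.normal(true_mean, true_sd, size=n_loc), *true_range)
        vals = np.zeros((n_repeats, 54), dtype=int)
        latent = true[None, :] + rng.normal(size=(n_repeats, n_loc)) * var.sd(true)
        vals[:, info] = _record(latent)
        vals[:, ~info] = _record(rng.normal(2.0, 3.0, size=(n_repeats, 2)))
        tests = [VFTest(float(k), vals[k]) for k in range(n_repeats)]
        out.append(TestRetestSet(f"tr{i + 1:04d}", tests))
    return out


def preset(name: str, full_size: bool = False, **overrides):
    """Named cohort presets.

    ``clinical-like`` returns a :class:`CohortSpec` (335 eyes desk-scale, 3352
    full size); ``rapid-like`` and ``halifax-like`` return keyword dicts for
    :func:`generate_testretest` emulating the two test-retest populations
    (146 eyes / ~10 repeats and 30 eyes / 12 repeats respectively).
    """
    if name == "clinical-like":
        spec = CohortSpec(n_eyes=3352 if full_size else 335)
        return replace(spec, **overrides) if overrides else spec
    if name == "rapid-like":
        kw = {"n_eyes": 146 if full_size else 15, "n_repeats": 10,
              "true_mean": 26.0, "true_sd": 7.0}
    elif name == "halifax-like":
        kw = {"n_eyes": 30, "n_repeats": 12, "true_mean": 27.0, "true_sd": 6.0}
    else:
        raise ValueError(f"unknown preset {name!r}")
    kw.update(overrides)
    return kw
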