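"""Evaluation harness: filters, shifts, HR curves, survival, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import vfprog as vf
from vfprog import evaluation as ev

from conftest import make_series


class TestSelectLowCensoring:
    def test_single_bad_location_excludes(self, grid):
        vals = np.full((10, 54), 25)
        vals[:4, 5] = 0  # 40% zeros at one location
        assert ev.select_low_censoring([make_series(vals)]) == []

    def test_clean_series_included(self):
        s = make_series(np.full((10, 54), 25))
        assert ev.select_low_censoring([s]) == [s]

    def test_matches_independent_recount(self, grid):
        """The subset agrees with a pandas-based recount of zero fractions."""
        cohort = vf.generate_cohort(
            vf.CohortSpec(n_eyes=25, baseline_mean=18.0, seed=51)
        )
        kept = {s.eye_id for s in ev.select_low_censoring(cohort)}
        recount = set()
        for s in cohort:
            df = pd.DataFrame(s.values[:, grid.informative])
            if (df.eq(0).mean() < 0.30).all():
                recount.add(s.eye_id)
        assert kept == recount
        assert 0 < len(kept) < len(cohort)


class TestShiftAndInflate:
    def test_zero_shift_is_identity(self, var_model, one_eye):
        pair = ev.shift_and_inflate(one_eye, 0.0, var_model, seed=1)
        assert pair.shifted == one_eye

    def test_shift_censors_and_bounds(self, grid, var_model, one_eye):
        pair = ev.shift_and_inflate(one_eye, -10.0, var_model, seed=1)
        v0 = one_eye.values[:, grid.informative].astype(float)
        v1 = pair.shifted.values[:, grid.informative].astype(float)
        assert v1.min() >= 0 and v1.max() <= 50
        low = v0 <= 10
        assert (v1[low] <= np.maximum(v0[low] - 10 + 8, 0)).all()
        # deep values land on the floor with the censored flag set
        hit = v0 - 10 < -5
        if hit.any():
            assert np.all(v1[hit] == 0)

    def test_total_sd_matches_target_level(self, grid, var_model):
        """Observations at 35 dB shifted to 25 dB end up with the polynomial
        SD of the *new* level (variance top-up), Monte-Carlo checked."""
        rng = np.random.default_rng(9)
        n = 400
        sd35 = float(var_model.sd(35, "polynomial"))
        vals = np.clip(np.round(35 + rng.normal(0, sd35, (n, 54))), 0, 50)
        s = make_series(vals, times=np.arange(n, dtype=float))
        pair = ev.shift_and_inflate(s, -10.0, var_model, seed=2)
        shifted = pair.shifted.values[:, grid.informative].astype(float)
        target = float(var_model.sd(25, "polynomial"))
        assert shifted.std() == pytest.approx(
            np.sqrt(target**2 + 1 / 12), rel=0.08
        )

    def test_requires_model(self, one_eye):
        with pytest.raises(ValueError):
            ev.shift_and_inflate(one_eye, -10.0, None)


class TestHRCurve:
    def test_perfect_separation(self):
        c = ev.hr_fpr_curve(np.linspace(2, 3, 50), np.linspace(0, 1, 50), n_boot=50)
        for lv in (0.975, 0.95, 0.90):
            assert c.hr_at[lv][0] == 1.0
        assert c.pauc == pytest.approx(0.1, abs=1e-6)

    def test_identical_distributions_near_chance(self):
        rng = np.random.default_rng(61)
        a = rng.normal(size=4000)
        b = rng.normal(size=4000)
        c = ev.hr_fpr_curve(a, b, n_boot=0)
        assert c.pauc == pytest.approx(0.005, abs=0.002)

    def test_tied_scores_match_bruteforce_sweep(self):
        """Heavily tied integer scores: every curve point and the read-off
        hit-rates equal an independent brute-force sweep that applies each
        cutoff identically to both cohorts."""
        rng = np.random.default_rng(67)
        clin = rng.integers(0, 6, 200).astype(float)
        stab = rng.integers(0, 5, 150).astype(float)
        c = ev.hr_fpr_curve(clin, stab, n_boot=0)
        got = set(zip(np.round(c.specificity, 12), np.round(c.hit_rate, 12)))
        for k in np.unique(np.concatenate([clin, stab])):
            pt = (round(1 - (stab >= k).mean(), 12), round((clin >= k).mean(), 12))
            assert pt in got
        for lv in (0.975, 0.95, 0.90):
            cut = np.quantile(stab, lv, method="midpoint")
            assert c.hr_at[lv][0] == pytest.approx((clin > cut).mean())

    def test_monotone_hr_in_specificity(self):
        rng = np.random.default_rng(71)
        c = ev.hr_fpr_curve(rng.normal(1, 1, 300), rng.normal(0, 1, 300), n_boot=0)
        assert c.hr_at[0.90][0] >= c.hr_at[0.975][0]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            ev.hr_fpr_curve([], [1.0])


@pytest.fixture(scope="module")
def setup():
    tr = vf.generate_testretest(10, 12, seed=81)
    clin = vf.generate_cohort(vf.CohortSpec(n_eyes=8, seed=82))
    return tr, clin, ev.stable_series_permutations(tr, clin, seed=83)


class TestStablePermutations:
    def test_times_and_source_multiset(self, setup):
        tr, clin, stable = setup
        by_id = {t.eye_id: t for t in tr}
        for s, c in zip(stable, clin):
            assert np.array_equal(s.times, c.times[:10])
            source_rows = {
                tuple(v) for t in tr for v in [t.values[i] for i in range(t.n_repeats)]
            }
            for t in s.tests:
                assert tuple(t.sensitivities) in source_rows

    def test_requires_ten_repeats(self):
        tr = vf.generate_testretest(3, 5, seed=84)
        clin = vf.generate_cohort(vf.CohortSpec(n_eyes=2, seed=85))
        with pytest.raises(ValueError, match=">= 10"):
            ev.stable_series_permutations(tr, clin)

    def test_expected_slope_is_zero(self):
        tr = vf.generate_testretest(10, 12, seed=86)
        clin = vf.generate_cohort(vf.CohortSpec(n_eyes=60, seed=87))
        stable = ev.stable_series_permutations(tr, clin, seed=88)
        slopes = [vf.plr(s).slope for s in stable]
        assert np.mean(slopes) == pytest.approx(0.0, abs=0.05)


class TestTimeToProgression:
    def _stats(self):
        rows = []
        # eye A crosses at the 4th test, eye B at the 6th, eye C never
        for eye, cross in [("A", 4), ("B", 6), ("C", None)]:
            for n in range(4, 11):
                rows.append(
                    {"eye_id": eye, "n_tests": n, "time_years": n - 1.0,
                     "score": 0.9 if cross and n >= cross else 0.1}
                )
        return pd.DataFrame(rows)

    def test_event_times_and_censoring(self):
        r = ev.time_to_progression(self._stats(), cutoffs=0.5)
        tab = r.table.set_index("eye_id")
        assert tab.loc["A", "time"] == 3.0 and tab.loc["A", "event"] == 1
        assert tab.loc["B", "time"] == 5.0 and tab.loc["B", "event"] == 1
        assert tab.loc["C", "time"] == 9.0 and tab.loc["C", "event"] == 0

    def test_km_median_matches_direct_recomputation(self):
        from lifelines import KaplanMeierFitter

        r = ev.time_to_progression(self._stats(), cutoffs=0.5)
        kmf = KaplanMeierFitter().fit(r.table["time"], r.table["event"])
        assert r.km_median == float(kmf.median_survival_time_)
        assert r.km_median == 5.0  # S drops to 1/3 at the second event

    def test_per_truncation_cutoffs(self):
        cutoffs = {n: (0.95 if n < 6 else 0.5) for n in range(4, 11)}
        r = ev.time_to_progression(self._stats(), cutoffs=cutoffs)
        tab = r.table.set_index("eye_id")
        # eye A's early crossing is suppressed by the stricter early cutoff
        assert tab.loc["A", "time"] == 5.0

    def test_survival_compare_smoke(self):
        rng = np.random.default_rng(91)
        t1 = rng.exponential(3, 60)
        t2 = rng.exponential(9, 60)
        mk = lambda t: ev.SurvivalResult(
            pd.DataFrame({"eye_id": [f"e{i}" for i in range(len(t))],
                          "time": t, "event": 1}),
            float(np.median(t)), (0, 0),
        )
        out = ev.survival_compare({"fast": mk(t1), "slow": mk(t2)})
        assert len(out) == 1
        assert out.iloc[0].p_holm < 0.01


class TestPredictionError:
    def test_noiseless_linear_series(self, fast_mcmc, var_model):
        """Exact linear decline: every regression method predicts the future
        perfectly; the no-change baseline misses by the accumulated decline."""
        vals = np.clip(
            np.array([np.full(54, 35 - i) for i in range(10)]), 0, 50
        )
        s = make_series(vals)
        r = ev.prediction_error(
            [s], variants=("hi_censored",), var_model=var_model,
            mcmc=fast_mcmc, truncations=[5],
        )
        tab = r.table.set_index("method")
        assert tab.loc["plr", "mae"] == pytest.approx(0.0, abs=1e-9)
        assert tab.loc["hi_censored", "mae"] < 0.3
        # no-change from mean(first two tests) = 34.5; future 30..26
        expected = np.mean([34.5 - v for v in range(30, 25, -1)])
        assert tab.loc["no_change", "mae"] == pytest.approx(expected)

    def test_mae_matches_hand_recomputation(self, grid):
        """PLR MAE on one noisy eye equals a direct recomputation with an
        independent OLS (scipy.linregress per location)."""
        rng = np.random.default_rng(95)
        lat = 28 - 0.5 * np.arange(10)[:, None] + rng.normal(0, 2, (10, 54))
        s = make_series(np.clip(np.round(lat), 0, 50))
        r = ev.prediction_error([s], variants=(), truncations=[6])
        got = r.table.set_index("method").loc["plr", "mae"]

        t = s.times
        Y = s.values[:, grid.informative].astype(float)
        errs = []
        for l in range(52):
            res = stats.linregress(t[:6], Y[:6, l])
            pred = np.clip(res.intercept + res.slope * t[6:], 0, 50)
            errs.extend(np.abs(pred - Y[6:, l]))
        assert got == pytest.approx(np.mean(errs))

    def test_short_series_skipped(self, one_eye):
        r = ev.prediction_error(
            [one_eye, one_eye.truncate(8)], variants=(), truncations=[4]
        )
        assert r.n_skipped == 1

    def test_stratified_tables_cover_methods(self, one_eye):
        r = ev.prediction_error([one_eye], variants=(), truncations=[4, 6])
        assert set(r.table.method) == {"plr", "no_change"}
        assert {"method", "change_bin", "mean_signed_error"} <= set(
            r.by_baseline_change.columns
        )


class TestUnitCounts:
    def test_per_eye_multipliers(self, grid):
        c = ev.unit_counts(10, grid)
        assert c == {"eyes": 10, "clusters": 60, "locations": 520}
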