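"""Model-core tests: likelihood, correlations, fitting, selection, CIs."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import simulate_pairs
from twinace.twin_models import (ModelFit, TwinData, VarianceComponents,
                                 compare_models, component_ci, falconer_h2,
                                 fit_all_models, fit_model, pair_correlation,
                                 select_best_model, twin_loglik)


def cohort_from_pairs(mz, dz, singles=()):
    """Wrap raw pair arrays in a TwinCohort + value series."""
    from twinace.cohort_sim import TwinCohort

    rows, values = [], {}
    for zyg, pairs in (("MZ", mz), ("DZ", dz)):
        for i, (x1, x2) in enumerate(pairs):
            fam = f"{zyg}{i:04d}"
            for j, x in enumerate((x1, x2), 1):
                sid = f"{fam}.{j}"
                rows.append((sid, fam, zyg, 50.0, "F"))
                values[sid] = x
    for i, x in enumerate(singles):
        fam = f"SG{i:04d}"
        rows.append((f"{fam}.1", fam, "singleton", 50.0, "F"))
        values[f"{fam}.1"] = x
    cohort = TwinCohort(pd.DataFrame(
        rows, columns=["subject_id", "family_id", "zygosity", "age", "sex"]))
    return cohort, pd.Series(values)


class TestPairCorrelation:
    def test_double_entry_hand_example(self):
        # pairs (1,2) and (3,4): Pearson on x=[1,2,3,4], y=[2,1,4,3] is 0.6
        cohort, vals = cohort_from_pairs([(1.0, 2.0), (3.0, 4.0)], [])
        assert pair_correlation(vals, cohort, "MZ", min_pairs=2) \
            == pytest.approx(0.6)

    def test_identical_cotwins_give_unit_correlation(self):
        cohort, vals = cohort_from_pairs([(1, 1), (2, 2), (5, 5)], [])
        assert pair_correlation(vals, cohort, "MZ") == pytest.approx(1.0)

    def test_invariant_to_member_order(self):
        rng = np.random.default_rng(0)
        pairs = rng.standard_normal((20, 2))
        c1, v1 = cohort_from_pairs(pairs, [])
        c2, v2 = cohort_from_pairs(pairs[:, ::-1], [])
        assert pair_correlation(v1, c1, "MZ") \
            == pytest.approx(pair_correlation(v2, c2, "MZ"))

    def test_too_few_pairs_undefined(self):
        cohort, vals = cohort_from_pairs([(1, 2), (3, 4)], [])
        assert math.isnan(pair_correlation(vals, cohort, "MZ"))

    def test_incomplete_pair_dropped_from_correlation(self):
        cohort, vals = cohort_from_pairs(
            [(1, 2), (3, 4), (5, 6), (7, 8)], [])
        vals.loc["MZ0003.2"] = np.nan
        r_with = pair_correlation(vals, cohort, "MZ")
        c3, v3 = cohort_from_pairs([(1, 2), (3, 4), (5, 6)], [])
        assert r_with == pytest.approx(pair_correlation(v3, c3, "MZ"))


class TestFalconer:
    @pytest.mark.parametrize("r_mz,r_dz,expected", [
        (0.61, 0.35, 0.52),   # the cohort-mean correlations
        (0.5, 0.5, 0.0),
        (0.3, 0.4, -0.2),
    ])
    def test_formula(self, r_mz, r_dz, expected):
        est = falconer_h2(r_mz, r_dz)
        assert est.h2 == pytest.approx(expected)

    def test_clipped_companion(self):
        est = falconer_h2(0.3, 0.4)
        assert est.h2 == pytest.approx(-0.2)
        assert est.h2_clipped == 0.0
        assert falconer_h2(0.9, 0.2).h2_clipped == 1.0


class TestTwinLoglik:
    def test_independent_standard_normal_at_mode(self):
        ll = twin_loglik({"mean": 0.0, "a": 0.0, "c": 0.0, "e": 1.0},
                         [(0.0, 0.0)], np.empty((0, 2)))
        assert ll == pytest.approx(-math.log(2 * math.pi), abs=1e-12)

    def test_member_exchange_symmetry(self):
        rng = np.random.default_rng(1)
        mz, dz = rng.standard_normal((5, 2)), rng.standard_normal((4, 2))
        params = {"mean": 0.3, "a": 0.7, "c": 0.4, "e": 0.5}
        assert twin_loglik(params, mz, dz) \
            == pytest.approx(twin_loglik(params, mz[:, ::-1], dz[:, ::-1]),
                             abs=1e-12)

    def test_matches_multivariate_normal_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a, c, e = rng.uniform(0.05, 1.5, 3)
            mu = rng.normal()
            mz = rng.normal(size=(3, 2))
            dz = rng.normal(size=(4, 2))
            sg = rng.normal(size=2)
            ll = twin_loglik({"mean": mu, "a": a, "c": c, "e": e}, mz, dz, sg)
            v = a * a + c * c + e * e
            ref = 0.0
            for pairs, s in ((mz, a * a + c * c), (dz, 0.5 * a * a + c * c)):
                mvn = stats.multivariate_normal([mu, mu], [[v, s], [s, v]])
                ref += mvn.logpdf(pairs).sum()
            ref += stats.norm(mu, math.sqrt(v)).logpdf(sg).sum()
            assert ll == pytest.approx(ref, abs=1e-9)

    def test_degenerate_covariance_rejected(self):
        ll = twin_loglik({"mean": 0.0, "a": 1.0, "c": 0.0, "e": 0.0},
                         [(0.0, 1.0)], np.empty((0, 2)))
        assert ll == -math.inf


class TestFitModel:
    def test_e_only_fit_is_sample_variance_mle(self):
        rng = np.random.default_rng(3)
        data = simulate_pairs(rng, 50, 50, 0.3, 0.2, n_singles=5)
        fit = fit_model(data, "E")
        x = data.all_values()
        assert fit.mean == pytest.approx(x.mean())
        assert fit.components.total_variance \
            == pytest.approx(np.var(x))  # MLE, ddof=0
        assert (fit.components.a2, fit.components.c2, fit.components.e2) \
            == (0.0, 0.0, 1.0)

    def test_recovery_under_ae_truth(self):
        rng = np.random.default_rng(4)
        data = simulate_pairs(rng, 5000, 5000, 0.8, 0.0)
        fit = fit_model(data, "ACE")
        assert fit.converged
        assert fit.components.a2 == pytest.approx(0.8, abs=0.03)
        assert fit.components.c2 == pytest.approx(0.0, abs=0.03)
        assert fit.components.e2 == pytest.approx(0.2, abs=0.03)

    def test_aic_consistent_with_loglik(self):
        rng = np.random.default_rng(5)
        data = simulate_pairs(rng, 100, 100, 0.5, 0.2)
        for label, k in (("ACE", 4), ("AE", 3), ("CE", 3), ("E", 2)):
            fit = fit_model(data, label)
            assert fit.k == k
            assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k,
                                            abs=1e-10)

    def test_too_few_pairs_rejected(self):
        rng = np.random.default_rng(6)
        data = simulate_pairs(rng, 3, 3, 0.5, 0.2)
        with pytest.raises(ValueError, match="pairs"):
            fit_model(data, "ACE")

    def test_nesting_inequality(self):
        rng = np.random.default_rng(7)
        for seed in range(5):
            data = simulate_pairs(np.random.default_rng(seed), 60, 120,
                                  rng.uniform(0, 0.6), rng.uniform(0, 0.3))
            fits = fit_all_models(data)
            assert fits["ACE"].loglik >= fits["AE"].loglik - 1e-6
            assert fits["ACE"].loglik >= fits["CE"].loglik - 1e-6
            assert fits["AE"].loglik >= fits["E"].loglik - 1e-6
            assert fits["CE"].loglik >= fits["E"].loglik - 1e-6

    def test_half_missing_pairs_enter_as_marginals(self):
        rng = np.random.default_rng(8)
        cohort, vals = cohort_from_pairs(rng.standard_normal((30, 2)),
                                         rng.standard_normal((30, 2)))
        vals.loc["MZ0000.2"] = np.nan
        data = TwinData.from_trait(vals, cohort)
        assert len(data.mz) == 29
        assert len(data.singles) == 1


class TestCompareSelect:
    def _fit(self, label, loglik, k):
        comp = VarianceComponents(0.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0)
        return ModelFit(label, comp, 0.0, loglik, k,
                        -2 * loglik + 2 * k, True)

    def test_equal_logliks_give_p_one(self):
        cmp_ = compare_models(self._fit("ACE", -10.0, 4),
                              self._fit("AE", -10.0, 3))
        assert cmp_.lrt_stat == 0.0 and cmp_.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("stat,df", [(3.841, 1), (5.991, 2)])
    def test_chi2_quantiles(self, stat, df):
        full = self._fit("ACE", 0.0, 4)
        nested = self._fit("AE" if df == 1 else "E", -stat / 2, 4 - df)
        cmp_ = compare_models(full, nested)
        assert cmp_.df == df
        assert cmp_.p_value == pytest.approx(0.05, abs=5e-4)

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            compare_models(self._fit("AE", 0.0, 3), self._fit("CE", -1.0, 3))

    def test_lowest_aic_wins(self):
        fits = {"ACE": self._fit("ACE", -47.0, 4),   # AIC 102
                "AE": self._fit("AE", -47.0, 3),     # AIC 100
                "CE": self._fit("CE", -51.0, 3),     # AIC 108
                "E": self._fit("E", -68.0, 2)}       # AIC 140
        best, record = select_best_model(fits)
        assert best == "AE"
        assert record["aic"]["AE"] == pytest.approx(100.0)

    def test_tie_broken_by_label_order(self):
        fits = {"AE": self._fit("AE", -47.0, 3),
                "CE": self._fit("CE", -47.0, 3),
                "E": self._fit("E", -60.0, 2)}
        best, _ = select_best_model(fits)
        assert best == "CE"  # E < CE < AE < ACE

    def test_unconverged_fits_excluded(self):
        bad = ModelFit("ACE", VarianceComponents(0, 0, 1.0, 1.0, 0, 0, 1.0),
                       0.0, 0.0, 4, 8.0, False)
        best, _ = select_best_model({"ACE": bad, "E": self._fit("E", -1, 2)})
        assert best == "E"
        with pytest.raises(ValueError, match="converged"):
            select_best_model({"ACE": bad})


class TestComponentCI:
    def test_e2_interval_excludes_zero(self):
        rng = np.random.default_rng(9)
        data = simulate_pairs(rng, 75, 170, 0.6, 0.2)
        fits = fit_all_models(data)
        ci = component_ci(fits["ACE"], data)
        assert ci["e2"][0] > 0.0
        for comp in ("a2", "c2", "e2"):
            lo, hi = ci[comp]
            assert 0.0 <= lo <= hi <= 1.0

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(10)
        data = simulate_pairs(rng, 100, 200, 0.5, 0.1)
        fit = fit_model(data, "AE")
        ci = component_ci(fit, data)
        assert ci["a2"][0] <= fit.components.a2 <= ci["a2"][1]
        assert ci["c2"] == (0.0, 0.0)

    def test_width_shrinks_with_pair_count(self):
        widths = []
        for n in (100, 400, 1600):
            data = simulate_pairs(np.random.default_rng(11), n, n, 0.6, 0.0)
            fit = fit_model(data, "AE")
            lo, hi = component_ci(fit, data)["a2"]
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_e_model_degenerate_intervals(self):
        rng = np.random.default_rng(12)
        data = simulate_pairs(rng, 50, 50, 0.0, 0.0)
        fit = fit_model(data, "E")
        ci = component_ci(fit, data)
        assert ci == {"a2": (0.0, 0.0), "c2": (0.0, 0.0), "e2": (1.0, 1.0)}


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_label_invariance_of_estimates(seed):
    """Permuting within-pair member order changes no ML estimate."""
    rng = np.random.default_rng(seed)
    data = simulate_pairs(rng, 30, 40, 0.5, 0.2)
    flipped = TwinData(data.mz[:, ::-1], data.dz[:, ::-1], data.singles)
    f1 = fit_model(data, "ACE")
    f2 = fit_model(flipped, "ACE")
    assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)
    assert f1.components.a2 == pytest.approx(f2.components.a2, abs=1e-5)
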