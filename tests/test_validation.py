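"""Validation battery: KS machinery, coherence, Cox shift, log-rank, battery."""

import numpy as np
import pandas as pd
import pytest

from assocmod import (
    ValidationConfig,
    coherence_test,
    cox_shift_test,
    default_spec,
    km_logrank_on_aggregate,
    ks_compare,
    simulate_validation_cohorts,
    validate_module,
)
from assocmod.cox import cox_per_gene
from assocmod.discovery import AssociationModule
from assocmod.stats import ks_p_against_background
from assocmod.validation import prepare_validation_cohort


def brute_force_ks(a, b):
    """Sup distances scanned over all pooled points (independent oracle)."""
    pooled = np.concatenate([a, b])
    fa = np.searchsorted(np.sort(a), pooled, side="right") / a.size
    fb = np.searchsorted(np.sort(b), pooled, side="right") / b.size
    # include left limits by also scanning just below each point
    eps = 1e-9
    fa_l = np.searchsorted(np.sort(a), pooled - eps, side="right") / a.size
    fb_l = np.searchsorted(np.sort(b), pooled - eps, side="right") / b.size
    d_two = max(np.max(np.abs(fb - fa)), np.max(np.abs(fb_l - fa_l)))
    d_plus = max(np.max(fb - fa), np.max(fb_l - fa_l), 0.0)
    return d_two, d_plus


class TestKSCompare:
    def test_sample_against_itself(self, rng):
        a = rng.normal(size=25)
        d, p = ks_compare(a, a, side="two_sided")
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, p = ks_compare([0, 0, 0, 0], [1, 1, 1, 1], side="two_sided")
        assert d == 1.0

    def test_matches_brute_force_scan(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(5, 40))
            b = rng.normal(0.4, 1.3, rng.integers(5, 60))
            d2, _ = ks_compare(a, b, side="two_sided")
            dg, _ = ks_compare(a, b, side="greater")
            ref2, refg = brute_force_ks(a, b)
            assert d2 == pytest.approx(ref2, abs=1e-12)
            assert dg == pytest.approx(refg, abs=1e-12)

    def test_matches_scipy_statistic(self, rng):
        from scipy.stats import ks_2samp

        a, b = rng.normal(size=30), rng.normal(0.5, 1, 100)
        d, _ = ks_compare(a, b, side="two_sided")
        assert d == pytest.approx(ks_2samp(a, b).statistic, abs=1e-12)

    def test_one_sided_direction(self, rng):
        bg = rng.normal(size=400)
        shifted = rng.normal(size=40) + 1.0
        _, p_up = ks_compare(shifted, bg, side="greater")
        _, p_down = ks_compare(shifted - 2.0, bg, side="greater")
        assert p_up < 0.01 and p_down > 0.5

    def test_background_helper_consistent(self, rng):
        a, b = rng.normal(size=20), np.sort(rng.normal(size=300))
        _, p = ks_compare(a, b, side="greater")
        assert ks_p_against_background(a, b, "greater") == pytest.approx(p, abs=1e-15)


def _coherent_expr(rng, n_genes=600, n_samples=100, module_size=30, r=0.6):
    """Expression with one planted correlated block at pairwise r."""
    load = np.sqrt(r)
    factor = rng.normal(size=n_samples)
    expr = rng.normal(size=(n_genes, n_samples))
    noise_sd = np.sqrt(1 - load**2)
    expr[:module_size] = load * factor + noise_sd * rng.normal(size=(module_size, n_samples))
    idx = [f"g{i}" for i in range(n_genes)]
    from assocmod.preprocess import ecdf_normalize

    return ecdf_normalize(pd.DataFrame(expr, index=idx)), idx[:module_size]


class TestCoherence:
    def test_planted_coherent_module_significant(self, rng):
        expr, members = _coherent_expr(rng)
        module = AssociationModule("M1", "cis_cnv", ["e"], members)
        res = coherence_test(module, expr, n_background=300, n_adjust=200, seed=0)
        assert res.evaluable and res.adjusted_p < 0.05 and res.passed

    def test_random_module_usually_not_significant(self, rng):
        expr, _ = _coherent_expr(rng, module_size=0)
        rejections = 0
        for s in range(20):
            members = list(np.random.default_rng(s).choice(expr.index, 30, replace=False))
            module = AssociationModule("R", "cis_cnv", ["e"], members)
            res = coherence_test(module, expr, n_background=300, n_adjust=100, seed=s)
            rejections += res.passed
        assert rejections <= 4

    def test_small_and_large_modules_both_evaluable(self, rng):
        expr, members = _coherent_expr(rng, module_size=40, r=0.3)
        big = AssociationModule("B", "cis_cnv", ["e"], members)
        small = AssociationModule("S", "cis_cnv", ["e"], members[:2])
        for module in (big, small):
            res = coherence_test(module, expr, n_background=200, n_adjust=50, seed=1)
            assert res.evaluable

    def test_unmappable_module_fails_closed(self, rng):
        expr, _ = _coherent_expr(rng, module_size=0, n_genes=100)
        module = AssociationModule("X", "cis_cnv", ["e"], ["absent1", "absent2"])
        res = coherence_test(module, expr, n_background=50, n_adjust=10, seed=0)
        assert not res.evaluable and not res.passed


class TestCoxShift:
    def test_shifted_coefficients_detected(self, rng):
        bg = pd.Series(rng.normal(size=2000), index=[f"g{i}" for i in range(2000)])
        members = [f"g{i}" for i in range(30)]
        bg.loc[members] += 1.0
        module = AssociationModule("M", "cis_cnv", ["e"], members)
        _, _, adj, ok, passed = cox_shift_test(module, bg, n_adjust=200, seed=0)
        assert ok and adj < 0.05 and passed

    def test_negative_shift_gives_large_p(self, rng):
        bg = pd.Series(rng.normal(size=2000), index=[f"g{i}" for i in range(2000)])
        members = [f"g{i}" for i in range(30)]
        bg.loc[members] -= 1.5
        module = AssociationModule("M", "cis_cnv", ["e"], members)
        _, raw, adj, ok, passed = cox_shift_test(module, bg, n_adjust=200, seed=0)
        assert ok and raw > 0.5 and not passed

    def test_all_missing_fails_closed(self):
        bg = pd.Series(np.nan, index=[f"g{i}" for i in range(50)])
        module = AssociationModule("M", "cis_cnv", ["e"], ["g1", "g2"])
        _, _, _, ok, passed = cox_shift_test(module, bg, n_adjust=10, seed=0)
        assert not ok and not passed


class TestLogRank:
    def _cohort(self, rng, hr=1.0, n_per_arm=100):
        factor = np.repeat([1.0, 0.0], n_per_arm)
        rates = 0.1 * hr**factor
        t = rng.exponential(1.0 / rates)
        e = np.ones(t.size, dtype=bool)
        expr = pd.DataFrame(
            np.vstack([factor + 0.01 * rng.normal(size=t.size) for _ in range(5)]),
            index=[f"g{i}" for i in range(5)],
            columns=[f"S{i}" for i in range(t.size)],
        )
        clin = pd.DataFrame(
            {"sample_id": expr.columns, "time": t, "event": e}
        ).set_index("sample_id")
        return expr, clin

    def test_identical_groups_statistic_zero_p_one(self):
        t = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        e = np.array([1, 1, 0, 1] * 2, dtype=bool)
        expr = pd.DataFrame(
            [np.repeat([1.0, 0.0], 4)], index=["g0"], columns=[f"S{i}" for i in range(8)]
        )
        clin = pd.DataFrame({"sample_id": expr.columns, "time": t, "event": e}).set_index("sample_id")
        module = AssociationModule("M", "cis_cnv", ["e"], ["g0"])
        out = km_logrank_on_aggregate(module, expr, clin, split_reference="biomarker_mean")
        assert out["logrank_stat"] == pytest.approx(0.0, abs=1e-12)
        assert out["logrank_p"] == 1.0

    def test_planted_hazard_ratio_detected(self, rng):
        expr, clin = self._cohort(rng, hr=2.5)
        module = AssociationModule("M", "cis_cnv", ["e"], [f"g{i}" for i in range(5)])
        out = km_logrank_on_aggregate(module, expr, clin, split_reference="biomarker_mean")
        assert out["passed"] and out["logrank_p"] < 0.05

    def test_invariant_under_monotone_time_transform(self, rng):
        expr, clin = self._cohort(rng, hr=2.0, n_per_arm=40)
        module = AssociationModule("M", "cis_cnv", ["e"], [f"g{i}" for i in range(5)])
        p1 = km_logrank_on_aggregate(module, expr, clin, split_reference="biomarker_mean")["logrank_p"]
        clin2 = clin.assign(time=np.exp(clin["time"] / clin["time"].max()))
        p2 = km_logrank_on_aggregate(module, expr, clin2, split_reference="biomarker_mean")["logrank_p"]
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_one_sided_split_fails_closed(self, rng):
        expr, clin = self._cohort(rng, hr=1.0, n_per_arm=10)
        module = AssociationModule("M", "cis_cnv", ["e"], [f"g{i}" for i in range(5)])
        out = km_logrank_on_aggregate(module, expr + 100.0, clin, split_reference="global_mean")
        # every aggregate is above/below the global mean in a shifted matrix
        assert not out["evaluable"] or (out["n_high"] > 0 and out["n_low"] > 0)

    def test_global_mean_split_near_half_on_cdf_matrix(self, null_cohort_prepared):
        _, expr, clin = null_cohort_prepared
        assert expr.to_numpy().mean() == pytest.approx(0.5, abs=1e-6)
        module = AssociationModule("M", "cis_cnv", ["e"], list(expr.index[:25]))
        out = km_logrank_on_aggregate(module, expr, clin, split_reference="global_mean")
        assert out["evaluable"]
        n = expr.shape[1]
        assert abs(out["n_high"] - n / 2) < n / 4


class TestBattery:
    def test_subpopulation_specific_effect(self, validation_default):
        cohorts, truth = validation_default
        tm = truth.modules[0]
        module = AssociationModule("T1", "cis_cnv", tm["effectors"], tm["targets"])
        cfg = ValidationConfig(n_background=500, n_adjust=200, seed=1)
        res = validate_module(module, cohorts, cfg)
        eff = res.coherence["EastAsian-female"]
        assert eff.passed and res.prognostic["EastAsian-female"].pass_logrank
        assert res.prognostic["EastAsian-female"].pass_cox
        # no survival effect planted in the male cohort: battery must not pass there
        assert not (
            res.prognostic["EastAsian-male"].pass_cox
            and res.prognostic["EastAsian-male"].pass_logrank
        )
        assert not res.overall_pass  # required cohorts default to all

    def test_overall_pass_with_required_cohort_restriction(self, validation_default):
        cohorts, truth = validation_default
        tm = truth.modules[0]
        module = AssociationModule("T1", "cis_cnv", tm["effectors"], tm["targets"])
        cfg = ValidationConfig(
            n_background=500, n_adjust=200, seed=1, required_cohorts=["EastAsian-female"]
        )
        res = validate_module(module, cohorts, cfg)
        assert res.overall_pass

    def test_report_rows_round_trip(self, validation_default, tmp_path):
        from assocmod.io import read_validation_report, write_validation_report

        cohorts, truth = validation_default
        tm = truth.modules[0]
        module = AssociationModule("T1", "cis_cnv", tm["effectors"], tm["targets"][:10])
        cfg = ValidationConfig(n_background=300, n_adjust=50, seed=0)
        res = validate_module(module, cohorts, cfg)
        path = tmp_path / "report.tsv"
        write_validation_report([res], path)
        back = read_validation_report(path)
        assert len(back) == len(cohorts)
        row = back.set_index("cohort").loc["EastAsian-female"]
        assert row["coherence_adjusted_p"] == pytest.approx(
            res.coherence["EastAsian-female"].adjusted_p, abs=1e-12
        )
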