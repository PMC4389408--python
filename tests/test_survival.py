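import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tnbcsub.simulate import CohortSpec, generate_tnbc_cohort, simulate_cox_cohort
from tnbcsub.survival import (
    bh_adjust,
    cox_univariate,
    fisher_exact_rxc,
    group_compare,
    kaplan_meier,
    logrank_test,
    validate_records,
)


def records(times, events):
    return pd.DataFrame({"time": times, "event": events})


class TestKaplanMeier:
    def test_no_events_survival_constant_one(self):
        out = kaplan_meier(records([1.0, 2.0, 3.0], [0, 0, 0]))
        assert (out["all"]["survival"] == 1.0).all()

    def test_hand_computed_product_limit(self):
        # events at t=1 and t=2, censoring at t=1.5:
        # S(1) = 2/3; at t=2 one at risk, one event -> S(2) = 2/3 * 0 ... the
        # classic three-subject worked example instead uses S(2)=1/3 with the
        # censored subject still at risk at t=2? No: censored at 1.5 leaves 1
        # at risk at t=2, so S(2) = 2/3 * (1 - 1/1) = 0.  Use censor at 2.5:
        out = kaplan_meier(records([1.0, 2.5, 2.0], [1, 0, 1]))["all"]
        curve = dict(zip(out["time"], out["survival"]))
        assert curve[1.0] == pytest.approx(2 / 3)
        assert curve[2.0] == pytest.approx(2 / 3 * 1 / 2)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(5, size=50).round(2) + 0.01
        out = kaplan_meier(records(t, np.ones(50, dtype=int)))["all"]
        for time, surv in zip(out["time"], out["survival"]):
            assert surv == pytest.approx((t > time).mean(), abs=1e-12)

    def test_curve_monotone_in_unit_interval(self, rng):
        t = rng.exponential(3, size=40) + 0.01
        ev = rng.integers(0, 2, size=40)
        out = kaplan_meier(records(t, ev))["all"]
        s = out["survival"].to_numpy()
        assert (np.diff(s) <= 1e-12).all()
        assert ((s >= 0) & (s <= 1)).all()

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            validate_records(records([0.0, 1.0], [1, 1]))


class TestLogrank:
    def test_identical_groups_null(self):
        rec = records([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], [1, 1, 0, 1, 1, 0])
        out = logrank_test(rec, ["a", "a", "a", "b", "b", "b"])
        assert out["statistic"] == pytest.approx(0.0, abs=1e-9)
        assert out["p_value"] == pytest.approx(1.0, abs=1e-9)

    def test_all_censored(self):
        out = logrank_test(records([1.0, 2.0], [0, 0]), ["a", "b"])
        assert out == {"statistic": 0.0, "df": 1, "p_value": 1.0}

    def test_six_subject_observed_expected_oracle(self):
        # distinct event times, no censoring: chi-square from the O-E table
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1] * 6
        groups = ["a", "b", "a", "b", "a", "b"]
        out = logrank_test(records(times, events), groups)
        # hand computation of the logrank statistic
        o_a = e_a = v = 0.0
        at_risk = list(zip(times, groups))
        for t, g in sorted(at_risk):
            risk = [(tt, gg) for tt, gg in at_risk if tt >= t]
            n = len(risk)
            n_a = sum(1 for _, gg in risk if gg == "a")
            o_a += 1.0 if g == "a" else 0.0
            e_a += n_a / n
            v += (n_a / n) * (1 - n_a / n)
        chi2 = (o_a - e_a) ** 2 / v
        assert out["statistic"] == pytest.approx(chi2, rel=1e-6)
        assert out["p_value"] == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-6)

    def test_symmetric_under_label_swap(self, rng):
        t = rng.exponential(5, size=30) + 0.01
        ev = rng.integers(0, 2, size=30)
        g = np.array(["a"] * 15 + ["b"] * 15)
        out1 = logrank_test(records(t, ev), g)
        out2 = logrank_test(records(t, ev), np.where(g == "a", "b", "a"))
        assert out1["statistic"] == pytest.approx(out2["statistic"])

    def test_power_at_planted_cluster_hazards(self):
        hits = 0
        for seed in range(10):
            cohort = generate_tnbc_cohort(CohortSpec(seed=300 + seed))
            rec = cohort.clinical.rename(
                columns={"efs_time": "time", "efs_event": "event"}
            )[["time", "event"]]
            out = logrank_test(rec, cohort.truth)
            hits += out["p_value"] < 0.05
        assert hits >= 8


class TestCox:
    def test_constant_covariate_rejected(self):
        rec = records([1.0, 2.0, 3.0], [1, 1, 0])
        with pytest.raises(ValueError, match="vary"):
            cox_univariate(rec, [1.0, 1.0, 1.0])

    def test_null_covariate_hr_near_one(self):
        inside = 0
        for seed in range(5):
            rec, x = simulate_cox_cohort(150, 0.0, seed=seed)
            fit = cox_univariate(rec, x)
            inside += fit.ci95[0] <= 1.0 <= fit.ci95[1]
        assert inside >= 4

    def test_log_hr_recovery(self):
        errors = []
        for seed in range(20):
            rec, x = simulate_cox_cohort(200, -0.5, seed=seed)
            fit = cox_univariate(rec, x, scale="per_sd")
            errors.append(fit.log_hr - (-0.5))
        assert abs(np.mean(errors)) <= 0.15

    def test_negated_covariate_reciprocal_hr(self):
        rec, x = simulate_cox_cohort(100, -0.4, seed=1)
        f1 = cox_univariate(rec, x, scale="per_unit")
        f2 = cox_univariate(rec, -x, scale="per_unit")
        assert f2.hazard_ratio == pytest.approx(1 / f1.hazard_ratio, rel=1e-6)

    def test_ci_brackets_hr(self):
        rec, x = simulate_cox_cohort(100, -0.4, seed=2)
        fit = cox_univariate(rec, x)
        assert fit.ci95[0] <= fit.hazard_ratio <= fit.ci95[1]


class TestGroupCompare:
    def test_fisher_2x2_by_enumeration(self):
        # table (3,0; 0,3): hypergeometric tail enumeration gives p = 0.1
        assert group_compare([[3, 0], [0, 3]], "fisher_exact")["p_value"] == pytest.approx(0.1)
        # cross-check against summing the hypergeometric point masses
        p = sum(
            stats.hypergeom.pmf(k, 6, 3, 3)
            for k in range(4)
            if stats.hypergeom.pmf(k, 6, 3, 3)
            <= stats.hypergeom.pmf(3, 6, 3, 3) + 1e-12
        )
        assert group_compare([[3, 0], [0, 3]], "fisher_exact")["p_value"] == pytest.approx(p)

    def test_fisher_rxc_enumeration_agrees_with_2x2_special_case(self):
        table = np.array([[4, 1], [1, 4]])
        ours = fisher_exact_rxc(table)
        scipy_p = stats.fisher_exact(table).pvalue
        assert ours == pytest.approx(scipy_p, rel=1e-9)

    def test_fisher_rxc_against_r_oracle_value(self):
        # 3x2 table; reference value from the exact conditional enumeration
        table = np.array([[3, 1], [1, 3], [0, 4]])
        p = fisher_exact_rxc(table)
        # brute-force check: enumerate all tables with the same margins
        row_sums, col_sums = table.sum(1), table.sum(0)
        from math import comb

        def prob(M):
            num = 1.0
            for r in row_sums:
                num *= comb(int(r), 0) or 1
            # multivariate hypergeometric probability
            import math

            lp = (
                sum(math.lgamma(r + 1) for r in row_sums)
                + sum(math.lgamma(c + 1) for c in col_sums)
                - math.lgamma(table.sum() + 1)
                - sum(math.lgamma(v + 1) for v in M.ravel())
            )
            return math.exp(lp)

        obs_p = prob(table)
        total = 0.0
        for a, b, c in itertools.product(range(5), repeat=3):
            M = np.array([[a, row_sums[0] - a], [b, row_sums[1] - b], [c, row_sums[2] - c]])
            if (M >= 0).all() and M[:, 0].sum() == col_sums[0]:
                pm = prob(M)
                if pm <= obs_p + 1e-12:
                    total += pm
        assert p == pytest.approx(total, rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_rxc(np.array([[0, 0], [1, 2]]))

    def test_anova_tukey_detects_age_separation(self):
        # three groups at the cohort's age means and sizes
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            data = {
                "C1": rng.normal(64.6, 12, size=24),
                "C2": rng.normal(56.8, 12, size=48),
                "C3": rng.normal(51.9, 12, size=35),
            }
            out = group_compare(data, "anova_tukey")
            hits += out["p_value"] < 0.01
            assert set(len(k) for k in out["pairwise_p"]) == {2}
        assert hits >= 8

    def test_pearson_perfect_line(self):
        x = np.arange(10.0)
        out = group_compare((x, 2 * x + 1), "pearson_cor")
        assert out["r"] == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            group_compare((np.ones(5), np.arange(5.0)), "pearson_cor")


def test_bh_adjustment_monotone():
    p = np.array([0.001, 0.01, 0.02, 0.8])
    adj = bh_adjust(p)
    assert (np.diff(adj[np.argsort(p)]) >= -1e-12).all()
    assert (adj >= p - 1e-12).all()
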