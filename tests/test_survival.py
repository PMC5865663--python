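"""Kaplan-Meier, log-rank, Cox fits and the concordance index."""

import numpy as np
import pandas as pd
import pytest
from lifelines.utils import concordance_index as ll_concordance

from tp53sig import (
    SyntheticConfig,
    compare_signatures,
    concordance_index,
    cox_fit,
    generate_cohort,
    km_estimate,
    logrank_test,
)


def outcomes_frame(times, events, samples=None):
    idx = samples or [f"P{i}" for i in range(len(times))]
    df = pd.DataFrame({"time": times, "event": events}, index=idx)
    df.index.name = "sample_id"
    return df


def km_oracle(times, events):
    """Hand product-limit estimate at each distinct event time."""
    times, events = np.asarray(times, float), np.asarray(events, int)
    surv, s = {}, 1.0
    for t in np.unique(times[events == 1]):
        at_risk = (times >= t).sum()
        deaths = ((times == t) & (events == 1)).sum()
        s *= 1 - deaths / at_risk
        surv[t] = s
    return surv


def cindex_oracle(risk, times, events):
    """Plain O(n^2) Harrell pair enumeration."""
    usable = concordant = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                usable += 1
                if risk[i] > risk[j]:
                    concordant += 1
                elif risk[i] == risk[j]:
                    concordant += 0.5
    if usable == 0:
        return float("nan"), 0
    return concordant / usable, int(usable)


class TestKaplanMeier:
    def test_hand_product_limit_example(self):
        curves = km_estimate(outcomes_frame([1, 2, 3], [1, 0, 1]), ["all"] * 3)
        c = curves["all"].set_index("time")["survival"]
        assert c.loc[1.0] == pytest.approx(2 / 3)
        assert c.loc[3.0] == pytest.approx(0.0)

    def test_no_censoring_is_empirical_survival(self):
        times = [3.0, 1.0, 4.0, 1.0, 5.0]
        curves = km_estimate(outcomes_frame(times, [1] * 5), ["g"] * 5)
        c = curves["g"].set_index("time")["survival"]
        for t in sorted(set(times)):
            assert c.loc[t] == pytest.approx(np.mean(np.array(times) > t))

    def test_all_censored_is_constant_one(self):
        curves = km_estimate(outcomes_frame([2, 4, 6], [0, 0, 0]), ["g"] * 3)
        assert (curves["g"]["survival"] == 1.0).all()

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 30))
            times = rng.integers(1, 10, size=n).astype(float)
            events = rng.integers(0, 2, size=n)
            if events.sum() == 0:
                continue
            curves = km_estimate(outcomes_frame(times, events), ["g"] * n)
            c = curves["g"].set_index("time")["survival"]
            for t, s in km_oracle(times, events).items():
                assert c.loc[t] == pytest.approx(s, rel=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(outcomes_frame([], []), [])


class TestLogrank:
    def test_identical_groups_are_null(self):
        out = outcomes_frame([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0])
        stat, p = logrank_test(out, ["a"] * 3 + ["b"] * 3)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_strong_separation_detected(self, sig):
        cohort = generate_cohort(
            SyntheticConfig(seed=21, n_mutant=200, n_wildtype=200, hazard_ratio=5.0), sig
        )
        _, p = logrank_test(cohort.outcomes, cohort.true_status)
        assert p < 0.001

    def test_needs_exactly_two_groups(self):
        out = outcomes_frame([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError, match="two groups"):
            logrank_test(out, ["a", "b", "c"])


class TestCox:
    def test_null_covariate_recovers_unit_hazard(self, rng):
        n = 2000
        times = rng.exponential(20, size=n)
        out = outcomes_frame(np.minimum(times, 30), (times <= 30).astype(int))
        cov = pd.DataFrame({"x": rng.integers(0, 2, size=n)}, index=out.index)
        (res,) = cox_fit(cov, out, "univariate")
        assert res.hazard_ratio == pytest.approx(1.0, abs=0.1)
        assert res.ci_low <= res.hazard_ratio <= res.ci_high

    def test_recovers_simulated_hazard_ratio(self, sig):
        cohort = generate_cohort(
            SyntheticConfig(seed=31, n_mutant=1000, n_wildtype=1000, hazard_ratio=4.9), sig
        )
        cov = pd.DataFrame({"mt": (cohort.true_status == "MT").astype(int)})
        (res,) = cox_fit(cov, cohort.outcomes, "univariate")
        assert res.hazard_ratio == pytest.approx(4.9, rel=0.15)

    def test_collinear_covariates_flagged(self, rng):
        n = 100
        x = rng.integers(0, 2, size=n)
        times = rng.exponential(10, size=n)
        out = outcomes_frame(times, np.ones(n, dtype=int))
        cov = pd.DataFrame({"x": x, "x_copy": x}, index=out.index)
        with pytest.raises(RuntimeError, match="Cox fit failed"):
            cox_fit(cov, out, "multivariate", multivariate_variables=["x", "x_copy"])

    def test_multivariate_entry_rule(self, sig):
        cohort = generate_cohort(SyntheticConfig(seed=41, n_mutant=300, n_wildtype=300), sig)
        cov = pd.DataFrame(
            {
                "mt": (cohort.true_status == "MT").astype(int),
                "noise": np.random.default_rng(0).normal(size=len(cohort.outcomes)),
            },
            index=cohort.outcomes.index,
        )
        multi = cox_fit(cov, cohort.outcomes, "multivariate", entry_p=0.05)
        assert [r.variable for r in multi] == ["mt"]

    def test_missing_values_rejected(self):
        out = outcomes_frame([1, 2], [1, 1])
        cov = pd.DataFrame({"x": [1.0, np.nan]}, index=out.index)
        with pytest.raises(ValueError, match="missing"):
            cox_fit(cov, out, "univariate")


class TestConcordance:
    def test_reverse_ordering_is_perfect(self):
        out = outcomes_frame([1, 2, 3, 4], [1, 1, 1, 1])
        assert concordance_index([4, 3, 2, 1], out).c_index == 1.0

    def test_times_as_risk_is_zero(self):
        out = outcomes_frame([1, 2, 3, 4], [1, 1, 1, 1])
        assert concordance_index([1, 2, 3, 4], out).c_index == 0.0

    def test_hand_enumerated_example(self):
        out = outcomes_frame([2, 4, 6], [1, 1, 0])
        res = concordance_index([5, 1, 3], out)
        assert res.n_usable_pairs == 3
        assert res.c_index == pytest.approx(2 / 3)

    def test_negation_flips_index(self, rng):
        risk = rng.normal(size=30)
        times = rng.exponential(5, size=30)
        out = outcomes_frame(times, rng.integers(0, 2, size=30))
        a = concordance_index(risk, out).c_index
        b = concordance_index(-risk, out).c_index
        assert a + b == pytest.approx(1.0)

    def test_matches_bruteforce_and_lifelines(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 60))
            risk = np.round(rng.normal(size=n), 1)  # induces risk ties
            times = rng.exponential(10, size=n)  # continuous: no time ties
            events = rng.integers(0, 2, size=n)
            if events.sum() == 0:
                continue
            out = outcomes_frame(times, events)
            res = concordance_index(risk, out)
            c_oracle, n_oracle = cindex_oracle(risk, times, events)
            assert res.c_index == pytest.approx(c_oracle, abs=1e-12)
            assert res.n_usable_pairs == n_oracle
            # lifelines scores predicted survival (low risk = long survival)
            assert res.c_index == pytest.approx(ll_concordance(times, -risk, events), abs=1e-12)

    def test_no_usable_pairs_rejected(self):
        out = outcomes_frame([5, 5], [1, 1])
        with pytest.raises(ValueError, match="usable"):
            concordance_index([1, 2], out)


class TestCompareSignatures:
    def test_columns_scored_on_identical_samples(self, rng):
        n = 50
        times = rng.exponential(10, size=n)
        out = outcomes_frame(times, np.ones(n, dtype=int))
        risk = pd.DataFrame(
            {"good": -times + rng.normal(0, 1, n), "noise": rng.normal(size=n)}, index=out.index
        )
        res = {r.name: r for r in compare_signatures(risk, out)}
        assert res["good"].c_index > 0.8
        assert res["good"].n_usable_pairs == res["noise"].n_usable_pairs

    def test_missing_column_values_rejected(self):
        out = outcomes_frame([1, 2], [1, 1])
        risk = pd.DataFrame({"a": [1.0, np.nan]}, index=out.index)
        with pytest.raises(ValueError, match="missing"):
            compare_signatures(risk, out)
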