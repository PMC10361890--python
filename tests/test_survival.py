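"""Survival statistics against hand-computed and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from lauren_mil.survival import (
    BEST,
    INTERMEDIATE,
    WORST,
    SurvivalRecord,
    agreement_stratify,
    cox_fit,
    km_estimate,
    logrank_pairwise,
    logrank_test,
    truncate_endpoint,
    truncate_frame,
)
from lauren_mil.synthetic import DIFFUSE, INTESTINAL


def logrank_oracle(times_a, events_a, times_b, events_b):
    """Hand hypergeometric computation of the two-group log-rank statistic."""
    times = np.concatenate([times_a, times_b])
    events = np.concatenate([events_a, events_b]).astype(bool)
    group_a = np.concatenate(
        [np.ones(len(times_a), bool), np.zeros(len(times_b), bool)]
    )
    O = E = V = 0.0
    for t in sorted(set(times[events])):
        at_risk = times >= t
        n, n_a = at_risk.sum(), (at_risk & group_a).sum()
        d = (events & (times == t)).sum()
        d_a = (events & (times == t) & group_a).sum()
        O += d_a
        E += d * n_a / n
        if n > 1:
            V += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def efron_partial_loglik(beta, times, events, x):
    """Efron-tie partial log-likelihood for a single covariate."""
    ll = 0.0
    risk = np.exp(beta * x)
    for t in sorted(set(times[events.astype(bool)])):
        at_risk = times >= t
        tied = events.astype(bool) & (times == t)
        d = tied.sum()
        sum_risk = risk[at_risk].sum()
        sum_tied = risk[tied].sum()
        ll += beta * x[tied].sum()
        for j in range(d):
            ll -= np.log(sum_risk - j / d * sum_tied)
    return ll


class TestTruncation:
    def test_event_after_horizon_becomes_censoring(self):
        rec = SurvivalRecord("a", "OS", 70.0, True)
        out = truncate_endpoint([rec])[0]
        assert out.time == 60.0 and out.event is False

    def test_event_before_horizon_unchanged(self):
        rec = SurvivalRecord("a", "OS", 59.0, True)
        out = truncate_endpoint([rec])[0]
        assert out.time == 59.0 and out.event is True

    def test_identity_when_all_within_horizon(self):
        recs = [SurvivalRecord(f"c{i}", "OS", t, True)
                for i, t in enumerate([5.0, 30.0, 60.0])]
        assert truncate_endpoint(recs) == recs

    def test_frame_version_matches(self):
        df = pd.DataFrame({"t": [70.0, 59.0], "e": [True, True]})
        out = truncate_frame(df, "t", "e")
        assert out["t"].tolist() == [60.0, 59.0]
        assert out["e"].tolist() == [False, True]


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        km = km_estimate([3.0, 5.0, 7.0], [False, False, False])
        assert all(s == 1.0 for s in km.survival)

    def test_two_subject_hand_example(self):
        # event at 1 with 2 at risk, censoring at 2: S(1) = 1/2
        km = km_estimate([1.0, 2.0], [True, False])
        assert km.survival_at(1.0) == pytest.approx(0.5)

    def test_four_subject_hand_product_limit(self):
        # events at 1 (4 at risk) and 2 (2 at risk): 3/4 * 1/2 = 0.375
        km = km_estimate([1.0, 1.5, 2.0, 3.0], [True, False, True, False])
        assert km.survival_at(1.0) == pytest.approx(0.75)
        assert km.survival_at(2.0) == pytest.approx(0.375)

    def test_curve_starts_at_one_and_is_nonincreasing(self, rng):
        t = rng.exponential(10, 50)
        e = rng.random(50) < 0.7
        km = km_estimate(t, e)
        assert km.survival_at(0.0) == 1.0
        assert np.all(np.diff(km.survival) <= 1e-12)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = np.round(rng.exponential(10, 40), 1)
        km = km_estimate(t, np.ones(40, bool))
        for q in (2.0, 5.0, 10.0, 20.0):
            assert km.survival_at(q) == pytest.approx((t > q).mean())


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        t, e = [1.0, 2.0, 3.0], [True, True, False]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_hypergeometric(self):
        """All of group A dies before any of group B; the statistic matches
        the observed-minus-expected sums computed by hand."""
        ta, tb = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        ea = eb = [True, True, True]
        stat, _ = logrank_test(ta, ea, tb, eb)
        oracle = logrank_oracle(np.array(ta), np.array(ea, dtype=bool),
                                np.array(tb), np.array(eb, dtype=bool))
        # hand value: O=3, E=0.5+0.4+0.25=1.15, V=0.25+0.24+0.1875
        assert oracle == pytest.approx((3 - 1.15) ** 2 / 0.6775)
        assert stat == pytest.approx(oracle, rel=1e-6)

    def test_statistic_symmetric_under_group_swap(self, rng):
        ta, tb = rng.exponential(5, 20), rng.exponential(8, 25)
        ea, eb = rng.random(20) < 0.8, rng.random(25) < 0.8
        s1, _ = logrank_test(ta, ea, tb, eb)
        s2, _ = logrank_test(tb, eb, ta, ea)
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [1.0], [True])

    def test_pairwise_covers_all_pairs(self, rng):
        groups = {
            name: (rng.exponential(5, 15), rng.random(15) < 0.8)
            for name in ("a", "b", "c")
        }
        out = logrank_pairwise(groups)
        assert set(out) == {("a", "b"), ("a", "c"), ("b", "c")}


class TestCox:
    def test_matches_grid_search_partial_likelihood_oracle(self):
        """Ten-subject fit agrees with a brute-force maximizer of the Efron
        partial likelihood to 1e-3 on the coefficient."""
        times = np.array([2.0, 3.0, 3.0, 5.0, 7.0, 8.0, 8.0, 10.0, 12.0, 15.0])
        events = np.array([1, 1, 1, 0, 1, 1, 0, 1, 0, 1])
        x = np.array([1.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 0.0, 1.0, 0.0])
        grid = np.arange(-3.0, 3.0, 1e-4)
        lls = [efron_partial_loglik(b, times, events, x) for b in grid]
        beta_oracle = grid[int(np.argmax(lls))]
        df = pd.DataFrame({"t": times, "e": events.astype(bool), "x": x})
        res = cox_fit(df, "t", "e", ["x"], ties="efron")
        assert res["x"].coef == pytest.approx(beta_oracle, abs=1e-3)

    def test_recovers_planted_hazard_ratio_two(self, rng):
        z = rng.random(2000) < 0.5
        t = rng.exponential(1.0 / (0.015 * np.where(z, 2.0, 1.0)))
        c = rng.exponential(1.0 / (0.015 * 0.3))
        df = pd.DataFrame(
            {"t": np.minimum(t, c), "e": t <= c, "z": z.astype(float)}
        )
        res = cox_fit(df, "t", "e", ["z"])
        assert 1.8 <= res["z"].hazard_ratio <= 2.2
        assert res["z"].ci_low <= res["z"].hazard_ratio <= res["z"].ci_high

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame(
            {"t": [1.0, 2.0, 3.0], "e": [True, True, False], "x": [1.0] * 3}
        )
        with pytest.raises(ValueError, match="degenerate covariate"):
            cox_fit(df, "t", "e", ["x"])

    def test_more_covariates_than_events_rejected(self):
        df = pd.DataFrame(
            {"t": [1.0, 2.0, 3.0], "e": [True, False, False],
             "x": [1.0, 0.0, 1.0], "y": [0.0, 1.0, 1.0]}
        )
        with pytest.raises(ValueError, match="events"):
            cox_fit(df, "t", "e", ["x", "y"])

    def test_breslow_close_to_efron_without_ties(self, rng):
        t = np.round(rng.exponential(10, 200), 3)  # effectively untied
        e = rng.random(200) < 0.8
        x = rng.random(200)
        df = pd.DataFrame({"t": t, "e": e, "x": x})
        a = cox_fit(df, "t", "e", ["x"], ties="efron")
        b = cox_fit(df, "t", "e", ["x"], ties="breslow")
        assert a["x"].coef == pytest.approx(b["x"].coef, abs=1e-6)


class TestAgreementStratification:
    def test_workflow_mapping(self):
        """Pathologist-intestinal -> best without consulting the model;
        unanimity on diffuse -> worst; discordance -> intermediate."""
        path = {"a": INTESTINAL, "b": DIFFUSE, "c": DIFFUSE}
        model = {"a": DIFFUSE, "b": DIFFUSE, "c": INTESTINAL}
        strata = agreement_stratify(path, model)
        assert strata == {"a": BEST, "b": WORST, "c": INTERMEDIATE}

    def test_model_label_optional_for_pathologist_intestinal(self):
        strata = agreement_stratify({"a": INTESTINAL}, {})
        assert strata == {"a": BEST}

    def test_missing_model_label_rejected(self):
        with pytest.raises(ValueError, match="missing model label"):
            agreement_stratify({"a": DIFFUSE}, {})

    def test_nonbinary_label_rejected(self):
        with pytest.raises(ValueError, match="not binary"):
            agreement_stratify({"a": "mixed"}, {"a": DIFFUSE})
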