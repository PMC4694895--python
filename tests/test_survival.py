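"""Kaplan-Meier, the GBW weighted log-rank, stratification and the screen."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from glioscreen.survival import (SurvivalTable, bh_adjust, gbw_test, km,
                                 km_median, logistic_screen, stratify)

from conftest import make_survival


def oracle_gbw_statistic(times, events, in_a):
    """Naive, loop-based GBW statistic (weight = number at risk)."""
    u, var = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = [i for i in range(len(times)) if times[i] >= t]
        n = len(at_risk)
        n1 = sum(1 for i in at_risk if in_a[i])
        deaths = [i for i in range(len(times))
                  if times[i] == t and events[i] == 1]
        d = len(deaths)
        d1 = sum(1 for i in deaths if in_a[i])
        u += n * (d1 - d * n1 / n)
        if n > 1:
            var += n * n * d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return 0.0 if var == 0 else u * u / var


def oracle_gbw_permutation_p(a_tab, b_tab):
    ta, ea = a_tab.times_events()
    tb, eb = b_tab.times_events()
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    n, n_a = len(times), len(ta)
    observed = oracle_gbw_statistic(times, events,
                                    [i < n_a for i in range(n)])
    hits = total = 0
    for idx in combinations(range(n), n_a):
        member = [i in set(idx) for i in range(n)]
        total += 1
        if oracle_gbw_statistic(times, events, member) >= observed - 1e-9:
            hits += 1
    return hits / total


class TestKaplanMeier:
    def test_median_of_uncensored_one_to_five(self):
        tab = make_survival([1, 2, 3, 4, 5], [1] * 5)
        assert km_median(km(tab)) == 3.0

    def test_no_events_has_undefined_median(self):
        curve = km(make_survival([5, 6, 7], [0, 0, 0]))
        assert curve.event_times.size == 0
        assert km_median(curve) is None

    def test_hand_computation_with_censoring(self):
        # deaths at 2 (n=5) and 5 (n=3); censored at 3 and 6
        tab = make_survival([2, 3, 5, 5, 6], [1, 0, 1, 1, 0])
        curve = km(tab)
        assert curve.event_times.tolist() == [2.0, 5.0]
        assert curve.survival == pytest.approx([4 / 5, 4 / 5 * 1 / 3])
        assert curve.at_risk.tolist() == [5, 3]

    def test_censoring_at_a_death_time_keeps_patient_at_risk(self):
        # death and censoring both at t=2: censored patient counts at risk
        tab = make_survival([2, 2, 4], [1, 0, 1])
        curve = km(tab)
        assert curve.survival[0] == pytest.approx(2 / 3)

    def test_agrees_with_lifelines_on_random_data(self, rng):
        lifelines = pytest.importorskip("lifelines")
        times = rng.exponential(100, size=40).round(1) + 1
        events = rng.integers(0, 2, size=40)
        tab = make_survival(times.tolist(), events.tolist())
        curve = km(tab)
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        for t in curve.event_times:
            assert curve.step(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]))

    def test_survival_starts_at_one_and_never_increases(self, rng):
        times = rng.exponential(50, size=30) + 1
        events = rng.integers(0, 2, size=30)
        curve = km(make_survival(times.tolist(), events.tolist()))
        assert curve.step(0.0) == 1.0
        assert (np.diff(curve.survival) <= 1e-12).all()


class TestGBW:
    def test_identical_groups_give_zero_statistic_and_p_one(self):
        a = make_survival([3, 5, 8], [1, 1, 0], patient_ids=list("abc"))
        b = make_survival([3, 5, 8], [1, 1, 0], patient_ids=list("xyz"))
        stat, p = gbw_test(a, b)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a = make_survival([2, 4, 9, 11], [1, 1, 0, 1],
                          patient_ids=[f"a{i}" for i in range(4)])
        b = make_survival([1, 3, 6], [1, 0, 1],
                          patient_ids=[f"b{i}" for i in range(3)])
        assert gbw_test(a, b) == pytest.approx(gbw_test(b, a))

    @pytest.mark.parametrize("ta,ea,tb,eb", [
        ([1, 2, 3], [1, 1, 1], [10, 11, 12], [1, 1, 1]),
        ([2, 5, 9], [1, 0, 1], [3, 4, 7, 8], [1, 1, 1, 0]),
        ([1, 1, 6, 8], [1, 1, 1, 0], [2, 9, 12, 15], [0, 1, 1, 1]),
    ])
    def test_exact_p_matches_independent_permutation_oracle(
            self, ta, ea, tb, eb):
        a = make_survival(ta, ea, patient_ids=[f"a{i}" for i in range(len(ta))])
        b = make_survival(tb, eb, patient_ids=[f"b{i}" for i in range(len(tb))])
        stat, p = gbw_test(a, b, exact=True)
        assert stat == pytest.approx(
            oracle_gbw_statistic(np.array(ta + tb), np.array(ea + eb),
                                 [i < len(ta) for i in range(len(ta + tb))]))
        assert p == pytest.approx(oracle_gbw_permutation_p(a, b))

    def test_agrees_with_lifelines_wilcoxon_weighting(self, rng):
        stats_mod = pytest.importorskip("lifelines.statistics")
        ta = rng.exponential(100, size=30) + 1
        tb = rng.exponential(60, size=25) + 1
        ea = rng.integers(0, 2, size=30)
        eb = rng.integers(0, 2, size=25)
        a = make_survival(ta.tolist(), ea.tolist(),
                          patient_ids=[f"a{i}" for i in range(30)])
        b = make_survival(tb.tolist(), eb.tolist(),
                          patient_ids=[f"b{i}" for i in range(25)])
        stat, p = gbw_test(a, b)
        ref = stats_mod.logrank_test(ta, tb, ea, eb, weightings="wilcoxon")
        assert stat == pytest.approx(ref.test_statistic, rel=1e-6)
        assert p == pytest.approx(ref.p_value, rel=1e-6)

    def test_no_events_is_an_error(self):
        a = make_survival([1, 2], [0, 0], patient_ids=["a0", "a1"])
        b = make_survival([3, 4], [0, 0], patient_ids=["b0", "b1"])
        with pytest.raises(ValueError, match="events"):
            gbw_test(a, b)


class TestStratify:
    def _table(self, rng, rows, ids, genes):
        frame = pd.DataFrame(rows, index=ids, columns=genes)
        frame.insert(0, "time_days", 100.0)
        frame.insert(1, "event", 1)
        return SurvivalTable(frame)

    def _three_level_table(self, rng, noise=0.3):
        genes = [f"G{i}" for i in range(6)]
        rows, ids = [], []
        for level, offset in (("lo", -4.0), ("mid", 0.0), ("hi", 4.0)):
            for i in range(10):
                rows.append(offset * np.linspace(0.5, 1.5, 6)
                            + rng.normal(0, noise, size=6))
                ids.append(f"{level}{i}")
        return self._table(rng, rows, ids, genes), genes

    def test_tertile_mode_recovers_well_separated_levels_exactly(self, rng):
        tab, genes = self._three_level_table(rng)
        strat = stratify(tab, genes, k=3, mode="tertile")
        assert set(strat.group("low")) == {f"lo{i}" for i in range(10)}
        assert set(strat.group("intermediate")) == \
            {f"mid{i}" for i in range(10)}
        assert set(strat.group("high")) == {f"hi{i}" for i in range(10)}

    def test_cluster_mode_recovers_distinct_expression_patterns(self, rng):
        # cluster mode compares patient profiles (Pearson), so the planted
        # groups are distinct patterns; which label each pattern receives
        # follows from its mean z-score
        genes = [f"G{i}" for i in range(6)]
        patterns = {level: rng.normal(0, 2.0, size=6)
                    for level in ("p0", "p1", "p2")}
        rows, ids = [], []
        for level in patterns:
            for i in range(10):
                rows.append(patterns[level] + rng.normal(0, 0.3, size=6))
                ids.append(f"{level}_{i}")
        tab = self._table(rng, rows, ids, genes)
        strat = stratify(tab, genes, k=3, mode="cluster")
        got = {frozenset(strat.group(lab)) for lab in strat.labels()}
        planted = {frozenset(f"{lv}_{i}" for i in range(10))
                   for lv in patterns}
        assert got == planted

    def test_high_label_goes_to_largest_mean_z(self, rng):
        tab, genes = self._three_level_table(rng)
        strat = stratify(tab, genes, k=2, mode="tertile")
        z = tab.expression(genes).apply(lambda c: (c - c.mean()) / c.std())
        high_mean = z.loc[strat.group("high")].mean().mean()
        low_mean = z.loc[strat.group("low")].mean().mean()
        assert high_mean > low_mean

    def test_constant_gene_is_an_error(self):
        tab = make_survival([1, 2, 3], [1, 1, 1], GENE=[5.0, 5.0, 5.0])
        with pytest.raises(ValueError, match="GENE"):
            stratify(tab, ["GENE"], k=2, mode="tertile")

    def test_k_exceeding_patients_is_an_error(self, rng):
        tab = make_survival([1, 2, 3], [1, 1, 1],
                            A=[1.0, 2.0, 3.0], B=[2.0, 1.0, 3.0],
                            C=[1.0, 3.0, 2.0])
        with pytest.raises(ValueError):
            stratify(tab, ["A", "B", "C"], k=4)


class TestLogisticScreen:
    def test_binary_predictor_slope_equals_log_odds_ratio(self):
        y = [0, 0, 0, 1, 1, 1, 0, 1]
        x = pd.DataFrame({"bin": [0, 0, 1, 1, 1, 0, 0, 1]})
        res = logistic_screen(y, x)
        tab = pd.crosstab(x["bin"], pd.Series(y))
        log_or = np.log(tab.loc[1, 1] * tab.loc[0, 0]
                        / (tab.loc[1, 0] * tab.loc[0, 1]))
        assert res.loc["bin", "slope"] == pytest.approx(log_or, rel=1e-4)

    def test_constant_predictor_is_uninformative(self):
        res = logistic_screen([0, 1, 0, 1], pd.DataFrame({"c": [2.0] * 4}))
        assert res.loc["c", "slope"] == 0.0
        assert res.loc["c", "p"] == 1.0

    def test_complete_separation_is_flagged_without_p(self):
        y = [0, 0, 0, 1, 1, 1]
        x = pd.DataFrame({"sep": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]})
        res = logistic_screen(y, x)
        assert bool(res.loc["sep", "separated"])
        assert np.isnan(res.loc["sep", "p"])

    def test_single_class_response_rejected(self):
        with pytest.raises(ValueError):
            logistic_screen([1, 1, 1], pd.DataFrame({"x": [1.0, 2.0, 3.0]}))


class TestBHAdjust:
    def test_step_up_hand_computation(self):
        adjusted, passed = bh_adjust([0.01, 0.02, 0.03, 0.04], q=0.10)
        assert adjusted == pytest.approx([0.04, 0.04, 0.04, 0.04])
        assert passed.all()

    def test_monotone_in_p_order_and_bounded(self, rng):
        p = rng.uniform(size=50)
        adjusted, _ = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adjusted[order]) >= -1e-12).all()
        assert (adjusted <= 1.0).all()
        assert (adjusted >= p - 1e-12).all()
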