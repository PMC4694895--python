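"""Pfaffl ratios and the fixed-reallocation randomization test."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from glioscreen.qpcr import (CqTable, call_regulation, pfaffl_ratio,
                             reallocation_test, relative_expression,
                             RelativeExpressionResult)

from conftest import make_cq


def oracle_reallocation_p(case, ctrl):
    """Exhaustive enumeration oracle for a single target with a constant
    reference at E = 2: statistic |mean(ctrl Cq) - mean(case Cq)|."""
    values = list(case) + list(ctrl)
    n, n_case = len(values), len(case)

    def stat(case_idx):
        case_vals = [values[i] for i in case_idx]
        ctrl_vals = [values[i] for i in range(n) if i not in case_idx]
        return abs(sum(ctrl_vals) / len(ctrl_vals)
                   - sum(case_vals) / len(case_vals))

    observed = stat(set(range(n_case)))
    hits = sum(1 for idx in combinations(range(n), n_case)
               if stat(set(idx)) >= observed - 1e-12)
    total = sum(1 for _ in combinations(range(n), n_case))
    return hits / total


class TestPfafflRatio:
    def test_identical_distributions_give_unity(self):
        t = make_cq({"T": ([25, 26], [25, 26])}, {"R": ([20, 20], [20, 20])})
        assert pfaffl_ratio(t, "T") == pytest.approx(1.0)

    def test_reduces_to_two_power_ddct_at_e2(self):
        # target dCq = 3, reference dCq = 0 -> 2**3
        t = make_cq({"T": ([22, 22], [25, 25])}, {"R": ([20, 20], [20, 20])})
        assert pfaffl_ratio(t, "T") == pytest.approx(8.0)

    def test_geometric_mean_over_two_references(self):
        # refs with dCq 1 and 3, target dCq 2: 2**2 / sqrt(2**1 * 2**3) = 1
        t = make_cq(
            {"T": ([23, 23], [25, 25])},
            {"R1": ([24, 24], [25, 25]), "R2": ([22, 22], [25, 25])})
        assert pfaffl_ratio(t, "T") == pytest.approx(1.0)

    def test_efficiency_correction(self):
        # E = 1.5 on the target: ratio = 1.5**3 with flat reference
        t = make_cq({"T": ([22, 22], [25, 25])}, {"R": ([20, 20], [20, 20])})
        data = t.data.copy()
        data.loc[data["gene_id"] == "T", "efficiency"] = 1.5
        t2 = CqTable(data, dict(t.groups))
        assert pfaffl_ratio(t2, "T") == pytest.approx(1.5 ** 3)

    def test_sample_shift_cancels_through_references_at_e2(self):
        t = make_cq({"T": ([22.0, 23.0], [25.0, 26.0])},
                    {"R": ([20.0, 21.5], [19.0, 20.0])})
        base = pfaffl_ratio(t, "T")
        shifted = t.data.copy()
        shifted.loc[shifted["sample_id"] == "C0", "cq"] += 2.7
        assert pfaffl_ratio(CqTable(shifted, dict(t.groups)), "T") == \
            pytest.approx(base)

    def test_replicates_average_before_group_means(self):
        rows = [("T", "C0", r, cq, 2.0, False)
                for r, cq in [(1, 21.0), (2, 23.0)]]
        rows += [("T", "N0", 1, 25.0, 2.0, False),
                 ("R", "C0", 1, 20.0, 2.0, True),
                 ("R", "N0", 1, 20.0, 2.0, True)]
        t = CqTable(pd.DataFrame(rows, columns=[
            "gene_id", "sample_id", "replicate", "cq", "efficiency",
            "is_reference"]), {"C0": "case", "N0": "control"})
        # replicate mean 22 -> dCq 3
        assert pfaffl_ratio(t, "T") == pytest.approx(8.0)

    def test_missing_reference_is_an_error(self):
        with pytest.raises(ValueError):
            make_cq({"T": ([22], [25])}, {})


class TestReallocationTest:
    def test_two_vs_two_enumeration(self):
        t = make_cq({"T": ([1.0, 2.0], [9.0, 10.0])},
                    {"R": ([20.0] * 2, [20.0] * 2)})
        assert reallocation_test(t, "T") == pytest.approx(2 / 6)
        assert oracle_reallocation_p([1, 2], [9, 10]) == pytest.approx(2 / 6)

    @pytest.mark.parametrize("case,ctrl", [
        ([20.5, 21.0, 23.0], [24.0, 25.0, 22.0]),
        ([19.0, 20.0, 21.0, 22.5], [23.0, 24.0, 21.5, 25.0]),
    ])
    def test_matches_enumeration_oracle(self, case, ctrl):
        t = make_cq({"T": (case, ctrl)},
                    {"R": ([20.0] * len(case), [20.0] * len(ctrl))})
        assert reallocation_test(t, "T") == pytest.approx(
            oracle_reallocation_p(case, ctrl))

    def test_identical_values_give_p_one(self):
        t = make_cq({"T": ([25.0, 25.0], [25.0, 25.0])},
                    {"R": ([20.0] * 2, [20.0] * 2)})
        assert reallocation_test(t, "T") == pytest.approx(1.0)

    def test_monte_carlo_agrees_with_exhaustive(self):
        case = [20.0, 21.0, 22.0, 24.5, 23.0]
        ctrl = [23.5, 24.0, 25.0, 21.0, 26.0]
        t = make_cq({"T": (case, ctrl)}, {"R": ([20.0] * 5, [20.0] * 5)})
        exact = reallocation_test(t, "T", iterations=1000)  # C(10,5)=252
        mc = reallocation_test(t, "T", iterations=200, seed=1)
        se = np.sqrt(exact * (1 - exact) / 200)
        assert abs(mc - exact) <= 3 * se + 1 / 200

    def test_label_swap_inverts_ratio_and_keeps_p(self):
        case = [21.0, 22.0, 20.5]
        ctrl = [24.0, 25.0, 23.5]
        t = make_cq({"T": (case, ctrl)}, {"R": ([20.0] * 3, [20.0] * 3)})
        swapped_groups = {s: ("control" if g == "case" else "case")
                          for s, g in t.groups.items()}
        t_swapped = CqTable(t.data, swapped_groups)
        assert pfaffl_ratio(t_swapped, "T") == \
            pytest.approx(1.0 / pfaffl_ratio(t, "T"))
        assert reallocation_test(t_swapped, "T") == \
            pytest.approx(reallocation_test(t, "T"))

    def test_degenerate_groups_are_errors(self):
        t = make_cq({"T": ([22.0], [25.0, 26.0])},
                    {"R": ([20.0], [20.0, 20.0])})
        with pytest.raises(ValueError):
            reallocation_test(t, "T")

    def test_p_is_never_zero(self):
        t = make_cq({"T": ([1.0, 1.1, 0.9], [30.0, 30.2, 29.8])},
                    {"R": ([20.0] * 3, [20.0] * 3)})
        assert reallocation_test(t, "T") > 0.0


class TestCalls:
    def test_up_and_ns(self):
        up = RelativeExpressionResult("G", 8.0, 0.001, "")
        ns = RelativeExpressionResult("G", 0.3, 0.2, "")
        assert call_regulation(up) == "UP"
        assert call_regulation(ns) == "NS"
        dr = RelativeExpressionResult("G", 0.3, 0.01, "")
        assert call_regulation(dr) == "DR"

    def test_relative_expression_table(self):
        t = make_cq({"T": ([22.0, 21.5, 22.5], [25.0, 25.5, 24.5])},
                    {"R": ([20.0] * 3, [20.0] * 3)})
        res = relative_expression(t, seed=0)
        assert res.loc["T", "ratio"] > 1
        assert res.loc["T", "call"] in {"UP", "NS"}

    def test_invalid_result_values_rejected(self):
        with pytest.raises(ValueError):
            RelativeExpressionResult("G", -1.0, 0.5, "NS")
        with pytest.raises(ValueError):
            RelativeExpressionResult("G", 2.0, 0.0, "NS")
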