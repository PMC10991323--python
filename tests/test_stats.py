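"""The statistical battery: ln(y+1), ANOVA, Dunnett, pairwise t-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from anttrail import (
    GroupData,
    dunnett_vs_control,
    log_transform,
    one_way_anova,
    pairwise_t,
)
from anttrail.stats import (
    dunnett_critical_value,
    dunnett_statistics,
    pairwise_t_table,
    star_code,
)


def make_groupdata(groups: dict[str, list[float]], control: str) -> GroupData:
    rows = []
    for label, ys in groups.items():
        prep, _, conc = label.partition("@")
        for i, y in enumerate(ys):
            rows.append(
                {"ant_id": f"{label}-{i}", "preparation": prep,
                 "concentration": conc or "-", "group": label, "y_mm": y}
            )
    return GroupData(data=pd.DataFrame(rows), control_label=control)


def from_transformed(groups: dict[str, list[float]], control: str) -> GroupData:
    """Build y values whose ln(y+1) equal the given numbers exactly."""
    return make_groupdata(
        {k: list(np.expm1(v)) for k, v in groups.items()}, control
    )


class TestTransform:
    def test_zero_maps_to_zero(self):
        assert log_transform(0.0) == 0.0

    def test_e_minus_one_maps_to_one(self):
        assert log_transform(np.e - 1) == pytest.approx(1.0)

    def test_monotone(self, rng):
        y = np.sort(rng.uniform(0, 1000, 50))
        assert np.all(np.diff(log_transform(y)) >= 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform(-0.1)


class TestAnova:
    @pytest.mark.parametrize("k,n,df1,df2", [(13, 15, 12, 182), (18, 15, 17, 252)])
    def test_design_determined_degrees_of_freedom(self, k, n, df1, df2, rng):
        groups = {f"g{i}@-": list(rng.uniform(0, 500, n)) for i in range(k)}
        res = one_way_anova(make_groupdata(groups, "g0@-"))
        assert (res.df1, res.df2) == (df1, df2)
        assert res.F >= 0 and 0 <= res.p <= 1

    def test_hand_computed_sums_of_squares(self):
        # transformed values {1,2,3} vs {2,3,4}: SSB = 1.5, SSW = 4,
        # F = (1.5/1)/(4/4) = 1.5 with df (1, 4)
        g = from_transformed({"a@-": [1, 2, 3], "b@-": [2, 3, 4]}, "a@-")
        res = one_way_anova(g)
        assert res.F == pytest.approx(1.5)
        assert (res.df1, res.df2) == (1, 4)
        assert res.p == pytest.approx(1 - sps.f.cdf(1.5, 1, 4))

    def test_degenerate_variance_rejected(self):
        g = make_groupdata({"a@-": [1.0, 1.0], "b@-": [2.0, 2.0]}, "a@-")
        with pytest.raises(ValueError):
            one_way_anova(g)


class TestDunnett:
    def test_single_comparison_reduces_to_pooled_t(self, rng):
        a = list(rng.uniform(0, 300, 15))
        b = list(rng.uniform(0, 300, 15))
        g = make_groupdata({"ctl@-": a, "trt@-": b}, "ctl@-")
        res = dunnett_vs_control(g, seed=0)
        assert len(res.comparisons) == 1
        _, p_t = pairwise_t(g, "trt@-", "ctl@-")
        assert res.comparisons[0].p_adjusted == pytest.approx(p_t, abs=1e-3)

    def test_adjusted_p_at_least_unadjusted(self, rng):
        groups = {f"g{i}@-": list(rng.uniform(0, 300, 15)) for i in range(6)}
        g = make_groupdata(groups, "g0@-")
        res = dunnett_vs_control(g, seed=1)
        labels, t, dfe = dunnett_statistics(g)
        raw = 2 * sps.t.sf(np.abs(t), dfe)
        for comp, p_raw in zip(res.comparisons, raw):
            assert comp.p_adjusted >= p_raw - 1e-9

    def test_pooled_t_statistics_match_library(self, rng):
        """Dual route: our pooled per-comparison t statistics equal the
        library's Dunnett statistics."""
        groups = {f"g{i}@-": list(rng.uniform(0, 300, 15)) for i in range(5)}
        g = make_groupdata(groups, "g0@-")
        res = dunnett_vs_control(g, seed=2)
        labels, t, dfe = dunnett_statistics(g)
        got = {c.label: c.statistic for c in res.comparisons}
        for label, ti in zip(labels, t):
            assert got[label] == pytest.approx(ti, abs=1e-9)

    def test_critical_value_reproduces_rejection_decision(self, rng):
        crit = dunnett_critical_value(4, 45, alpha=0.05)
        for seed in range(8):
            r = np.random.default_rng(seed)
            groups = {f"g{i}@-": list(r.uniform(0, 300, 10)) for i in range(5)}
            g = make_groupdata(groups, "g0@-")
            res = dunnett_vs_control(g, seed=seed)
            min_p = min(c.p_adjusted for c in res.comparisons)
            labels, t, dfe = dunnett_statistics(g)
            assert (min_p < 0.05) == (np.abs(t).max() > crit)

    def test_missing_control_rejected(self, rng):
        g = make_groupdata({"a@-": [1, 2], "b@-": [2, 3]}, "a@-")
        g.control_label = "nope"
        with pytest.raises(ValueError):
            dunnett_vs_control(g)

    def test_star_codes(self):
        assert star_code(0.2) == "ns"
        assert star_code(0.03) == "*"
        assert star_code(0.004) == "**"
        assert star_code(5e-4) == "***"
        assert star_code(5e-5) == "****"


class TestPairwiseT:
    def test_identical_groups_give_t0_p1(self):
        vals = [10.0, 20.0, 35.0]
        g = make_groupdata({"a@-": vals, "b@-": vals, "c@-": vals}, "a@-")
        t, p = pairwise_t(g, "a@-", "b@-")
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        g = make_groupdata(
            {"a@-": list(rng.uniform(0, 100, 8)), "b@-": list(rng.uniform(0, 100, 8))},
            "a@-",
        )
        t_ab, p_ab = pairwise_t(g, "a@-", "b@-")
        t_ba, p_ba = pairwise_t(g, "b@-", "a@-")
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_hand_formula_oracle(self):
        # transformed {1,2,3} vs {2,3,4}: pooled s^2 = 1, t = -1/sqrt(2/3)
        g = from_transformed({"a@-": [1, 2, 3], "b@-": [2, 3, 4]}, "a@-")
        t, p = pairwise_t(g, "a@-", "b@-")
        expected_t = -1.0 / np.sqrt(2.0 / 3.0)
        assert t == pytest.approx(expected_t)
        assert p == pytest.approx(2 * sps.t.sf(abs(expected_t), 4))

    def test_unknown_label_rejected(self):
        g = make_groupdata({"a@-": [1, 2], "b@-": [2, 3]}, "a@-")
        with pytest.raises(KeyError):
            pairwise_t(g, "a@-", "zzz")

    def test_matched_concentration_table(self, rng):
        groups = {}
        for prep in ("x", "y"):
            for conc in ("1e-1", "1e0"):
                groups[f"{prep}@{conc}"] = list(rng.uniform(0, 300, 15))
        groups["blank@-"] = list(rng.uniform(0, 300, 15))
        g = make_groupdata(groups, "blank@-")
        table = pairwise_t_table(g, ("x", "y"))
        assert list(table["concentration"]) == ["1e-1", "1e0"]
        assert ((table["p"] >= 0) & (table["p"] <= 1)).all()
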