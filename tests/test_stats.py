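"""Gated group comparisons, post-hoc tests and box summaries."""

import numpy as np
import pandas as pd
import pytest

from fibroquant.stats import (
    compare_groups,
    gate_assumptions,
    stars,
    summarise_box,
)
from oracles import anova_f_and_p


def make_table(**groups):
    rows = []
    for g, vals in groups.items():
        for v in vals:
            rows.append({"group": g, "value": float(v)})
    return pd.DataFrame(rows)


NAMES = ("unloaded", "physiological", "pathological")


def simulate_table(rng, dists):
    return make_table(**{g: d(rng) for g, d in zip(NAMES, dists)})


class TestGate:
    def test_normal_groups_usually_parametric(self):
        n_param = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            t = simulate_table(
                rng, [lambda r: r.normal(0, 1, 50)] * 3
            )
            if gate_assumptions(t) == "parametric":
                n_param += 1
        # four screens each at alpha=0.05: pass rate ~= 0.95**4 ~ 0.81 under
        # independence, a little higher in practice
        assert n_param >= 160

    def test_exponential_group_usually_nonparametric(self):
        n_nonp = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            t = simulate_table(
                rng,
                [
                    lambda r: r.normal(0, 1, 50),
                    lambda r: r.normal(0, 1, 50),
                    lambda r: r.exponential(1.0, 50),
                ],
            )
            if gate_assumptions(t) == "nonparametric":
                n_nonp += 1
        assert n_nonp >= 160  # >= 80% of seeds

    def test_constant_group_degenerate_path(self):
        t = make_table(
            unloaded=[1.0] * 5, physiological=[1.0] * 5, pathological=[1.0] * 5
        )
        with pytest.warns(UserWarning):
            assert gate_assumptions(t) == "nonparametric"

    def test_tiny_group_forces_nonparametric(self):
        t = make_table(unloaded=[1.0, 2.0], physiological=[1.0, 2.0, 3.0, 4.0])
        with pytest.warns(UserWarning):
            assert gate_assumptions(t) == "nonparametric"


class TestCompareGroups:
    def test_identical_groups_no_significance(self):
        t = make_table(
            unloaded=[1, 2, 3], physiological=[1, 2, 3], pathological=[1, 2, 3]
        )
        res = compare_groups(t)
        assert res.omnibus_p == pytest.approx(1.0)
        assert not any(p.significant for p in res.pairwise)

    def test_constant_data_p_one(self):
        t = make_table(
            unloaded=[5.0] * 4, physiological=[5.0] * 4, pathological=[5.0] * 4
        )
        res = compare_groups(t)
        assert res.omnibus_p == 1.0
        assert all(p.stars == "ns" for p in res.pairwise)

    def test_anova_matches_sum_of_squares_oracle(self):
        groups = [
            np.array([1.0, 2, 3, 4]),
            np.array([2.0, 3, 4, 5]),
            np.array([7.0, 8, 9, 10]),
        ]
        F_ref, p_ref = anova_f_and_p(groups)
        assert F_ref == pytest.approx(24.8, abs=1e-10)
        t = make_table(
            unloaded=groups[0], physiological=groups[1], pathological=groups[2]
        )
        res = compare_groups(t)
        assert res.gate == "parametric"
        assert res.omnibus_stat == pytest.approx(F_ref, rel=1e-10)
        assert res.omnibus_p == pytest.approx(p_ref, rel=1e-8)
        # only the pairs involving the shifted third group are significant
        for pc in res.pairwise:
            involves_path = "pathological" in (pc.group_a, pc.group_b)
            assert pc.significant == involves_path

    def test_large_shift_detected_reliably(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            t = make_table(
                unloaded=rng.normal(0, 1, 30),
                physiological=rng.normal(0, 1, 30),
                pathological=rng.normal(3, 1, 30),
            )
            res = compare_groups(t)
            pair = next(
                p for p in res.pairwise
                if {p.group_a, p.group_b} == {"unloaded", "pathological"}
            )
            hits += pair.significant
        assert hits >= 190  # >= 95% power at a 3-sigma shift

    def test_pairwise_label_permutation_symmetry(self):
        rng = np.random.default_rng(42)
        a, b, c = rng.normal(0, 1, 20), rng.normal(1, 1, 20), rng.normal(2, 1, 20)
        t1 = make_table(unloaded=a, physiological=b, pathological=c)
        t2 = make_table(pathological=c, unloaded=a, physiological=b)
        p1 = {
            frozenset((p.group_a, p.group_b)): p.p for p in compare_groups(t1).pairwise
        }
        p2 = {
            frozenset((p.group_a, p.group_b)): p.p for p in compare_groups(t2).pairwise
        }
        for key in p1:
            assert p1[key] == pytest.approx(p2[key], rel=1e-12)

    def test_nonparametric_branch_runs_dunn(self):
        rng = np.random.default_rng(7)
        t = make_table(
            unloaded=rng.exponential(1, 40),
            physiological=rng.exponential(1, 40),
            pathological=rng.exponential(1, 40) + 4,
        )
        res = compare_groups(t)
        assert res.gate == "nonparametric"
        pair = next(
            p for p in res.pairwise
            if {p.group_a, p.group_b} == {"unloaded", "pathological"}
        )
        assert pair.significant

    def test_dunn_z_matches_hand_computation(self):
        """Dunn on a tiny tie-free data set against explicitly computed
        mean ranks and the z-statistic formula."""
        a = [1.0, 3.0, 5.0]
        b = [2.0, 4.0, 9.0]
        c = [6.0, 7.0, 8.0]
        # pooled ranks: a -> 1, 3, 5 ; b -> 2, 4, 9 ; c -> 6, 7, 8
        rbar = {"unloaded": 3.0, "physiological": 5.0, "pathological": 7.0}
        n = 9
        var = n * (n + 1) / 12.0  # no ties
        from scipy.stats import norm

        t = make_table(unloaded=a, physiological=b, pathological=c)
        from fibroquant.stats import _dunn_pairwise

        groups = {k: np.array(v) for k, v in
                  [("unloaded", a), ("physiological", b), ("pathological", c)]}
        for pc in _dunn_pairwise(groups):
            z = (rbar[pc.group_a] - rbar[pc.group_b]) / np.sqrt(var * (2 / 3))
            p_expected = min(1.0, 2 * norm.sf(abs(z)) * 3)
            assert pc.p == pytest.approx(p_expected, rel=1e-12)


class TestStars:
    @pytest.mark.parametrize(
        "p,code",
        [(0.2, "ns"), (0.049, "*"), (0.009, "**"), (0.0009, "***"), (0.05, "ns")],
    )
    def test_mapping(self, p, code):
        assert stars(p) == code


class TestBoxSummary:
    def test_one_to_nine(self):
        t = make_table(unloaded=range(1, 10))
        (b,) = summarise_box(t)
        assert (b.median, b.q1, b.q3) == (5.0, 3.0, 7.0)
        assert b.outliers == ()
        assert (b.whisker_low, b.whisker_high) == (1.0, 9.0)

    def test_constant_group_zero_height(self):
        t = make_table(unloaded=[4.0] * 6)
        (b,) = summarise_box(t)
        assert b.median == b.q1 == b.q3 == 4.0
        assert b.whisker_low == b.whisker_high == 4.0

    def test_extreme_point_flagged_outlier(self):
        t = make_table(unloaded=list(range(1, 10)) + [100])
        (b,) = summarise_box(t)
        assert b.outliers == (100.0,)
        assert b.whisker_high == 9.0
        # hand check of the 1.5 IQR fence with type-7 quartiles
        assert b.q1 == pytest.approx(3.25)
        assert b.q3 == pytest.approx(7.75)

    def test_median_and_sd_reported(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(10, 2, 100)
        t = make_table(unloaded=vals)
        (b,) = summarise_box(t)
        assert b.mean == pytest.approx(vals.mean())
        assert b.sd == pytest.approx(vals.std(ddof=1))
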