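"""L18 design handling, S/N, response tables, ANOVA, optimal levels."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import seedspread as sp
from seedspread.taguchi import FactorSS, TaguchiDesign, _dense_ranks_desc


def runset_from_run_means(values):
    """Wrap 18 run-level responses as single-observation runs."""
    return sp.TaguchiRunSet(
        design=sp.l18_design(), observations=tuple((float(v),) for v in values)
    )


class TestDesign:
    def test_l18_shape_and_balance(self):
        d = sp.l18_design()
        assert d.n_runs == 18
        assert len(d.factors) == 6
        assert d.occurrences("socket_arrangement") == 9
        for name in d.factor_names()[1:]:
            assert d.occurrences(name) == 6

    def test_csv_roundtrip(self, tmp_path):
        d = sp.l18_design()
        path = tmp_path / "design.csv"
        d.to_csv(path)
        d2 = TaguchiDesign.from_csv(path)
        assert d2.factors == d.factors
        assert np.array_equal(d2.runs, d.runs)

    def test_unbalanced_design_rejected(self):
        with pytest.raises(ValueError, match="balanced"):
            TaguchiDesign(
                factors=(("f", ("a", "b")),), runs=np.array([[0], [0], [1]])
            )


class TestSnSmallerBetter:
    @pytest.mark.parametrize(
        "obs,expected",
        [
            ([1.0], 0.0),
            ([0.1], 20.0),
            ([0.1, 0.2, 0.3], -10.0 * math.log10(0.14 / 3)),
        ],
    )
    def test_hand_computed_values(self, obs, expected):
        assert sp.sn_smaller_better(obs) == pytest.approx(expected, abs=1e-9)

    def test_all_zero_observations_give_positive_infinity(self):
        assert sp.sn_smaller_better([0.0, 0.0]) == math.inf

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError):
            sp.sn_smaller_better([])

    @settings(derandomize=True, max_examples=30)
    @given(
        c=st.floats(0.01, 100.0),
        seed=st.integers(0, 10_000),
    )
    def test_scale_law(self, c, seed):
        # S/N(c*Y) = S/N(Y) - 20*log10(c)
        y = np.random.default_rng(seed).uniform(0.05, 1.0, 5)
        assert sp.sn_smaller_better(c * y) == pytest.approx(
            sp.sn_smaller_better(y) - 20.0 * math.log10(c), abs=1e-9
        )


class TestResponseTable:
    def test_constant_response_all_factors_tied_at_rank_one(self):
        rt = sp.response_table(runset_from_run_means([0.2] * 18))
        for name in rt.factor_names():
            assert rt.delta("mean")[name] == 0.0
            assert rt.ranks("mean")[name] == 1

    def test_single_active_factor_dominates_ranks(self):
        d = sp.l18_design()
        y = d.runs[:, 2].astype(float)  # response = motor_speed level index
        rt = sp.response_table(runset_from_run_means(y))
        assert rt.ranks("mean")["motor_speed"] == 1
        # orthogonality: every other factor sees a flat response
        for name in rt.factor_names():
            if name != "motor_speed":
                assert rt.delta("mean")[name] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rt.level_means["motor_speed"], [0.0, 1.0, 2.0])

    def test_grand_mean_consistency(self):
        rng = np.random.default_rng(2)
        rt = sp.response_table(runset_from_run_means(rng.uniform(0.05, 0.5, 18)))
        for name in rt.factor_names():
            occ = rt.occurrences[name]
            weighted = np.sum(np.asarray(rt.level_means[name]) * occ) / 18.0
            assert weighted == pytest.approx(rt.grand_mean, abs=1e-9)
            weighted_sn = np.sum(np.asarray(rt.level_sn[name]) * occ) / 18.0
            assert weighted_sn == pytest.approx(rt.grand_sn, abs=1e-9)

    def test_dense_ranks_share_smaller_rank_on_ties(self):
        assert _dense_ranks_desc(np.array([5.0, 5.0, 3.0, 1.0])).tolist() == [1, 1, 2, 3]


class TestAnova:
    def test_level_means_at_grand_mean_give_zero_ss(self):
        fss = sp.anova_from_levels([0.3, 0.3, 0.3], 6, grand_mean=0.3)
        assert fss == FactorSS(ss=0.0, dof=2, ms=0.0)

    def test_factor_ss_equals_total_minus_within_by_enumeration(self):
        # independent oracle: SS_between = SS_total - SS_within, both by
        # direct enumeration over a random balanced one-factor layout
        rng = np.random.default_rng(8)
        for _ in range(20):
            levels, n_per = 3, 6
            y = rng.normal(0, 1, (levels, n_per))
            grand = y.mean()
            ss_total = ((y - grand) ** 2).sum()
            ss_within = sum(
                ((y[v] - y[v].mean()) ** 2).sum() for v in range(levels)
            )
            fss = sp.anova_from_levels(y.mean(axis=1), n_per, grand)
            assert fss.ss == pytest.approx(ss_total - ss_within, abs=1e-9)

    def test_occurrence_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sp.anova_from_levels([0.1, 0.2, 0.3], [6, 6], 0.2)
        with pytest.raises(ValueError):
            sp.anova_from_levels([0.1, 0.2, 0.3], [6, 6, 9], 0.2)

    def test_decomposition_sums_to_total(self):
        rng = np.random.default_rng(3)
        runset = runset_from_run_means(rng.uniform(0, 1, 18))
        table = sp.anova(runset, "mean")
        assert table.dof_err == 6
        assert sum(table.ss.values()) + table.ss_err == pytest.approx(
            table.total_ss, abs=1e-9
        )
        assert all(v >= 0 for v in table.ss.values())
        for name in table.factors:
            assert table.ms[name] == pytest.approx(
                table.ss[name] / table.dof[name]
            )

    def test_dominant_injected_factor_has_max_f_min_p(self):
        d = sp.l18_design()
        rng = np.random.default_rng(4)
        y = 1.0 * d.runs[:, 1] + rng.normal(0, 0.05, 18)  # roller dominates
        table = sp.anova(runset_from_run_means(y), "mean")
        assert max(table.f, key=table.f.get) == "roller_speed"
        assert min(table.p, key=table.p.get) == "roller_speed"
        assert table.p["roller_speed"] < 0.01

    def test_null_p_values_are_uniform(self):
        # pure-noise responses: each factor's P is exactly F-distributed
        # under the null, hence uniform on (0,1)
        rng = np.random.default_rng(5)
        pvals = {name: [] for name in sp.l18_design().factor_names()}
        for _ in range(500):
            table = sp.anova(runset_from_run_means(rng.normal(0, 1, 18)), "mean")
            for name, p in table.p.items():
                pvals[name].append(p)
        for name, ps in pvals.items():
            stat = stats.kstest(ps, "uniform")
            assert stat.pvalue > 0.01, name

    def test_effect_ranking_recovered_under_noise(self):
        # additive model at SNR 3: injected ordering of the two active
        # factors is recovered in >= 95% of replicates
        d = sp.l18_design()
        rng = np.random.default_rng(6)
        effect = 0.3
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            y = (
                effect * d.runs[:, 2]
                + 0.5 * effect * d.runs[:, 1]
                + rng.normal(0, effect / 3, 18)
            )
            table = sp.anova(runset_from_run_means(y), "mean")
            ranked = sorted(table.f, key=table.f.get, reverse=True)
            hits += ranked[:2] == ["motor_speed", "roller_speed"]
        assert hits / n_rep >= 0.95

    def test_sn_response_with_infinite_run_rejected(self):
        obs = [(0.0,)] + [(0.1,)] * 17
        runset = sp.TaguchiRunSet(design=sp.l18_design(), observations=tuple(obs))
        with pytest.raises(ValueError, match="non-finite"):
            sp.anova(runset, "sn")


class TestOptimalLevels:
    def test_mean_rule_picks_level_closest_to_zero(self):
        d = sp.l18_design()
        y = 0.1 * (d.runs[:, 2] - 1.0)  # motor level 2 -> mean exactly 0
        rt = sp.response_table(runset_from_run_means(y + 0.001 * d.runs[:, 1]))
        sel = sp.optimal_levels(rt)
        assert sel["motor_speed"]["level_by_mean"] == "150"

    def test_all_levels_equal_reports_tie_and_first_level(self):
        rt = sp.response_table(runset_from_run_means([0.2] * 18))
        sel = sp.optimal_levels(rt)
        for name, levels in rt.factors:
            assert sel[name]["level_by_mean"] == levels[0]
            assert sel[name]["tie_mean"] and sel[name]["tie_sn"]

    def test_unknown_rule_rejected(self):
        rt = sp.response_table(runset_from_run_means([0.2] * 18))
        with pytest.raises(ValueError):
            sp.optimal_levels(rt, mean_rule="nominal_best")


class TestRunSetIO:
    def test_observations_csv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(9)
        obs = tuple(tuple(rng.uniform(0, 0.5, 3)) for _ in range(18))
        runset = sp.TaguchiRunSet(design=sp.l18_design(), observations=obs)
        path = tmp_path / "obs.csv"
        runset.to_csv(path)
        back = sp.TaguchiRunSet.from_csv(sp.l18_design(), path)
        assert np.allclose(back.run_means(), runset.run_means())

    def test_every_run_needs_observations(self):
        with pytest.raises(ValueError):
            sp.TaguchiRunSet(design=sp.l18_design(), observations=((),) * 18)
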