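"""T/C enumeration and per-feature ratio statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from microtc.design import FactorDecl, Sample, SampleSet
from microtc.errors import UnreplicatedError
from microtc.matrix import ExpressionMatrix
from microtc.synth import generate_experiment, ice1_like_spec, Spike
from microtc.tc import (
    compute_tc_stats,
    enumerate_tcs,
    fold_from_log2r,
    log2r_from_fold,
    signed_fold,
    welch_ttest,
)


def _sset(name, profile):
    return SampleSet(name, [Sample(f"{name}_r1", f"{name}_r1"), Sample(f"{name}_r2", f"{name}_r2")], profile)


def _factorial_sets(factors):
    sets = []
    for combo in itertools.product(*[f.levels for f in factors]):
        profile = {f.name: lvl for f, lvl in zip(factors, combo)}
        sets.append(_sset("_".join(combo).replace(" ", ""), profile))
    return sets


def _brute_force_pairs(sample_sets, factors):
    """Independent filter over all ordered sample-set pairs."""
    out = set()
    for treat, ctrl in itertools.permutations(sample_sets, 2):
        diff = [f for f in {**treat.profile, **ctrl.profile} if treat.profile.get(f) != ctrl.profile.get(f)]
        if len(diff) == 1:
            f = factors[diff[0]]
            if ctrl.profile[diff[0]] == f.control_level and treat.profile[diff[0]] != f.control_level:
                out.add((treat.name, ctrl.name))
    return out


ICE1_FACTORS = (
    FactorDecl("genotype", ("wild type", "ice1"), "wild type"),
    FactorDecl("cold", ("none", "3 hr", "6 hr", "24 hr"), "none"),
)


def test_ice1_design_enumerates_ten_tcs():
    """2 genotypes x 4 cold durations: 3 cold-in-mutant + 3 cold-in-WT +
    3 mutation-under-cold + 1 mutation-untreated = 10."""
    sets = _factorial_sets(ICE1_FACTORS)
    factors = {f.name: f for f in ICE1_FACTORS}
    tcs = enumerate_tcs(sets, factors)
    assert len(tcs) == 10
    by_factor = {}
    for tc in tcs:
        by_factor.setdefault(tc.differing_factor, []).append(tc)
    assert len(by_factor["cold"]) == 6  # 3 durations x 2 genotypes
    assert len(by_factor["genotype"]) == 4  # under none/3/6/24 hr
    for tc in tcs:
        assert tc.control.profile[tc.differing_factor] == factors[tc.differing_factor].control_level
        diff = [f for f in tc.treatment.profile if tc.treatment.profile[f] != tc.control.profile[f]]
        assert diff == [tc.differing_factor]


def test_single_factor_two_levels_gives_one_tc():
    f = FactorDecl("dose", ("control", "treated"), "control")
    tcs = enumerate_tcs(_factorial_sets((f,)), {"dose": f})
    assert len(tcs) == 1
    assert tcs[0].treatment.profile["dose"] == "treated"


def test_two_by_two_gives_four_tcs():
    factors = (
        FactorDecl("genotype", ("wt", "mut"), "wt"),
        FactorDecl("stress", ("no", "yes"), "no"),
    )
    tcs = enumerate_tcs(_factorial_sets(factors), {f.name: f for f in factors})
    assert len(tcs) == 4


def test_enumeration_matches_bruteforce_on_random_designs():
    rng = np.random.default_rng(9)
    for _ in range(20):
        n_factors = int(rng.integers(1, 4))
        factors = {}
        for i in range(n_factors):
            n_lvl = int(rng.integers(2, 5))
            levels = tuple(f"f{i}l{j}" for j in range(n_lvl))
            factors[f"f{i}"] = FactorDecl(f"f{i}", levels, levels[int(rng.integers(n_lvl))])
        full = _factorial_sets(tuple(factors.values()))
        keep = [s for s in full if rng.random() < 0.7]
        got = {(t.treatment.name, t.control.name) for t in enumerate_tcs(keep, factors)}
        assert got == _brute_force_pairs(keep, factors)


def test_enumeration_order_is_deterministic():
    sets = _factorial_sets(ICE1_FACTORS)
    factors = {f.name: f for f in ICE1_FACTORS}
    a = [t.tc_id for t in enumerate_tcs(sets, factors)]
    b = [t.tc_id for t in enumerate_tcs(list(reversed(sets)), factors)]
    assert a == b


# ---- Welch t-test ---------------------------------------------------------


def test_welch_example_against_t_distribution():
    t, p, df, flag = welch_ttest([1, 2, 3], [2, 3, 4])
    assert t == pytest.approx(-1.224745, abs=1e-6)
    assert df == pytest.approx(4.0)
    assert p == pytest.approx(0.288, abs=5e-4)
    assert not flag


def test_welch_matches_scipy_oracle_on_random_draws():
    rng = np.random.default_rng(4)
    for _ in range(200):
        x = rng.normal(0, 1, int(rng.integers(2, 8)))
        y = rng.normal(0.3, 1.7, int(rng.integers(2, 8)))
        t, p, _, _ = welch_ttest(x, y)
        ot, op = sps.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ot, abs=1e-10)
        assert p == pytest.approx(op, abs=1e-10)


def test_pooled_variant_matches_scipy():
    rng = np.random.default_rng(5)
    x, y = rng.normal(0, 1, 5), rng.normal(1, 1, 4)
    t, p, df, _ = welch_ttest(x, y, equal_var=True)
    ot, op = sps.ttest_ind(x, y, equal_var=True)
    assert (t, p) == pytest.approx((ot, op), abs=1e-12)
    assert df == 7


def test_identical_groups_give_t0_p1():
    t, p, _, _ = welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert (t, p) == (0.0, 1.0)


def test_swap_negates_t_keeps_p():
    x, y = [1.0, 2.0, 5.0], [2.0, 4.0, 4.5]
    a = welch_ttest(x, y)
    b = welch_ttest(y, x)
    assert a.t_stat == pytest.approx(-b.t_stat)
    assert a.p_value == pytest.approx(b.p_value)


def test_degenerate_zero_variance_cases():
    t, p, _, flag = welch_ttest([2.0, 2.0], [2.0, 2.0])
    assert (t, p, flag) == (0.0, 1.0, False)
    t, p, _, flag = welch_ttest([3.0, 3.0], [2.0, 2.0])
    assert p == 0.0 and flag and t == np.inf


def test_unreplicated_group_rejected():
    with pytest.raises(UnreplicatedError):
        welch_ttest([1.0], [1.0, 2.0])


# ---- per-T/C statistics ---------------------------------------------------


def _stats_for(vals_t, vals_c):
    n = len(vals_t[0])
    chips = [f"t{j}" for j in range(n)] + [f"c{j}" for j in range(n)]
    arr = np.hstack([vals_t, vals_c])
    em = ExpressionMatrix(pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])], columns=chips))
    treat = SampleSet("T", [Sample(c, c) for c in chips[:n]], {"f": "t"})
    ctrl = SampleSet("C", [Sample(c, c) for c in chips[n:]], {"f": "c"})
    from microtc.tc import TCPair

    return compute_tc_stats(em, TCPair("T__vs__C", "T vs C", treat, ctrl, "f"))


def test_tc_stats_definitional_arithmetic():
    table = _stats_for(np.array([[9.0, 10.0, 11.0]]), np.array([[7.0, 8.0, 9.0]]))
    row = table.loc["g0"]
    assert row["mean_t"] == pytest.approx(10.0)
    assert row["mean_c"] == pytest.approx(8.0)
    assert row["log2r"] == pytest.approx(2.0)
    assert row["a_value"] == pytest.approx(9.0)
    assert row["fold"] == pytest.approx(4.0)


def test_identical_sides_give_zero_log2r_p_one():
    v = np.array([[5.0, 6.0, 7.0]])
    table = _stats_for(v, v)
    assert table.loc["g0", "log2r"] == 0.0
    assert table.loc["g0", "p_value"] == 1.0


def test_reversal_negates_log2r_keeps_a_and_p():
    rng = np.random.default_rng(6)
    a = rng.normal(8, 1, (10, 3))
    b = rng.normal(8, 1, (10, 3))
    fwd = _stats_for(a, b)
    rev = _stats_for(b, a)
    np.testing.assert_allclose(fwd["log2r"], -rev["log2r"])
    np.testing.assert_allclose(fwd["a_value"], rev["a_value"])
    np.testing.assert_allclose(fwd["p_value"], rev["p_value"])


def test_fold_column_is_two_to_the_log2r():
    rng = np.random.default_rng(7)
    table = _stats_for(rng.normal(9, 1, (20, 3)), rng.normal(8, 1, (20, 3)))
    np.testing.assert_allclose(table["fold"], np.power(2.0, table["log2r"]), atol=1e-12)


def test_vectorized_stats_agree_with_scalar_welch():
    rng = np.random.default_rng(8)
    a = rng.normal(8, 1, (12, 4))
    b = rng.normal(8.5, 1.2, (12, 3))
    table = _stats_for_uneven(a, b)
    for i in range(12):
        t, p, _, _ = welch_ttest(a[i], b[i])
        assert table.iloc[i]["t_stat"] == pytest.approx(t, abs=1e-12)
        assert table.iloc[i]["p_value"] == pytest.approx(p, abs=1e-12)


def _stats_for_uneven(vals_t, vals_c):
    chips = [f"t{j}" for j in range(vals_t.shape[1])] + [f"c{j}" for j in range(vals_c.shape[1])]
    arr = np.hstack([vals_t, vals_c])
    em = ExpressionMatrix(pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])], columns=chips))
    treat = SampleSet("T", [Sample(c, c) for c in chips[: vals_t.shape[1]]], {"f": "t"})
    ctrl = SampleSet("C", [Sample(c, c) for c in chips[vals_t.shape[1] :]], {"f": "c"})
    from microtc.tc import TCPair

    return compute_tc_stats(em, TCPair("T__vs__C", "T vs C", treat, ctrl, "f"))


def test_spiked_shift_recovered_within_noise_bound():
    spec = ice1_like_spec(seed=21, n_features=40, noise_sd=0.1,
                          spikes=(Spike("g00000", {"cold": "6 hr"}, 1.0),))
    exp = generate_experiment(spec)
    tcs = enumerate_tcs(exp.design.sample_sets, exp.design.factors)
    tc = next(t for t in tcs if t.differing_factor == "cold"
              and t.treatment.profile["cold"] == "6 hr"
              and t.treatment.profile["genotype"] == "wild type")
    table = compute_tc_stats(exp.matrix, tc)
    assert abs(table.loc["g00000", "log2r"] - 1.0) < 3 * 0.1 / np.sqrt(3)


def test_fold_log2r_conversions():
    assert fold_from_log2r(1.0) == 2.0
    assert fold_from_log2r(0.0) == 1.0
    assert log2r_from_fold(30.0) == pytest.approx(4.9069, abs=1e-4)
    assert round(log2r_from_fold(30.0), 1) == 4.9
    assert signed_fold(-1.0) == -2.0
    with pytest.raises(ValueError):
        log2r_from_fold(0.0)
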