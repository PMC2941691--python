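"""Double-cutoff regulation sets, Dice overlap, relation index, ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from microtc.errors import MicrotcError
from microtc.reference_tables import (
    PSEUDOMONAS16H_N_REF,
    derive_reference_set_size,
    load_coregulation_table,
)
from microtc.relations import (
    RatioUniverse,
    RegulationSet,
    op_from_counts,
    overlap_percentage,
    overlapped_correlation,
    rank_relations,
    relate,
    relation_index,
    select_regulated,
)


def _stats(log2r, p):
    idx = [f"i{k}" for k in range(len(log2r))]
    return pd.DataFrame({"log2r": log2r, "p_value": p}, index=idx)


# ---- double cutoff --------------------------------------------------------


def test_double_cutoff_boundaries():
    stats = _stats([1.0, 1.0, -1.0, 0.9, 5.0], [0.049, 0.05, 0.01, 0.001, 0.2])
    rs = select_regulated(stats, fold_min=2.0, p_max=0.05)
    assert rs.up == {"i0"}  # log2r >= 1 and p strictly < 0.05
    assert rs.down == {"i2"}
    assert "i1" not in rs.all  # p == 0.05 excluded
    assert "i3" not in rs.all  # below 2-fold
    assert "i4" not in rs.all  # not significant


def test_up_down_disjoint_and_monotone():
    rng = np.random.default_rng(12)
    stats = _stats(rng.normal(0, 2, 200), rng.uniform(0, 0.2, 200))
    tight = select_regulated(stats, fold_min=2.5, p_max=0.01)
    loose = select_regulated(stats, fold_min=2.0, p_max=0.05)
    assert not (tight.up & tight.down)
    assert tight.up <= loose.up and tight.down <= loose.down


def test_strong_induction_lands_in_up_set():
    stats = _stats([math.log2(338.61)], [0.0024])
    assert select_regulated(stats).up == {"i0"}


# ---- overlap percentage ---------------------------------------------------


def _rs(items, owner="x"):
    return RegulationSet(owner=owner, up=frozenset(items), down=frozenset())


def test_dice_overlap_from_reference_row():
    assert op_from_counts(381, 477, 277) == pytest.approx(64.568764, abs=1e-5)


def test_overlap_identical_and_disjoint():
    a = _rs({"t1", "t2", "t3"})
    n, op = overlap_percentage(a, _rs({"t1", "t2", "t3"}, "y"))
    assert (n, op) == (3, 100.0)
    n, op = overlap_percentage(a, _rs({"t4", "t5"}, "y"))
    assert (n, op) == (0, 0.0)


def test_overlap_undefined_for_empty_sets():
    with pytest.raises(MicrotcError):
        overlap_percentage(_rs(set()), _rs(set(), "y"))


# ---- overlapped correlation ----------------------------------------------


def test_correlation_limits_and_oracle():
    ref = np.array([1.0, 2.0, 3.0, 4.0])
    assert overlapped_correlation(ref, 2 * ref) == pytest.approx(1.0)
    assert overlapped_correlation(ref, -ref) == pytest.approx(-1.0)
    rng = np.random.default_rng(13)
    x, y = rng.normal(0, 1, 50), rng.normal(0, 1, 50)
    assert overlapped_correlation(x, y) == pytest.approx(pearsonr(x, y)[0], abs=1e-12)


def test_correlation_undefined_cases():
    assert overlapped_correlation([1.0], [2.0]) is None
    assert overlapped_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) is None


# ---- relation index -------------------------------------------------------


def test_relation_index_reference_rows():
    assert relation_index(64.568764, 0.982917) == pytest.approx(0.623816, abs=1e-5)
    assert relation_index(38.5844, -0.82538) == pytest.approx(0.26286, abs=1e-4)
    assert relation_index(100.0, 1.0) == 1.0
    assert relation_index(100.0, -1.0) == 1.0  # sign-blind via the square
    assert relation_index(50.0, 0.5, cc_exponent=1) == pytest.approx(0.25)


def test_relation_index_bounds():
    with pytest.raises(ValueError):
        relation_index(101.0, 0.5)
    with pytest.raises(ValueError):
        relation_index(50.0, 1.5)


# ---- full published-table reproduction ------------------------------------


def test_reference_set_size_inverts_to_381():
    assert derive_reference_set_size() == 381 == PSEUDOMONAS16H_N_REF


def test_published_coregulation_table_reproduced():
    """With N=381 every printed row's RI is matched within 1e-4 and the
    floored OP matches the printed integer; the recomputed ranking puts
    '24 hr Pseudomonas infection' first."""
    table = load_coregulation_table()
    assert len(table) >= 10
    n_ref = PSEUDOMONAS16H_N_REF
    ops = [op_from_counts(n_ref, b, c) for b, c in zip(table["n_genes"], table["n_overlap"])]
    ris = [relation_index(op, cc) for op, cc in zip(ops, table["cc"])]
    np.testing.assert_allclose(ris, table["ri_printed"], atol=1e-4)
    assert [math.floor(op) for op in ops] == list(table["op_printed"])
    neg = table[table["cc"] < 0]
    assert len(neg) >= 2  # anti-correlated relations rank positively
    assert set(neg["ri_printed"]).issuperset({0.26286, 0.158267})
    order = np.argsort(ris)[::-1]
    assert table["tc_name"].iloc[order[0]].startswith("24 hr")


# ---- ranking --------------------------------------------------------------


def test_near_duplicate_gene_ranks_first(multi_tc_spec):
    from microtc.synth import generate_experiment
    from microtc.tc import compute_tc_stats, enumerate_tcs

    spec = multi_tc_spec(seed=3, pair=("g00000", "g00001", 1))
    exp = generate_experiment(spec)
    tcs = enumerate_tcs(exp.design.sample_sets, exp.design.factors)
    universe = RatioUniverse.from_tc_tables(
        {t.tc_id: compute_tc_stats(exp.matrix, t) for t in tcs}
    )
    ranked = rank_relations(universe, "g00000", axis="genes")
    assert ranked[0].other_id == "g00001"
    assert ranked[0].relation_index == pytest.approx(
        ranked[0].overlap_percentage / 100 * ranked[0].correlation ** 2
    )


def _oracle_rank(universe, ref, axis, fold_min=2.0, p_max=0.05, min_overlap=3):
    """Brute-force double loop with independently coded OP/CC/RI."""

    def regset(eid):
        sl = universe.slice(axis, eid)
        thr = math.log2(fold_min)
        sig = sl["p_value"] < p_max
        return set(sl.index[sig & (sl["log2r"].abs() >= thr)])

    ref_set = regset(ref)
    rows = []
    ids = universe.gene_ids if axis == "genes" else universe.tc_ids
    for other in ids:
        if other == ref:
            continue
        oset = regset(other)
        inter = sorted(ref_set & oset)
        if len(ref_set) + len(oset) == 0 or len(inter) < max(min_overlap, 2):
            continue
        if axis == "genes":
            x = universe.log2r.loc[ref, inter]
            y = universe.log2r.loc[other, inter]
        else:
            x = universe.log2r.loc[inter, ref]
            y = universe.log2r.loc[inter, other]
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        cc = pearsonr(x, y)[0]
        op = 200.0 * len(inter) / (len(ref_set) + len(oset))
        rows.append((other, op / 100 * cc**2, cc))
    rows.sort(key=lambda r: (-r[1], -r[2] ** 2, r[0]))
    return rows


@pytest.mark.parametrize("axis,ref", [("genes", "g03"), ("tcs", "tc05"), ("genes", "g10")])
def test_ranking_matches_bruteforce_double_loop(random_universe, axis, ref):
    got = rank_relations(random_universe, ref, axis=axis)
    want = _oracle_rank(random_universe, ref, axis)
    assert [(r.other_id) for r in got] == [w[0] for w in want]
    for r, w in zip(got, want):
        assert r.relation_index == pytest.approx(w[1], abs=1e-12)
        assert r.correlation == pytest.approx(w[2], abs=1e-12)


def test_relation_symmetry(random_universe):
    defined = 0
    for ref in random_universe.gene_ids[:8]:
        for other in random_universe.gene_ids[8:16]:
            a = relate(random_universe, "genes", ref, other)
            b = relate(random_universe, "genes", other, ref)
            assert (a is None) == (b is None)
            if a is None:
                continue
            defined += 1
            assert a.overlap_percentage == pytest.approx(b.overlap_percentage)
            assert a.correlation**2 == pytest.approx(b.correlation**2)
            assert a.relation_index == pytest.approx(b.relation_index)
    assert defined > 0


def test_empty_reference_set_warns_and_returns_nothing(random_universe):
    universe = RatioUniverse(random_universe.log2r * 0.0, random_universe.p_value)
    with pytest.warns(UserWarning, match="empty regulation set"):
        assert rank_relations(universe, "g00", axis="genes") == []
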