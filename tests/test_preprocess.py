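"""Quantile normalization, median-polish summarization, %CV quality control."""

import numpy as np
import pandas as pd
import pytest

from microtc.design import Sample, SampleSet
from microtc.errors import MatrixFormatError
from microtc.matrix import ExpressionMatrix
from microtc.preprocess import (
    median_polish_summarize,
    qc_flag_samplesets,
    quantile_normalize,
    sampleset_stats,
)


def _em(arr, features=None, chips=None, scale="log2"):
    arr = np.asarray(arr, dtype=float)
    features = features or [f"f{i}" for i in range(arr.shape[0])]
    chips = chips or [f"c{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=features, columns=chips), scale=scale)


# ---- quantile normalization ----------------------------------------------


def test_quantile_hand_oracle():
    m = quantile_normalize(_em(np.array([[2, 4], [1, 3], [3, 8]])))
    np.testing.assert_allclose(m.values.to_numpy(), [[3, 3], [2, 2], [5.5, 5.5]])


def test_permuted_columns_are_a_fixed_point():
    vals = np.array([[5.0, 2.0, 9.0], [2.0, 9.0, 5.0], [9.0, 5.0, 2.0]])
    m = quantile_normalize(_em(vals))
    for j in range(3):
        assert sorted(m.values.iloc[:, j]) == [2.0, 5.0, 9.0]
    np.testing.assert_allclose(m.values.to_numpy(), vals)


def test_column_means_equal_after_normalization():
    rng = np.random.default_rng(0)
    m = quantile_normalize(_em(rng.normal(8, 2, (50, 5))))
    means = m.values.mean(axis=0).to_numpy()
    np.testing.assert_allclose(means, means[0])


def test_idempotence():
    rng = np.random.default_rng(1)
    once = quantile_normalize(_em(rng.normal(0, 1, (30, 4))))
    twice = quantile_normalize(once)
    np.testing.assert_allclose(twice.values.to_numpy(), once.values.to_numpy(), atol=1e-12)


def test_single_chip_rejected():
    with pytest.raises(MatrixFormatError, match="2 chips"):
        quantile_normalize(_em([[1.0], [2.0]]))


def test_ties_get_average_of_tied_quantile_means():
    # column 0 has a tie at value 1; tied entries share the mean of quantile means 1 and 2
    m = quantile_normalize(_em(np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])))
    col0 = m.values.iloc[:, 0].to_numpy()
    assert col0[0] == col0[1]
    mq = np.sort(np.array([[1, 1, 5], [10, 20, 30]]), axis=1).mean(axis=0)
    assert col0[0] == pytest.approx((mq[0] + mq[1]) / 2)


# ---- median polish --------------------------------------------------------


def _oracle_polish(block, iters=20):
    resid = np.array(block, dtype=float)
    overall, row, col = 0.0, np.zeros(resid.shape[0]), np.zeros(resid.shape[1])
    for _ in range(iters):
        rm = np.median(resid, axis=1)
        row += rm
        resid -= rm[:, None]
        d = np.median(row)
        overall += d
        row -= d
        cm = np.median(resid, axis=0)
        col += cm
        resid -= cm[None, :]
        d = np.median(col)
        overall += d
        col -= d
    return overall, row, col, resid


def _summarize(block, membership_id="ps1", **kw):
    block = np.asarray(block, dtype=float)
    probes = [f"p{i}" for i in range(block.shape[0])]
    em = _em(block, features=probes)
    out = median_polish_summarize(em, {p: membership_id for p in probes}, **kw)
    return out.values.loc[membership_id].to_numpy()


def test_additive_block_gives_exact_chip_effects():
    np.testing.assert_allclose(_summarize([[1, 2], [3, 4]]), [2.0, 3.0])


def test_constant_probes_give_constant_chip_effect():
    np.testing.assert_allclose(_summarize(np.full((4, 3), 6.25)), [6.25] * 3)


def test_outlier_robustness_vs_oracle():
    rng = np.random.default_rng(5)
    row_eff = rng.normal(0, 0.5, 5)
    col_eff = np.array([0.0, 0.8, -0.3])
    clean = 7.0 + row_eff[:, None] + col_eff[None, :]
    dirty = clean.copy()
    dirty[2, 1] += 4.0  # single corrupted cell
    chip_clean = _summarize(clean)
    chip_dirty = _summarize(dirty)
    np.testing.assert_allclose(chip_dirty, chip_clean, atol=0.25)
    # and equals an independently coded polish
    overall, _row, col, resid = _oracle_polish(dirty)
    np.testing.assert_allclose(chip_dirty, overall + col, atol=1e-8)
    assert np.abs(np.median(resid, axis=0)).max() < 1e-8
    assert np.abs(np.median(resid, axis=1)).max() < 1e-8


def test_single_probe_set_passes_through_with_warning():
    em = _em([[1.0, 2.0], [3.0, 4.0]], features=["p0", "p1"])
    with pytest.warns(UserWarning, match="single probe"):
        out = median_polish_summarize(em, {"p0": "psA", "p1": "psB"})
    np.testing.assert_allclose(out.values.loc["psA"], [1.0, 2.0])


def test_unassigned_probe_rejected():
    em = _em([[1.0, 2.0]], features=["p0"])
    with pytest.raises(MatrixFormatError, match="membership"):
        median_polish_summarize(em, {})


# ---- sample-set statistics and %CV ---------------------------------------


def _sset(chips, name="s"):
    return SampleSet(name=name, members=[Sample(c, c) for c in chips])


def test_sampleset_stats_hand_arithmetic():
    em = _em([[8.0, 10.0, 12.0], [5.0, 5.0, 5.0]])
    s = sampleset_stats(em, _sset(["c0", "c1", "c2"]))
    assert s.mean["f0"] == pytest.approx(10.0)
    assert s.sd["f0"] == pytest.approx(2.0)  # sample SD, n-1
    assert s.percent_cv["f0"] == pytest.approx(20.0)
    assert s.percent_cv["f1"] == pytest.approx(0.0)
    assert s.mean_percent_cv == pytest.approx(10.0)


def test_mean_percent_cv_is_arithmetic_mean_over_features():
    # two features with %CV 10 and 30 -> mean 20
    em = _em([[10.0 - 1.0, 10.0 + 1.0], [10.0 - 3.0, 10.0 + 3.0]])
    s = sampleset_stats(em, _sset(["c0", "c1"]))
    cv = s.percent_cv.to_numpy()
    np.testing.assert_allclose(cv, [100 * np.std([9, 11], ddof=1) / 10, 100 * np.std([7, 13], ddof=1) / 10])
    assert s.mean_percent_cv == pytest.approx(cv.mean())


def test_percent_cv_scale_invariance_on_linear_scale():
    rng = np.random.default_rng(2)
    lin = rng.lognormal(6, 0.3, (20, 3))
    a = sampleset_stats(_em(lin, scale="linear"), _sset(["c0", "c1", "c2"]), cv_scale="linear")
    b = sampleset_stats(_em(lin * 37.5, scale="linear"), _sset(["c0", "c1", "c2"]), cv_scale="linear")
    np.testing.assert_allclose(a.percent_cv, b.percent_cv, rtol=1e-10)


def test_mean_matches_bruteforce_on_random_fixtures():
    rng = np.random.default_rng(3)
    arr = rng.normal(8, 1, (15, 4))
    s = sampleset_stats(_em(arr), _sset([f"c{j}" for j in range(4)]))
    np.testing.assert_allclose(s.mean.to_numpy(), [np.mean(r) for r in arr])
    np.testing.assert_allclose(s.sd.to_numpy(), [np.std(r, ddof=1) for r in arr])


def test_reciprocal_cv_definition_available():
    em = _em([[8.0, 10.0, 12.0]])
    s = sampleset_stats(em, _sset(["c0", "c1", "c2"]), cv_definition="mean_over_sd")
    assert s.percent_cv["f0"] == pytest.approx(100 * 10.0 / 2.0)


def _summary(name, cv):
    from microtc.preprocess import SampleSetSummary

    empty = pd.Series(dtype=float)
    return SampleSetSummary(name, empty, empty, empty, cv)


def test_qc_flagging_thresholds():
    flags = qc_flag_samplesets([_summary("ok", 3.0), _summary("bad", 16.0)], threshold=4.68)
    assert flags == [("ok", 3.0, False), ("bad", 16.0, True)]
    flags = qc_flag_samplesets([_summary("bad", 16.0)], threshold=np.inf)
    assert flags[0][2] is False
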