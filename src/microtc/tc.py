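"""Treatment-over-control (T/C) pairs and per-feature ratio statistics.

A T/C pairs a treatment sample set against a control sample set whose
factor profiles differ in *exactly one* factor, with the control side
holding that factor's declared control level.  Recasting every experiment
as T/Cs gives heterogeneous designs a common shape, and the log2 ratio

    LOG2R (M) = mean log2 intensity(treatment) − mean log2 intensity(control)

cancels systematic effects shared by both sides.  Alongside M, each
feature gets A = (mean_t + mean_c)/2 (MA-plot x-axis), the fold change
2^M, and a two-sample two-tailed t-test P value over the replicate log2
intensities (Welch by default, pooled variance optionally).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .design import FactorDecl, SampleSet
from .errors import DesignError, UnreplicatedError
from .matrix import ExpressionMatrix

#: Columns of a T/C statistics table (one row per feature).
TC_STAT_COLUMNS = ["mean_t", "mean_c", "log2r", "a_value", "fold", "t_stat", "p_value", "degenerate"]


@dataclass(frozen=True)
class TCPair:
    """A treatment/control contrast between two sample sets."""

    tc_id: str
    name: str
    treatment: SampleSet
    control: SampleSet
    differing_factor: str = ""
    description: str = ""


def _profile_diff(a: dict[str, str], b: dict[str, str]) -> list[str]:
    keys = set(a) | set(b)
    return [k for k in keys if a.get(k) != b.get(k)]


def enumerate_tcs(sample_sets: list[SampleSet], factors: dict[str, FactorDecl]) -> list[TCPair]:
    """Enumerate all T/C pairs implied by the single-differing-factor rule.

    A pair (treatment, control) qualifies iff the two profiles differ in
    exactly one factor, the control side holds that factor's declared
    control level, and the treatment side does not.  Treatment levels are
    contrasted only against the control level, never against each other;
    level-vs-level contrasts must be declared explicitly in the design.

    The output order is deterministic: sorted by differing factor, then
    that factor's treatment-level index, then the shared profile.
    """
    for f in factors.values():
        if f.control_level not in f.levels:  # FactorDecl already enforces; belt and braces
            raise DesignError(f"factor {f.name!r} has no valid control level")
    pairs = []
    for treat, ctrl in itertools.permutations(sample_sets, 2):
        diff = _profile_diff(treat.profile, ctrl.profile)
        if len(diff) != 1:
            continue
        factor = diff[0]
        if factor not in factors:
            raise DesignError(f"profiles differ on undeclared factor {factor!r}")
        decl = factors[factor]
        if ctrl.profile.get(factor) != decl.control_level:
            continue
        if treat.profile.get(factor) == decl.control_level:
            continue
        pairs.append(
            TCPair(
                tc_id=f"{treat.name}__vs__{ctrl.name}",
                name=f"{treat.name} vs {ctrl.name}",
                treatment=treat,
                control=ctrl,
                differing_factor=factor,
            )
        )

    def sort_key(tc: TCPair):
        decl = factors[tc.differing_factor]
        shared = tuple(
            sorted((f, lvl) for f, lvl in tc.treatment.profile.items() if f != tc.differing_factor)
        )
        return (
            tc.differing_factor,
            decl.level_index(tc.treatment.profile[tc.differing_factor]),
            shared,
        )

    pairs.sort(key=sort_key)
    return pairs


def resolve_declared_tcs(design) -> list[TCPair]:
    """Turn a design's explicit T/C declarations into TCPair objects."""
    out = []
    for d in design.tcs:
        treat = design.sample_set(d.treatment)
        ctrl = design.sample_set(d.control)
        diff = _profile_diff(treat.profile, ctrl.profile)
        out.append(
            TCPair(
                tc_id=f"{treat.name}__vs__{ctrl.name}",
                name=d.name,
                treatment=treat,
                control=ctrl,
                differing_factor=diff[0] if len(diff) == 1 else "",
                description=d.description,
            )
        )
    return out


class TTestResult(NamedTuple):
    t_stat: float
    p_value: float
    df: float
    degenerate: bool = False


def welch_ttest(x, y, equal_var: bool = False) -> TTestResult:
    """Two-sample two-tailed t-test (Welch by default).

    Degenerate inputs where both groups have zero variance are resolved
    deterministically: equal means give (t=0, P=1); unequal means give
    P=0 with the ``degenerate`` flag set (the difference is real but no
    variance estimate exists).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise UnreplicatedError("t-test needs >=2 replicates per group")
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    if v1 == 0.0 and v2 == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, 1.0, float(n1 + n2 - 2), False)
        return TTestResult(math.copysign(math.inf, diff), 0.0, float(n1 + n2 - 2), True)
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
    else:
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    t = diff / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(float(t), p, float(df), False)


def compute_tc_stats(matrix: ExpressionMatrix, tc: TCPair, equal_var: bool = False) -> pd.DataFrame:
    """Per-feature ratio statistics for one T/C.

    Returns a DataFrame indexed by feature ID with columns
    ``mean_t, mean_c, log2r, a_value, fold, t_stat, p_value, degenerate``.
    The t-test runs on the log2-scale replicate intensities of the two
    sample sets (vectorized over features).
    """
    for side in (tc.treatment, tc.control):
        if len(side.members) < 2:
            raise UnreplicatedError(
                f"T/C {tc.tc_id!r}: sample set {side.name!r} is unreplicated"
            )
    log2m = matrix.to_log2()
    xt = log2m.subset_chips(tc.treatment.chip_columns).values.to_numpy(dtype=float)
    xc = log2m.subset_chips(tc.control.chip_columns).values.to_numpy(dtype=float)
    n1, n2 = xt.shape[1], xc.shape[1]
    mean_t, mean_c = xt.mean(axis=1), xc.mean(axis=1)
    v1, v2 = xt.var(axis=1, ddof=1), xc.var(axis=1, ddof=1)
    diff = mean_t - mean_c
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
            df = np.full_like(se, float(n1 + n2 - 2))
        else:
            se = np.sqrt(v1 / n1 + v2 / n2)
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        t = diff / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_se = se == 0.0
    degenerate = zero_se & (diff != 0.0)
    with np.errstate(invalid="ignore"):
        t = np.where(zero_se, np.where(diff == 0.0, 0.0, np.sign(diff) * np.inf), t)
        p = np.where(zero_se, np.where(diff == 0.0, 1.0, 0.0), p)
    return pd.DataFrame(
        {
            "mean_t": mean_t,
            "mean_c": mean_c,
            "log2r": diff,
            "a_value": (mean_t + mean_c) / 2.0,
            "fold": np.power(2.0, diff),
            "t_stat": t,
            "p_value": p,
            "degenerate": degenerate,
        },
        index=log2m.values.index,
    )


def fold_from_log2r(log2r: float) -> float:
    """Fold change 2^LOG2R (values < 1 denote down-regulation)."""
    return float(np.power(2.0, log2r))


def log2r_from_fold(fold: float) -> float:
    """Inverse of :func:`fold_from_log2r`; fold must be > 0."""
    if fold <= 0:
        raise ValueError("fold change must be positive")
    return float(np.log2(fold))


def signed_fold(log2r: float) -> float:
    """Display convention: 2^M for M>=0, −2^−M (=−1/fold) for M<0."""
    f = fold_from_log2r(log2r)
    return f if f >= 1.0 else -1.0 / f


def write_tc_stats_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="feature_id", float_format="%.10g")
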