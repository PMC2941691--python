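"""Within-experiment normalization, summarization and replicate QC.

The normalization stage makes chips of one experiment comparable:

* :func:`quantile_normalize` forces every chip onto the common
  distribution of across-chip mean order statistics (the normalization
  component of RMA-style preprocessing).
* :func:`median_polish_summarize` collapses probe-level matrices to
  probe-set level with Tukey's median polish, reporting the fitted chip
  effects (overall + column effects) — the robust summarization
  component.

Replicate quality is monitored per sample set by the mean percentage
coefficient of variation (%CV): per feature, ``100·SD/mean`` over the
replicate chips, averaged over all features.  Sample sets whose mean %CV
exceeds a threshold (default 4.68, the upper edge of the bulk of the
compendium-wide distribution; the long tail runs up to ~16) are flagged
as probable poor quality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .design import SampleSet
from .errors import MatrixFormatError
from .matrix import ExpressionMatrix

#: Default mean-%CV QC threshold: upper bound of the range most
#: replicate sets fall in (0.5–4.68); the poor-quality tail reaches ~16.
DEFAULT_CV_THRESHOLD = 4.68


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize chips so every column shares one distribution.

    Each column's values are replaced by the across-chip mean of the
    order statistics at their rank; within-column rank order is
    preserved.  Ties receive the mean of the tied quantile means
    ("ties=average").

    Raises
    ------
    MatrixFormatError
        If the matrix has a single chip (nothing to normalize against).
    """
    if matrix.shape[1] < 2:
        raise MatrixFormatError("quantile normalization needs at least 2 chips")
    arr = matrix.values.to_numpy(dtype=float)
    n = arr.shape[0]
    mean_quantiles = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    grid = np.arange(n, dtype=float)
    for j in range(arr.shape[1]):
        # average ranks -> fractional positions into the mean-quantile vector
        ranks = rankdata(arr[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, grid, mean_quantiles)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        scale=matrix.scale,
    )


def _median_polish_block(block: np.ndarray, max_iter: int, tol: float) -> np.ndarray:
    """Tukey median polish of one probes × chips block; returns overall + column effects."""
    resid = block.astype(float).copy()
    overall = 0.0
    row_eff = np.zeros(block.shape[0])
    col_eff = np.zeros(block.shape[1])
    for _ in range(max_iter):
        rmed = np.median(resid, axis=1)
        row_eff += rmed
        resid -= rmed[:, None]
        cmed_r = np.median(row_eff)
        overall += cmed_r
        row_eff -= cmed_r
        cmed = np.median(resid, axis=0)
        col_eff += cmed
        resid -= cmed[None, :]
        rmed_c = np.median(col_eff)
        overall += rmed_c
        col_eff -= rmed_c
        if np.abs(rmed).max(initial=0.0) < tol and np.abs(cmed).max(initial=0.0) < tol:
            break
    return overall + col_eff


def median_polish_summarize(
    probe_matrix: ExpressionMatrix,
    membership: dict[str, str],
    max_iter: int = 10,
    tol: float = 1e-6,
) -> ExpressionMatrix:
    """Summarize a log2 probe-level matrix to probe-set level.

    ``membership`` maps every probe ID to its probe-set ID.  Each probe
    set's block is fitted with an additive model (overall + probe + chip
    effects) by median polish; the returned matrix holds overall + chip
    effects per probe set.  Single-probe sets pass through unchanged with
    a warning.
    """
    missing = [p for p in probe_matrix.feature_ids if p not in membership]
    if missing:
        raise MatrixFormatError(f"probe(s) without probe-set membership: {missing[:5]}")
    if probe_matrix.scale != "log2":
        probe_matrix = probe_matrix.to_log2()
    arr = probe_matrix.values
    groups: dict[str, list[str]] = {}
    for probe in probe_matrix.feature_ids:
        groups.setdefault(membership[probe], []).append(probe)
    out_rows = {}
    for ps_id in sorted(groups):
        probes = groups[ps_id]
        block = arr.loc[probes].to_numpy(dtype=float)
        if block.shape[0] == 1:
            warnings.warn(f"probe set {ps_id!r} has a single probe; passed through unchanged")
            out_rows[ps_id] = block[0]
        else:
            out_rows[ps_id] = _median_polish_block(block, max_iter=max_iter, tol=tol)
    df = pd.DataFrame.from_dict(out_rows, orient="index", columns=arr.columns)
    return ExpressionMatrix(df.sort_index(), scale="log2")


@dataclass
class SampleSetSummary:
    """Per-feature replicate statistics and the scalar mean %CV of one sample set."""

    name: str
    mean: pd.Series
    sd: pd.Series
    percent_cv: pd.Series
    mean_percent_cv: float


def sampleset_stats(
    matrix: ExpressionMatrix,
    sample_set: SampleSet,
    cv_definition: str = "sd_over_mean",
    cv_scale: str = "log2",
) -> SampleSetSummary:
    """Per-feature mean, sample SD (n−1) and %CV over one sample set's chips.

    ``cv_definition="sd_over_mean"`` is the standard ``100·SD/mean``;
    ``"mean_over_sd"`` is provided for compatibility with the reciprocal
    reading some sources print.  ``cv_scale`` picks the intensity scale
    the %CV is computed on (the mean/SD columns always report the
    canonical log2 scale).
    """
    if cv_definition not in ("sd_over_mean", "mean_over_sd"):
        raise ValueError(f"unknown cv_definition {cv_definition!r}")
    if cv_scale not in ("log2", "linear"):
        raise ValueError(f"unknown cv_scale {cv_scale!r}")
    if len(sample_set.members) < 2:
        raise MatrixFormatError(f"sample set {sample_set.name!r} has <2 members")
    log2m = matrix.to_log2()
    sub = log2m.subset_chips(sample_set.chip_columns).values
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    if cv_scale == "log2":
        cv_mean, cv_sd = mean, sd
    else:
        lin = np.power(2.0, sub)
        cv_mean, cv_sd = lin.mean(axis=1), lin.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if cv_definition == "sd_over_mean":
            cv = 100.0 * cv_sd / cv_mean
        else:
            cv = 100.0 * cv_mean / cv_sd
    cv = cv.replace([np.inf, -np.inf], np.nan)
    return SampleSetSummary(
        name=sample_set.name,
        mean=mean,
        sd=sd,
        percent_cv=cv,
        mean_percent_cv=float(cv.mean(skipna=True)),
    )


def qc_flag_samplesets(
    summaries: list[SampleSetSummary], threshold: float = DEFAULT_CV_THRESHOLD
) -> list[tuple[str, float, bool]]:
    """Flag sample sets whose mean %CV exceeds ``threshold``."""
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    return [(s.name, s.mean_percent_cv, s.mean_percent_cv > threshold) for s in summaries]


def write_summary_tsv(summaries: list[SampleSetSummary], path, threshold: float = DEFAULT_CV_THRESHOLD) -> None:
    rows = [
        {"sample_set": n, "mean_percent_cv": cv, "flagged": fl}
        for n, cv, fl in qc_flag_samplesets(summaries, threshold)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
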