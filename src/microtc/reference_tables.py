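"""Curated reference tables packaged with the toolkit.

Two tables transcribed from a published 301-experiment Arabidopsis
T/C compendium serve as ground-truth fixtures:

* ``pr1_induction_tcs.tsv`` — the 95 T/Cs reported to up-regulate the
  pathogenesis-related gene PR-1 at the standard double cutoff
  (fold ≥ 2, P < 0.05), with treatment classification, fold change and
  t-test P value.
* ``pseudomonas16h_coregulation.tsv`` — the published co-regulation
  table for the "16 hr Pseudomonas infection" T/C: per related T/C its
  regulated-gene count (B), overlapping-gene count (C), displayed
  overlap percentage (floored), Pearson correlation coefficient and
  relation index.

The reference T/C's own regulated-gene count is not published; it is
recovered by inverting the top row's relation-index equation
``RI = (2C/(N+B))·CC²`` and is exposed as
:data:`PSEUDOMONAS16H_N_REF` (= 381) — a derived fixture constant, not a
published number.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Derived reference-set size for "16 hr Pseudomonas infection":
#: N = 2·277·0.982917²/0.623816 − 477, rounded to the nearest integer.
PSEUDOMONAS16H_N_REF = 381


def _load(name: str) -> pd.DataFrame:
    with resources.files("microtc.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_pr1_induction_table() -> pd.DataFrame:
    """The PR-1 up-regulation T/C list (columns: tc_name, treatment_type,
    fold_change, p_value)."""
    return _load("pr1_induction_tcs.tsv")


def load_coregulation_table() -> pd.DataFrame:
    """The 16 hr Pseudomonas infection co-regulation T/C list (columns:
    tc_name, classification, n_genes, n_overlap, op_printed, cc, ri_printed)."""
    return _load("pseudomonas16h_coregulation.tsv")


def derive_reference_set_size(row=None) -> int:
    """Re-derive N for the reference T/C by inverting a co-regulation row.

    By default the top row (24 hr Pseudomonas infection) is used:
    solving ``RI = (2·C/(N+B))·CC²`` for N.
    """
    if row is None:
        row = load_coregulation_table().iloc[0]
    cc2 = float(row["cc"]) ** 2
    n = 2.0 * float(row["n_overlap"]) * cc2 / float(row["ri_printed"]) - float(row["n_genes"])
    return int(round(n))
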