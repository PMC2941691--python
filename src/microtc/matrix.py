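"""Expression matrices: the features × chips tables all statistics run on.

An :class:`ExpressionMatrix` wraps a pandas DataFrame whose rows are
microarray features (probes or probe sets) and whose columns are chips
(hybridized arrays).  Values carry an explicit scale declaration —
``"log2"`` or ``"linear"`` — and the canonical internal scale is log2
intensity, matching the convention of RMA-style normalization output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import MatrixFormatError

VALID_SCALES = ("log2", "linear")


class ExpressionMatrix:
    """A validated features × chips numeric table.

    Parameters
    ----------
    values
        DataFrame with feature IDs as the index and chip IDs as columns.
    scale
        ``"log2"`` (canonical) or ``"linear"``.  Linear values must be
        strictly positive so that a log2 transform is always defined.

    Raises
    ------
    MatrixFormatError
        On duplicate labels, non-numeric or non-finite cells, empty
        tables, or non-positive linear intensities.
    """

    def __init__(self, values: pd.DataFrame, scale: str = "log2"):
        if scale not in VALID_SCALES:
            raise MatrixFormatError(f"unknown scale {scale!r}; expected one of {VALID_SCALES}")
        if values.shape[0] == 0 or values.shape[1] == 0:
            raise MatrixFormatError("empty expression matrix")
        dup_f = values.index[values.index.duplicated()].unique()
        if len(dup_f):
            raise MatrixFormatError(f"duplicate feature ID(s): {list(map(str, dup_f))}")
        dup_c = values.columns[values.columns.duplicated()].unique()
        if len(dup_c):
            raise MatrixFormatError(f"duplicate chip ID(s): {list(map(str, dup_c))}")
        numeric = values.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna()
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise MatrixFormatError(
                f"non-numeric or missing cell at feature {values.index[r]!r}, "
                f"chip {values.columns[c]!r}"
            )
        arr = numeric.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise MatrixFormatError(
                f"non-finite value at feature {values.index[r]!r}, chip {values.columns[c]!r}"
            )
        if scale == "linear" and (arr <= 0).any():
            r, c = np.argwhere(arr <= 0)[0]
            raise MatrixFormatError(
                f"non-positive linear intensity at feature {values.index[r]!r}, "
                f"chip {values.columns[c]!r}"
            )
        self.values = pd.DataFrame(arr, index=values.index.astype(str), columns=values.columns.astype(str))
        self.scale = scale

    # -- basic introspection -------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def chip_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        f, c = self.shape
        return f"ExpressionMatrix({f} features x {c} chips, scale={self.scale})"

    # -- transforms ----------------------------------------------------------

    def to_log2(self) -> "ExpressionMatrix":
        """Return the matrix on log2 scale (identity if already log2)."""
        if self.scale == "log2":
            return self
        return ExpressionMatrix(np.log2(self.values), scale="log2")

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale == "linear":
            return self
        return ExpressionMatrix(np.power(2.0, self.values), scale="linear")

    def subset_chips(self, chips: list[str]) -> "ExpressionMatrix":
        missing = [c for c in chips if c not in self.values.columns]
        if missing:
            raise MatrixFormatError(f"chip(s) not in matrix: {missing}")
        return ExpressionMatrix(self.values[chips], scale=self.scale)

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.scale == other.scale and self.values.equals(other.values)

    # -- I/O -----------------------------------------------------------------

    def write_tsv(self, path) -> None:
        """Write as TSV: row 1 = chip IDs, column 1 = feature IDs."""
        self.values.to_csv(path, sep="\t", index_label="feature_id", float_format="%.10g")


def read_expression_matrix(path, orientation: str = "row-features", scale: str = "log2") -> ExpressionMatrix:
    """Read a tab-separated expression table.

    ``orientation="row-features"`` expects features as rows (the on-disk
    convention of this package); ``"row-chips"`` transposes chip-per-row
    tables on load.
    """
    if orientation not in ("row-features", "row-chips"):
        raise MatrixFormatError(f"unknown orientation {orientation!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise MatrixFormatError(f"empty expression matrix file: {path}") from exc
    if orientation == "row-chips":
        df = df.T
    return ExpressionMatrix(df, scale=scale)
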