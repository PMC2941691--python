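"""Reader for GEO SOFT series-matrix files (local-file ingestion).

A series-matrix file carries ``!``-prefixed metadata lines (sample titles,
characteristics) and one expression table delimited by
``!series_matrix_table_begin`` / ``!series_matrix_table_end``.  The reader
returns the table as an :class:`~microtc.matrix.ExpressionMatrix` plus one
:class:`~microtc.design.Sample` per chip, carrying the title and
characteristics text so it can feed the full-text search index.
"""

from __future__ import annotations

import pandas as pd

from .design import Sample
from .errors import SoftFormatError
from .matrix import ExpressionMatrix

TABLE_BEGIN = "!series_matrix_table_begin"
TABLE_END = "!series_matrix_table_end"


def _unquote(tok: str) -> str:
    tok = tok.strip()
    if len(tok) >= 2 and tok[0] == '"' and tok[-1] == '"':
        tok = tok[1:-1]
    return tok


def read_soft_series_matrix(path, scale: str = "log2") -> tuple[ExpressionMatrix, list[Sample]]:
    """Parse a SOFT series-matrix file.

    Returns the expression matrix and the samples with their
    ``!Sample_title`` and ``!Sample_characteristics*`` annotations joined
    into each sample's description.
    """
    meta: dict[str, list[list[str]]] = {}
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.strip() == TABLE_BEGIN:
                if saw_begin:
                    raise SoftFormatError("duplicate table-begin marker")
                saw_begin, in_table = True, True
                continue
            if line.strip() == TABLE_END:
                if not in_table:
                    raise SoftFormatError("table-end marker before table-begin")
                saw_end, in_table = True, False
                continue
            if in_table:
                if line.strip():
                    table_lines.append(line)
            elif line.startswith("!"):
                key, _, rest = line.partition("\t")
                meta.setdefault(key[1:], []).append([_unquote(t) for t in rest.split("\t")])
    if not saw_begin:
        raise SoftFormatError(f"{path}: missing {TABLE_BEGIN} marker")
    if not saw_end:
        raise SoftFormatError(f"{path}: missing {TABLE_END} marker")
    if not table_lines:
        raise SoftFormatError(f"{path}: empty expression table")

    header = [_unquote(t) for t in table_lines[0].split("\t")]
    ncol = len(header)
    rows = []
    index = []
    for line in table_lines[1:]:
        cells = [_unquote(t) for t in line.split("\t")]
        if len(cells) != ncol:
            raise SoftFormatError(
                f"row {cells[0]!r}: {len(cells)} columns, header has {ncol}"
            )
        index.append(cells[0])
        rows.append(cells[1:])
    df = pd.DataFrame(rows, index=index, columns=header[1:])
    matrix = ExpressionMatrix(df, scale=scale)

    chip_ids = matrix.chip_ids
    titles = meta.get("Sample_title", [[]])[0]
    char_lines = [v for k, vals in meta.items() if k.startswith("Sample_characteristics") for v in vals]
    samples = []
    for i, chip in enumerate(chip_ids):
        parts = []
        if i < len(titles) and titles[i]:
            parts.append(titles[i])
        for chars in char_lines:
            if i < len(chars) and chars[i]:
                parts.append(chars[i])
        samples.append(Sample(sample_id=chip, chip_column=chip, description="; ".join(parts)))
    return matrix, samples
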