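"""Co-responsive genes and co-regulation T/Cs via the relation index.

The ratio compendium is a genes × T/Cs matrix of LOG2R values with
matching P values.  Along either axis, an entity's *regulation set* is
picked by a double cutoff — |fold| ≥ ``fold_min`` (default 2) and
P < ``p_max`` (default 0.05) — split into up- and down-regulated members.
Two entities are related through three quantities:

* **OP**, the overlap percentage: the Sørensen–Dice percentage of their
  regulation sets, ``100 · 2·|A∩B| / (|A| + |B|)``;
* **CC**, the Pearson correlation of their LOG2R values over the
  overlapped items only;
* **RI**, the relation index ``(OP/100) · CC²`` ∈ [0, 1], by which
  related genes (co-responsive) or T/Cs (co-regulation) are ranked.

Squaring CC makes anti-correlated partners rank as highly as correlated
ones — a strong negative relation is as informative as a positive one —
while OP caps the index by the fraction of shared regulated items.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MicrotcError

#: Double-cutoff defaults: at least 2-fold change with P < 0.05.
DEFAULT_FOLD_MIN = 2.0
DEFAULT_P_MAX = 0.05
#: Pearson correlation over fewer than 3 points is unstable; relations
#: with a smaller overlap are skipped by default.
DEFAULT_MIN_OVERLAP = 3


@dataclass(frozen=True)
class RegulationSet:
    """Up-/down-regulated item sets of one gene or T/C under a double cutoff."""

    owner: str
    up: frozenset
    down: frozenset
    fold_min: float = DEFAULT_FOLD_MIN
    p_max: float = DEFAULT_P_MAX

    @property
    def all(self) -> frozenset:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


@dataclass
class RelationRecord:
    """One scored relation between a reference entity and a candidate."""

    ref_id: str
    other_id: str
    n_ref: int
    n_other: int
    n_overlap: int
    overlap_percentage: float
    correlation: float
    relation_index: float
    classification: str = ""

    @property
    def op_floor(self) -> int:
        """OP as displayed: floored to an integer."""
        return int(math.floor(self.overlap_percentage))


def select_regulated(
    stats: pd.DataFrame,
    fold_min: float = DEFAULT_FOLD_MIN,
    p_max: float = DEFAULT_P_MAX,
    owner: str = "",
) -> RegulationSet:
    """Apply the double cutoff to a stats slice (columns ``log2r``, ``p_value``).

    Membership is |LOG2R| ≥ log2(fold_min) — sign deciding up vs down —
    together with P strictly below ``p_max``.
    """
    if not fold_min >= 1:
        raise ValueError("fold_min must be >= 1")
    if not (0 < p_max <= 1):
        raise ValueError("p_max must be in (0, 1]")
    thr = math.log2(fold_min)
    sig = stats["p_value"] < p_max
    up = frozenset(stats.index[sig & (stats["log2r"] >= thr)])
    down = frozenset(stats.index[sig & (stats["log2r"] <= -thr)])
    if thr == 0.0:
        down = down - up  # fold_min=1 would place M=0 items in both
    return RegulationSet(owner=owner, up=up, down=down, fold_min=fold_min, p_max=p_max)


def overlap_percentage(set_ref: RegulationSet, set_other: RegulationSet) -> tuple[int, float]:
    """Sørensen–Dice overlap of two regulation sets, in percent.

    Uses the union of up and down members on each side (sign-blind), so
    anti-correlated partners — whose up set overlaps the other's down
    set — still overlap.
    """
    n_ref, n_other = len(set_ref), len(set_other)
    if n_ref + n_other == 0:
        raise MicrotcError("overlap percentage undefined: both regulation sets empty")
    n_overlap = len(set_ref.all & set_other.all)
    return n_overlap, op_from_counts(n_ref, n_other, n_overlap)


def op_from_counts(n_ref: int, n_other: int, n_overlap: int) -> float:
    """OP = 100·2C/(N_ref+N_other) from bare set sizes."""
    if n_ref + n_other <= 0:
        raise MicrotcError("overlap percentage undefined for empty sets")
    if n_overlap > min(n_ref, n_other):
        raise ValueError("overlap larger than one of the sets")
    return 100.0 * 2.0 * n_overlap / (n_ref + n_other)


def overlapped_correlation(ref_values, other_values) -> float | None:
    """Pearson correlation of two LOG2R vectors aligned on the overlap items.

    Returns ``None`` (relation skipped) when fewer than 2 points or
    either vector has zero variance.
    """
    x = np.asarray(ref_values, dtype=float)
    y = np.asarray(other_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("overlap vectors must be aligned")
    if len(x) < 2:
        return None
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt((xc**2).sum()))
    sy = float(np.sqrt((yc**2).sum()))
    if sx == 0.0 or sy == 0.0:
        return None
    return float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))


def relation_index(op: float, cc: float, cc_exponent: int = 2) -> float:
    """RI = (OP/100)·CC^cc_exponent.

    The default exponent 2 makes RI sign-blind in CC and bounded in
    [0, 1]; ``cc_exponent=1`` preserves the signed alternative.
    """
    if not (0.0 <= op <= 100.0):
        raise ValueError("OP must be in [0, 100]")
    if not (-1.0 <= cc <= 1.0):
        raise ValueError("CC must be in [-1, 1]")
    return (op / 100.0) * cc**cc_exponent


class RatioUniverse:
    """The genes × T/Cs LOG2R/P compendium all relation queries run on."""

    def __init__(self, log2r: pd.DataFrame, p_value: pd.DataFrame):
        if not (log2r.index.equals(p_value.index) and log2r.columns.equals(p_value.columns)):
            raise MicrotcError("log2r and p_value tables must share axes (genes x T/Cs)")
        self.log2r = log2r
        self.p_value = p_value

    @classmethod
    def from_tc_tables(cls, tables: dict[str, pd.DataFrame]) -> "RatioUniverse":
        """Assemble from per-T/C stats tables (as from ``compute_tc_stats``)."""
        if not tables:
            raise MicrotcError("no T/C tables given")
        log2r = pd.DataFrame({tc: t["log2r"] for tc, t in tables.items()})
        p = pd.DataFrame({tc: t["p_value"] for tc, t in tables.items()})
        return cls(log2r, p)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.log2r.index)

    @property
    def tc_ids(self) -> list[str]:
        return list(self.log2r.columns)

    def slice(self, axis: str, entity_id: str) -> pd.DataFrame:
        """LOG2R/P slice for one entity: per-T/C rows for a gene, per-gene rows for a T/C."""
        if axis == "genes":
            if entity_id not in self.log2r.index:
                raise KeyError(f"unknown gene {entity_id!r}")
            return pd.DataFrame(
                {"log2r": self.log2r.loc[entity_id], "p_value": self.p_value.loc[entity_id]}
            )
        if axis == "tcs":
            if entity_id not in self.log2r.columns:
                raise KeyError(f"unknown T/C {entity_id!r}")
            return pd.DataFrame(
                {"log2r": self.log2r[entity_id], "p_value": self.p_value[entity_id]}
            )
        raise ValueError(f"axis must be 'genes' or 'tcs', got {axis!r}")

    def regulation_set(self, axis: str, entity_id: str, fold_min=DEFAULT_FOLD_MIN, p_max=DEFAULT_P_MAX) -> RegulationSet:
        return select_regulated(self.slice(axis, entity_id), fold_min, p_max, owner=entity_id)


def relate(
    universe: RatioUniverse,
    axis: str,
    ref_id: str,
    other_id: str,
    fold_min: float = DEFAULT_FOLD_MIN,
    p_max: float = DEFAULT_P_MAX,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    cc_exponent: int = 2,
) -> RelationRecord | None:
    """Score one (ref, other) relation; ``None`` when OP or CC is undefined."""
    rs_ref = universe.regulation_set(axis, ref_id, fold_min, p_max)
    rs_other = universe.regulation_set(axis, other_id, fold_min, p_max)
    return _relate_sets(universe, axis, rs_ref, rs_other, min_overlap, cc_exponent)


def _relate_sets(universe, axis, rs_ref, rs_other, min_overlap, cc_exponent) -> RelationRecord | None:
    if len(rs_ref) + len(rs_other) == 0:
        return None
    overlap = rs_ref.all & rs_other.all
    if len(overlap) < max(min_overlap, 2):
        return None
    items = sorted(overlap)
    if axis == "genes":
        ref_vec = universe.log2r.loc[rs_ref.owner, items]
        other_vec = universe.log2r.loc[rs_other.owner, items]
    else:
        ref_vec = universe.log2r.loc[items, rs_ref.owner]
        other_vec = universe.log2r.loc[items, rs_other.owner]
    cc = overlapped_correlation(ref_vec, other_vec)
    if cc is None:
        return None
    op = op_from_counts(len(rs_ref), len(rs_other), len(overlap))
    return RelationRecord(
        ref_id=rs_ref.owner,
        other_id=rs_other.owner,
        n_ref=len(rs_ref),
        n_other=len(rs_other),
        n_overlap=len(overlap),
        overlap_percentage=op,
        correlation=cc,
        relation_index=relation_index(op, cc, cc_exponent),
    )


def rank_relations(
    universe: RatioUniverse,
    ref_id: str,
    axis: str = "genes",
    fold_min: float = DEFAULT_FOLD_MIN,
    p_max: float = DEFAULT_P_MAX,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    cc_exponent: int = 2,
    top_k: int | None = None,
) -> list[RelationRecord]:
    """All defined relations of ``ref_id``, ranked by relation index.

    ``axis="genes"`` finds co-responsive genes (overlap over T/Cs,
    correlation over the shared T/Cs); ``axis="tcs"`` finds
    co-regulation T/Cs (overlap and correlation over shared genes).
    Sorted by RI descending, ties by CC² descending then candidate ID.
    """
    rs_ref = universe.regulation_set(axis, ref_id, fold_min, p_max)
    if len(rs_ref) == 0:
        import warnings

        warnings.warn(f"reference {ref_id!r} has an empty regulation set; no relations")
        return []
    candidates = universe.gene_ids if axis == "genes" else universe.tc_ids
    records = []
    for other in candidates:
        if other == ref_id:
            continue
        rs_other = universe.regulation_set(axis, other, fold_min, p_max)
        rec = _relate_sets(universe, axis, rs_ref, rs_other, min_overlap, cc_exponent)
        if rec is not None:
            records.append(rec)
    records.sort(key=lambda r: (-r.relation_index, -r.correlation**2, r.other_id))
    return records[:top_k] if top_k is not None else records


def relations_to_frame(records: list[RelationRecord]) -> pd.DataFrame:
    """Tabular export mirroring the display columns (floored OP, full-precision CC/RI)."""
    return pd.DataFrame(
        [
            {
                "other_id": r.other_id,
                "classification": r.classification,
                "n_other": r.n_other,
                "n_overlap": r.n_overlap,
                "op_floor": r.op_floor,
                "correlation": r.correlation,
                "relation_index": r.relation_index,
            }
            for r in records
        ]
    )


def write_edge_list(records: list[RelationRecord], path) -> None:
    """Edge-list export (ref, other, RI, CC) for network tools."""
    pd.DataFrame(
        [
            {"ref_id": r.ref_id, "other_id": r.other_id, "relation_index": r.relation_index, "correlation": r.correlation}
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
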