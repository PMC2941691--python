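"""MA-plot rendering and the 2-layer display artifacts.

Each plot is produced twice: a static raster (the overview layer, default
480 × 480 px PNG) and a machine-readable overlay (JSON lines, one record
per point with data coordinates, pixel coordinates and color class) from
which an interactive layer can highlight, label or select points without
re-plotting.  Point color encodes the t-test P value: blue for P < 0.01,
green for 0.01 ≤ P ≤ 0.05, yellow for P > 0.05.

Slide decks render an ordered list of MA plots on shared axis ranges, so
the same item's position is comparable from slide to slide, with one
persistent highlighted set chosen on the first slide.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import pandas as pd
from matplotlib.figure import Figure

from .errors import MicrotcError

COLOR_HEX = {"blue": "#1f4fd8", "green": "#2ca02c", "yellow": "#e6c700"}


def significance_color(p: float) -> str:
    """Color class of a P value: blue <0.01, green 0.01–0.05 (inclusive), yellow >0.05."""
    if not (0.0 <= p <= 1.0) or math.isnan(p):
        raise ValueError(f"P value out of [0, 1]: {p!r}")
    if p < 0.01:
        return "blue"
    if p <= 0.05:
        return "green"
    return "yellow"


@dataclass(frozen=True)
class MAPoint:
    """One point of an MA plot: a T/C (Gene View) or a gene (T/C View)."""

    item_id: str
    a_value: float
    log2r: float
    p_value: float

    @property
    def color_class(self) -> str:
        return significance_color(self.p_value)


@dataclass(frozen=True)
class PlotStyle:
    width_px: int = 480
    height_px: int = 480
    dpi: int = 96
    a_range: tuple[float, float] | None = None
    m_range: tuple[float, float] | None = None
    point_size: float = 9.0
    title: str = ""

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("plot dimensions must be positive")


@dataclass(frozen=True)
class HighlightWindow:
    """Inclusive rectangle in data coordinates; infinite bounds leave an edge open."""

    a_min: float = -math.inf
    a_max: float = math.inf
    m_min: float = -math.inf
    m_max: float = math.inf

    def __post_init__(self):
        if self.a_min > self.a_max or self.m_min > self.m_max:
            raise ValueError("window bounds inverted")

    def contains(self, point: MAPoint) -> bool:
        return (self.a_min <= point.a_value <= self.a_max) and (
            self.m_min <= point.log2r <= self.m_max
        )


def ma_points_for_gene(gene: str, tc_tables: dict[str, pd.DataFrame]) -> list[MAPoint]:
    """Gene View points: one per T/C in which the gene is measured."""
    points = []
    for tc_id in tc_tables:
        table = tc_tables[tc_id]
        if gene in table.index:
            row = table.loc[gene]
            points.append(MAPoint(tc_id, float(row["a_value"]), float(row["log2r"]), float(row["p_value"])))
    if not points:
        raise MicrotcError(f"gene {gene!r} measured in no T/C")
    return points


def ma_points_for_tc(tc_id: str, table: pd.DataFrame) -> list[MAPoint]:
    """T/C View points: one per gene, (A, M, P) passed through from the stats table."""
    return [
        MAPoint(str(g), float(r["a_value"]), float(r["log2r"]), float(r["p_value"]))
        for g, r in table.iterrows()
    ]


def select_in_window(points: list[MAPoint], window: HighlightWindow) -> list[MAPoint]:
    """Points inside the (inclusive) highlight window."""
    return [p for p in points if window.contains(p)]


def _axis_ranges(points: list[MAPoint], style: PlotStyle) -> tuple[tuple[float, float], tuple[float, float]]:
    def padded(lo: float, hi: float) -> tuple[float, float]:
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        pad = 0.05 * (hi - lo)
        return lo - pad, hi + pad

    if style.a_range is not None:
        a_rng = style.a_range
    elif points:
        a_rng = padded(min(p.a_value for p in points), max(p.a_value for p in points))
    else:
        a_rng = (0.0, 1.0)
    if style.m_range is not None:
        m_rng = style.m_range
    elif points:
        m_rng = padded(min(p.log2r for p in points), max(p.log2r for p in points))
    else:
        m_rng = (-1.0, 1.0)
    return a_rng, m_rng


def render_ma_plot(
    points: list[MAPoint],
    style: PlotStyle,
    out: str,
    overlay_out: str | None = None,
    highlighted: set[str] | None = None,
) -> tuple[str, str | None]:
    """Render the static raster and its machine-readable point overlay.

    The raster is exactly ``style.width_px × style.height_px``.  The
    overlay (JSON lines) records, per point: item_id, data coordinates
    (a, m), P value, pixel coordinates (origin top-left), color class and
    highlight state — everything an interactive second layer needs.
    """
    highlighted = highlighted or set()
    fig = Figure(figsize=(style.width_px / style.dpi, style.height_px / style.dpi), dpi=style.dpi)
    ax = fig.add_axes((0.13, 0.11, 0.83, 0.81))
    a_rng, m_rng = _axis_ranges(points, style)
    ax.set_xlim(*a_rng)
    ax.set_ylim(*m_rng)
    ax.axhline(0.0, color="0.6", linewidth=0.7, zorder=1)
    for color in ("yellow", "green", "blue"):
        xs = [p.a_value for p in points if p.color_class == color]
        ys = [p.log2r for p in points if p.color_class == color]
        if xs:
            ax.scatter(xs, ys, s=style.point_size, c=COLOR_HEX[color], linewidths=0, zorder=2)
    hl = [p for p in points if p.item_id in highlighted]
    if hl:
        ax.scatter(
            [p.a_value for p in hl],
            [p.log2r for p in hl],
            s=style.point_size * 6,
            facecolors="none",
            edgecolors="red",
            marker="s",
            linewidths=0.9,
            zorder=3,
        )
    ax.set_xlabel("A (average log2 intensity)", fontsize=8)
    ax.set_ylabel("M (LOG2R)", fontsize=8)
    if style.title:
        ax.set_title(style.title, fontsize=9)
    ax.tick_params(labelsize=7)
    fig.savefig(out, dpi=style.dpi)

    if overlay_out is not None:
        trans = ax.transData
        with open(overlay_out, "w") as fh:
            for p in points:
                px, py = trans.transform((p.a_value, p.log2r))
                fh.write(
                    json.dumps(
                        {
                            "item_id": p.item_id,
                            "a": p.a_value,
                            "m": p.log2r,
                            "p": p.p_value,
                            "px": round(float(px), 3),
                            "py": round(float(style.height_px) - float(py), 3),
                            "color": p.color_class,
                            "highlighted": p.item_id in highlighted,
                        },
                        sort_keys=True,
                    )
                    + "\n"
                )
    return out, overlay_out


def overlay_transform(points: list[MAPoint], style: PlotStyle):
    """The data→pixel transform used by :func:`render_ma_plot` (for round-trip checks)."""
    fig = Figure(figsize=(style.width_px / style.dpi, style.height_px / style.dpi), dpi=style.dpi)
    ax = fig.add_axes((0.13, 0.11, 0.83, 0.81))
    a_rng, m_rng = _axis_ranges(points, style)
    ax.set_xlim(*a_rng)
    ax.set_ylim(*m_rng)
    return ax.transData


@dataclass
class SlideDeck:
    """Ordered MA plots sharing one persistent highlighted item set."""

    slides: list[tuple[str, list[MAPoint]]]
    selection: set[str] = field(default_factory=set)
    style: PlotStyle = field(default_factory=PlotStyle)


def build_slides(
    slides: list[tuple[str, list[MAPoint]]],
    selection_window: HighlightWindow,
    style: PlotStyle | None = None,
) -> SlideDeck:
    """Build a deck whose highlight set is chosen by a window on slide 1.

    Axis ranges are fixed across all slides (global data extent), so an
    item's movement between slides is positionally meaningful.
    """
    if not slides:
        raise MicrotcError("a slide deck needs at least one slide")
    style = style or PlotStyle()
    selection = {p.item_id for p in select_in_window(slides[0][1], selection_window)}
    all_points = [p for _, pts in slides for p in pts]
    a_rng, m_rng = _axis_ranges(all_points, PlotStyle(a_range=style.a_range, m_range=style.m_range))
    return SlideDeck(slides=list(slides), selection=selection, style=replace(style, a_range=a_rng, m_range=m_rng))


def render_slide_deck(deck: SlideDeck, outdir) -> list[tuple[str, str]]:
    """Render every slide plus overlay; selected items missing from a slide
    are recorded in that slide's overlay as ``missing`` rather than dropped."""
    import os

    os.makedirs(outdir, exist_ok=True)
    outputs = []
    for i, (plot_id, points) in enumerate(deck.slides, start=1):
        img = os.path.join(outdir, f"slide{i:02d}_{plot_id}.png")
        ovl = os.path.join(outdir, f"slide{i:02d}_{plot_id}.overlay.jsonl")
        style = replace(deck.style, title=plot_id)
        render_ma_plot(points, style, img, ovl, highlighted=deck.selection)
        present = {p.item_id for p in points}
        absent = sorted(deck.selection - present)
        if absent:
            with open(ovl, "a") as fh:
                for item in absent:
                    fh.write(json.dumps({"item_id": item, "missing": True, "highlighted": True}, sort_keys=True) + "\n")
        outputs.append((img, ovl))
    return outputs
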