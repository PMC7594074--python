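"""The FAIR balloon plot.

Use cases are rows, the 15 indicators are columns. Mark size encodes the
score, color the FAIR category (Findable blue, Accessible red,
Interoperable green, Reusable orange), shape the retrieval mode: circles
for automatically determined indicators, diamonds for manual ones, crosses
for indicators not assessed. Cells with a missing value (qualitative
"unclear") draw nothing.

No composite FAIR score is computed anywhere — the plot compares indicator
by indicator, by design.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import matplotlib
matplotlib.use("Agg")  # headless; must precede pyplot
import matplotlib.pyplot as plt
from matplotlib.lines import Line2D

import yaml

from .assessment import AssessmentMatrix
from .errors import ConfigurationError
from .indicators import CANONICAL_ORDER, FairCategory, RetrievalMode

__all__ = ["MarkSpec", "PlotStyle", "layout_marks", "render", "plot_matrix"]


@dataclass(frozen=True)
class MarkSpec:
    """One drawable mark of the balloon plot."""

    row_index: int
    col_index: int
    size: Optional[float]  # the score; None for crosses
    shape: str  # circle | diamond | cross
    category: FairCategory
    use_case: str = ""
    indicator_code: str = ""


_SHAPE_BY_MODE = {
    RetrievalMode.AUTOMATIC: "circle",
    RetrievalMode.MANUAL: "diamond",
    RetrievalMode.NOT_ASSESSED: "cross",
}

_MARKERS = {"circle": "o", "diamond": "D", "cross": "x"}


@dataclass(frozen=True)
class PlotStyle:
    """Colors and mark scaling. Hues are choices, not constants of nature."""

    category_colors: dict = field(default_factory=lambda: {
        "Findable": "#1f77b4",       # blue
        "Accessible": "#d62728",     # red
        "Interoperable": "#2ca02c",  # green
        "Reusable": "#ff7f0e",       # orange
    })
    min_area: float = 30.0    # pt^2 at score 0 — zero stays visible
    max_area: float = 330.0   # pt^2 at score 1
    cross_area: float = 60.0
    cell_inches: float = 0.55

    def color(self, category: FairCategory) -> str:
        return self.category_colors[category.value]

    def area(self, score: float) -> float:
        # strictly increasing in the score
        return self.min_area + (self.max_area - self.min_area) * score

    @classmethod
    def from_file(cls, path: str) -> "PlotStyle":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown style keys {sorted(unknown)}; known: {sorted(known)}")
        if "category_colors" in data:
            base = cls().category_colors | dict(data["category_colors"])
            data["category_colors"] = base
        return cls(**data)


def layout_marks(matrix: AssessmentMatrix) -> list[MarkSpec]:
    """One mark per assessed cell, in canonical row-major order.

    Missing cells (value absent but not "not assessed") emit no mark.
    """
    marks: list[MarkSpec] = []
    for row_index, row in enumerate(matrix.rows):
        for col_index, indicator in enumerate(CANONICAL_ORDER):
            score = row.scores[indicator]
            if score.is_missing:
                continue
            shape = _SHAPE_BY_MODE[score.mode]
            marks.append(MarkSpec(
                row_index=row_index,
                col_index=col_index,
                size=score.value,
                shape=shape,
                category=indicator.category,
                use_case=row.use_case,
                indicator_code=indicator.code,
            ))
    return marks


def render(marks: list[MarkSpec], destination: str,
           image_format: Optional[str] = None,
           style: Optional[PlotStyle] = None,
           n_rows: Optional[int] = None,
           row_labels: Optional[list[str]] = None) -> str:
    """Draw marks to a PNG or SVG file; deterministic for fixed input/style.

    Returns the written path.
    """
    if not marks:
        raise ConfigurationError("nothing to draw: empty mark list")
    style = style or PlotStyle()
    fmt = (image_format
           or os.path.splitext(destination)[1].lstrip(".") or "png").lower()

    n_rows = n_rows or (max(m.row_index for m in marks) + 1)
    n_cols = len(CANONICAL_ORDER)
    if row_labels is None:
        labels = [""] * n_rows
        for mark in marks:
            if mark.use_case:
                labels[mark.row_index] = mark.use_case
        row_labels = labels

    # reproducible SVG ids
    plt.rcParams["svg.hashsalt"] = "fairmi"

    fig, ax = plt.subplots(
        figsize=(n_cols * style.cell_inches + 2.8,
                 n_rows * style.cell_inches + 1.6))
    for mark in marks:
        y = n_rows - 1 - mark.row_index  # first use case on top
        color = style.color(mark.category)
        if mark.shape == "cross":
            ax.scatter([mark.col_index], [y], s=style.cross_area,
                       marker=_MARKERS["cross"], color=color, linewidths=1.5)
        else:
            ax.scatter([mark.col_index], [y],
                       s=style.area(mark.size if mark.size is not None else 0),
                       marker=_MARKERS[mark.shape], color=color,
                       edgecolors="none", alpha=0.9)

    ax.set_xticks(range(n_cols))
    ax.set_xticklabels([i.code for i in CANONICAL_ORDER])
    ax.set_yticks(range(n_rows))
    ax.set_yticklabels(list(reversed(row_labels)))
    ax.set_xlim(-0.7, n_cols - 0.3)
    ax.set_ylim(-0.7, n_rows - 0.3)
    for spine in ax.spines.values():
        spine.set_visible(False)
    ax.tick_params(length=0)
    ax.grid(True, linestyle=":", linewidth=0.5, alpha=0.5)
    ax.set_axisbelow(True)

    legend_elements = [
        Line2D([0], [0], marker="o", linestyle="", label=cat.value,
               markerfacecolor=style.color(cat), markeredgecolor="none",
               markersize=9)
        for cat in FairCategory
    ] + [
        Line2D([0], [0], marker=_MARKERS["circle"], linestyle="",
               color="gray", label="automatic", markersize=8),
        Line2D([0], [0], marker=_MARKERS["diamond"], linestyle="",
               color="gray", label="manual", markersize=7),
        Line2D([0], [0], marker=_MARKERS["cross"], linestyle="",
               color="gray", label="not assessed", markersize=8),
    ]
    ax.legend(handles=legend_elements, loc="center left",
              bbox_to_anchor=(1.01, 0.5), frameon=False, fontsize=8)
    fig.tight_layout()

    try:
        # strip timestamps so identical inputs give identical bytes
        metadata = {"Date": None} if fmt == "svg" else None
        fig.savefig(destination, format=fmt, dpi=150, metadata=metadata,
                    bbox_inches="tight")
    except OSError as exc:
        raise IOError(f"cannot write image to {destination!r}: {exc}") from exc
    finally:
        plt.close(fig)
    return destination


def plot_matrix(matrix: AssessmentMatrix, destination: str,
                image_format: Optional[str] = None,
                style: Optional[PlotStyle] = None) -> str:
    """Convenience: layout + render in one call."""
    return render(layout_marks(matrix), destination, image_format, style,
                  n_rows=len(matrix), row_labels=list(matrix.use_cases))
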