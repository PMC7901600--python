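"""Text rendering and transparency reports.

A computed measure encapsulates the perspective chain of its derivation;
communicating it transparently means explicating that chain. This module
renders tables, trees and cell-role icons as deterministic plain text,
and turns a :class:`~fourfold.metrics.MetricValue` into a
:class:`TransparencyReport` whose step list can be replayed to reproduce
the reported value and whose ``lost_information`` names everything the
derivation dropped (the population size at normalization, the margins at
conditionalization).

Output is plain text plus structured JSON "viz specs"; no pixels are
produced here, because transparency is a property of explicated
structure, not of a particular graphic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from ._markers import Undefined, is_undefined
from .grid import TreeProjection
from .metrics import IconSpec, MetricValue, _evaluate, resolve
from .tables import (
    FrequencyTable2x2,
    ProbabilityTable2x2,
    enumerate_layouts,
    margins,
    round_half_away,
)

__all__ = [
    "IconSpec",
    "TransparencyReport",
    "render_matrix",
    "render_tree",
    "render_icon",
    "transparency_report",
    "format_percent",
    "format_number",
    "matrix_viz_spec",
    "tree_viz_spec",
]


def format_percent(value: float, decimals: int = 1) -> str:
    """Format a probability as a percentage, halves rounding away from zero
    (so 0.0776 prints as '7.8%' and 0.4957 as '50%' at zero decimals)."""
    scale = 10 ** decimals
    scaled = round_half_away(value * 100 * scale) / scale
    return f"{scaled:.{decimals}f}%"


def format_number(value, decimals: int = 3) -> str:
    if is_undefined(value):
        return f"undefined ({value.reason})"
    if isinstance(value, Fraction) and value.denominator == 1:
        return str(int(value))
    if isinstance(value, int):
        return str(value)
    scale = 10 ** decimals
    return f"{round_half_away(float(value) * scale) / scale:.{decimals}f}"


# ---------------------------------------------------------------------------
# matrices


def _cell_text(v, probability: bool) -> str:
    if is_undefined(v):
        return "--"
    if probability:
        return format_number(float(v), 3)
    return format_number(v, 3) if isinstance(v, Fraction) and v.denominator != 1 else str(int(v))


def render_matrix(table, layout_index: int = 0, show: tuple[str, ...] = ("margins",)) -> str:
    """Fixed-width text rendering of one of the eight layout variants.

    ``show`` may contain ``"margins"`` (append row/column sums and the
    grand total) and/or ``"diagonals"`` (append the two diagonal sums).
    Byte-identical output for identical inputs.
    """
    if not 0 <= layout_index <= 7:
        raise ValueError("layout_index must lie in 0..7")
    probability = isinstance(table, ProbabilityTable2x2)
    layout = enumerate_layouts(table)[layout_index]
    (tl, tr), (bl, br) = layout.grid
    with_margins = "margins" in show
    rows = []
    header = ["", *(f"{layout.col_dim}={c}" for c in layout.col_categories)]
    if with_margins:
        header.append("sum")
    rows.append(header)
    grid_rows = [(layout.row_categories[0], tl, tr), (layout.row_categories[1], bl, br)]
    for cat, left, right in grid_rows:
        row = [f"{layout.row_dim}={cat}", _cell_text(left, probability),
               _cell_text(right, probability)]
        if with_margins:
            row.append(_cell_text(left + right, probability))
        rows.append(row)
    if with_margins:
        total = tl + tr + bl + br
        rows.append(
            ["sum", _cell_text(tl + bl, probability), _cell_text(tr + br, probability),
             _cell_text(total, probability)]
        )
    widths = [max(len(r[i]) for r in rows) for i in range(len(rows[0]))]
    lines = ["  ".join(cell.rjust(w) for cell, w in zip(r, widths)) for r in rows]
    if "diagonals" in show:
        main, off = margins(table, "diagonal")
        lines.append(
            f"diagonals: main={_cell_text(main, probability)} "
            f"off={_cell_text(off, probability)}"
        )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# trees


def render_tree(tree: TreeProjection) -> str:
    """Two-level frequency tree: root N, the first-branch margins, and the
    four leaves, each edge labelled with its category."""
    lines = [f"root: {_cell_text(tree.root, False)}"]
    for i, cat in enumerate(tree.branch_categories):
        branch_prefix = "├─" if i == 0 else "└─"
        child_prefix = "│  " if i == 0 else "   "
        lines.append(
            f"{branch_prefix} {tree.first_branch}={cat}: "
            f"{_cell_text(tree.level1[i], False)}"
        )
        for j in (0, 1):
            leaf_index = 2 * i + j
            leaf_cat = tree.leaf_categories[leaf_index][1]
            twig = "├─" if j == 0 else "└─"
            lines.append(
                f"{child_prefix}{twig} {tree.second_branch}={leaf_cat}: "
                f"{_cell_text(tree.leaves[leaf_index], False)}"
            )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# icons

#: stable role-to-glyph mapping for the 2x2 cell icons
_GLYPHS = {"numerator": "#", "denominator_only": "o", "ignored": "."}


def render_icon(icon: IconSpec) -> str:
    """Compact two-line glyph: '#' numerator, 'o' denominator-only,
    '.' ignored, in canonical a b / c d positions."""
    r = icon.roles
    return (
        f"{_GLYPHS[r['a']]}{_GLYPHS[r['b']]}\n"
        f"{_GLYPHS[r['c']]}{_GLYPHS[r['d']]}"
    )


# ---------------------------------------------------------------------------
# transparency reports


@dataclass(frozen=True)
class TransparencyReport:
    """The explicated derivation chain of one reported measure."""

    metric: str
    steps: tuple
    lost_information: tuple[str, ...]
    value: float | Undefined
    value_formatted: str
    icon_text: str = ""

    def replay(self) -> float | Undefined:
        """Re-execute the recorded steps and return the resulting value."""
        frame_step = next(s for s in self.steps if s["step"] == "frame")
        if frame_step.get("kind") == "PartialTable":
            raise ValueError("partial-table reports replay through problems.solve")
        cells = frame_step["cells"]
        from .tables import default_frame, FrequencyTable2x2

        table = FrequencyTable2x2.__new__(FrequencyTable2x2)
        object.__setattr__(table, "a", cells["a"])
        object.__setattr__(table, "b", cells["b"])
        object.__setattr__(table, "c", cells["c"])
        object.__setattr__(table, "d", cells["d"])
        object.__setattr__(table, "frame", default_frame())
        object.__setattr__(table, "meta", {})
        return _evaluate(table, resolve(self.metric))

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "steps": [dict(s) for s in self.steps],
            "lost_information": list(self.lost_information),
            "value": None if is_undefined(self.value) else self.value,
            "value_formatted": self.value_formatted,
            "icon": self.icon_text,
        }


_PERSPECTIVE_LOSS = {
    "by_row": "prevalence and bias margins dropped at by_row conditionalization",
    "by_column": "prevalence and bias margins dropped at by_column conditionalization",
    "by_diagonal": "cell-level distinctions within each diagonal dropped at "
    "by_diagonal aggregation",
}


def transparency_report(value: MetricValue) -> TransparencyReport:
    """Explicate how a measure was derived and what was lost on the way.

    Raises if the value carries no provenance (i.e. was not computed
    through the pipeline).
    """
    if not value.provenance:
        raise ValueError(
            "metric value has no provenance; compute it through the pipeline"
        )
    focus = next((s for s in value.provenance if s["step"] == "focus"), None)
    frame_step = next((s for s in value.provenance if s["step"] == "frame"), None)
    if focus is None or frame_step is None:
        raise ValueError("provenance misses a frame or focus step")
    lost: list[str] = []
    denominator = set(focus.get("denominator", []))
    is_probability_source = frame_step.get("kind") == "ProbabilityTable2x2"
    normalizes = denominator == {"a", "b", "c", "d"} or focus.get("components")
    if is_probability_source or normalizes or focus.get("perspective"):
        lost.append("population size N dropped at normalization")
    perspective = focus.get("perspective")
    if perspective in _PERSPECTIVE_LOSS:
        lost.append(_PERSPECTIVE_LOSS[perspective])
    if not denominator and not focus.get("components"):
        lost = []  # a raw cell or margin readout loses nothing
    formatted = (
        f"undefined ({value.value.reason})"
        if is_undefined(value.value)
        else format_percent(value.value)
        if 0.0 <= value.value <= 1.0
        else format_number(value.value)
    )
    return TransparencyReport(
        metric=value.metric,
        steps=value.provenance,
        lost_information=tuple(lost),
        value=value.value,
        value_formatted=formatted,
        icon_text=render_icon(value.icon) if value.icon else "",
    )


# ---------------------------------------------------------------------------
# structured viz specs


def matrix_viz_spec(table) -> dict:
    """JSON-ready description of a table for downstream graphics."""
    spec = table.to_dict()
    spec["type"] = (
        "probability_matrix" if isinstance(table, ProbabilityTable2x2)
        else "frequency_matrix"
    )
    spec["margins"] = {
        axis: [float(v) for v in margins(table, axis)]
        for axis in ("row", "column", "diagonal")
    }
    return spec


def tree_viz_spec(tree: TreeProjection) -> dict:
    return {
        "type": "frequency_tree",
        "first_branch": tree.first_branch,
        "second_branch": tree.second_branch,
        "root": float(tree.root),
        "level1": [float(v) for v in tree.level1],
        "leaves": [float(v) for v in tree.leaves],
        "branch_categories": list(tree.branch_categories),
        "leaf_categories": [list(pair) for pair in tree.leaf_categories],
    }
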