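"""2x2 contingency tables and their elementary transformations.

The central object is a fourfold table of joint frequency counts

    =========  =========
    a (y+,x+)  b (y+,x-)
    c (y-,x+)  d (y-,x-)
    =========  =========

whose columns carry one binary dimension (conventionally the *true
condition*, ``C`` vs ``nC``) and whose rows carry a second one (the *test
outcome*, ``T`` vs ``nT``). The canonical orientation puts the
positive-by-positive cell top-left; every other spatial arrangement is a
derived view (:func:`enumerate_layouts`).

Three normalizations are supported: dividing the four cells by the grand
total ``N`` yields joint probabilities (:func:`normalize`); dividing by
row, column, or diagonal margins yields conditional probabilities under
the corresponding *perspective* (:func:`conditionalize`). Each lossy step
records what it dropped (the population size, the margins) so that the
inverse transformations (:func:`denormalize`, :func:`reconstruct`) can
rebuild the original table when that information is resupplied.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from numbers import Rational
from typing import Mapping

from ._markers import Undefined, is_defined

__all__ = [
    "Dimension",
    "FrameSpec",
    "Perspective",
    "FrequencyTable2x2",
    "ProbabilityTable2x2",
    "ConditionalTable",
    "PartialTable",
    "LayoutVariant",
    "from_counts",
    "from_probability_format",
    "normalize",
    "denormalize",
    "conditionalize",
    "reconstruct",
    "enumerate_layouts",
    "margins",
    "round_half_away",
    "PROB_TOL",
]

#: Absolute tolerance for probability identities.
PROB_TOL = 1e-9


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (so 95.5 -> 96)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# frames


@dataclass(frozen=True)
class Dimension:
    """A binary dimension: a label and an ordered pair of category labels."""

    label: str
    categories: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.categories) != 2 or self.categories[0] == self.categories[1]:
            raise ValueError(
                f"dimension {self.label!r} needs exactly two distinct categories, "
                f"got {self.categories!r}"
            )

    def other(self, category: str) -> str:
        if category == self.categories[0]:
            return self.categories[1]
        if category == self.categories[1]:
            return self.categories[0]
        raise KeyError(f"{category!r} is not a category of dimension {self.label!r}")


@dataclass(frozen=True)
class FrameSpec:
    """Which two dimensions a table crosses, and which categories are positive.

    ``dim_x`` labels the columns, ``dim_y`` the rows. ``domain_tag``
    optionally names the semantic domain (``"diagnostics"``,
    ``"classification"``, ``"information_retrieval"``, ``"risk"``,
    ``"treatment"``, ...) used for metric-alias resolution.
    """

    dim_x: Dimension
    dim_y: Dimension
    positive_x: str
    positive_y: str
    domain_tag: str | None = None

    def __post_init__(self) -> None:
        if self.positive_x not in self.dim_x.categories:
            raise ValueError(
                f"positive_x={self.positive_x!r} is not a category of {self.dim_x.label!r}"
            )
        if self.positive_y not in self.dim_y.categories:
            raise ValueError(
                f"positive_y={self.positive_y!r} is not a category of {self.dim_y.label!r}"
            )

    @property
    def negative_x(self) -> str:
        return self.dim_x.other(self.positive_x)

    @property
    def negative_y(self) -> str:
        return self.dim_y.other(self.positive_y)

    def transposed(self) -> "FrameSpec":
        return FrameSpec(
            dim_x=self.dim_y,
            dim_y=self.dim_x,
            positive_x=self.positive_y,
            positive_y=self.positive_x,
            domain_tag=self.domain_tag,
        )


def default_frame(domain_tag: str | None = "diagnostics") -> FrameSpec:
    """The condition-by-test frame used throughout the documentation."""
    return FrameSpec(
        dim_x=Dimension("condition", ("C", "nC")),
        dim_y=Dimension("test", ("T", "nT")),
        positive_x="C",
        positive_y="T",
        domain_tag=domain_tag,
    )


class Perspective(str, enum.Enum):
    """Direction of conditionalization on a 2x2 matrix."""

    BY_ROW = "by_row"
    BY_COLUMN = "by_column"
    BY_DIAGONAL = "by_diagonal"


class Axis(str, enum.Enum):
    ROW = "row"
    COLUMN = "column"
    DIAGONAL = "diagonal"


# ---------------------------------------------------------------------------
# tables


class _CellAccess:
    """Shared semantic (label-aware) cell addressing for 2x2 tables."""

    a: object
    b: object
    c: object
    d: object
    frame: FrameSpec

    def cells(self) -> tuple:
        return (self.a, self.b, self.c, self.d)

    def cell(self, x_category: str, y_category: str):
        """Look a cell up by its category labels, independent of layout."""
        f = self.frame
        xpos = x_category == f.positive_x
        ypos = y_category == f.positive_y
        if not xpos and x_category != f.negative_x:
            raise KeyError(f"{x_category!r} is not a category of {f.dim_x.label!r}")
        if not ypos and y_category != f.negative_y:
            raise KeyError(f"{y_category!r} is not a category of {f.dim_y.label!r}")
        if ypos:
            return self.a if xpos else self.b
        return self.c if xpos else self.d


@dataclass(frozen=True)
class FrequencyTable2x2(_CellAccess):
    """Four joint frequency counts in canonical orientation plus their frame.

    Cells are non-negative integers; exact non-integer rationals are
    accepted to support analytic (unrounded) expected frequencies.
    ``meta`` carries transform lineage (e.g. which cube axis framed this
    table) and never affects equality.
    """

    a: int | Fraction
    b: int | Fraction
    c: int | Fraction
    d: int | Fraction
    frame: FrameSpec
    meta: Mapping[str, object] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for name, v in zip("abcd", self.cells()):
            if not isinstance(v, Rational):
                raise TypeError(f"cell {name!r} must be an integer count, got {v!r}")
            if v < 0:
                raise ValueError(f"cell {name!r} must be non-negative, got {v!r}")

    @property
    def n(self):
        return self.a + self.b + self.c + self.d

    def margins(self, axis: Axis | str) -> tuple:
        return margins(self, axis)

    def with_meta(self, **meta: object) -> "FrequencyTable2x2":
        return replace(self, meta={**self.meta, **meta})

    def to_dict(self) -> dict:
        return {
            "frame": _frame_to_dict(self.frame),
            "cells": {"a": _num(self.a), "b": _num(self.b), "c": _num(self.c), "d": _num(self.d)},
        }


@dataclass(frozen=True)
class ProbabilityTable2x2(_CellAccess):
    """Four joint probabilities summing to one.

    ``n_origin`` records the population size dropped at normalization;
    it is required to map back to frequency counts.
    """

    a: float
    b: float
    c: float
    d: float
    frame: FrameSpec
    n_origin: int | None = None

    def __post_init__(self) -> None:
        for name, v in zip("abcd", self.cells()):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"cell {name!r} must lie in [0, 1], got {v!r}")
        total = sum(self.cells())
        if abs(total - 1.0) > PROB_TOL:
            raise ValueError(f"joint probabilities must sum to 1, got {total!r}")

    def margins(self, axis: Axis | str) -> tuple:
        return margins(self, axis)

    def to_dict(self) -> dict:
        return {
            "frame": _frame_to_dict(self.frame),
            "cells": {"a": self.a, "b": self.b, "c": self.c, "d": self.d},
            "n_origin": self.n_origin,
        }


@dataclass(frozen=True)
class ConditionalTable(_CellAccess):
    """A 2x2 of conditional probabilities tagged with its perspective.

    ``margins`` stores the pair of normalizing sums (as probabilities)
    dropped during conditionalization, keyed to the perspective, so the
    joint table can be rebuilt. A zero normalization group leaves its
    cells as :class:`Undefined` markers.
    """

    a: float | Undefined
    b: float | Undefined
    c: float | Undefined
    d: float | Undefined
    perspective: Perspective
    margins: tuple[float, float]
    frame: FrameSpec

    def __post_init__(self) -> None:
        for pair in self._groups():
            vals = [v for v in pair if is_defined(v)]
            if len(vals) == len(pair):
                s = sum(vals)
                if abs(s - 1.0) > PROB_TOL:
                    raise ValueError(
                        f"conditional group {pair!r} must sum to 1 under "
                        f"{self.perspective.value}, got {s!r}"
                    )

    def _groups(self) -> tuple[tuple, tuple]:
        if self.perspective is Perspective.BY_ROW:
            return ((self.a, self.b), (self.c, self.d))
        if self.perspective is Perspective.BY_COLUMN:
            return ((self.a, self.c), (self.b, self.d))
        return ((self.a, self.d), (self.b, self.c))


# cell/margin identifiers admitted by PartialTable, with the linear
# constraints tying them together (each id = sum of elementary cells).
_PARTIAL_IDS: dict[str, frozenset[str]] = {
    "a": frozenset("a"),
    "b": frozenset("b"),
    "c": frozenset("c"),
    "d": frozenset("d"),
    "row_pos": frozenset("ab"),
    "row_neg": frozenset("cd"),
    "col_pos": frozenset("ac"),
    "col_neg": frozenset("bd"),
    "diag_main": frozenset("ad"),
    "diag_off": frozenset("bc"),
    "n": frozenset("abcd"),
}


class PartialTable:
    """A 2x2 table with only some cells or margins known.

    Encodes under-determined problem statements (e.g. a short-menu format
    that states only the top row and the grand total). Insertions are
    checked eagerly: a value that contradicts what is already derivable
    is rejected. :meth:`get` returns the value of any cell or margin that
    the known facts determine, else ``None``.
    """

    def __init__(self, frame: FrameSpec, known: Mapping[str, float] | None = None):
        self.frame = frame
        self._known: dict[str, float] = {}
        for key, value in (known or {}).items():
            self.set(key, value)

    def set(self, key: str, value: float) -> None:
        if key not in _PARTIAL_IDS:
            raise KeyError(f"unknown cell/margin identifier {key!r}")
        if value < 0:
            raise ValueError(f"{key!r} must be non-negative, got {value!r}")
        current = self.get(key)
        if current is not None and abs(current - value) > PROB_TOL:
            raise ValueError(
                f"{key!r}={value!r} contradicts the derivable value {current!r}"
            )
        self._known[key] = value
        self._closure()

    def get(self, key: str) -> float | None:
        if key not in _PARTIAL_IDS:
            raise KeyError(f"unknown cell/margin identifier {key!r}")
        return self._solve().get(key)

    def known_keys(self) -> set[str]:
        return {k for k, v in self._solve().items() if v is not None}

    def _closure(self) -> None:
        # raises on contradiction via _solve
        self._solve()

    def _solve(self) -> dict[str, float]:
        """Fixpoint propagation over the sum constraints."""
        cells: dict[str, float] = {}
        facts = dict(self._known)
        changed = True
        while changed:
            changed = False
            for key, members in _PARTIAL_IDS.items():
                if key in facts:
                    unknown = [m for m in members if m not in cells]
                    partial = sum(cells[m] for m in members if m in cells)
                    if not unknown:
                        if abs(partial - facts[key]) > PROB_TOL:
                            raise ValueError(
                                f"stored {key!r}={facts[key]!r} contradicts cells "
                                f"summing to {partial!r}"
                            )
                    elif len(unknown) == 1:
                        v = facts[key] - partial
                        if v < -PROB_TOL:
                            raise ValueError(
                                f"{key!r}={facts[key]!r} forces negative cell {unknown[0]!r}"
                            )
                        cells[unknown[0]] = max(v, 0.0)
                        changed = True
            # derive margin facts from completed cells
            for key, members in _PARTIAL_IDS.items():
                if key not in facts and all(m in cells for m in members):
                    facts[key] = sum(cells[m] for m in members)
                    changed = True
            # complementary margin pairs partition N
            for left, right in (("row_pos", "row_neg"), ("col_pos", "col_neg"),
                                ("diag_main", "diag_off")):
                if "n" in facts:
                    for key, other in ((left, right), (right, left)):
                        if key in facts and other not in facts:
                            v = facts["n"] - facts[key]
                            if v < -PROB_TOL:
                                raise ValueError(
                                    f"{key!r}={facts[key]!r} exceeds n={facts['n']!r}"
                                )
                            facts[other] = max(v, 0.0)
                            changed = True
                elif left in facts and right in facts:
                    facts["n"] = facts[left] + facts[right]
                    changed = True
        return facts


# ---------------------------------------------------------------------------
# constructors and transformations


def from_counts(a, b, c, d, frame: FrameSpec | None = None) -> FrequencyTable2x2:
    """Build a frequency table from the four joint counts."""
    frame = frame or default_frame()
    for name, v in zip("abcd", (a, b, c, d)):
        if isinstance(v, bool) or not isinstance(v, int):
            raise TypeError(f"cell {name!r} must be an integer count, got {v!r}")
        if v < 0:
            raise ValueError(f"cell {name!r} must be non-negative, got {v!r}")
    return FrequencyTable2x2(a, b, c, d, frame)


def from_probability_format(
    prevalence: float,
    sensitivity: float,
    false_positive_rate: float,
    n: int,
    rounding: str = "nearest",
    frame: FrameSpec | None = None,
) -> FrequencyTable2x2:
    """Reconstruct expected joint frequencies from a probability parameterization.

    ``nearest`` rounds half away from zero at each stage and then fills
    the remaining cell of each column so the column margins stay exact
    (the convention that turns an expected 95.04 false positives into 95
    while keeping the 990 condition-negative cases intact).
    ``exact_rational`` keeps every cell as an exact fraction.
    """
    frame = frame or default_frame()
    for name, p in (
        ("prevalence", prevalence),
        ("sensitivity", sensitivity),
        ("false_positive_rate", false_positive_rate),
    ):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p!r}")
    if n < 1 or not isinstance(n, int):
        raise ValueError(f"n must be a positive integer, got {n!r}")
    if rounding == "nearest":
        n_pos = round_half_away(n * prevalence)
        a = round_half_away(n_pos * sensitivity)
        b = round_half_away((n - n_pos) * false_positive_rate)
        c = n_pos - a
        d = (n - n_pos) - b
        return FrequencyTable2x2(a, b, c, d, frame)
    if rounding == "exact_rational":
        prev = Fraction(prevalence).limit_denominator(10**9)
        sens = Fraction(sensitivity).limit_denominator(10**9)
        fpr = Fraction(false_positive_rate).limit_denominator(10**9)
        a = n * prev * sens
        c = n * prev * (1 - sens)
        b = n * (1 - prev) * fpr
        d = n * (1 - prev) * (1 - fpr)
        return FrequencyTable2x2(a, b, c, d, frame)
    raise ValueError(f"rounding must be 'nearest' or 'exact_rational', got {rounding!r}")


def normalize(table: FrequencyTable2x2) -> ProbabilityTable2x2:
    """Divide the four counts by N, recording N as ``n_origin``."""
    n = table.n
    if n == 0:
        raise ValueError("cannot normalize an empty table (N = 0)")
    return ProbabilityTable2x2(
        float(table.a / n),
        float(table.b / n),
        float(table.c / n),
        float(table.d / n),
        frame=table.frame,
        n_origin=int(n) if isinstance(n, int) or n == int(n) else None,
    )


def denormalize(ptable: ProbabilityTable2x2, n: int) -> FrequencyTable2x2:
    """Rescale joint probabilities to counts for a population of size ``n``.

    Cells a, b, c round to nearest; d absorbs the residue so the grand
    total is exactly ``n`` (margin repair). Exact when the probabilities
    arise from counts dividing ``n`` evenly.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n!r}")
    a = round_half_away(ptable.a * n)
    b = round_half_away(ptable.b * n)
    c = round_half_away(ptable.c * n)
    d = n - a - b - c
    if d < 0:
        raise ValueError("rounding left no room for cell 'd'; choose a larger n")
    return FrequencyTable2x2(a, b, c, d, frame=ptable.frame)


def _group_divide(cells, groups, reasons):
    out = list(cells)
    sums = []
    for idx_pair, reason in zip(groups, reasons):
        s = sum(cells[i] for i in idx_pair)
        sums.append(s)
        for i in idx_pair:
            out[i] = float(cells[i] / s) if s != 0 else Undefined(reason)
    return out, sums


def conditionalize(
    table: FrequencyTable2x2 | ProbabilityTable2x2, perspective: Perspective | str
) -> ConditionalTable:
    """Divide cells by their row, column, or diagonal sums.

    The dropped margins are retained (as probabilities) for
    :func:`reconstruct`. Zero groups yield Undefined markers, never
    exceptions.
    """
    perspective = Perspective(perspective)
    cells = table.cells()
    f = table.frame
    if perspective is Perspective.BY_ROW:
        groups = ((0, 1), (2, 3))
        reasons = (
            f"zero margin: row {f.positive_y}",
            f"zero margin: row {f.negative_y}",
        )
    elif perspective is Perspective.BY_COLUMN:
        groups = ((0, 2), (1, 3))
        reasons = (
            f"zero margin: column {f.positive_x}",
            f"zero margin: column {f.negative_x}",
        )
    else:
        groups = ((0, 3), (1, 2))
        reasons = ("zero margin: main diagonal", "zero margin: off diagonal")
    out, sums = _group_divide(cells, groups, reasons)
    total = sum(cells)
    dropped = tuple(float(s / total) if total else 0.0 for s in sums)
    return ConditionalTable(
        out[0], out[1], out[2], out[3],
        perspective=perspective, margins=dropped, frame=f,
    )


def reconstruct(
    cond: ConditionalTable, margins: tuple[float, float] | None = None
) -> ProbabilityTable2x2:
    """Rebuild the joint probability table from conditionals plus margins.

    ``margins`` must be the pair of normalizing sums for the table's
    perspective (e.g. prevalence and its complement for ``by_column``);
    defaults to the pair stored at conditionalization time.
    """
    m = cond.margins if margins is None else tuple(margins)
    if len(m) != 2:
        raise ValueError(f"expected two margins for {cond.perspective.value}, got {m!r}")
    if abs(sum(m) - 1.0) > 1e-6:
        raise ValueError(f"margins must sum to 1, got {m!r}")
    groups = {
        Perspective.BY_ROW: ((0, 1), (2, 3)),
        Perspective.BY_COLUMN: ((0, 2), (1, 3)),
        Perspective.BY_DIAGONAL: ((0, 3), (1, 2)),
    }[cond.perspective]
    cells = [0.0, 0.0, 0.0, 0.0]
    for idx_pair, margin in zip(groups, m):
        for i in idx_pair:
            v = cond.cells()[i]
            if isinstance(v, Undefined):
                if margin > PROB_TOL:
                    raise ValueError(
                        f"cell {'abcd'[i]} is undefined but its margin is {margin!r}"
                    )
                cells[i] = 0.0
            else:
                cells[i] = v * margin
    return ProbabilityTable2x2(*cells, frame=cond.frame)


# ---------------------------------------------------------------------------
# layouts and margins


@dataclass(frozen=True)
class LayoutVariant:
    """One of the eight spatial arrangements of a 2x2 table.

    ``grid`` is the positional 2x2 cell matrix ((top-left, top-right),
    (bottom-left, bottom-right)); ``row_categories``/``col_categories``
    name what each position means, so semantic lookups stay invariant.
    """

    grid: tuple[tuple, tuple]
    row_dim: str
    col_dim: str
    row_categories: tuple[str, str]
    col_categories: tuple[str, str]
    transposed: bool
    x_reversed: bool
    y_reversed: bool
    source: FrequencyTable2x2

    def cell(self, x_category: str, y_category: str):
        """Label-aware access; equal across all eight variants."""
        return self.source.cell(x_category, y_category)


def enumerate_layouts(table: FrequencyTable2x2) -> list[LayoutVariant]:
    """All 2^3 = 8 arrangements: {transpose} x {reverse x} x {reverse y}."""
    f = table.frame
    variants = []
    for transposed in (False, True):
        for x_reversed in (False, True):
            for y_reversed in (False, True):
                cols = (f.positive_x, f.negative_x)
                rows = (f.positive_y, f.negative_y)
                if x_reversed:
                    cols = cols[::-1]
                if y_reversed:
                    rows = rows[::-1]
                grid = tuple(
                    tuple(table.cell(x, y) for x in cols) for y in rows
                )
                row_dim, col_dim = f.dim_y.label, f.dim_x.label
                row_cats, col_cats = rows, cols
                if transposed:
                    grid = tuple(zip(*grid))
                    row_dim, col_dim = col_dim, row_dim
                    row_cats, col_cats = col_cats, row_cats
                variants.append(
                    LayoutVariant(
                        grid=grid,
                        row_dim=row_dim,
                        col_dim=col_dim,
                        row_categories=tuple(row_cats),
                        col_categories=tuple(col_cats),
                        transposed=transposed,
                        x_reversed=x_reversed,
                        y_reversed=y_reversed,
                        source=table,
                    )
                )
    return variants


def margins(table, axis: Axis | str) -> tuple:
    """Pair of marginal sums: rows (a+b, c+d), columns (a+c, b+d), or
    diagonals (a+d, b+c)."""
    axis = Axis(axis)
    a, b, c, d = table.cells()
    if axis is Axis.ROW:
        return (a + b, c + d)
    if axis is Axis.COLUMN:
        return (a + c, b + d)
    return (a + d, b + c)


# ---------------------------------------------------------------------------
# (de)serialization helpers


def _num(v):
    if isinstance(v, Fraction):
        return float(v) if v.denominator != 1 else int(v)
    return v


def _frame_to_dict(frame: FrameSpec) -> dict:
    return {
        "version": 1,
        "dim_x": {"label": frame.dim_x.label, "categories": list(frame.dim_x.categories)},
        "dim_y": {"label": frame.dim_y.label, "categories": list(frame.dim_y.categories)},
        "positive_x": frame.positive_x,
        "positive_y": frame.positive_y,
        "domain_tag": frame.domain_tag,
    }


def frame_from_dict(spec: Mapping) -> FrameSpec:
    return FrameSpec(
        dim_x=Dimension(spec["dim_x"]["label"], tuple(spec["dim_x"]["categories"])),
        dim_y=Dimension(spec["dim_y"]["label"], tuple(spec["dim_y"]["categories"])),
        positive_x=spec["positive_x"],
        positive_y=spec["positive_y"],
        domain_tag=spec.get("domain_tag"),
    )


def table_from_dict(spec: Mapping) -> FrequencyTable2x2 | ProbabilityTable2x2:
    """Parse the JSON table spec {"frame": {...}, "cells": {...}}."""
    frame = frame_from_dict(spec["frame"]) if "frame" in spec else default_frame()
    cells = spec["cells"]
    values = [cells[k] for k in "abcd"]
    if all(isinstance(v, int) for v in values):
        return from_counts(*values, frame=frame)
    return ProbabilityTable2x2(*values, frame=frame, n_origin=spec.get("n_origin"))
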