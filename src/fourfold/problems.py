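"""Classic Bayesian textbook problems, solved through the table pipeline.

Four worked problems are built in: the mammography screening problem in
its three formats (standard probabilities, natural frequencies, and the
short frequency menu), the hit-and-run cab problem, the Monty Hall
three-door game, and the Titanic rescue-policy question. Each is encoded
declaratively as a :class:`ProblemSpec` (what is given, in which format,
and what is asked), and :func:`solve` routes it through table
construction, conditionalization and focusing, so the answer provably
equals the closed-form Bayesian posterior (:func:`bayes_invert`).

Beyond the correct answer, :func:`predict_errors` derives the values of
the canonical reasoning errors: using the right formula on conditional
instead of joint quantities (false inputs, the formal core of base-rate
neglect), reporting the inverse conditional probability itself (false
measure, the inverse fallacy), and — for Monty Hall — framing a uniform
matrix from the two remaining doors (false framing). Empirical solution
rates reported in the experimental literature travel along as metadata
only; nothing recomputes them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

from ._markers import Undefined, is_undefined
from .io import titanic_fixture
from .metrics import MetricValue, compute, resolve, risk_measures
from .tables import (
    Dimension,
    FrameSpec,
    FrequencyTable2x2,
    PartialTable,
    Perspective,
    _PARTIAL_IDS,
    conditionalize,
    default_frame,
    from_counts,
    from_probability_format,
)

__all__ = [
    "Given",
    "ProblemSpec",
    "CaseMatrix3x3",
    "ErrorId",
    "ErrorPrediction",
    "fixture",
    "fixture_names",
    "solve",
    "bayes_invert",
    "monty_hall",
    "collapse_monty",
    "switch_stick_posteriors",
    "predict_errors",
    "titanic_policy_report",
]


@dataclass(frozen=True)
class Given:
    """One provided quantity, tagged by its scale."""

    kind: str  # "probability" | "frequency" | "count"
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("probability", "frequency", "count"):
            raise ValueError(f"bad given kind {self.kind!r}")
        if self.kind == "probability" and not 0.0 <= self.value <= 1.0:
            raise ValueError(f"probability given out of range: {self.value!r}")


@dataclass(frozen=True)
class ProblemSpec:
    """Declarative encoding of a worked problem."""

    name: str
    format_variant: str  # standard_probability | natural_frequencies |
    #                      short_frequencies | custom
    givens: Mapping[str, Given]
    question: Mapping[str, object]  # {"metric": ..., optional extras}
    annotations: Mapping[str, object] = field(default_factory=dict)
    partially_determined: bool = False

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "format_variant": self.format_variant,
            "givens": {
                k: {"kind": g.kind, "value": g.value} for k, g in self.givens.items()
            },
            "question": dict(self.question),
            "annotations": dict(self.annotations),
            "partially_determined": self.partially_determined,
        }

    @staticmethod
    def from_dict(spec: Mapping) -> "ProblemSpec":
        return ProblemSpec(
            name=spec["name"],
            format_variant=spec["format_variant"],
            givens={
                k: Given(v["kind"], v["value"]) for k, v in spec["givens"].items()
            },
            question=dict(spec["question"]),
            annotations=dict(spec.get("annotations", {})),
            partially_determined=bool(spec.get("partially_determined", False)),
        )


# ---------------------------------------------------------------------------
# built-in fixtures (all numbers are the classic published problem inputs)


def _mammography(variant: str) -> ProblemSpec:
    annotations = {
        # empirical correct-solution rates per format, from the experimental
        # literature (Gigerenzer & Hoffrage 1995; McDowell & Jacobs 2017
        # meta-analysis); metadata only, never recomputed here
        "empirical_correct_rate": {
            "standard_probability": 0.04,
            "natural_frequencies": 0.24,
            "short_frequencies": 0.36,
        }[variant],
        "modal_wrong_answer": 0.80,
        "percent_decimals": 1,  # the answer is conventionally printed as 7.8%
    }
    if variant == "standard_probability":
        givens = {
            "prevalence": Given("probability", 0.01),
            "sensitivity": Given("probability", 0.80),
            "false_positive_rate": Given("probability", 0.096),
            "n": Given("count", 1000),
        }
        partially = False
    elif variant == "natural_frequencies":
        givens = {
            "n": Given("count", 1000),
            "n_condition": Given("frequency", 10),
            "n_condition_and_positive": Given("frequency", 8),
            "n_no_condition": Given("frequency", 990),
            "n_no_condition_and_positive": Given("frequency", 95),
        }
        partially = False
    elif variant == "short_frequencies":
        givens = {
            "n": Given("count", 1000),
            "n_positive": Given("frequency", 103),
            "n_condition_and_positive": Given("frequency", 8),
        }
        partially = True  # the split of the negative-test row is unknown
    else:
        raise KeyError(f"unknown mammography variant {variant!r}")
    return ProblemSpec(
        name=f"mammography:{variant}",
        format_variant=variant,
        givens=givens,
        question={"metric": "PPV"},
        annotations=annotations,
        partially_determined=partially,
    )


def _cab() -> ProblemSpec:
    # witness accuracy is symmetric: p(blue|Blue) = p(green|Green) = 0.80
    return ProblemSpec(
        name="cab",
        format_variant="standard_probability",
        givens={
            "prevalence": Given("probability", 0.15),
            "sensitivity": Given("probability", 0.80),
            "false_positive_rate": Given("probability", 0.20),
        },
        question={"metric": "PPV"},
        annotations={"modal_wrong_answer": 0.80, "percent_decimals": 0},
    )


def _monty() -> ProblemSpec:
    return ProblemSpec(
        name="monty_hall",
        format_variant="custom",
        givens={
            "contestant_choice": Given("count", 1),  # door D1
            "host_bias": Given("probability", 0.5),
        },
        question={"metric": "switch_posterior"},
        annotations={"empirical_sticking_rate": 0.87, "percent_decimals": 0},
    )


def _titanic() -> ProblemSpec:
    return ProblemSpec(
        name="titanic",
        format_variant="custom",
        givens={
            "n": Given("count", 2201),
            "death_fraction": Given("probability", 0.677),
            "male_adult_survivors": Given("frequency", 338),
            "women_children_dead": Given("frequency", 161),
        },
        question={"metric": "ARR"},
        annotations={"percent_decimals": 0},
    )


_FIXTURES = {
    "mammography:standard": lambda: _mammography("standard_probability"),
    "mammography:natural_frequencies": lambda: _mammography("natural_frequencies"),
    "mammography:short_frequencies": lambda: _mammography("short_frequencies"),
    "cab": _cab,
    "monty_hall": _monty,
    "titanic": _titanic,
}


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def fixture(name: str) -> ProblemSpec:
    """A built-in problem by name (see :func:`fixture_names`)."""
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown problem {name!r}; available: {fixture_names()}"
        ) from None


# ---------------------------------------------------------------------------
# solving


def bayes_invert(
    prior: float, likelihood_pos: float, likelihood_neg: float
) -> float | Undefined:
    """Closed-form posterior p(C|T) from prior and the two likelihoods.

    p(C|T) = p(C) p(T|C) / [p(C) p(T|C) + p(nC) p(T|nC)].
    """
    for name, p in (
        ("prior", prior),
        ("likelihood_pos", likelihood_pos),
        ("likelihood_neg", likelihood_neg),
    ):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p!r}")
    num = prior * likelihood_pos
    den = num + (1.0 - prior) * likelihood_neg
    if den == 0:
        return Undefined("posterior: zero marginal probability of the evidence")
    return num / den


def problem_table(spec: ProblemSpec) -> FrequencyTable2x2 | PartialTable:
    """Construct the (possibly partial) 2x2 table a problem determines.

    Probability formats use exact rational expected frequencies, so the
    downstream focus equals the closed-form posterior to machine
    precision rather than only after integer rounding.
    """
    g = spec.givens
    if spec.format_variant == "standard_probability":
        n = int(g["n"].value) if "n" in g else 1000
        return from_probability_format(
            g["prevalence"].value,
            g["sensitivity"].value,
            g["false_positive_rate"].value,
            n,
            rounding="exact_rational",
        )
    if spec.format_variant == "natural_frequencies":
        a = int(g["n_condition_and_positive"].value)
        b = int(g["n_no_condition_and_positive"].value)
        c = int(g["n_condition"].value) - a
        d = int(g["n_no_condition"].value) - b
        return from_counts(a, b, c, d)
    if spec.format_variant == "short_frequencies":
        return PartialTable(
            default_frame(),
            {
                "n": g["n"].value,
                "row_pos": g["n_positive"].value,
                "a": g["n_condition_and_positive"].value,
            },
        )
    if spec.name == "monty_hall":
        return collapse_monty(
            monty_hall(
                f"D{int(g['contestant_choice'].value)}", g["host_bias"].value
            )
        )
    if spec.name == "titanic":
        return titanic_fixture()
    raise ValueError(f"cannot build a table for {spec.name!r}")


def _solve_partial(partial: PartialTable, metric_name: str) -> MetricValue:
    """Answer a focus question from a partially known table if possible."""
    defn = resolve(metric_name)
    if defn.formula_class != "cell_ratio":
        raise ValueError(
            f"{defn.canonical_name} is not answerable from a partial table"
        )
    by_cells = {members: key for key, members in _PARTIAL_IDS.items()}

    def group_sum(cells: frozenset) -> float | None:
        key = by_cells.get(cells)
        if key is not None:
            return partial.get(key)
        total = 0.0
        for cell in cells:
            v = partial.get(cell)
            if v is None:
                return None
            total += v
        return total

    num = group_sum(defn.numerator)
    den = group_sum(defn.denominator)
    if num is None or den is None:
        missing = sorted(
            cell
            for cell in defn.numerator | defn.denominator
            if partial.get(cell) is None
        )
        raise ValueError(
            f"under-determined: {defn.canonical_name} needs unknown "
            f"quantities {missing}"
        )
    value = num / den if den else Undefined(f"{defn.canonical_name}: zero denominator")
    return MetricValue(
        value=value,
        metric=defn.canonical_name,
        provenance=(
            {"step": "frame", "kind": "PartialTable",
             "known": sorted(partial.known_keys())},
            {"step": "focus", "metric": defn.canonical_name,
             "numerator": sorted(defn.numerator),
             "denominator": sorted(defn.denominator),
             "perspective": defn.perspective.value if defn.perspective else None},
        ),
        icon=defn.icon(),
        table=partial,
    )


def solve(spec: ProblemSpec) -> MetricValue:
    """Answer a problem's question through the table pipeline."""
    metric_name = str(spec.question["metric"])
    if spec.name == "monty_hall":
        table = problem_table(spec)
        stick, switch = switch_stick_posteriors(table)
        value = switch if metric_name == "switch_posterior" else stick
        return MetricValue(
            value=float(value),
            metric=metric_name,
            provenance=(
                {"step": "frame", "kind": "collapsed case matrix",
                 "cells": {k: float(v) for k, v in zip("abcd", table.cells())}},
                {"step": "focus", "perspective": "by_row",
                 "metric": metric_name},
            ),
            table=table,
        )
    table = problem_table(spec)
    if isinstance(table, PartialTable):
        return _solve_partial(table, metric_name)
    return compute(table, metric_name)


# ---------------------------------------------------------------------------
# Monty Hall


@dataclass(frozen=True)
class CaseMatrix3x3:
    """Host-door by car-location case counts for the three-door game.

    Rows are the doors the host can open (D1-D3), columns the
    equiprobable car locations (C1-C3). With two distinguishable goats
    there are 3! = 6 base arrangements, two per car location. The row of
    the contestant's chosen door is all zero (the host never opens it);
    ``host_bias`` is the probability of opening the lower-numbered
    openable door when the host has a free choice.
    """

    counts: tuple[tuple[Fraction, ...], ...]  # [door][car]
    contestant_choice: str
    host_bias: Fraction

    DOORS = ("D1", "D2", "D3")
    CARS = ("C1", "C2", "C3")

    def count(self, door: str, car: str) -> Fraction:
        return self.counts[self.DOORS.index(door)][self.CARS.index(car)]

    @property
    def total(self) -> Fraction:
        return sum(sum(row) for row in self.counts)

    def column_sums(self) -> tuple[Fraction, ...]:
        return tuple(sum(row[j] for row in self.counts) for j in range(3))


def monty_hall(contestant_choice: str = "D1", host_bias: float = 0.5) -> CaseMatrix3x3:
    """Enumerate the six base cases of the standard three-door game."""
    doors = CaseMatrix3x3.DOORS
    if contestant_choice not in doors:
        raise ValueError(f"contestant_choice must be one of {doors}")
    if not 0.0 <= host_bias <= 1.0:
        raise ValueError(f"host_bias must lie in [0, 1], got {host_bias!r}")
    bias = Fraction(host_bias).limit_denominator(10**9)
    openable = [d for d in doors if d != contestant_choice]
    grid = [[Fraction(0)] * 3 for _ in range(3)]
    for j, car in enumerate(CaseMatrix3x3.CARS):
        # two arrangements of the distinguishable goats per car location
        if doors[j] == contestant_choice:
            # host chooses freely between the two goat doors
            grid[doors.index(openable[0])][j] += 2 * bias
            grid[doors.index(openable[1])][j] += 2 * (1 - bias)
        else:
            # the car blocks one openable door; the host is forced
            forced = next(d for d in openable if d != doors[j])
            grid[doors.index(forced)][j] += 2
    return CaseMatrix3x3(
        counts=tuple(tuple(row) for row in grid),
        contestant_choice=contestant_choice,
        host_bias=bias,
    )


def collapse_monty(cases: CaseMatrix3x3) -> FrequencyTable2x2:
    """Frame the 3x3 case matrix as a 2x2 by merging the non-chosen car
    locations and dropping the impossible chosen-door row."""
    choice = cases.contestant_choice
    chosen_car = "C" + choice[1]
    other_cars = [c for c in CaseMatrix3x3.CARS if c != chosen_car]
    open_doors = [d for d in CaseMatrix3x3.DOORS if d != choice]
    merged = "|".join(other_cars)
    frame = FrameSpec(
        dim_x=Dimension("car_location", (chosen_car, merged)),
        dim_y=Dimension("opened_door", tuple(open_doors)),
        positive_x=chosen_car,
        positive_y=open_doors[0],
    )
    def cell(door, chosen):
        if chosen:
            return cases.count(door, chosen_car)
        return sum(cases.count(door, c) for c in other_cars)
    return FrequencyTable2x2(
        cell(open_doors[0], True), cell(open_doors[0], False),
        cell(open_doors[1], True), cell(open_doors[1], False),
        frame,
        meta={"contestant_choice": choice},
    )


def switch_stick_posteriors(
    table: FrequencyTable2x2, opened_door: str | None = None
) -> tuple[float | Undefined, float | Undefined]:
    """(stick, switch) posteriors given the door the host opened.

    Conditionalizes the collapsed matrix by row; sticking keeps the
    originally chosen car column, switching takes the merged complement.
    Defaults to the second openable door (the narrative's opened door).
    """
    cond = conditionalize(table, Perspective.BY_ROW)
    f = table.frame
    opened = opened_door or f.negative_y
    stick = cond.cell(f.positive_x, opened)
    switch = cond.cell(f.negative_x, opened)
    return stick, switch


# ---------------------------------------------------------------------------
# predicted reasoning errors


class ErrorId(str, enum.Enum):
    E1_FALSE_INPUTS = "E1_false_inputs"
    E2_FALSE_MEASURE = "E2_false_measure"
    E3_FALSE_FRAMING = "E3_false_framing"


@dataclass(frozen=True)
class ErrorPrediction:
    """A predicted wrong answer and the reasoning route that produces it."""

    error_id: ErrorId
    predicted_value: float
    note: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.predicted_value <= 1.0:
            raise ValueError("predicted values are probabilities")


def predict_errors(spec: ProblemSpec) -> list[ErrorPrediction]:
    """Derive the canonical wrong answers for a determined problem.

    False inputs applies the correct posterior formula to the by-column
    conditional cells instead of the joint cells; false measure reports
    the inverse conditional (the sensitivity) itself; false framing
    (Monty Hall only) posits a uniform two-option matrix.
    """
    table = problem_table(spec)
    if isinstance(table, PartialTable):
        raise ValueError("error predictions need a fully determined problem")
    cond = conditionalize(table, Perspective.BY_COLUMN)
    sens = cond.a
    denominator = cond.a + cond.b
    e1 = float(cond.a / denominator)
    out = [
        ErrorPrediction(
            ErrorId.E1_FALSE_INPUTS,
            e1,
            "right formula, wrong inputs: a/(a+b) computed on the by-column "
            "conditional cells (base-rate neglect)",
        ),
        ErrorPrediction(
            ErrorId.E2_FALSE_MEASURE,
            float(sens),
            "the inverse conditional p(T|C) reported as the answer "
            "(inverse fallacy)",
        ),
    ]
    if spec.name == "monty_hall":
        out.append(
            ErrorPrediction(
                ErrorId.E3_FALSE_FRAMING,
                0.5,
                "uniform 2x2 matrix over the two remaining doors: any "
                "perspective on it yields 50%",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Titanic policy report


def titanic_policy_report(table: FrequencyTable2x2) -> dict:
    """Evaluate a preferential-rescue policy from both perspectives.

    Survival rates per rescue category answer 'who survived at what
    rate'; the conflict odds contrast the two cells that can violate the
    policy (survivors outside the priority group vs. dead within it).
    The two readings can point in opposite directions, so the report
    flags both instead of issuing a single verdict.
    """
    f = table.frame
    measures = risk_measures(table, f.dim_x.label, f.positive_y)
    odds = measures["row_odds"].value
    notes = [
        "survival-rate perspective: the priority group survived at "
        "a higher absolute rate" if _defined_positive(measures["ARR"].value)
        else "survival-rate perspective: no survival advantage for the "
        "priority group",
    ]
    if is_undefined(odds):
        notes.append("policy fully satisfied: no conflict cases")
    elif odds > 1:
        notes.append(
            "conflict-odds perspective: seats taken by non-priority "
            "survivors exceeded priority deaths — the policy was not "
            "fully implemented"
        )
    else:
        notes.append("conflict-odds perspective: priority deaths were not "
                     "outnumbered by non-priority survivors")
    return {
        "survival_rate_priority": measures["AR_exposed"],
        "survival_rate_others": measures["AR_unexposed"],
        "ARR": measures["ARR"],
        "relative_increase": measures["relative_increase"],
        "conflict_odds": measures["row_odds"],
        "verdict_notes": notes,
    }


def _defined_positive(v) -> bool:
    return not is_undefined(v) and v > 0
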