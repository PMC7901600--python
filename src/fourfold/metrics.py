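"""The cross-domain catalog of 2x2 matrix measures.

Every measure here is a *focus* on a fourfold table: a ratio of cell
sums (optionally after conditionalizing in a row, column, or diagonal
direction), or a composition of such ratios. The catalog spans the
vocabularies of medical diagnostics (sensitivity, specificity, PPV,
NPV, likelihood ratios, DOR), classification and information retrieval
(recall, precision, accuracy, F1, MCC), association (deltaP, the
chi-square score), and epidemiological risk (absolute risk, ARR,
relative risk, NNT, odds). The same formula often carries different
names in different fields — e.g. sensitivity = recall, PPV = precision,
and relative risk shares its formula with the positive likelihood
ratio — so each definition registers its domain aliases and
:func:`resolve` maps any known name (plus an optional domain tag) to its
canonical definition.

Computed values are :class:`MetricValue` objects that carry, besides the
number, the derivation chain (frame -> perspective -> focused cells) and
a cell-role icon, so a report can explicate exactly how the number was
obtained and what information the derivation dropped.
"""

from __future__ import annotations

import difflib
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

from ._markers import Undefined, is_undefined, safe_div
from .tables import (
    FrequencyTable2x2,
    Perspective,
    ProbabilityTable2x2,
    _frame_to_dict,
)

__all__ = [
    "IconSpec",
    "MetricDef",
    "MetricValue",
    "catalog",
    "catalog_json",
    "resolve",
    "compute",
    "delta_p",
    "chi_square",
    "mcc",
    "risk_measures",
]

_CELLS = ("a", "b", "c", "d")


@dataclass(frozen=True)
class IconSpec:
    """Cell roles for a measure's focus: which cells sit in the numerator,
    which only in the denominator, and which are ignored entirely."""

    roles: Mapping[str, str]  # cell -> "numerator" | "denominator_only" | "ignored"

    def __post_init__(self) -> None:
        for cell in _CELLS:
            if self.roles.get(cell) not in ("numerator", "denominator_only", "ignored"):
                raise ValueError(f"cell {cell!r} needs a role")

    @staticmethod
    def from_focus(numerator: frozenset, denominator: frozenset) -> "IconSpec":
        roles = {}
        for cell in _CELLS:
            if cell in numerator:
                roles[cell] = "numerator"
            elif cell in denominator:
                roles[cell] = "denominator_only"
            else:
                roles[cell] = "ignored"
        return IconSpec(roles)


@dataclass(frozen=True)
class MetricDef:
    """Declarative definition of one measure.

    ``cell_ratio`` metrics are sums-of-cells over sums-of-cells with the
    numerator nested in the denominator; ``composite`` metrics combine
    previously defined metrics through ``combine`` (the composition is a
    finite tree, checked acyclic at registration).
    """

    canonical_name: str
    description: str
    formula_class: str  # "cell_ratio" | "composite"
    numerator: frozenset = frozenset()
    denominator: frozenset = frozenset()
    composite_of: tuple[str, ...] = ()
    combine: Callable | None = None
    expression: str = ""
    perspective: Perspective | None = None
    valid_range: tuple[float, float] = (-math.inf, math.inf)
    aliases: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.formula_class == "cell_ratio":
            if not self.numerator <= self.denominator:
                raise ValueError(
                    f"{self.canonical_name}: numerator cells must nest in denominator"
                )
        elif self.formula_class == "margin_ratio":
            if not self.numerator or not self.denominator:
                raise ValueError(f"{self.canonical_name}: margin_ratio needs both sides")
        elif self.formula_class == "composite":
            if self.combine is None or not self.composite_of:
                raise ValueError(f"{self.canonical_name}: composite needs components")
        else:
            raise ValueError(f"bad formula_class {self.formula_class!r}")

    def icon(self) -> IconSpec:
        if self.formula_class in ("cell_ratio", "margin_ratio"):
            return IconSpec.from_focus(
                self.numerator, self.numerator | self.denominator
            )
        # composites touch every cell through their components
        return IconSpec.from_focus(frozenset(), frozenset(_CELLS))


@dataclass(frozen=True)
class MetricValue:
    """A computed measure plus its full derivation chain."""

    value: float | Undefined
    metric: str
    provenance: tuple = ()
    icon: IconSpec | None = None
    table: object = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not is_undefined(self.value):
            definition = _REGISTRY.get(self.metric)
            if definition is not None and math.isfinite(self.value):
                lo, hi = definition.valid_range
                if not (lo - 1e-12 <= self.value <= hi + 1e-12):
                    raise ValueError(
                        f"{self.metric}={self.value!r} outside valid range {definition.valid_range}"
                    )


# ---------------------------------------------------------------------------
# registry


_REGISTRY: dict[str, MetricDef] = {}


def _register(defn: MetricDef) -> None:
    if defn.canonical_name in _REGISTRY:
        raise ValueError(f"duplicate metric {defn.canonical_name}")
    # composition trees must be acyclic: components must already exist
    for component in defn.composite_of:
        if component not in _REGISTRY:
            raise ValueError(
                f"{defn.canonical_name}: unknown component {component!r}"
            )
    _REGISTRY[defn.canonical_name] = defn


def _ratio(name, desc, num, den, perspective=None, rng=(0.0, 1.0), aliases=None):
    _register(
        MetricDef(
            canonical_name=name,
            description=desc,
            formula_class="cell_ratio",
            numerator=frozenset(num),
            denominator=frozenset(den),
            expression=f"({'+'.join(sorted(num))})/({'+'.join(sorted(den))})",
            perspective=perspective,
            valid_range=rng,
            aliases=aliases or {},
        )
    )


def _composite(name, desc, components, combine, expression,
               perspective=None, rng=(-math.inf, math.inf), aliases=None):
    _register(
        MetricDef(
            canonical_name=name,
            description=desc,
            formula_class="composite",
            composite_of=tuple(components),
            combine=combine,
            expression=expression,
            perspective=perspective,
            valid_range=rng,
            aliases=aliases or {},
        )
    )


def _chain(*values):
    """First Undefined marker among composite inputs, else None."""
    for v in values:
        if is_undefined(v):
            return v
    return None


ALL = frozenset(_CELLS)

_ratio("prevalence", "marginal probability of the positive condition, P(C)",
       "ac", ALL, aliases={"risk": ("exposure_rate",), "treatment": ("base_rate",)})
_ratio("bias", "marginal probability of a positive test/prediction, P(T)",
       "ab", ALL)
_ratio("sensitivity", "P(T|C): positive rate among condition positives",
       "a", "ac", Perspective.BY_COLUMN,
       aliases={"classification": ("recall", "TPR", "true_positive_rate"),
                "information_retrieval": ("recall",),
                "signal_detection": ("hit_rate",)})
_ratio("specificity", "P(nT|nC): negative rate among condition negatives",
       "d", "bd", Perspective.BY_COLUMN,
       aliases={"classification": ("TNR", "true_negative_rate"),
                "signal_detection": ("correct_rejection_rate",)})
_ratio("false_positive_rate", "P(T|nC)", "b", "bd", Perspective.BY_COLUMN,
       aliases={"classification": ("FPR", "fall_out"),
                "signal_detection": ("false_alarm_rate",)})
_ratio("false_negative_rate", "P(nT|C)", "c", "ac", Perspective.BY_COLUMN,
       aliases={"classification": ("FNR", "miss_rate")})
_ratio("PPV", "P(C|T): condition rate among test positives",
       "a", "ab", Perspective.BY_ROW,
       aliases={"classification": ("precision",),
                "information_retrieval": ("precision",),
                "diagnostics": ("positive_predictive_value",)})
_ratio("NPV", "P(nC|nT)", "d", "cd", Perspective.BY_ROW,
       aliases={"diagnostics": ("negative_predictive_value",)})
_ratio("FDR", "P(nC|T): false discovery rate", "b", "ab", Perspective.BY_ROW)
_ratio("FOR", "P(C|nT): false omission rate", "c", "cd", Perspective.BY_ROW)
_ratio("accuracy", "(a+d)/N: proportion of correspondence cases",
       "ad", ALL, Perspective.BY_DIAGONAL,
       aliases={"classification": ("ACC",), "information_retrieval": ("rand_accuracy",)})
_ratio("error_rate", "(b+c)/N", "bc", ALL, Perspective.BY_DIAGONAL,
       aliases={"classification": ("misclassification_rate",)})
# risk-domain absolute risks share their focus cells with the by-column rates
_ratio("absolute_risk_exposed", "outcome probability in the exposed group",
       "a", "ac", Perspective.BY_COLUMN, aliases={"risk": ("AR_exposed",)})
_ratio("absolute_risk_unexposed", "outcome probability in the unexposed group",
       "b", "bd", Perspective.BY_COLUMN,
       aliases={"risk": ("AR_unexposed", "baseline_risk")})

_composite("LR_plus", "positive likelihood ratio: sensitivity / FPR",
           ("sensitivity", "false_positive_rate"),
           lambda s, fpr: _chain(s, fpr) or safe_div(s, fpr, "LR+: 0/0"),
           "sensitivity/FPR", Perspective.BY_COLUMN, (0.0, math.inf),
           aliases={"diagnostics": ("positive_likelihood_ratio",)})
_composite("LR_minus", "negative likelihood ratio: FNR / specificity",
           ("false_negative_rate", "specificity"),
           lambda fnr, s: _chain(fnr, s) or safe_div(fnr, s, "LR-: 0/0"),
           "FNR/specificity", Perspective.BY_COLUMN, (0.0, math.inf),
           aliases={"diagnostics": ("negative_likelihood_ratio",)})
_composite("DOR", "diagnostic odds ratio: LR+ / LR- = ad/bc",
           ("LR_plus", "LR_minus"),
           lambda p, m: _chain(p, m) or safe_div(p, m, "DOR: 0/0"),
           "LR+/LR-", None, (0.0, math.inf),
           aliases={"diagnostics": ("diagnostic_odds_ratio",),
                    "risk": ("odds_ratio",)})
_composite("F1", "harmonic mean of precision (PPV) and recall (sensitivity)",
           ("PPV", "sensitivity"),
           lambda p, r: _chain(p, r)
           or (Undefined("F1: precision + recall = 0") if p + r == 0
               else 2 * p * r / (p + r)),
           "2*PPV*sens/(PPV+sens)", None, (0.0, 1.0),
           aliases={"information_retrieval": ("F_score", "F_measure")})
_composite("deltaP_row", "row-wise contingency: P(x+|y+) - P(x+|y-)",
           ("PPV", "FOR"),
           lambda ppv, for_: _chain(ppv, for_) or ppv - for_,
           "PPV - FOR", Perspective.BY_ROW, (-1.0, 1.0))
_composite("deltaP_col", "column-wise contingency: P(y+|x+) - P(y+|x-)",
           ("sensitivity", "false_positive_rate"),
           lambda s, fpr: _chain(s, fpr) or s - fpr,
           "sens - FPR", Perspective.BY_COLUMN, (-1.0, 1.0))
_composite("ARR", "absolute risk reduction: AR_exposed - AR_unexposed",
           ("absolute_risk_exposed", "absolute_risk_unexposed"),
           lambda e, u: _chain(e, u) or e - u,
           "AR_exposed - AR_unexposed", Perspective.BY_COLUMN, (-1.0, 1.0),
           aliases={"treatment": ("risk_difference",)})
_composite("relative_risk", "risk ratio AR_exposed / AR_unexposed "
           "(formula-identical to LR+ under the risk frame)",
           ("absolute_risk_exposed", "absolute_risk_unexposed"),
           lambda e, u: _chain(e, u) or safe_div(e, u, "RR: 0/0"),
           "AR_exposed/AR_unexposed", Perspective.BY_COLUMN, (0.0, math.inf),
           aliases={"risk": ("RR", "risk_ratio")})
_composite("relative_increase", "ARR relative to the baseline group: "
           "ARR / AR_unexposed",
           ("ARR", "absolute_risk_unexposed"),
           lambda arr, u: _chain(arr, u) or safe_div(arr, u, "relative increase: 0/0"),
           "ARR/AR_unexposed", Perspective.BY_COLUMN)
_composite("NNT", "number needed to treat: reciprocal of ARR",
           ("ARR",),
           lambda arr: _chain(arr) or safe_div(1.0, arr, "NNT: ARR = 0"),
           "1/ARR", Perspective.BY_COLUMN)
_register(
    MetricDef(
        canonical_name="row_odds",
        description="odds of the two correspondence-conflict cells "
        "(the off-diagonal pair, read as a row after re-framing): b/c",
        formula_class="margin_ratio",
        numerator=frozenset("b"),
        denominator=frozenset("c"),
        expression="b/c",
        valid_range=(0.0, math.inf),
        aliases={"risk": ("conflict_odds",)},
    )
)


def _classical_chi_square(table) -> float | Undefined:
    a, b, c, d = (float(v) for v in table.cells())
    n = a + b + c + d
    den = (a + b) * (c + d) * (a + c) * (b + d)
    if den == 0:
        return Undefined("chi-square: zero margin")
    return n * (a * d - b * c) ** 2 / den


def _chi_square_value(table) -> float | Undefined:
    dpr = _evaluate(table, _REGISTRY["deltaP_row"])
    dpc = _evaluate(table, _REGISTRY["deltaP_col"])
    bad = _chain(dpr, dpc)
    if bad is not None:
        return Undefined("chi-square: zero margin")
    n = float(table.n) if isinstance(table, FrequencyTable2x2) else (
        table.n_origin if table.n_origin else 1.0)
    value = n * dpr * dpc
    classical = _classical_chi_square(table)
    # the deltaP product is algebraically the classical score; guard the identity
    if not is_undefined(classical):
        assert abs(value - classical) <= 1e-9 * max(1.0, abs(classical)), (
            "deltaP-product chi-square diverged from the classical formula"
        )
    return value


def _mcc_value(table) -> float | Undefined:
    chi = _chi_square_value(table)
    if is_undefined(chi):
        return Undefined("MCC: zero margin")
    a, b, c, d = (float(v) for v in table.cells())
    n = a + b + c + d
    sign = 1.0 if a * d - b * c > 0 else (-1.0 if a * d - b * c < 0 else 0.0)
    return sign * math.sqrt(max(chi, 0.0) / n)


_composite("chi_square", "N * deltaP_row * deltaP_col; algebraically the "
           "classical N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))",
           ("deltaP_row", "deltaP_col"),
           lambda *_: None,  # replaced below
           "N*dP_R*dP_C", None, (0.0, math.inf),
           aliases={"classification": ("chi2_score",)})
_composite("MCC", "Matthews correlation: sign(ad-bc) * sqrt(chi_square/N)",
           ("chi_square",),
           lambda *_: None,  # replaced below
           "sign(ad-bc)*sqrt(chi2/N)", None, (-1.0, 1.0),
           aliases={"classification": ("matthews_correlation", "phi_coefficient")})

# metrics whose value needs the raw table rather than component values
_TABLE_EVALUATED: dict[str, Callable] = {
    "chi_square": _chi_square_value,
    "MCC": _mcc_value,
}


def catalog() -> list[MetricDef]:
    """All registered metric definitions."""
    return list(_REGISTRY.values())


def catalog_json() -> list[dict]:
    """Machine-readable catalog export."""
    out = []
    for d in _REGISTRY.values():
        out.append(
            {
                "name": d.canonical_name,
                "description": d.description,
                "formula_class": d.formula_class,
                "expression": d.expression,
                "numerator": sorted(d.numerator),
                "denominator": sorted(d.denominator),
                "components": list(d.composite_of),
                "perspective": d.perspective.value if d.perspective else None,
                "valid_range": [
                    None if math.isinf(v) else v for v in d.valid_range
                ],
                "aliases": {k: list(v) for k, v in d.aliases.items()},
            }
        )
    return out


def resolve(name: str, domain: str | None = None) -> MetricDef:
    """Map a metric name or domain alias to its canonical definition.

    An alias used by several domains for different measures requires a
    ``domain`` tag; unknown names raise with near-miss suggestions.
    """
    if name in _REGISTRY:
        return _REGISTRY[name]
    candidates = set()
    for defn in _REGISTRY.values():
        for dom, names in defn.aliases.items():
            if name in names and (domain is None or dom == domain):
                candidates.add(defn.canonical_name)
    if len(candidates) == 1:
        return _REGISTRY[candidates.pop()]
    if len(candidates) > 1:
        raise ValueError(
            f"alias {name!r} is ambiguous across domains "
            f"({sorted(candidates)}); pass a domain tag"
        )
    known = set(_REGISTRY)
    for defn in _REGISTRY.values():
        for names in defn.aliases.values():
            known.update(names)
    hints = difflib.get_close_matches(name, sorted(known), n=3)
    hint = f"; did you mean {hints}?" if hints else ""
    raise KeyError(f"unknown metric {name!r}{hint}")


# ---------------------------------------------------------------------------
# evaluation


def _evaluate(table, defn: MetricDef) -> float | Undefined:
    if defn.canonical_name in _TABLE_EVALUATED:
        return _TABLE_EVALUATED[defn.canonical_name](table)
    cells = dict(zip(_CELLS, (float(v) for v in table.cells())))
    if defn.formula_class == "cell_ratio":
        num = sum(cells[k] for k in defn.numerator)
        den = sum(cells[k] for k in defn.denominator)
        if den == 0:
            return Undefined(
                f"{defn.canonical_name}: zero denominator "
                f"({'+'.join(sorted(defn.denominator))})"
            )
        return num / den
    if defn.formula_class == "margin_ratio":
        num = sum(cells[k] for k in defn.numerator)
        den = sum(cells[k] for k in defn.denominator)
        return safe_div(num, den, f"{defn.canonical_name}: 0/0")
    parts = [_evaluate(table, _REGISTRY[c]) for c in defn.composite_of]
    return defn.combine(*parts)


def _provenance(table, defn: MetricDef) -> tuple:
    steps: list[dict] = []
    meta = getattr(table, "meta", {}) or {}
    if "filter" in meta:
        steps.append({"step": "filter", **meta["filter"]})
    steps.append(
        {
            "step": "frame",
            "frame": _frame_to_dict(table.frame),
            "cells": {k: float(v) for k, v in zip(_CELLS, table.cells())},
            "kind": type(table).__name__,
        }
    )
    if defn.formula_class in ("cell_ratio", "margin_ratio"):
        steps.append(
            {
                "step": "focus",
                "metric": defn.canonical_name,
                "perspective": defn.perspective.value if defn.perspective else None,
                "formula_class": defn.formula_class,
                "numerator": sorted(defn.numerator),
                "denominator": sorted(defn.denominator),
            }
        )
    else:
        steps.append(
            {
                "step": "focus",
                "metric": defn.canonical_name,
                "perspective": defn.perspective.value if defn.perspective else None,
                "composition": defn.expression,
                "components": list(defn.composite_of),
            }
        )
    return tuple(steps)


def compute(
    table: FrequencyTable2x2 | ProbabilityTable2x2,
    name: str,
    domain: str | None = None,
) -> MetricValue:
    """Compute one catalog metric on a table, with provenance and icon."""
    defn = resolve(name, domain or getattr(table.frame, "domain_tag", None))
    value = _evaluate(table, defn)
    return MetricValue(
        value=value,
        metric=defn.canonical_name,
        provenance=_provenance(table, defn),
        icon=defn.icon(),
        table=table,
    )


def delta_p(table, perspective: Perspective | str) -> MetricValue:
    """Directional contingency: difference of two conditional probabilities."""
    perspective = Perspective(perspective)
    if perspective is Perspective.BY_ROW:
        return compute(table, "deltaP_row")
    if perspective is Perspective.BY_COLUMN:
        return compute(table, "deltaP_col")
    raise ValueError("delta_p is defined for by_row and by_column only")


def chi_square(table) -> MetricValue:
    """The chi-square association score N * deltaP_row * deltaP_col."""
    return compute(table, "chi_square")


def mcc(table) -> MetricValue:
    """Matthews correlation coefficient, the signed root of chi_square/N."""
    return compute(table, "MCC")


def risk_measures(
    table: FrequencyTable2x2,
    exposure_dim: str,
    outcome_category: str,
) -> dict[str, MetricValue]:
    """Risk-domain panel for an exposure dimension and an outcome category.

    Absolute risks are the outcome's conditional probability per exposure
    group; ARR and RR compare them; ``relative_increase`` is ARR over the
    baseline (unexposed) risk; ``row_odds`` contrasts the two cells that
    can conflict with a priority policy (good outcome without priority
    vs. bad outcome with priority), i.e. the off-diagonal pair read as a
    row after re-framing.
    """
    f = table.frame
    if exposure_dim == f.dim_x.label:
        exp_dim, out_dim = f.dim_x, f.dim_y
        count = table.cell
    elif exposure_dim == f.dim_y.label:
        exp_dim, out_dim = f.dim_y, f.dim_x
        def count(e, o):
            return table.cell(o, e)
    else:
        raise KeyError(f"{exposure_dim!r} is not a dimension of this table")
    if outcome_category not in out_dim.categories:
        raise KeyError(
            f"{outcome_category!r} is not a category of {out_dim.label!r}"
        )
    e_pos = f.positive_x if exp_dim is f.dim_x else f.positive_y
    e_neg = exp_dim.other(e_pos)
    o_pos = outcome_category
    o_neg = out_dim.other(o_pos)

    # orient a risk-frame table: exposure on columns, outcome on rows
    from .tables import FrameSpec, Dimension  # local to avoid top clutter

    risk_frame = FrameSpec(
        dim_x=Dimension(exp_dim.label, (e_pos, e_neg)),
        dim_y=Dimension(out_dim.label, (o_pos, o_neg)),
        positive_x=e_pos,
        positive_y=o_pos,
        domain_tag="risk",
    )
    oriented = FrequencyTable2x2(
        count(e_pos, o_pos), count(e_neg, o_pos),
        count(e_pos, o_neg), count(e_neg, o_neg),
        risk_frame,
        meta=dict(getattr(table, "meta", {}) or {}),
    )
    names = (
        "absolute_risk_exposed",
        "absolute_risk_unexposed",
        "ARR",
        "relative_risk",
        "relative_increase",
        "row_odds",
    )
    out = {name: compute(oriented, name) for name in names}
    out["AR_exposed"] = out.pop("absolute_risk_exposed")
    out["AR_unexposed"] = out.pop("absolute_risk_unexposed")
    out["RR"] = out.pop("relative_risk")
    return out
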