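"""Record-file I/O, built-in fixtures, and the synthetic-record generator.

CSV record files have a header row of dimension labels and one row per
element (or pre-aggregated rows with a count column). Raw values can be
mapped onto binary categories through a :class:`RecordFileSpec`; a
dimension that still has more than two categories after mapping is an
error, because downstream analysis assumes exhaustive dichotomies.

The Titanic rescue-policy table is reconstructed here from four printed
summary numbers rather than shipped as micro-data; the synthetic
generator emits condition/test record sets either with deterministic
expected counts or as seeded binomial samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .grid import BinaryRecordSet
from .tables import (
    Dimension,
    FrameSpec,
    FrequencyTable2x2,
    from_probability_format,
    round_half_away,
)

__all__ = [
    "RecordFileSpec",
    "GeneratorParams",
    "read_records",
    "write_records",
    "titanic_fixture",
    "synthesize_records",
    "load_mapping_file",
]


@dataclass(frozen=True)
class RecordFileSpec:
    """How to parse a delimited record file into binary dimensions.

    ``dimensions`` maps each dimension label to its ordered pair of
    categories; ``value_maps`` optionally recodes raw file values into
    those categories (e.g. years-of-age bands into Adult/Child);
    ``count_column`` names a column of row multiplicities for
    pre-aggregated files.
    """

    path: str | Path
    dimensions: Mapping[str, tuple[str, str]]
    delimiter: str = ","
    count_column: str | None = None
    value_maps: Mapping[str, Mapping[str, str]] = field(default_factory=dict)


def load_mapping_file(path: str | Path) -> dict:
    """Read a category-mapping config (YAML or JSON) for RecordFileSpec."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def read_records(spec: RecordFileSpec) -> BinaryRecordSet:
    """Parse a record file, validating every row against the registry."""
    try:
        frame = pd.read_csv(spec.path, sep=spec.delimiter, dtype=str,
                            skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"cannot parse {spec.path}: {exc}") from exc
    dims = [Dimension(label, tuple(cats)) for label, cats in spec.dimensions.items()]
    records = BinaryRecordSet(dims)
    if frame.empty:
        return records
    missing = [d.label for d in dims if d.label not in frame.columns]
    if missing:
        raise ValueError(f"{spec.path}: missing dimension columns {missing}")
    # recode and check binarity before expanding
    for label, mapping in spec.value_maps.items():
        frame[label] = frame[label].map(lambda v: mapping.get(v, v))
    for dim in dims:
        observed = set(frame[dim.label].dropna().unique())
        extra = observed - set(dim.categories)
        if extra:
            raise ValueError(
                f"{spec.path}: dimension {dim.label!r} has values {sorted(extra)} "
                f"outside its two categories {dim.categories} after mapping"
            )
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        count = 1
        if spec.count_column is not None:
            try:
                count = int(row[spec.count_column])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{spec.path} line {line}: bad count {row[spec.count_column]!r}"
                ) from None
        record = {}
        for dim in dims:
            value = row[dim.label]
            if pd.isna(value):
                raise ValueError(
                    f"{spec.path} line {line}: missing value for {dim.label!r}"
                )
            record[dim.label] = value
        for _ in range(count):
            records.append(record, _index=line)
    return records


def write_records(records: BinaryRecordSet, path: str | Path) -> None:
    """Inverse of read_records for unaggregated files."""
    labels = [d.label for d in records.dimensions]
    pd.DataFrame(records.records, columns=labels).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fixtures

#: Printed summary numbers the Titanic table is rebuilt from.
TITANIC_N = 2201
TITANIC_DEATH_FRACTION = 0.677
TITANIC_MALE_ADULT_SURVIVORS = 338
TITANIC_WOMEN_CHILDREN_DEAD = 161


def titanic_fixture() -> FrequencyTable2x2:
    """The rescue-policy table of the Titanic disaster.

    Reconstructed from four published summary figures: N = 2201
    passengers, an overall death fraction of 67.7%, 338 surviving male
    adults, and 161 women and children among the dead. Columns contrast
    the preferential rescue category (women and children) with male
    adults; rows contrast survival. Because 67.7% is itself a rounded
    figure, derived cells carry a +/-1 count uncertainty.
    """
    n = TITANIC_N
    deaths = round_half_away(TITANIC_DEATH_FRACTION * n)
    survivors = n - deaths
    wc_alive = survivors - TITANIC_MALE_ADULT_SURVIVORS
    wc_total = wc_alive + TITANIC_WOMEN_CHILDREN_DEAD
    ma_total = n - wc_total
    ma_dead = ma_total - TITANIC_MALE_ADULT_SURVIVORS
    frame = FrameSpec(
        dim_x=Dimension("rescue_category", ("women_children", "male_adults")),
        dim_y=Dimension("survival", ("Alive", "Dead")),
        positive_x="women_children",
        positive_y="Alive",
        domain_tag="risk",
    )
    return FrequencyTable2x2(
        wc_alive, TITANIC_MALE_ADULT_SURVIVORS,
        TITANIC_WOMEN_CHILDREN_DEAD, ma_dead,
        frame,
        meta={"filter": {"population": "RMS Titanic passengers", "n": n}},
    )


# ---------------------------------------------------------------------------
# synthetic records


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the condition/test record generator.

    ``expected`` mode emits the deterministic expected counts for the
    given prevalence/sensitivity/specificity (matching the
    probability-format reconstruction rules); ``sample`` mode draws the
    condition split and the two test outcomes as seeded binomials.
    """

    prevalence: float
    sensitivity: float
    specificity: float
    n: int
    mode: str = "expected"
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("prevalence", "sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n!r}")
        if self.mode not in ("expected", "sample"):
            raise ValueError(f"mode must be 'expected' or 'sample', got {self.mode!r}")
        if self.mode == "sample" and self.seed is None:
            raise ValueError("sample mode needs a seed")


_CONDITION = Dimension("condition", ("C", "nC"))
_TEST = Dimension("test", ("T", "nT"))


def synthesize_records(params: GeneratorParams) -> BinaryRecordSet:
    """Emit a record set whose tally follows the generator parameters.

    Sampling is staged: condition ~ Binomial(n, prevalence), then test
    outcomes per condition group ~ Binomial(n_C, sensitivity) and
    Binomial(n_nC, specificity), all from one generator seeded once, so
    identical seeds give identical output.
    """
    if params.mode == "expected":
        table = from_probability_format(
            params.prevalence,
            params.sensitivity,
            1.0 - params.specificity,
            params.n,
            rounding="nearest",
        )
        a, b, c, d = (int(v) for v in table.cells())
    else:
        rng = np.random.default_rng(params.seed)
        n_pos = int(rng.binomial(params.n, params.prevalence))
        a = int(rng.binomial(n_pos, params.sensitivity)) if n_pos else 0
        n_neg = params.n - n_pos
        d = int(rng.binomial(n_neg, params.specificity)) if n_neg else 0
        c = n_pos - a
        b = n_neg - d
    records = BinaryRecordSet([_CONDITION, _TEST])
    for count, condition, test in (
        (a, "C", "T"), (b, "nC", "T"), (c, "C", "nT"), (d, "nC", "nT")
    ):
        for _ in range(count):
            records.append({"condition": condition, "test": test})
    return records
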