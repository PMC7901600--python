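"""Typed markers for undefined quantities.

A 2x2 table with a zero margin cannot support every derived quantity
(e.g., the PPV of a test that nobody took). Rather than silently emitting
``nan``, degenerate derivations produce an :class:`Undefined` marker that
records *why* the value does not exist. Markers propagate through
arithmetic helpers and compare equal when their reasons match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class Undefined:
    """A value that does not exist, carrying the reason (e.g. a zero margin)."""

    reason: str

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Undefined({self.reason!r})"


def is_undefined(x: object) -> bool:
    return isinstance(x, Undefined)


def is_defined(x: object) -> bool:
    return not isinstance(x, Undefined)


def safe_div(num: float, den: float, reason: str) -> float | Undefined:
    """Divide, mapping 0/0 to an Undefined marker and x/0 to +/-inf.

    A zero denominator with a nonzero numerator is a genuine limit
    (e.g. an odds ratio with an empty off cell) and is reported as
    signed infinity; 0/0 carries no information at all.
    """
    if den == 0:
        if num == 0:
            return Undefined(reason)
        return math.copysign(math.inf, num)
    return num / den
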