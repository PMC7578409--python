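"""Family-planning indicator primitives shared by the whole package.

Definitions (married/in-union women of reproductive age, MWRA, 15-49):

* **mCPR** -- modern contraceptive prevalence rate: the proportion
  currently using a modern contraceptive method.
* **Traditional prevalence** -- proportion using a traditional method.
* **Unmet need** -- proportion who want to stop or delay childbearing but
  use no method of contraception.
* **Total demand** -- modern + traditional prevalence + unmet need.
* **Demand satisfied (DS)** -- modern prevalence divided by total demand,
  the SDG 3.7.1 convention.

Unit convention: every computation inside the package is on the
proportion scale in ``[0, 1]``; files and printed reports use percent.
The conversion happens exactly once, at the I/O boundary, which rules out
silent double-scaling bugs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SUM_TOLERANCE",
    "ValidationError",
    "PrevalenceState",
    "total_demand",
    "demand_satisfied",
    "percent_to_proportion",
    "proportion_to_percent",
]

#: slack when checking modern + traditional + unmet <= 1, absorbing
#: floating-point accumulation in projected series
SUM_TOLERANCE = 1e-9


class ValidationError(ValueError):
    """An indicator value or state violates its invariants."""


@dataclass(frozen=True)
class PrevalenceState:
    """Contraceptive-use state of one country-year.

    All three components are proportions of MWRA; they are non-negative
    and sum to at most 1 (the remainder being women with no demand).
    """

    modern: float
    traditional: float
    unmet: float

    def __post_init__(self) -> None:
        for name in ("modern", "traditional", "unmet"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValidationError(f"{name} must be finite, got {value!r}")
            if value < 0.0:
                raise ValidationError(f"{name} must be >= 0, got {value!r}")
        total = self.modern + self.traditional + self.unmet
        if total > 1.0 + SUM_TOLERANCE:
            raise ValidationError(
                "modern + traditional + unmet must be <= 1, got "
                f"{total!r} (modern={self.modern!r}, traditional="
                f"{self.traditional!r}, unmet={self.unmet!r})"
            )


def total_demand(state: PrevalenceState) -> float:
    """Total demand for family planning: prevalence (any method) plus unmet need."""
    return state.modern + state.traditional + state.unmet


def demand_satisfied(state: PrevalenceState) -> float:
    """Proportion of demand satisfied with modern methods (SDG 3.7.1).

    Defined as 0 when total demand is 0.  Zero demand never occurs on a
    projected trajectory with positive prevalence; the convention only
    pins down the degenerate corner.
    """
    demand = total_demand(state)
    if demand == 0.0:
        return 0.0
    return state.modern / demand


def percent_to_proportion(x: float) -> float:
    """Convert a percent in [0, 100] to a proportion in [0, 1]."""
    if not (0.0 <= x <= 100.0):
        raise ValidationError(f"percent must be in [0, 100], got {x!r}")
    return x / 100.0


def proportion_to_percent(x: float) -> float:
    """Convert a proportion in [0, 1] to a percent in [0, 100]."""
    if not (0.0 <= x <= 1.0):
        raise ValidationError(f"proportion must be in [0, 1], got {x!r}")
    return x * 100.0
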