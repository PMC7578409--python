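"""Demand-based (DB) comparator for mCPR target setting.

The DB method sets the mCPR target to the DS target share of the
*business-as-usual* total demand at the goal year (e.g. 75% of projected
2030 demand).  It therefore assumes demand stays on its BAU path while
modern use alone accelerates.  Because accelerating modern use in
practice pulls demand up with it, the DB target understates the mCPR
needed whenever demand is still growing between the goal year and the
accelerated-transition target year ``t*`` -- which is exactly the
comparison this module makes quantitative.
"""

from __future__ import annotations

from dataclasses import dataclass

from .at_method import ATConfig, ATResult
from .indicators import ValidationError
from .transition import Trajectory

__all__ = ["DBResult", "ATDBComparison", "db_target", "compare_at_db"]


@dataclass(frozen=True)
class DBResult:
    """Demand-based target and gap for one country (proportion scale)."""

    country: str
    db_target_mcpr: float
    db_gap: float


@dataclass(frozen=True)
class ATDBComparison:
    """Paired AT and DB targets/gaps for one country (proportion scale)."""

    country: str
    at_target_mcpr: float
    db_target_mcpr: float
    at_gap: float
    db_gap: float
    gap_difference: float


def db_target(traj: Trajectory, config: ATConfig | None = None) -> DBResult:
    """DB target: ds_target x BAU demand at the goal year.

    The gap uses the same current-year mCPR baseline as the AT gap, so
    AT-DB differences isolate the target definition.
    """
    if config is None:
        config = ATConfig()
    demand_goal = float(traj.demand[traj.index_of(config.goal_year)])
    target = config.ds_target * demand_goal
    current_m = float(traj.modern[traj.index_of(config.current_year)])
    return DBResult(traj.country, target, target - current_m)


def compare_at_db(at: ATResult, db: DBResult) -> ATDBComparison:
    """Pair the AT and DB assessments of one country."""
    if at.country != db.country:
        raise ValidationError(
            f"country mismatch: AT result is {at.country!r}, DB result is {db.country!r}"
        )
    return ATDBComparison(
        country=at.country,
        at_target_mcpr=at.target_mcpr,
        db_target_mcpr=db.db_target_mcpr,
        at_gap=at.mcpr_gap,
        db_gap=db.db_gap,
        gap_difference=at.mcpr_gap - db.db_gap,
    )
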