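"""Accelerated Transition (AT) target setting.

Converts a demand-satisfied (DS) goal -- e.g. 75% of the demand for
family planning satisfied with modern methods by 2030 -- into a
modern-contraceptive-prevalence (mCPR) target for the goal year.

Given a business-as-usual (BAU) trajectory, the method finds ``t*``, the
earliest year the DS goal is reached under BAU (capped at 2100).  For a
country with ``t* > goal``, meeting the goal on time requires the whole
contraceptive-use transition to run faster by the factor

    rel_accel = (t* - t_current) / (goal - t_current),

and the mCPR target for the goal year is the BAU mCPR at ``t*``:
accelerating the transition moves the *entire* (mCPR, demand) path
forward in time, so the mCPR that accompanies the DS goal is the one the
country would have had at ``t*``.  The mCPR gap (target minus current
mCPR) multiplied by the number of married/in-union women of reproductive
age (MWRA) gives the additional modern users required.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .indicators import ValidationError
from .transition import (
    PriorPenalty,
    SurveyObservation,
    Trajectory,
    fit_transition,
    project,
)

__all__ = [
    "ATConfig",
    "ATResult",
    "find_target_year",
    "relative_acceleration",
    "target_mcpr",
    "mcpr_gap",
    "users_gap",
    "accelerated_trajectory",
    "assess_country",
]


@dataclass(frozen=True)
class ATConfig:
    """Configuration of the DS goal and assessment horizon.

    Defaults encode the DS75-by-2030 benchmark assessed from 2019, with
    the target year capped at 2100 for countries never projected to reach
    the goal.
    """

    ds_target: float = 0.75
    goal_year: int = 2030
    current_year: int = 2019
    cap_year: int = 2100

    def __post_init__(self) -> None:
        if not (0.0 < self.ds_target < 1.0):
            raise ValidationError(f"ds_target must be in (0, 1), got {self.ds_target!r}")
        if not (self.current_year < self.goal_year <= self.cap_year):
            raise ValidationError(
                "need current_year < goal_year <= cap_year, got "
                f"{self.current_year} / {self.goal_year} / {self.cap_year}"
            )


@dataclass(frozen=True)
class ATResult:
    """Per-country outcome of the AT assessment.

    Proportion scale throughout; ``users_gap`` is a person count (None
    when no MWRA denominator was supplied).  For on-track countries
    (``t_star <= goal_year``) the gaps are reported as 0 with the
    ``on_track`` flag set; for countries needing acceleration
    ``mcpr_gap = target_mcpr - mCPR(current_year)``.
    """

    country: str
    t_star: int
    capped: bool
    rel_accel: float
    target_mcpr: float
    mcpr_gap: float
    users_gap: float | None
    on_track: bool


def find_target_year(traj: Trajectory, config: ATConfig) -> tuple[int, bool]:
    """Earliest grid year at or above the DS target; capped at ``cap_year``.

    Returns ``(t_star, capped)``.  The trajectory must cover
    ``[current_year, cap_year]``.
    """
    if not traj.covers(config.current_year, config.cap_year):
        raise ValidationError(
            f"trajectory for {traj.country} spans [{traj.years[0]}, {traj.years[-1]}], "
            f"must cover [{config.current_year}, {config.cap_year}]"
        )
    i0 = traj.index_of(config.current_year)
    i1 = traj.index_of(config.cap_year)
    ds = traj.ds[i0 : i1 + 1]
    hits = np.nonzero(ds >= config.ds_target)[0]
    if len(hits) == 0:
        return config.cap_year, True
    return int(config.current_year + hits[0]), False


def relative_acceleration(t_star: int, config: ATConfig) -> float:
    """Speed-up factor (t* - t_current)/(goal - t_current), unrounded.

    The reporting layer rounds to one decimal, half away from zero.
    """
    if t_star < config.current_year:
        raise ValidationError(f"t_star {t_star} precedes current_year {config.current_year}")
    return (t_star - config.current_year) / (config.goal_year - config.current_year)


def target_mcpr(traj: Trajectory, t_star: int) -> float:
    """BAU mCPR at ``t*`` -- the AT mCPR target for the goal year."""
    return float(traj.modern[traj.index_of(t_star)])


def mcpr_gap(target: float, current: float) -> float:
    """Target minus current mCPR; negative for on-track countries."""
    for name, value in (("target", target), ("current", current)):
        if not (0.0 <= value <= 1.0):
            raise ValidationError(f"{name} mCPR must be in [0, 1], got {value!r}")
    return target - current


def users_gap(gap: float, mwra: float) -> float:
    """Additional modern users required: mCPR gap x MWRA population."""
    if gap < 0.0:
        raise ValidationError(f"gap must be >= 0, got {gap!r}")
    if mwra < 0.0:
        raise ValidationError(f"mwra must be >= 0, got {mwra!r}")
    return gap * mwra


def accelerated_trajectory(bau: Trajectory, t_star: int, config: ATConfig) -> Trajectory:
    """Time-rescaled trajectory reaching the BAU state of ``t*`` at the goal year.

    Between ``current_year`` and ``goal_year`` the accelerated state at
    ``t`` is the BAU state at ``current_year + rel_accel * (t -
    current_year)`` (linear interpolation between grid years), so at the
    goal year the accelerated state equals the BAU state at ``t*`` and DS
    reaches the target exactly on time.  Beyond the goal year the path
    continues as BAU time-shifted by ``t* - goal_year``.

    ``t_star == goal_year`` is the identity rescaling and returns the BAU
    path (from ``current_year`` on); earlier ``t_star`` is an error --
    the country is on track and acceleration is meaningless.
    """
    if t_star < config.goal_year:
        raise ValidationError(
            f"t_star {t_star} < goal_year {config.goal_year}: country is on track, "
            "use the BAU trajectory directly"
        )
    if not bau.covers(config.current_year, t_star):
        raise ValidationError(
            f"BAU trajectory must cover [{config.current_year}, {t_star}]"
        )
    rel = relative_acceleration(t_star, config)
    shift = t_star - config.goal_year
    years = np.arange(config.current_year, int(bau.years[-1]) - shift + 1)
    tau = np.where(
        years <= config.goal_year,
        config.current_year + rel * (years - config.current_year),
        years + shift,
    ).astype(float)
    grid = bau.years.astype(float)
    return Trajectory(
        bau.country,
        years,
        np.interp(tau, grid, bau.modern),
        np.interp(tau, grid, bau.traditional),
        np.interp(tau, grid, bau.unmet),
    )


def assess_country(
    data: Trajectory | Sequence[SurveyObservation],
    config: ATConfig | None = None,
    mwra: float | None = None,
    penalty: PriorPenalty | None = None,
) -> ATResult:
    """Run the full AT assessment for one country.

    ``data`` is either a BAU trajectory covering ``[current_year,
    cap_year]`` or a survey series, in which case the transition model is
    fitted and projected first.
    """
    if config is None:
        config = ATConfig()
    if isinstance(data, Trajectory):
        traj = data
    else:
        observations = list(data)
        params = fit_transition(observations, penalty=penalty)
        traj = project(params, observations[0].country, config.current_year, config.cap_year)

    t_star, capped = find_target_year(traj, config)
    rel = relative_acceleration(t_star, config)
    tm = target_mcpr(traj, t_star)
    current_m = float(traj.modern[traj.index_of(config.current_year)])
    raw_gap = mcpr_gap(tm, current_m)
    on_track = t_star <= config.goal_year
    gap = 0.0 if on_track else raw_gap
    if mwra is None:
        ug = None
    else:
        ug = 0.0 if on_track else users_gap(max(raw_gap, 0.0), mwra)
    return ATResult(
        country=traj.country,
        t_star=t_star,
        capped=capped,
        rel_accel=rel,
        target_mcpr=tm,
        mcpr_gap=gap,
        users_gap=ug,
        on_track=on_track,
    )
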