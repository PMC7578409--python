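"""Deterministic one-country contraceptive-transition model.

Fits a parametric description of the contraceptive-use transition to a
sparse series of survey observations and projects annual business-as-usual
(BAU) trajectories of modern use, traditional use, unmet need, total
demand, and demand satisfied.

Model
-----
Total contraceptive prevalence (any method) follows a logistic growth
curve in calendar time ``t``:

    P(t) = P_max / (1 + exp(-omega * (t - Omega)))

where ``P_max`` is the asymptote (``cpr_asymptote``), ``omega`` the
per-year growth rate (``cpr_rate``) and ``Omega`` the midpoint year
(``cpr_midpoint``).  The modern share of total prevalence is logistic in
time,

    s(t) = expit(a_s + b_s * (t - Omega)),

so modern prevalence is ``s(t) P(t)`` and traditional prevalence is
``(1 - s(t)) P(t)``.  Unmet need is parameterised as a fraction of
non-users,

    U(t) = (1 - P(t)) * expit(a_u + b_u * P(t)),

which structurally guarantees ``P + U <= 1`` and ties unmet need to the
prevalence level: with ``b_u < 0`` unmet need shrinks as the transition
completes, the pattern seen in survey compilations.

Fitting is penalised weighted nonlinear least squares on the log-odds
scale of (total prevalence, modern share, unmet fraction of non-users).
Quadratic penalties pull the asymptote and rate toward documented
defaults; for data-sparse countries they play the role that hierarchical
shrinkage plays in a multi-country Bayesian fit.  The optimiser is a
bounded trust-region reflective solver started from a documented
deterministic point, so two runs on identical input produce bit-identical
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit, logit

from .indicators import (
    SUM_TOLERANCE,
    PrevalenceState,
    ValidationError,
    percent_to_proportion,
    proportion_to_percent,
)

__all__ = [
    "SurveyObservation",
    "TransitionParameters",
    "Trajectory",
    "PriorPenalty",
    "FitError",
    "model_curves",
    "fit_transition",
    "project",
    "read_survey_csv",
    "write_survey_csv",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_parameters_csv",
    "write_parameters_csv",
]

# clamp proportions away from {0, 1} before taking log-odds
_EPS = 1e-6

_PARAM_FIELDS = (
    "cpr_asymptote",
    "cpr_rate",
    "cpr_midpoint",
    "share_intercept",
    "share_slope",
    "unmet_intercept",
    "unmet_slope",
)

# box constraints for the optimiser, matching the parameter invariants
_LOWER = np.array([0.01, 1e-3, 1950.0, -10.0, -1.0, -10.0, -10.0])
_UPPER = np.array([0.95, 1.0, 2150.0, 10.0, 1.0, 10.0, 10.0])
# characteristic scales; the midpoint lives on a calendar-year scale while
# the rates live near 0.05/yr, so unscaled steps would be ill-conditioned
_X_SCALE = np.array([0.1, 0.05, 30.0, 1.0, 0.05, 1.0, 1.0])


class FitError(RuntimeError):
    """The transition fit did not converge; carries optimiser diagnostics."""

    def __init__(self, message: str, status: int | None = None, cost: float | None = None):
        super().__init__(message)
        self.status = status
        self.cost = cost


def _logit(x: np.ndarray | float) -> np.ndarray | float:
    return logit(np.clip(x, _EPS, 1.0 - _EPS))


@dataclass(frozen=True)
class SurveyObservation:
    """One country-year survey measurement (proportion scale).

    ``obs_sd`` is an optional sampling standard deviation on the
    proportion scale; when present for every observation of a country it
    drives inverse-variance weighting in the fit.
    """

    country: str
    year: float
    modern: float
    traditional: float
    unmet: float
    obs_sd: float | None = None

    def __post_init__(self) -> None:
        if not (1950.0 <= self.year <= 2030.0):
            raise ValidationError(f"year must be in [1950, 2030], got {self.year!r}")
        # reuse the state validation for the prevalence components
        PrevalenceState(self.modern, self.traditional, self.unmet)
        if self.obs_sd is not None and not self.obs_sd > 0.0:
            raise ValidationError(f"obs_sd must be positive when given, got {self.obs_sd!r}")

    @property
    def state(self) -> PrevalenceState:
        return PrevalenceState(self.modern, self.traditional, self.unmet)


@dataclass(frozen=True)
class TransitionParameters:
    """Fitted parameters of the simplified contraceptive transition.

    ``cpr_asymptote`` (P_max) is the ceiling of total prevalence;
    ``cpr_rate`` (omega, per year) and ``cpr_midpoint`` (Omega, calendar
    year of P_max/2) shape the logistic in time.  The share pair is the
    log-odds intercept/slope (per year, centred on the midpoint) of the
    modern share of total prevalence; the unmet pair is the log-odds
    intercept/slope (per unit of total prevalence) of unmet need as a
    fraction of non-users.
    """

    cpr_asymptote: float
    cpr_rate: float
    cpr_midpoint: float
    share_intercept: float
    share_slope: float
    unmet_intercept: float
    unmet_slope: float

    def __post_init__(self) -> None:
        if not (0.0 < self.cpr_asymptote <= 0.95):
            raise ValidationError(
                f"cpr_asymptote must be in (0, 0.95], got {self.cpr_asymptote!r}"
            )
        if not (0.0 < self.cpr_rate <= 1.0):
            raise ValidationError(f"cpr_rate must be in (0, 1], got {self.cpr_rate!r}")
        if not (1950.0 <= self.cpr_midpoint <= 2150.0):
            raise ValidationError(
                f"cpr_midpoint must be in [1950, 2150], got {self.cpr_midpoint!r}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _PARAM_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "TransitionParameters":
        return cls(*(float(v) for v in x))


def _curves(params: TransitionParameters, years: np.ndarray):
    """Vectorised evaluation of (modern, traditional, unmet) at ``years``."""
    t = np.asarray(years, dtype=float)
    total = params.cpr_asymptote * expit(params.cpr_rate * (t - params.cpr_midpoint))
    share = expit(params.share_intercept + params.share_slope * (t - params.cpr_midpoint))
    unmet = (1.0 - total) * expit(params.unmet_intercept + params.unmet_slope * total)
    return share * total, (1.0 - share) * total, unmet


def model_curves(params: TransitionParameters, year: float) -> PrevalenceState:
    """Evaluate the transition curves at one (possibly fractional) year."""
    modern, traditional, unmet = _curves(params, np.array([year]))
    return PrevalenceState(float(modern[0]), float(traditional[0]), float(unmet[0]))


@dataclass
class Trajectory:
    """Annual projected series of family-planning indicators for one country.

    ``demand`` and ``ds`` are always recomputed from the component
    series, never stored, so they cannot drift out of sync.
    """

    country: str
    years: np.ndarray
    modern: np.ndarray
    traditional: np.ndarray
    unmet: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.modern = np.asarray(self.modern, dtype=float)
        self.traditional = np.asarray(self.traditional, dtype=float)
        self.unmet = np.asarray(self.unmet, dtype=float)
        n = len(self.years)
        for name in ("modern", "traditional", "unmet"):
            series = getattr(self, name)
            if len(series) != n:
                raise ValidationError(f"{name} series length {len(series)} != {n} years")
            if np.any(series < 0.0) or not np.all(np.isfinite(series)):
                bad = int(np.argmin(series))
                raise ValidationError(
                    f"{name} must be finite and >= 0; offending year "
                    f"{self.years[bad]}: {series[bad]!r}"
                )
        total = self.modern + self.traditional + self.unmet
        if np.any(total > 1.0 + SUM_TOLERANCE):
            bad = int(np.argmax(total))
            raise ValidationError(
                f"component sum exceeds 1 at year {self.years[bad]}: {total[bad]!r}"
            )
        if n > 1 and np.any(np.diff(self.years) != 1):
            raise ValidationError("years must form a consecutive integer grid")

    @property
    def demand(self) -> np.ndarray:
        return self.modern + self.traditional + self.unmet

    @property
    def ds(self) -> np.ndarray:
        demand = self.demand
        out = np.zeros_like(demand)
        np.divide(self.modern, demand, out=out, where=demand > 0.0)
        return out

    def covers(self, y_start: int, y_end: int) -> bool:
        return self.years[0] <= y_start and y_end <= self.years[-1]

    def index_of(self, year: int) -> int:
        if not (self.years[0] <= year <= self.years[-1]):
            raise ValidationError(
                f"year {year} is off the trajectory grid "
                f"[{self.years[0]}, {self.years[-1]}] for {self.country}"
            )
        return int(year - self.years[0])

    def state_at(self, year: int) -> PrevalenceState:
        i = self.index_of(year)
        return PrevalenceState(
            float(self.modern[i]), float(self.traditional[i]), float(self.unmet[i])
        )


@dataclass(frozen=True)
class PriorPenalty:
    """Quadratic shrinkage applied during fitting.

    ``asymptote_center``/``rate_center`` are the values the asymptote and
    growth rate are pulled toward with the given weights; they stand in
    for the regional experience a hierarchical multi-country model would
    borrow.  The default weights are light: they decide the fit only
    where the data are uninformative (one or two surveys), and perturb a
    well-identified eight-survey fit by well under 1e-3 in relative
    terms.  ``slope_ridge`` is a tiny ridge on the two slope parameters
    that keeps the problem fully determined even with a single
    observation.
    """

    asymptote_center: float = 0.85
    asymptote_weight: float = 0.05
    rate_center: float = 0.07
    rate_weight: float = 0.05
    slope_ridge: float = 1e-6


def _observed_components(observations: Sequence[SurveyObservation]):
    """Per-observation (year, total prev, modern share, unmet fraction of non-users)."""
    t = np.array([o.year for o in observations], dtype=float)
    modern = np.array([o.modern for o in observations], dtype=float)
    traditional = np.array([o.traditional for o in observations], dtype=float)
    unmet = np.array([o.unmet for o in observations], dtype=float)
    total = modern + traditional
    share = np.where(total > 0.0, modern / np.maximum(total, _EPS), 0.5)
    nonuser = np.clip(1.0 - total, _EPS, 1.0)
    ufrac = unmet / nonuser
    return t, total, share, ufrac


def _line_fit(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least-squares line y ~ a + b x; slope 0 when degenerate."""
    if len(x) < 2 or np.ptp(x) == 0.0:
        return float(np.average(y, weights=w)), 0.0
    b, a = np.polyfit(x, y, 1, w=np.sqrt(w))
    return float(a), float(b)


def _starting_point(
    t: np.ndarray,
    total: np.ndarray,
    share: np.ndarray,
    ufrac: np.ndarray,
    w: np.ndarray,
    penalty: PriorPenalty,
) -> np.ndarray:
    """Documented deterministic start.

    Asymptote and rate start at the penalty centres.  The midpoint starts
    where a straight-line fit of logit(total/asymptote) against year
    crosses zero; with a single observation this degenerates to placing
    the default curve exactly through that observation.  Share and unmet
    parameters start at line fits of the corresponding log-odds.
    """
    pmax0 = penalty.asymptote_center
    rate0 = penalty.rate_center
    z = np.asarray(_logit(total / pmax0), dtype=float)
    a_z, b_z = _line_fit(t, z, w)
    if abs(b_z) > 1e-4:
        rate0 = float(np.clip(b_z, 0.005, 0.9))
        mid0 = float(np.clip(-a_z / b_z, _LOWER[2], _UPPER[2]))
    else:
        # flat series: anchor the default curve on the last observation
        mid0 = float(np.clip(t[-1] - z[-1] / rate0, _LOWER[2], _UPPER[2]))
    a_s, b_s = _line_fit(t - mid0, np.asarray(_logit(share)), w)
    # unmet log-odds against modelled total prevalence at the start
    p0 = pmax0 * expit(rate0 * (t - mid0))
    a_u, b_u = _line_fit(p0, np.asarray(_logit(ufrac)), w)
    x0 = np.array(
        [
            pmax0,
            rate0,
            mid0,
            np.clip(a_s, _LOWER[3], _UPPER[3]),
            np.clip(b_s, _LOWER[4], _UPPER[4]),
            np.clip(a_u, _LOWER[5], _UPPER[5]),
            np.clip(b_u, _LOWER[6], _UPPER[6]),
        ]
    )
    return np.clip(x0, _LOWER, _UPPER)


def fit_transition(
    observations: Sequence[SurveyObservation],
    penalty: PriorPenalty | None = None,
) -> TransitionParameters:
    """Fit transition parameters to one country's survey series.

    Minimises the weighted squared error of total prevalence, modern
    share, and unmet-fraction-of-non-users on the log-odds scale, plus
    quadratic penalties pulling ``cpr_asymptote`` and ``cpr_rate`` toward
    the :class:`PriorPenalty` centres.  Weights are proportional to
    ``1/obs_sd**2`` when every observation carries ``obs_sd``, equal
    otherwise.  Deterministic: fixed start, bounded trust-region solver,
    no randomness.

    Raises :class:`ValidationError` with no observations and
    :class:`FitError` (with optimiser diagnostics) on non-convergence.
    """
    if penalty is None:
        penalty = PriorPenalty()
    observations = list(observations)
    if not observations:
        raise ValidationError("fit_transition requires at least one observation")

    t, total, share, ufrac = _observed_components(observations)
    sds = [o.obs_sd for o in observations]
    if all(sd is not None for sd in sds):
        w = 1.0 / np.array(sds, dtype=float) ** 2
        w = w / w.mean()
    else:
        w = np.ones_like(t)
    sw = np.sqrt(w)

    z_total = np.asarray(_logit(total))
    z_share = np.asarray(_logit(share))
    z_ufrac = np.asarray(_logit(ufrac))
    pen_a = np.sqrt(penalty.asymptote_weight)
    pen_r = np.sqrt(penalty.rate_weight)
    pen_s = np.sqrt(penalty.slope_ridge)

    def residuals(x: np.ndarray) -> np.ndarray:
        pmax, rate, mid, a_s, b_s, a_u, b_u = x
        p_model = pmax * expit(rate * (t - mid))
        r_total = sw * (z_total - _logit(p_model))
        r_share = sw * (z_share - (a_s + b_s * (t - mid)))
        r_ufrac = sw * (z_ufrac - (a_u + b_u * p_model))
        return np.concatenate(
            [
                r_total,
                r_share,
                r_ufrac,
                [
                    pen_a * (pmax - penalty.asymptote_center),
                    pen_r * (rate - penalty.rate_center),
                    pen_s * b_s,
                    pen_s * b_u,
                ],
            ]
        )

    x0 = _starting_point(t, total, share, ufrac, w, penalty)
    result = least_squares(
        residuals,
        x0,
        bounds=(_LOWER, _UPPER),
        method="trf",
        x_scale=_X_SCALE,
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=5000,
    )
    if not result.success:
        raise FitError(
            f"transition fit failed for {observations[0].country!r}: "
            f"{result.message} (status {result.status}, cost {result.cost:.6g})",
            status=result.status,
            cost=float(result.cost),
        )
    return TransitionParameters.from_array(result.x)


def project(
    params: TransitionParameters, country: str, y_start: int, y_end: int
) -> Trajectory:
    """Project the BAU trajectory on the integer-year grid [y_start, y_end]."""
    if y_start > y_end:
        raise ValidationError(f"year range inverted: {y_start} > {y_end}")
    years = np.arange(int(y_start), int(y_end) + 1)
    modern, traditional, unmet = _curves(params, years)
    return Trajectory(country, years, modern, traditional, unmet)


# ---------------------------------------------------------------------------
# delimited-text interfaces (percent scale on disk)
# ---------------------------------------------------------------------------

_SURVEY_COLUMNS = ["country", "year", "modern_pct", "traditional_pct", "unmet_pct"]


def read_survey_csv(path) -> list[SurveyObservation]:
    """Read survey observations from CSV (percent scale, header required)."""
    frame = pd.read_csv(path)
    missing = [c for c in _SURVEY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"survey CSV {path} lacks required columns: {missing}")
    has_sd = "obs_sd_pct" in frame.columns
    observations = []
    for row in frame.itertuples(index=False):
        sd = getattr(row, "obs_sd_pct", None) if has_sd else None
        if sd is not None and (pd.isna(sd) or sd == 0):
            sd = None
        observations.append(
            SurveyObservation(
                country=str(row.country),
                year=float(row.year),
                modern=percent_to_proportion(float(row.modern_pct)),
                traditional=percent_to_proportion(float(row.traditional_pct)),
                unmet=percent_to_proportion(float(row.unmet_pct)),
                obs_sd=None if sd is None else float(sd) / 100.0,
            )
        )
    return observations


def write_survey_csv(observations: Iterable[SurveyObservation], path) -> None:
    rows = [
        {
            "country": o.country,
            "year": o.year,
            "modern_pct": proportion_to_percent(o.modern),
            "traditional_pct": proportion_to_percent(o.traditional),
            "unmet_pct": proportion_to_percent(o.unmet),
            "obs_sd_pct": None if o.obs_sd is None else o.obs_sd * 100.0,
        }
        for o in observations
    ]
    frame = pd.DataFrame(rows, columns=_SURVEY_COLUMNS + ["obs_sd_pct"])
    frame.to_csv(path, index=False)


def group_by_country(
    observations: Iterable[SurveyObservation],
) -> dict[str, list[SurveyObservation]]:
    """Group a flat observation list by country, preserving input order."""
    grouped: dict[str, list[SurveyObservation]] = {}
    for obs in observations:
        grouped.setdefault(obs.country, []).append(obs)
    return grouped


_TRAJ_COLUMNS = [
    "country",
    "year",
    "modern_pct",
    "traditional_pct",
    "unmet_pct",
    "demand_pct",
    "ds_pct",
]


def write_trajectory_csv(trajectories: Iterable[Trajectory], path) -> None:
    frames = []
    for traj in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "country": traj.country,
                    "year": traj.years,
                    "modern_pct": traj.modern * 100.0,
                    "traditional_pct": traj.traditional * 100.0,
                    "unmet_pct": traj.unmet * 100.0,
                    "demand_pct": traj.demand * 100.0,
                    "ds_pct": traj.ds * 100.0,
                }
            )
        )
    out = pd.concat(frames) if frames else pd.DataFrame(columns=_TRAJ_COLUMNS)
    out.to_csv(path, index=False, columns=_TRAJ_COLUMNS)


def read_trajectory_csv(path) -> list[Trajectory]:
    frame = pd.read_csv(path)
    missing = [c for c in _TRAJ_COLUMNS[:5] if c not in frame.columns]
    if missing:
        raise ValidationError(f"trajectory CSV {path} lacks required columns: {missing}")
    trajectories = []
    for country, sub in frame.groupby("country", sort=False):
        sub = sub.sort_values("year")
        trajectories.append(
            Trajectory(
                str(country),
                sub["year"].to_numpy(),
                sub["modern_pct"].to_numpy() / 100.0,
                sub["traditional_pct"].to_numpy() / 100.0,
                sub["unmet_pct"].to_numpy() / 100.0,
            )
        )
    return trajectories


def write_parameters_csv(params_by_country: dict[str, TransitionParameters], path) -> None:
    rows = [
        {"country": country, **{f: getattr(p, f) for f in _PARAM_FIELDS}}
        for country, p in params_by_country.items()
    ]
    pd.DataFrame(rows, columns=["country", *_PARAM_FIELDS]).to_csv(path, index=False)


def read_parameters_csv(path) -> dict[str, TransitionParameters]:
    frame = pd.read_csv(path)
    missing = [c for c in _PARAM_FIELDS if c not in frame.columns]
    if missing:
        raise ValidationError(f"parameters CSV {path} lacks required columns: {missing}")
    return {
        str(row.country): TransitionParameters(
            *(float(getattr(row, f)) for f in _PARAM_FIELDS)
        )
        for row in frame.itertuples(index=False)
    }
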