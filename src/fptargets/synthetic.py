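"""Synthetic survey panels with known ground truth.

Emulates the sparse survey record the assessment runs on in practice:
roughly eight observations per country between 1968 and 2019, measured
with sampling noise, lying on a contraceptive-use transition.  Every
generator is seeded (NumPy ``default_rng``, i.e. the PCG64 bit
generator) and deterministic given its seed.

Noise model: each observed quantity (total prevalence, modern share of
users, unmet fraction of non-users) receives independent Gaussian noise
on the log-odds scale, sized like binomial sampling error with a fixed
effective sample size: ``noise_sd`` is the proportion-scale standard
deviation at a mid-range proportion (q = 0.5), equivalent to an
effective sample size of ``1/(4 noise_sd^2)`` (625 for the default
0.02), and the log-odds standard deviation ``2 noise_sd / sqrt(q(1-q))``
is the delta-method image of the binomial proportion error.  It is
capped at 1.5 so pre-transition prevalences near zero stay small under
noise, as they do in real surveys.  Components are reconstructed from
the perturbed quantities, giving a valid prevalence state by
construction, whatever the draw.

Scenario presets draw truth parameters from documented uniform ranges
chosen so that the labelled behaviour holds for every draw (on-track
countries satisfy the DS goal already; late countries cross it strictly
between the goal year and the cap; capped countries never cross by the
cap year).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .indicators import ValidationError
from .transition import (
    PriorPenalty,
    SurveyObservation,
    TransitionParameters,
    fit_transition,
    model_curves,
)

__all__ = [
    "SyntheticCountrySpec",
    "STYLIZED_LATE_TRUTH",
    "SCENARIOS",
    "SCENARIO_RANGES",
    "generate_observations",
    "generate_panel",
    "parametric_bootstrap",
]

#: Stylized low-prevalence country used in examples and tests: current
#: mCPR in the low twenties (percent) and DS75 reached in the mid-2050s
#: under business as usual.
STYLIZED_LATE_TRUTH = TransitionParameters(
    cpr_asymptote=0.82,
    cpr_rate=0.055,
    cpr_midpoint=2028.0,
    share_intercept=0.9,
    share_slope=0.035,
    unmet_intercept=0.1,
    unmet_slope=-2.2,
)

#: Mid-transition country whose prevalence rise is essentially complete
#: within the survey era, so every parameter is well identified from the
#: default survey calendar.  Used for parameter-recovery studies.
MID_TRANSITION_TRUTH = TransitionParameters(
    cpr_asymptote=0.80,
    cpr_rate=0.09,
    cpr_midpoint=1990.0,
    share_intercept=0.5,
    share_slope=0.04,
    unmet_intercept=-0.3,
    unmet_slope=-2.0,
)

#: default survey calendar: eight rounds spanning the survey era
DEFAULT_SURVEY_YEARS = (1968.0, 1975.0, 1983.0, 1990.0, 1998.0, 2005.0, 2012.0, 2019.0)


@dataclass(frozen=True)
class SyntheticCountrySpec:
    """Recipe for one synthetic country: truth curves + survey design."""

    country: str
    truth: TransitionParameters
    survey_years: tuple[float, ...] = DEFAULT_SURVEY_YEARS
    noise_sd: float = 0.02
    mwra: float = 5e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0.0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd!r}")
        if self.mwra < 0.0:
            raise ValidationError(f"mwra must be >= 0, got {self.mwra!r}")


def _noisy_logit(q: float, sd_prop: float, rng: np.random.Generator) -> float:
    """Perturb a proportion on the log-odds scale with binomial-like error.

    ``sd_prop`` is the proportion-scale sd at q = 0.5; the log-odds sd
    scales as for a binomial proportion with that precision and is
    capped at 1.5 so near-degenerate proportions stay near-degenerate.
    """
    qc = float(np.clip(q, 1e-5, 1.0 - 1e-5))
    sd_logit = min(2.0 * sd_prop / math.sqrt(qc * (1.0 - qc)), 1.5)
    z = float(np.clip(logit(qc) + rng.normal(0.0, sd_logit), -12.0, 12.0))
    return float(expit(z))


def generate_observations(spec: SyntheticCountrySpec) -> list[SurveyObservation]:
    """Draw one noisy survey series from the spec's truth curves."""
    rng = np.random.default_rng(spec.seed)
    observations = []
    for year in spec.survey_years:
        state = model_curves(spec.truth, year)
        total = state.modern + state.traditional
        share = state.modern / total if total > 0.0 else 0.5
        nonuser = max(1.0 - total, 1e-9)
        ufrac = state.unmet / nonuser
        if spec.noise_sd == 0.0:
            modern, traditional, unmet = state.modern, state.traditional, state.unmet
        else:
            total_n = _noisy_logit(total, spec.noise_sd, rng)
            share_n = _noisy_logit(share, spec.noise_sd, rng)
            ufrac_n = _noisy_logit(ufrac, spec.noise_sd, rng)
            modern = share_n * total_n
            traditional = (1.0 - share_n) * total_n
            unmet = (1.0 - total_n) * ufrac_n
        observations.append(
            SurveyObservation(
                country=spec.country,
                year=year,
                modern=modern,
                traditional=traditional,
                unmet=unmet,
                obs_sd=spec.noise_sd if spec.noise_sd > 0.0 else None,
            )
        )
    return observations


# Uniform truth-parameter ranges per scenario class.  The bounds are
# chosen so the class property holds at every corner of the box (checked
# in the test suite): "on_track" countries have DS >= 0.75 already in
# 2019, "late" countries cross 0.75 strictly after 2030 but before 2100,
# and "capped" countries keep the modern share -- an upper bound on DS --
# below 0.75 through 2100.
SCENARIO_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "on_track": {
        "cpr_asymptote": (0.85, 0.95),
        "cpr_rate": (0.07, 0.10),
        "cpr_midpoint": (1980.0, 1995.0),
        "share_intercept": (1.8, 2.5),
        "share_slope": (0.02, 0.05),
        "unmet_intercept": (-1.0, -0.5),
        "unmet_slope": (-3.0, -2.0),
    },
    "late": {
        "cpr_asymptote": (0.75, 0.90),
        "cpr_rate": (0.06, 0.09),
        "cpr_midpoint": (2032.0, 2048.0),
        "share_intercept": (0.2, 0.8),
        "share_slope": (0.04, 0.07),
        "unmet_intercept": (-0.5, 0.5),
        "unmet_slope": (-3.0, -1.5),
    },
    "capped": {
        "cpr_asymptote": (0.40, 0.55),
        "cpr_rate": (0.04, 0.07),
        "cpr_midpoint": (2030.0, 2060.0),
        "share_intercept": (0.0, 0.3),
        "share_slope": (0.0, 0.004),
        "unmet_intercept": (0.0, 0.5),
        "unmet_slope": (-1.0, 0.0),
    },
}

#: scenario presets accepted by :func:`generate_panel`
SCENARIOS = ("mixed", "all-late", "all-on-track", "capped")

# class mix for the "mixed" preset, matching the observed split of the 68
# assessed countries: 18 on track, 47 needing acceleration, 3 capped
_MIXED_WEIGHTS = {"on_track": 18 / 68, "late": 47 / 68, "capped": 3 / 68}


def _draw_truth(rng: np.random.Generator, ranges: dict[str, tuple[float, float]]) -> TransitionParameters:
    return TransitionParameters(
        **{name: float(rng.uniform(lo, hi)) for name, (lo, hi) in ranges.items()}
    )


def generate_panel(
    n_countries: int,
    seed: int,
    scenario: str = "mixed",
    noise_sd: float = 0.02,
    n_surveys: int = 8,
) -> list[SyntheticCountrySpec]:
    """Draw a panel of synthetic country specs for a scenario preset.

    Survey years are ``n_surveys`` distinct integers in [1968, 2019] per
    country; MWRA denominators are log-uniform between ~0.3 and ~50
    million.  Deterministic given ``seed``.  In the "mixed" preset the
    first three countries are pinned to one class each, so every class is
    non-empty whenever ``n_countries >= 3``.
    """
    if scenario not in SCENARIOS:
        raise ValidationError(
            f"unknown scenario {scenario!r}; available presets: {', '.join(SCENARIOS)}"
        )
    rng = np.random.default_rng(seed)
    if scenario == "all-late":
        classes = ["late"] * n_countries
    elif scenario == "all-on-track":
        classes = ["on_track"] * n_countries
    elif scenario == "capped":
        classes = ["capped"] * n_countries
    else:
        names = list(_MIXED_WEIGHTS)
        classes = names[: min(3, n_countries)]
        if n_countries > 3:
            probs = np.array([_MIXED_WEIGHTS[c] for c in names])
            classes += list(rng.choice(names, size=n_countries - 3, p=probs))
    specs = []
    for i, cls in enumerate(classes):
        truth = _draw_truth(rng, SCENARIO_RANGES[cls])
        years = tuple(
            float(y) for y in sorted(rng.choice(np.arange(1968, 2020), size=n_surveys, replace=False))
        )
        mwra = float(10.0 ** rng.uniform(5.5, 7.7))
        specs.append(
            SyntheticCountrySpec(
                country=f"SYN-{i:03d}-{cls}",
                truth=truth,
                survey_years=years,
                noise_sd=noise_sd,
                mwra=mwra,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def parametric_bootstrap(
    truth: TransitionParameters,
    n_replicates: int,
    seed: int,
    survey_years: Sequence[float] = DEFAULT_SURVEY_YEARS,
    noise_sd: float = 0.02,
    penalty: PriorPenalty | None = None,
    country: str = "bootstrap",
) -> list[TransitionParameters]:
    """Refit the model to ``n_replicates`` noisy redraws from ``truth``.

    A cheap uncertainty wrapper around :func:`fit_transition`; the spread
    of the returned parameters approximates sampling variability of the
    fit under the stated noise model.
    """
    rng = np.random.default_rng(seed)
    fits = []
    for _ in range(n_replicates):
        spec = SyntheticCountrySpec(
            country=country,
            truth=truth,
            survey_years=tuple(float(y) for y in survey_years),
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        fits.append(fit_transition(generate_observations(spec), penalty=penalty))
    return fits
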