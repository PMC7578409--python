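"""Results tables, the packaged DS75 assessment table, and summaries.

The package ships the published 50-country DS75 assessment table (the
countries projected to need acceleration, ordered by target year) as a
checksummed CSV fixture.  Its country-specific target mCPRs, gaps and
user counts come from full Bayesian model fits to the UN survey
compilation and are served verbatim as printed inputs; the only column
that is a deterministic function of the others -- the relative
acceleration, from the target year -- is recomputable here and used for
validation.

Unit conventions on disk follow the published table: percent for mCPR
targets, percentage points for gaps, millions for user counts.
"""

from __future__ import annotations

import hashlib
import io
import logging
import math
import unicodedata
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .at_method import ATConfig, ATResult, relative_acceleration
from .db_method import DBResult
from .indicators import ValidationError, proportion_to_percent

__all__ = [
    "Table1Row",
    "TABLE1_SHA256",
    "round_half_away",
    "load_table1_fixture",
    "write_table1",
    "Summary",
    "summarize_results",
    "write_results",
    "read_results",
]

logger = logging.getLogger(__name__)

_FIXTURE_NAME = "table1_ds75.csv"

#: sha256 of the packaged fixture; the loader refuses a file that does not match
TABLE1_SHA256 = "61260619f2d3303052061e0c837a0dcf7e37477714553c5099fb0f7cad3b97c7"

_TABLE1_COLUMNS = [
    "country",
    "country_ascii",
    "target_year",
    "target_mcpr_pct",
    "mcpr_gap_pp",
    "users_gap_millions",
    "acceleration",
    "db_column_pct",
]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of the published table)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def ascii_name(name: str) -> str:
    """ASCII-normalised country name (accents stripped)."""
    return unicodedata.normalize("NFKD", name).encode("ascii", "ignore").decode("ascii")


@dataclass(frozen=True)
class Table1Row:
    """One row of the published DS75 assessment table.

    ``db_column`` stores the table's final printed column verbatim; its
    published heading is ambiguous (it matches the DB *target* quoted in
    the text, not a gap), so computation never interprets it.
    """

    country: str
    country_ascii: str
    target_year: int
    target_mcpr: float
    mcpr_gap: float
    users_gap: float
    acceleration: float
    db_column: float

    def __post_init__(self) -> None:
        if not (2031 <= self.target_year <= 2100):
            raise ValidationError(
                f"target_year must be in [2031, 2100], got {self.target_year!r}"
            )
        if self.acceleration < 1.1:
            raise ValidationError(
                f"acceleration must be >= 1.1 in the accelerating-country table, "
                f"got {self.acceleration!r}"
            )


def load_table1_fixture(path=None) -> list[Table1Row]:
    """Load the packaged 50-row DS75 assessment table.

    ``path`` overrides the packaged file (e.g. for a vendored copy); the
    content checksum is verified either way.
    """
    if path is None:
        source = resources.files("fptargets").joinpath("data").joinpath(_FIXTURE_NAME)
        raw = source.read_bytes()
    else:
        with open(path, "rb") as fh:
            raw = fh.read()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE1_SHA256:
        raise ValidationError(
            f"DS75 table fixture is corrupt: sha256 {digest} != expected {TABLE1_SHA256}"
        )
    logger.info("loaded DS75 assessment fixture (sha256 %s)", digest[:12])
    frame = pd.read_csv(io.BytesIO(raw), encoding="utf-8")
    rows = [
        Table1Row(
            country=str(r.country),
            country_ascii=str(r.country_ascii),
            target_year=int(r.target_year),
            target_mcpr=float(r.target_mcpr_pct),
            mcpr_gap=float(r.mcpr_gap_pp),
            users_gap=float(r.users_gap_millions),
            acceleration=float(r.acceleration),
            db_column=float(r.db_column_pct),
        )
        for r in frame.itertuples(index=False)
    ]
    if len(rows) != 50:
        raise ValidationError(f"DS75 table fixture must have 50 rows, got {len(rows)}")
    return rows


def write_table1(rows: Iterable[Table1Row], path) -> None:
    """Serialise assessment-table rows in the fixture dialect."""
    frame = pd.DataFrame(
        [
            {
                "country": r.country,
                "country_ascii": r.country_ascii,
                "target_year": r.target_year,
                "target_mcpr_pct": r.target_mcpr,
                "mcpr_gap_pp": r.mcpr_gap,
                "users_gap_millions": r.users_gap,
                "acceleration": r.acceleration,
                "db_column_pct": r.db_column,
            }
            for r in rows
        ],
        columns=_TABLE1_COLUMNS,
    )
    frame.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


@dataclass(frozen=True)
class Summary:
    """Headline counts of an assessment panel.

    ``n_accel_at_least`` counts countries whose *unrounded* relative
    acceleration (recomputed from the target year for table rows) meets
    the threshold; gaps are in percentage points.
    """

    n: int
    n_accel_at_least: int
    accel_threshold: float
    gap_min: float
    gap_max: float
    accel_min: float
    accel_max: float


def summarize_results(
    rows: Sequence[Table1Row] | Sequence[ATResult],
    accel_threshold: float = 3.0,
    config: ATConfig | None = None,
) -> Summary:
    """Summarise a panel of table rows or AT results."""
    if len(rows) == 0:
        raise ValidationError("summarize_results requires a non-empty panel")
    if config is None:
        config = ATConfig()
    if isinstance(rows[0], Table1Row):
        accels = [relative_acceleration(r.target_year, config) for r in rows]
        gaps = [r.mcpr_gap for r in rows]
    else:
        accels = [r.rel_accel for r in rows]
        gaps = [proportion_to_percent(r.mcpr_gap) for r in rows]
    return Summary(
        n=len(rows),
        n_accel_at_least=sum(a >= accel_threshold for a in accels),
        accel_threshold=accel_threshold,
        gap_min=min(gaps),
        gap_max=max(gaps),
        accel_min=min(accels),
        accel_max=max(accels),
    )


_RESULT_COLUMNS = [
    "country",
    "target_year",
    "target_mcpr_pct",
    "mcpr_gap_pp",
    "users_gap_millions",
    "acceleration",
    "db_target_mcpr_pct",
    "db_gap_pp",
    "at_minus_db_pp",
    "capped",
    "on_track",
]


def write_results(
    results: Iterable[tuple[ATResult, DBResult | None]] | pd.DataFrame, path
) -> None:
    """Write the assessment-results CSV (one row per country).

    Reported percents/gaps are rounded to one decimal (half away from
    zero) and user counts to 0.01 million, matching the published table;
    all internal arithmetic stays unrounded.  Accepts either
    ``(ATResult, DBResult | None)`` pairs or a frame previously produced
    by :func:`read_results` (round-trip re-serialisation).
    """
    if isinstance(results, pd.DataFrame):
        frame = results[_RESULT_COLUMNS]
    else:
        records = []
        for at, db in results:
            records.append(
                {
                    "country": at.country,
                    "target_year": at.t_star,
                    "target_mcpr_pct": round_half_away(proportion_to_percent(at.target_mcpr)),
                    "mcpr_gap_pp": round_half_away(at.mcpr_gap * 100.0),
                    "users_gap_millions": None
                    if at.users_gap is None
                    else round_half_away(at.users_gap / 1e6, 2),
                    "acceleration": round_half_away(at.rel_accel),
                    "db_target_mcpr_pct": None
                    if db is None
                    else round_half_away(proportion_to_percent(db.db_target_mcpr)),
                    "db_gap_pp": None if db is None else round_half_away(db.db_gap * 100.0),
                    "at_minus_db_pp": None
                    if db is None
                    else round_half_away((at.mcpr_gap - db.db_gap) * 100.0),
                    "capped": at.capped,
                    "on_track": at.on_track,
                }
            )
        frame = pd.DataFrame(records, columns=_RESULT_COLUMNS)
    frame.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def read_results(path) -> pd.DataFrame:
    """Read an assessment-results CSV back into a frame."""
    frame = pd.read_csv(path)
    missing = [c for c in _RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"results CSV {path} lacks required columns: {missing}")
    return frame
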