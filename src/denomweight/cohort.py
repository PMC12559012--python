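"""Cohort preparation for a pseudonymized patient registry.

Turns a raw registry extract into the analysis cohort used for
denominator-correction weighting:

1. de-duplication on the pseudonymized person identifier,
2. exclusion of records missing age or sex,
3. restriction to adults (default 18+),
4. derivation of the health-care *engagement* flag — whether any of the
   five recorded contact streams (GP consultation, hospitalization,
   laboratory result, COVID-19 test, COVID-19 vaccination) falls inside
   the lookback window ending at the index date.

The module also owns the demographic vocabulary shared across the
package: the seven NHS regions, the two recorded sexes, the single-year
weighting strata (18..89 plus an open-ended 90+), and the fifteen
presentational age bands used in distribution tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REGIONS: tuple[str, ...] = (
    "East of England",
    "London",
    "Midlands",
    "North East and Yorkshire",
    "North West",
    "South East",
    "South West",
)

SEXES: tuple[str, ...] = ("F", "M")

#: The five engagement event streams, in registry-CSV column order.
EVENT_COLUMNS: tuple[str, ...] = (
    "gp_consult_date",
    "hospitalization_date",
    "lab_result_date",
    "covid_test_date",
    "covid_vaccination_date",
)

# Presentational age bands: a wide 18-25 band, five-year bands to 90,
# then open-ended 90+.  Bands are half-open [lower, upper) — the upper
# label is exclusive, which is the only non-overlapping reading of
# labels like "18-25" followed by "25-30".
AGE_BAND_EDGES: tuple[int, ...] = (18, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85, 90)
AGE_BAND_LABELS: tuple[str, ...] = tuple(
    f"{lo}-{hi}" for lo, hi in zip(AGE_BAND_EDGES[:-1], AGE_BAND_EDGES[1:])
) + ("90+",)

#: Single-year weighting strata for the age axis.
STRATUM_AGE_LABELS: tuple[str, ...] = tuple(str(a) for a in range(18, 90)) + ("90+",)

STRATUM_COLUMNS: tuple[str, ...] = ("stratum_age", "sex", "region")

_MIN_TIMESTAMP = pd.Timestamp("1900-01-01")


class MalformedDateError(ValueError):
    """A registry row carries an unparseable event date."""


@dataclass(frozen=True)
class EngagementWindow:
    """Closed lookback interval [start, index_date] for engagement events."""

    start: date = date(2019, 1, 1)
    index_date: date = date(2021, 10, 1)

    def __post_init__(self) -> None:
        if self.start >= self.index_date:
            raise ValueError(
                f"engagement window start ({self.start}) must precede the "
                f"index date ({self.index_date})"
            )


@dataclass
class ExclusionLog:
    """Disjoint exclusion counts, applied in order: missing demographics, then age."""

    n_input: int = 0
    missing_demographics: int = 0
    under_age: int = 0
    n_output: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def assign_age_band(age_years: int) -> str:
    """Map an adult age in whole years to its presentational band.

    Bands are half-open: 25 falls in "25-30", not "18-25"; 90 and above
    fall in "90+".
    """
    if age_years < 18:
        raise ValueError(f"age {age_years} is below the adult cutoff of 18")
    idx = int(np.searchsorted(AGE_BAND_EDGES, age_years, side="right")) - 1
    return AGE_BAND_LABELS[idx]


def assign_age_bands(ages: pd.Series) -> pd.Series:
    """Vectorized :func:`assign_age_band` over a Series of adult ages."""
    if (ages < 18).any():
        bad = ages[ages < 18]
        raise ValueError(f"ages below 18 cannot be banded: {sorted(bad.unique())}")
    idx = np.searchsorted(AGE_BAND_EDGES, ages.to_numpy(), side="right") - 1
    return pd.Series(np.asarray(AGE_BAND_LABELS, dtype=object)[idx], index=ages.index)


def stratum_age(ages: pd.Series) -> pd.Series:
    """Single-year weighting stratum label: "18".."89" or "90+"."""
    a = ages.astype(int)
    return pd.Series(
        np.where(a >= 90, "90+", a.astype(str)), index=ages.index, dtype=object
    )


# ---------------------------------------------------------------------------
# Registry IO
# ---------------------------------------------------------------------------

def read_registry(path: str | Path) -> pd.DataFrame:
    """Read a registry CSV, parsing event dates and validating them.

    Empty cells mean a missing value (no event / unknown demographic).
    A non-empty cell that does not parse as an ISO-8601 date raises
    :class:`MalformedDateError` naming the offending row ids.
    """
    df = pd.read_csv(
        path,
        dtype={
            "record_row_id": np.int64,
            "pseudo_id": str,
            "sex": str,
            "region": str,
            "vaccinated": np.int64,
        },
    )
    df["age_years"] = pd.to_numeric(df["age_years"], errors="raise")
    for col in EVENT_COLUMNS:
        raw = df[col]
        parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        bad = raw.notna() & parsed.isna()
        if bad.any():
            rows = df.loc[bad, "record_row_id"].tolist()[:10]
            raise MalformedDateError(
                f"malformed {col} for record_row_id(s) {rows}"
            )
        df[col] = parsed
    return df


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False, date_format="%Y-%m-%d")


# ---------------------------------------------------------------------------
# Preparation stages
# ---------------------------------------------------------------------------

def deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """Keep one row per pseudonymized identifier.

    The retained row is the one whose most recent event date (across all
    five streams) is latest; rows with no events sort last.  Ties are
    broken by the smallest record_row_id, so the result is deterministic.
    """
    latest = records[list(EVENT_COLUMNS)].max(axis=1).fillna(_MIN_TIMESTAMP)
    order = (
        records.assign(_latest=latest)
        .sort_values(
            ["pseudo_id", "_latest", "record_row_id"],
            ascending=[True, False, True],
            kind="mergesort",
        )
        .drop_duplicates("pseudo_id", keep="first")
        .drop(columns="_latest")
        .sort_values("record_row_id")
        .reset_index(drop=True)
    )
    logger.info("deduplicate: %d rows -> %d unique ids", len(records), len(order))
    return order


def apply_exclusions(
    records: pd.DataFrame, min_age: int = 18
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop rows missing age or sex, then rows under ``min_age``.

    The two exclusion counts are disjoint and applied in that order; the
    total excluded does not depend on the order.  Surviving rows gain
    integer ``age_years``, ``age_band`` and ``stratum_age`` columns.
    """
    log = ExclusionLog(n_input=len(records))
    missing = records["age_years"].isna() | records["sex"].isna()
    log.missing_demographics = int(missing.sum())
    kept = records.loc[~missing].copy()
    kept["age_years"] = kept["age_years"].astype(int)

    under = kept["age_years"] < min_age
    log.under_age = int(under.sum())
    kept = kept.loc[~under].copy()
    log.n_output = len(kept)

    if len(kept):
        kept["age_band"] = assign_age_bands(kept["age_years"])
        kept["stratum_age"] = stratum_age(kept["age_years"])
    else:
        kept["age_band"] = pd.Series(dtype=object)
        kept["stratum_age"] = pd.Series(dtype=object)
    logger.info(
        "apply_exclusions: missing demographics %d, under age %d, kept %d",
        log.missing_demographics, log.under_age, log.n_output,
    )
    return kept.reset_index(drop=True), log


def flag_engagement(records: pd.DataFrame, window: EngagementWindow) -> pd.DataFrame:
    """Set ``engaged`` true iff any event date lies in the closed window."""
    start = pd.Timestamp(window.start)
    end = pd.Timestamp(window.index_date)
    engaged = np.zeros(len(records), dtype=bool)
    for col in EVENT_COLUMNS:
        engaged |= records[col].between(start, end).to_numpy()
    out = records.copy()
    out["engaged"] = engaged
    return out


def prepare_cohort(
    registry: pd.DataFrame,
    window: EngagementWindow,
    min_age: int = 18,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """De-duplicate, exclude, and flag engagement in one pass."""
    deduped = deduplicate(registry)
    cohort, log = apply_exclusions(deduped, min_age=min_age)
    return flag_engagement(cohort, window), log
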