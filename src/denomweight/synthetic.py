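"""Synthetic patient registry and census-style reference population.

Real national registry extracts are access-controlled, so the package
ships a generator that reproduces the *statistical pathologies* such
data exhibit, with per-record ground truth for testing:

* a census-style reference population by single year of age (18..89,
  90+) × sex × seven NHS regions, drawn multinomially from a realistic
  adult age pyramid and regional population shares;
* a registry whose stratum counts are the reference counts scaled by an
  over-representation factor at ages 30–45 and an under-representation
  factor at ages 65–75, then Poisson-perturbed;
* an *inactive* fraction of records (default 2.4%) that carry no
  engagement events inside the lookback window and are never
  vaccinated, concentrated by default in the over-represented ages;
* duplicate pseudonymized identifiers, rows with missing age/sex, five
  dated engagement-event streams, and ~82% vaccination coverage among
  active records.

Everything is driven by one integer seed: identical configs produce
byte-identical CSV output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    AGE_BAND_LABELS,
    EVENT_COLUMNS,
    REGIONS,
    SEXES,
    STRATUM_AGE_LABELS,
    assign_age_bands,
)

logger = logging.getLogger(__name__)

# Adult age pyramid: percentage of the adult population per presentational
# band, spread uniformly across the single years inside each band.
_BAND_PCT = {
    "18-25": 10.6, "25-30": 8.5, "30-35": 8.6, "35-40": 8.4, "40-45": 7.8,
    "45-50": 8.2, "50-55": 8.7, "55-60": 8.5, "60-65": 7.2, "65-70": 6.3,
    "70-75": 6.3, "75-80": 4.5, "80-85": 3.2, "85-90": 2.0, "90+": 1.2,
}

# Approximate adult population shares of the seven NHS regions (mid-2020).
_REGION_SHARE = {
    "East of England": 0.112,
    "London": 0.158,
    "Midlands": 0.190,
    "North East and Yorkshire": 0.153,
    "North West": 0.129,
    "South East": 0.162,
    "South West": 0.096,
}

_SEX_SHARE = {"F": 0.51, "M": 0.49}

_EVENT_RATES = {  # marginal probability of each stream among engaged records
    "gp_consult_date": 0.97,
    "covid_test_date": 0.62,
    "hospitalization_date": 0.28,
    "lab_result_date": 0.24,
}

_VACCINATION_ROLLOUT_START = date(2020, 12, 8)


def _check_fraction(name: str, value: float, lo: float, hi: float,
                    lo_closed: bool = True, hi_closed: bool = False) -> None:
    lo_ok = value >= lo if lo_closed else value > lo
    hi_ok = value <= hi if hi_closed else value < hi
    if not (lo_ok and hi_ok):
        lo_b = "[" if lo_closed else "("
        hi_b = "]" if hi_closed else ")"
        raise ValueError(f"{name} must be in {lo_b}{lo}, {hi}{hi_b}, got {value}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic registry.

    Defaults mirror the structure of the national extract the package
    targets: 2.4% inactive adult records concentrated at ages 30–45,
    over-representation at 30–45 and under-representation at 65–75
    relative to the census reference, 82% vaccination coverage among
    active records, and engagement events since 2019-01-01 with an
    index date of 2021-10-01.
    """

    n_reference_adults: int = 100_000
    inactive_fraction: float = 0.024
    duplicate_fraction: float = 0.05
    missing_demo_fraction: float = 0.005
    overrep_age_range: tuple[int, int] = (30, 45)
    overrep_factor: float = 1.08
    underrep_age_range: tuple[int, int] = (65, 75)
    underrep_factor: float = 0.92
    vaccination_coverage: float = 0.82
    engagement_window_start: date = date(2019, 1, 1)
    index_date: date = date(2021, 10, 1)
    seed: int = 0
    #: Relative inactivity rate inside overrep_age_range vs outside (>=0).
    inactive_rate_ratio: float = 3.0
    #: Probability that an unvaccinated active record has no in-window events.
    active_silent_fraction: float = 0.0
    #: When False, registry stratum counts are the scaled reference counts
    #: rounded, with no Poisson perturbation.
    count_noise: bool = True

    def __post_init__(self) -> None:
        if self.n_reference_adults < 0:
            raise ValueError(
                f"n_reference_adults must be >= 0, got {self.n_reference_adults}"
            )
        _check_fraction("inactive_fraction", self.inactive_fraction, 0.0, 1.0)
        _check_fraction("duplicate_fraction", self.duplicate_fraction, 0.0, 1.0)
        _check_fraction("missing_demo_fraction", self.missing_demo_fraction, 0.0, 1.0)
        _check_fraction("vaccination_coverage", self.vaccination_coverage,
                        0.0, 1.0, hi_closed=True)
        _check_fraction("active_silent_fraction", self.active_silent_fraction, 0.0, 1.0)
        if self.overrep_factor < 1.0:
            raise ValueError(f"overrep_factor must be >= 1, got {self.overrep_factor}")
        if not 0.0 < self.underrep_factor <= 1.0:
            raise ValueError(
                f"underrep_factor must be in (0, 1], got {self.underrep_factor}"
            )
        if self.inactive_rate_ratio < 0:
            raise ValueError(
                f"inactive_rate_ratio must be >= 0, got {self.inactive_rate_ratio}"
            )
        if self.engagement_window_start >= self.index_date:
            raise ValueError(
                "engagement_window_start must precede index_date "
                f"({self.engagement_window_start} >= {self.index_date})"
            )
        for name in ("overrep_age_range", "underrep_age_range"):
            lo, hi = getattr(self, name)
            if not 18 <= lo <= hi:
                raise ValueError(f"{name} must be an interval within adult ages, got {(lo, hi)}")

    def _rngs(self) -> tuple[np.random.Generator, np.random.Generator]:
        ref_ss, reg_ss = np.random.SeedSequence(self.seed).spawn(2)
        return np.random.default_rng(ref_ss), np.random.default_rng(reg_ss)


def _age_pyramid_weights() -> np.ndarray:
    """Per-stratum-age weight: band percentage spread over band years."""
    band_years = {
        label: hi - lo
        for label, (lo, hi) in zip(
            AGE_BAND_LABELS[:-1],
            [(18, 25)] + [(a, a + 5) for a in range(25, 90, 5)],
        )
    }
    weights = []
    for label in STRATUM_AGE_LABELS:
        if label == "90+":
            weights.append(_BAND_PCT["90+"])
        else:
            age = int(label)
            idx = np.searchsorted([18, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85, 90],
                                  age, side="right") - 1
            band = AGE_BAND_LABELS[idx]
            weights.append(_BAND_PCT[band] / band_years[band])
    return np.asarray(weights, dtype=float)


def _stratum_grid() -> pd.DataFrame:
    ages, sexes, regions = zip(
        *[(a, s, r) for a in STRATUM_AGE_LABELS for s in SEXES for r in REGIONS]
    )
    return pd.DataFrame({"age_year": ages, "sex": sexes, "region": regions})


def generate_reference(config: GeneratorConfig) -> pd.DataFrame:
    """Census-style counts per (age-year, sex, region) stratum.

    Counts are a single multinomial draw over all strata, so they sum
    exactly to ``n_reference_adults``.
    """
    rng, _ = config._rngs()
    grid = _stratum_grid()
    age_w = _age_pyramid_weights()
    p = np.array(
        [
            age_w[STRATUM_AGE_LABELS.index(a)] * _SEX_SHARE[s] * _REGION_SHARE[r]
            for a, s, r in grid.itertuples(index=False)
        ]
    )
    p /= p.sum()
    grid["count"] = rng.multinomial(config.n_reference_adults, p)
    return grid


def _scale_factors(config: GeneratorConfig) -> np.ndarray:
    """Registry/reference count ratio per stratum age (90+ is unscaled)."""
    factors = np.ones(len(STRATUM_AGE_LABELS))
    o_lo, o_hi = config.overrep_age_range
    u_lo, u_hi = config.underrep_age_range
    for i, label in enumerate(STRATUM_AGE_LABELS):
        if label == "90+":
            continue
        age = int(label)
        if o_lo <= age <= o_hi:
            factors[i] = config.overrep_factor
        elif u_lo <= age <= u_hi:
            factors[i] = config.underrep_factor
    return factors


def _uniform_dates(
    rng: np.random.Generator, start: date, end: date, size: int
) -> np.ndarray:
    """Dates drawn uniformly from the closed interval [start, end]."""
    lo = np.datetime64(start, "D")
    hi = np.datetime64(end, "D")
    span = int((hi - lo).astype(int)) + 1
    return lo + rng.integers(0, span, size=size).astype("timedelta64[D]")


def generate_registry(
    config: GeneratorConfig, reference: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a registry emulating an inflated national extract.

    Returns ``(registry, truth)``.  The registry has one row per record
    with demographics, the five event-date streams and the vaccination
    flag; the truth table records, per row, whether the underlying
    person is truly active and, for re-emitted duplicate rows, the
    record_row_id of the original row.
    """
    if reference["count"].sum() == 0:
        raise ValueError("reference population is empty")
    _, rng = config._rngs()
    window_start = config.engagement_window_start
    index_date = config.index_date

    factors_by_age = dict(zip(STRATUM_AGE_LABELS, _scale_factors(config)))
    expected = reference["count"].to_numpy() * reference["age_year"].map(factors_by_age).to_numpy()
    if config.count_noise:
        counts = rng.poisson(expected)
    else:
        counts = np.rint(expected).astype(np.int64)

    n = int(counts.sum())
    age_label = np.repeat(reference["age_year"].to_numpy(), counts)
    sex = np.repeat(reference["sex"].to_numpy(), counts)
    region = np.repeat(reference["region"].to_numpy(), counts)

    ages = np.where(age_label == "90+", -1, age_label).astype(np.int64)
    n_90 = int((ages < 0).sum())
    # integer ages within the open 90+ band, thinning with age
    ages[ages < 0] = 90 + np.minimum(rng.geometric(0.45, size=n_90) - 1, 9)

    # --- inactivity, concentrated in the over-represented ages -------------
    o_lo, o_hi = config.overrep_age_range
    in_conc = (ages >= o_lo) & (ages <= o_hi)
    rel = np.where(in_conc, config.inactive_rate_ratio, 1.0)
    mean_rel = rel.mean() if n else 1.0
    p_inactive = np.clip(config.inactive_fraction * rel / mean_rel, 0.0, 0.99)
    inactive = rng.random(n) < p_inactive
    active = ~inactive

    vaccinated = active & (rng.random(n) < config.vaccination_coverage)
    silent = (
        active
        & ~vaccinated
        & (rng.random(n) < config.active_silent_fraction)
    )
    engaged = active & ~silent

    # --- event streams ------------------------------------------------------
    events = {col: np.full(n, np.datetime64("NaT"), dtype="datetime64[D]") for col in EVENT_COLUMNS}
    for col, rate in _EVENT_RATES.items():
        mask = engaged & (rng.random(n) < rate)
        events[col][mask] = _uniform_dates(rng, window_start, index_date, int(mask.sum()))
    vax_start = max(window_start, _VACCINATION_ROLLOUT_START)
    events["covid_vaccination_date"][vaccinated] = _uniform_dates(
        rng, vax_start, index_date, int(vaccinated.sum())
    )
    # engagement is guaranteed: engaged rows with no event yet get a GP visit
    has_event = np.zeros(n, dtype=bool)
    for col in EVENT_COLUMNS:
        has_event |= ~np.isnat(events[col])
    force = engaged & ~has_event
    events["gp_consult_date"][force] = _uniform_dates(
        rng, window_start, index_date, int(force.sum())
    )
    # inactive and silent-active rows may still show pre-window contact
    pre_window_end = window_start - pd.Timedelta(days=1).to_pytimedelta()
    pre_window_start = window_start - pd.Timedelta(days=730).to_pytimedelta()
    dormant = ~engaged & (rng.random(n) < 0.6)
    events["gp_consult_date"][dormant] = _uniform_dates(
        rng, pre_window_start, pre_window_end, int(dormant.sum())
    )

    # --- missing demographics ----------------------------------------------
    age_out = ages.astype(float)
    sex_out = sex.astype(object)
    miss = rng.random(n) < config.missing_demo_fraction
    which = rng.integers(0, 3, size=n)  # 0: age, 1: sex, 2: both
    age_out[miss & (which != 1)] = np.nan
    sex_out[miss & (which != 0)] = None

    pseudo_id = np.array([f"P{i:08d}" for i in range(n)], dtype=object)
    base = pd.DataFrame(
        {
            "pseudo_id": pseudo_id,
            "age_years": age_out,
            "sex": sex_out,
            "region": region,
            "vaccinated": vaccinated.astype(np.int64),
            **{col: events[col] for col in EVENT_COLUMNS},
        }
    )
    truly_active = active

    # --- duplicates: re-emit existing rows under the same pseudo_id ---------
    n_dup = int(round(config.duplicate_fraction * n))
    if n_dup > 0:
        dup_idx = rng.choice(n, size=n_dup, replace=False)
        dup = base.iloc[dup_idx].copy().reset_index(drop=True)
        kind = rng.integers(0, 3, size=n_dup)  # 0: exact, 1: reduced, 2: later
        reduced = kind == 1
        dup.loc[reduced, "covid_test_date"] = pd.NaT
        dup.loc[reduced, "lab_result_date"] = pd.NaT
        # a copy with a later in-window contact than the original — only for
        # rows whose truth is active+engaged (inactive rows must never gain
        # in-window events)
        later = (kind == 2) & engaged[dup_idx]
        dup.loc[later, "gp_consult_date"] = pd.Timestamp(index_date)
        dup_orig_row = dup_idx + 1  # original record_row_ids (assigned below)
        registry = pd.concat([base, dup], ignore_index=True)
        truth_active = np.concatenate([truly_active, truly_active[dup_idx]])
        dup_of = np.concatenate(
            [np.full(n, np.nan), dup_orig_row.astype(float)]
        )
    else:
        registry = base
        truth_active = truly_active
        dup_of = np.full(n, np.nan)

    registry.insert(0, "record_row_id", np.arange(1, len(registry) + 1))
    for col in EVENT_COLUMNS:
        registry[col] = pd.to_datetime(registry[col])
    truth = pd.DataFrame(
        {
            "record_row_id": registry["record_row_id"],
            "truly_active": truth_active.astype(np.int64),
            "is_duplicate_of": pd.array(dup_of, dtype="Int64"),
        }
    )
    logger.info(
        "generate_registry: %d rows (%d duplicates), %d inactive (%.2f%%)",
        len(registry), n_dup, int(inactive.sum()), 100 * inactive.mean() if n else 0.0,
    )
    return registry, truth


def true_unvaccinated_profile(
    registry: pd.DataFrame, truth: pd.DataFrame, by_sex: bool = False
) -> pd.DataFrame:
    """Age-band profile of the *truly active* unvaccinated adult population.

    This is the generator's stand-in for an externally published
    unvaccinated reference profile: duplicates, inactive records and
    rows with missing demographics are excluded using the truth labels,
    leaving the genuine unvaccinated population.
    """
    merged = registry.merge(truth, on="record_row_id")
    sub = merged[
        (merged["truly_active"] == 1)
        & merged["is_duplicate_of"].isna()
        & (merged["vaccinated"] == 0)
        & merged["age_years"].notna()
        & merged["sex"].notna()
        & (merged["age_years"] >= 18)
    ].copy()
    sub["age_band"] = assign_age_bands(sub["age_years"].astype(int))
    keys = ["age_band", "sex"] if by_sex else ["age_band"]
    profile = sub.groupby(keys, observed=True).size().rename("count").reset_index()
    return profile


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------

def write_reference(reference: pd.DataFrame, path: str | Path) -> None:
    reference.to_csv(path, index=False)


def read_reference(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"age_year": str, "sex": str, "region": str})
    df["count"] = df["count"].astype(np.int64)
    return df


def write_registry(registry: pd.DataFrame, path: str | Path) -> None:
    out = registry.copy()
    out["age_years"] = out["age_years"].astype("Int64")
    out.to_csv(path, index=False, date_format="%Y-%m-%d")


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"record_row_id": np.int64, "truly_active": np.int64,
                                    "is_duplicate_of": "Int64"})
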