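"""Representation validation of the weighted cohort.

Compares banded age (optionally × sex) distributions of the cohort —
unweighted record counts and final-weight sums — against the census
reference, and, separately, the unvaccinated subset of the cohort
against an externally supplied unvaccinated reference profile.

The headline discrepancy metric is the total variation distance (TVD):
half the sum of absolute differences between two discrete
distributions, interpretable as the largest difference in probability
mass any set of bands can exhibit.  A successful correction moves the
weighted distribution toward the reference, i.e. lowers the TVD.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import AGE_BAND_LABELS, SEXES, assign_age_bands
from .weighting import WeightedCohort

logger = logging.getLogger(__name__)


@dataclass
class DistributionComparison:
    """Banded reference/unweighted/weighted percentages plus TVD metrics."""

    table: pd.DataFrame  # age_band [, sex], reference_pct, unweighted_pct, weighted_pct
    tvd_unweighted: float
    tvd_weighted: float
    by_sex: bool = False

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        for col in ("reference_pct", "unweighted_pct", "weighted_pct"):
            out[col] = out[col].round(1)
        out.to_csv(path, index=False)

    def metrics_to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "tvd_unweighted": self.tvd_unweighted,
                    "tvd_weighted": self.tvd_weighted,
                    "by_sex": self.by_sex,
                },
                indent=2,
            )
            + "\n"
        )


def total_variation_distance(p: np.ndarray, q: np.ndarray) -> float:
    """½·Σ|p−q| for two probability vectors on the same support."""
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def _cells(by_sex: bool) -> pd.DataFrame:
    if by_sex:
        return pd.DataFrame(
            [(b, s) for b in AGE_BAND_LABELS for s in SEXES],
            columns=["age_band", "sex"],
        )
    return pd.DataFrame({"age_band": list(AGE_BAND_LABELS)})


def _profile(
    df: pd.DataFrame, keys: list[str], value: pd.Series, cells: pd.DataFrame
) -> np.ndarray:
    """Mass per cell, aligned to ``cells``, normalized to proportions."""
    sums = df.assign(_v=value).groupby(keys, observed=True)["_v"].sum().reset_index()
    aligned = cells.merge(sums, on=keys, how="left")["_v"].fillna(0.0).to_numpy()
    total = aligned.sum()
    if total <= 0:
        raise ValueError("distribution has no mass")
    return aligned / total


def _reference_bands(reference: pd.DataFrame) -> pd.DataFrame:
    ref = reference.copy()
    ages = ref["age_year"].astype(str)
    numeric = ages.where(ages != "90+", "90")
    ref["age_band"] = assign_age_bands(numeric.astype(int))
    return ref


def banded_distribution(
    weighted: WeightedCohort, reference: pd.DataFrame, by_sex: bool = False
) -> DistributionComparison:
    """Reference vs unweighted vs weighted banded distributions.

    Unweighted percentages use record counts, weighted percentages use
    final-weight sums, reference percentages use the census counts —
    each normalized within itself.
    """
    records = weighted.records
    if len(records) == 0:
        raise ValueError("empty cohort")
    keys = ["age_band", "sex"] if by_sex else ["age_band"]
    cells = _cells(by_sex)

    ref = _reference_bands(reference)
    p_ref = _profile(ref, keys, ref["count"].astype(float), cells)
    ones = pd.Series(1.0, index=records.index)
    p_unw = _profile(records, keys, ones, cells)
    p_w = _profile(records, keys, records["final_weight"], cells)

    table = cells.assign(
        reference_pct=100 * p_ref,
        unweighted_pct=100 * p_unw,
        weighted_pct=100 * p_w,
    )
    return DistributionComparison(
        table=table,
        tvd_unweighted=total_variation_distance(p_unw, p_ref),
        tvd_weighted=total_variation_distance(p_w, p_ref),
        by_sex=by_sex,
    )


def unvaccinated_profile_comparison(
    weighted: WeightedCohort,
    unvax_reference: pd.DataFrame,
    by_sex: bool = False,
) -> DistributionComparison:
    """Compare the cohort's unvaccinated subset to a reference profile.

    ``unvax_reference`` carries ``age_band`` (and ``sex`` when
    ``by_sex``) with a ``count`` column giving the reference profile's
    mass per cell.  Inactive records are structurally unvaccinated, so
    before correction this subset skews toward the inactive population.
    """
    keys = ["age_band", "sex"] if by_sex else ["age_band"]
    missing = set(keys + ["count"]) - set(unvax_reference.columns)
    if missing:
        raise ValueError(f"unvaccinated reference profile missing columns: {sorted(missing)}")
    unknown = set(unvax_reference["age_band"]) - set(AGE_BAND_LABELS)
    if unknown:
        raise ValueError(f"unvaccinated reference profile has unknown age bands: {sorted(unknown)}")

    sub = weighted.records[weighted.records["vaccinated"] == 0]
    if len(sub) == 0:
        raise ValueError("empty unvaccinated subset")
    cells = _cells(by_sex)
    p_ref = _profile(unvax_reference, keys, unvax_reference["count"].astype(float), cells)
    ones = pd.Series(1.0, index=sub.index)
    p_unw = _profile(sub, keys, ones, cells)
    p_w = _profile(sub, keys, sub["final_weight"], cells)

    table = cells.assign(
        reference_pct=100 * p_ref,
        unweighted_pct=100 * p_unw,
        weighted_pct=100 * p_w,
    )
    return DistributionComparison(
        table=table,
        tvd_unweighted=total_variation_distance(p_unw, p_ref),
        tvd_weighted=total_variation_distance(p_w, p_ref),
        by_sex=by_sex,
    )
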