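"""Three-stage denominator-correction weights.

The weighting corrects a registry whose record count is inflated (or
locally deflated) relative to a census reference population, using full
cross-classification by single year of age × sex × region:

1. **Stratum-ratio weights** — every record in stratum ``s`` receives
   the initial weight ``w = N(s) / n(s)``, the reference-to-registry
   count ratio, so that weights sum to the reference population size.
2. **Engagement reset** — records showing any health-care contact in
   the lookback window are considered verifiably active and have their
   weight reset to exactly 1.
3. **Global renormalization** — the remaining (non-engaged) records'
   initial weights are rescaled by a common factor
   ``c = (S_w − S_h) / S_w_nh`` so that the grand total of revised
   weights again equals the reference population total ``S_w``; here
   ``S_h`` is the weight sum of engaged records (their count) and
   ``S_w_nh`` the initial-weight sum of non-engaged records.

When the registry is inflated, ``c < 1`` and records without recent
contact — the likely inactive ones — are down-weighted rather than
dropped.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass
from math import isnan
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import EngagementWindow, ExclusionLog, STRATUM_COLUMNS, prepare_cohort

logger = logging.getLogger(__name__)


class ContractError(RuntimeError):
    """An arithmetic precondition of the weighting scheme is violated."""


@dataclass
class WeightSummary:
    """Global weight bookkeeping across the three stages.

    ``s_w`` is the reference mass of strata actually covered by the
    cohort (equivalently the initial-weight sum); ``s_h`` the number of
    engaged records (their unit weights); ``s_w_nh`` the initial-weight
    sum of non-engaged records; ``scale_factor`` the common multiplier
    applied to non-engaged initial weights (NaN before renormalization
    or when there are no non-engaged records).
    """

    s_w: float = float("nan")
    s_h: float = float("nan")
    s_w_nh: float = float("nan")
    scale_factor: float = float("nan")
    uncovered_reference_mass: float = 0.0
    n_uncovered_strata: int = 0
    n_zero_reference_records: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


@dataclass
class WeightedCohort:
    """Cohort records carrying ``initial_weight``/``final_weight`` plus the summary."""

    records: pd.DataFrame
    summary: WeightSummary


def validate_reference(reference: pd.DataFrame) -> None:
    required = {"age_year", "sex", "region", "count"}
    missing = required - set(reference.columns)
    if missing:
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    if (reference["count"] < 0).any():
        raise ValueError("reference counts must be non-negative")
    if reference.duplicated(["age_year", "sex", "region"]).any():
        raise ValueError("reference table has duplicated strata")


def initial_weights(cohort: pd.DataFrame, reference: pd.DataFrame) -> WeightedCohort:
    """Assign the stratum-ratio weight ``N(s)/n(s)`` to every record.

    Reference strata with no cohort records contribute their mass to
    ``uncovered_reference_mass`` and are excluded from ``s_w``; cohort
    records in strata absent from the reference (or with reference
    count 0) get weight 0.  Both situations are logged, not hidden.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort: no records to weight")
    validate_reference(reference)

    ref = reference.rename(columns={"age_year": "stratum_age"})
    n_s = (
        cohort.groupby(list(STRATUM_COLUMNS), observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    merged = n_s.merge(ref, on=list(STRATUM_COLUMNS), how="left")
    absent = merged["count"].isna()
    if absent.any():
        logger.warning(
            "%d cohort strata absent from the reference; their records get weight 0",
            int(absent.sum()),
        )
    merged["count"] = merged["count"].fillna(0.0)
    merged["initial_weight"] = merged["count"] / merged["n"]

    s_w = float(merged["count"].sum())
    total_reference = float(ref["count"].sum())
    uncovered = total_reference - s_w
    covered_keys = set(map(tuple, merged[list(STRATUM_COLUMNS)].itertuples(index=False)))
    n_uncovered = int(
        sum(
            1
            for row in ref[ref["count"] > 0][list(STRATUM_COLUMNS)].itertuples(index=False)
            if tuple(row) not in covered_keys
        )
    )
    records = cohort.merge(
        merged[list(STRATUM_COLUMNS) + ["initial_weight"]],
        on=list(STRATUM_COLUMNS),
        how="left",
    )
    n_zero = int((records["initial_weight"] == 0).sum())
    if n_zero:
        logger.warning("%d records sit in strata with zero reference count", n_zero)
    if n_uncovered:
        logger.warning(
            "%d nonempty reference strata have no cohort records "
            "(uncovered mass %.1f excluded from S_w)",
            n_uncovered, uncovered,
        )
    summary = WeightSummary(
        s_w=s_w,
        uncovered_reference_mass=uncovered,
        n_uncovered_strata=n_uncovered,
        n_zero_reference_records=n_zero,
    )
    return WeightedCohort(records=records, summary=summary)


def reweight_engaged(weighted: WeightedCohort) -> WeightedCohort:
    """Reset engaged records' weights to exactly 1; tally S_h and S_w_nh."""
    records = weighted.records.copy()
    engaged = records["engaged"].to_numpy(dtype=bool)
    records["final_weight"] = np.where(engaged, 1.0, records["initial_weight"])
    summary = weighted.summary
    summary.s_h = float(engaged.sum())
    summary.s_w_nh = float(records.loc[~engaged, "initial_weight"].sum())
    return WeightedCohort(records=records, summary=summary)


def renormalize(weighted: WeightedCohort) -> WeightedCohort:
    """Rescale non-engaged weights so the grand total returns to ``s_w``.

    Raises :class:`ContractError` if engaged records alone already
    exceed the reference total (the scale factor would be negative).
    With no non-engaged records there is nothing to rescale; a warning
    notes that the total stays at ``s_h``.
    """
    summary = weighted.summary
    if isnan(summary.s_h) or isnan(summary.s_w_nh):
        raise ValueError("renormalize requires reweight_engaged to have run")
    if summary.s_h > summary.s_w:
        raise ContractError(
            "engaged count exceeds reference total; weights would be negative "
            f"(S_h={summary.s_h:.1f} > S_w={summary.s_w:.1f})"
        )
    records = weighted.records.copy()
    if summary.s_w_nh == 0:
        if summary.s_h != summary.s_w:
            warnings.warn(
                "no non-engaged records to rescale: total weight stays at "
                f"S_h={summary.s_h:.1f}, not S_w={summary.s_w:.1f}",
                stacklevel=2,
            )
        summary.scale_factor = float("nan")
        return WeightedCohort(records=records, summary=summary)

    scale = (summary.s_w - summary.s_h) / summary.s_w_nh
    summary.scale_factor = scale
    engaged = records["engaged"].to_numpy(dtype=bool)
    records.loc[~engaged, "final_weight"] = (
        records.loc[~engaged, "initial_weight"] * scale
    )
    total = float(records["final_weight"].sum())
    logger.info(
        "renormalize: scale_factor=%.6f, total weight %.3f vs S_w %.3f",
        scale, total, summary.s_w,
    )
    return WeightedCohort(records=records, summary=summary)


def weight_pipeline(
    registry: pd.DataFrame,
    reference: pd.DataFrame,
    window: EngagementWindow,
    min_age: int = 18,
) -> tuple[WeightedCohort, ExclusionLog]:
    """Full pipeline: de-duplicate → exclude → flag engagement → weight."""
    cohort, log = prepare_cohort(registry, window, min_age=min_age)
    weighted = initial_weights(cohort, reference)
    weighted = reweight_engaged(weighted)
    weighted = renormalize(weighted)
    return weighted, log


def write_weights(weighted: WeightedCohort, path: str | Path) -> None:
    cols = [
        "record_row_id", "pseudo_id", "stratum_age", "sex", "region",
        "age_band", "vaccinated", "engaged", "initial_weight", "final_weight",
    ]
    weighted.records[cols].to_csv(path, index=False)
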