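"""Quantitative bias analysis of inactive records in VE studies.

Inactive registry records cannot receive a documented vaccination or a
documented outcome, so they accumulate in the *unvaccinated* arm of a
vaccine-effectiveness (VE) study as event-free person-time.  The
unvaccinated event rate is diluted, and risk-ratio VE
``VE = 100 × (1 − RR)`` is underestimated.

Three closed-form scenarios quantify this:

* **A (truth)** — inactive records excluded; VE equals the generative
  value ``100 × (1 − true_rate_ratio)``.
* **B (naive)** — inactive records kept, inflating the unvaccinated
  denominator while event counts are unchanged.
* **C (weighted)** — records contribute their mean weight instead of a
  unit count: active records' denominators and events are scaled by
  ``weight_active``, inactive denominators by ``weight_inactive``.

Event counts are expected values (possibly fractional); an optional
stochastic mode replaces them with binomial draws.  Reported
percentages are rounded to one decimal place, round-half-even.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VEScenario:
    """Parameters of the hypothetical VE study.

    ``inactive_fraction`` of the ``n_total`` records are inactive — all
    unvaccinated with zero events, by the structural argument above.
    ``coverage_active`` is vaccination coverage among active records,
    ``true_rate_ratio`` the risk ratio vaccinated/unvaccinated among
    active records, ``risk_unvaccinated`` the outcome probability among
    active unvaccinated records.  ``weight_active``/``weight_inactive``
    are the mean weights the correction assigns to each group.
    """

    n_total: int = 10_000
    inactive_fraction: float = 0.03
    coverage_active: float = 0.60
    true_rate_ratio: float = 0.3
    risk_unvaccinated: float = 0.05
    weight_active: float = 0.9
    weight_inactive: float = 0.2

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError(f"n_total must be positive, got {self.n_total}")
        for name in ("inactive_fraction", "coverage_active", "risk_unvaccinated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.inactive_fraction >= 1.0:
            raise ValueError(
                f"inactive_fraction must be < 1, got {self.inactive_fraction}"
            )
        if not 0.0 < self.true_rate_ratio < 1.0:
            raise ValueError(
                f"true_rate_ratio must be in (0, 1), got {self.true_rate_ratio}"
            )
        for name in ("weight_active", "weight_inactive"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    @classmethod
    def from_risks(
        cls, risk_vaccinated: float, risk_unvaccinated: float, **kwargs
    ) -> "VEScenario":
        """Alternative parameterization via the two arm-specific risks."""
        if not 0 < risk_unvaccinated <= 1:
            raise ValueError(
                f"risk_unvaccinated must be in (0, 1], got {risk_unvaccinated}"
            )
        return cls(
            true_rate_ratio=risk_vaccinated / risk_unvaccinated,
            risk_unvaccinated=risk_unvaccinated,
            **kwargs,
        )

    @property
    def ve_true_pct(self) -> float:
        return 100.0 * (1.0 - self.true_rate_ratio)


@dataclass(frozen=True)
class ScenarioCounts:
    """Deterministic expected counts implied by a :class:`VEScenario`."""

    n_total: int
    n_active: float
    n_inactive: float
    n_vaccinated: float
    n_unvaccinated_active: float
    n_unvaccinated_total: float
    expected_events_vaccinated: float
    expected_events_unvaccinated: float


@dataclass(frozen=True)
class VEResult:
    """A VE estimate with its bias relative to the true VE.

    ``absolute_bias_pct_points`` is ``VE_true − VE_estimated`` in
    percentage points (positive under underestimation);
    ``relative_bias_pct`` is ``100 × (VE_estimated − VE_true)/VE_true``
    (negative under underestimation).
    """

    ve_true_pct: float
    ve_estimated_pct: float
    absolute_bias_pct_points: float
    relative_bias_pct: float

    def rounded(self, ndigits: int = 1) -> "VEResult":
        return VEResult(
            ve_true_pct=round(self.ve_true_pct, ndigits),
            ve_estimated_pct=round(self.ve_estimated_pct, ndigits),
            absolute_bias_pct_points=round(self.absolute_bias_pct_points, ndigits),
            relative_bias_pct=round(self.relative_bias_pct, ndigits),
        )

    def to_dict(self) -> dict[str, float]:
        return {
            "ve_true_pct": self.ve_true_pct,
            "ve_estimated_pct": self.ve_estimated_pct,
            "absolute_bias_pct_points": self.absolute_bias_pct_points,
            "relative_bias_pct": self.relative_bias_pct,
        }


def scenario_counts(scenario: VEScenario) -> ScenarioCounts:
    """Expand a scenario into group sizes and expected event counts."""
    n_inactive = scenario.n_total * scenario.inactive_fraction
    n_active = scenario.n_total - n_inactive
    n_vaccinated = n_active * scenario.coverage_active
    n_unvaccinated_active = n_active - n_vaccinated
    risk_v = scenario.risk_unvaccinated * scenario.true_rate_ratio
    return ScenarioCounts(
        n_total=scenario.n_total,
        n_active=n_active,
        n_inactive=n_inactive,
        n_vaccinated=n_vaccinated,
        n_unvaccinated_active=n_unvaccinated_active,
        n_unvaccinated_total=n_unvaccinated_active + n_inactive,
        expected_events_vaccinated=n_vaccinated * risk_v,
        expected_events_unvaccinated=n_unvaccinated_active * scenario.risk_unvaccinated,
    )


def bias_metrics(ve_true: float, ve_estimated: float) -> VEResult:
    """Absolute (pct points) and relative (%) bias of an estimate."""
    if ve_true == 0:
        raise ValueError("true VE is zero; relative bias undefined")
    return VEResult(
        ve_true_pct=ve_true,
        ve_estimated_pct=ve_estimated,
        absolute_bias_pct_points=ve_true - ve_estimated,
        relative_bias_pct=100.0 * (ve_estimated - ve_true) / ve_true,
    )


def _ve_from_rates(
    events_v: float, denom_v: float, events_u: float, denom_u: float
) -> float:
    if denom_v <= 0 or denom_u <= 0:
        raise ValueError("zero denominator in a study arm")
    if events_u <= 0:
        raise ValueError("no events in the unvaccinated arm; risk ratio undefined")
    return 100.0 * (1.0 - (events_v / denom_v) / (events_u / denom_u))


def ve_crude(counts: ScenarioCounts, include_inactive: bool) -> VEResult:
    """Unweighted risk-ratio VE.

    With ``include_inactive`` the unvaccinated denominator is inflated
    by the inactive records while event counts stay unchanged
    (scenario B); without it, only active records are analyzed
    (scenario A, the truth).
    """
    denom_u = (
        counts.n_unvaccinated_total if include_inactive else counts.n_unvaccinated_active
    )
    ve = _ve_from_rates(
        counts.expected_events_vaccinated,
        counts.n_vaccinated,
        counts.expected_events_unvaccinated,
        denom_u,
    )
    ve_true = _ve_from_rates(
        counts.expected_events_vaccinated,
        counts.n_vaccinated,
        counts.expected_events_unvaccinated,
        counts.n_unvaccinated_active,
    )
    return bias_metrics(ve_true, ve)


def ve_weighted(
    counts: ScenarioCounts, weight_active: float, weight_inactive: float
) -> VEResult:
    """Weighted risk-ratio VE (scenario C).

    Active records contribute ``weight_active`` to denominators and
    events in both arms (cancelling in the vaccinated arm); inactive
    records contribute ``weight_inactive`` to the unvaccinated
    denominator only.
    """
    if weight_active < 0 or weight_inactive < 0:
        raise ValueError("weights must be non-negative")
    denom_v = weight_active * counts.n_vaccinated
    events_v = weight_active * counts.expected_events_vaccinated
    denom_u = (
        weight_active * counts.n_unvaccinated_active
        + weight_inactive * counts.n_inactive
    )
    events_u = weight_active * counts.expected_events_unvaccinated
    ve = _ve_from_rates(events_v, denom_v, events_u, denom_u)
    ve_true = _ve_from_rates(
        counts.expected_events_vaccinated,
        counts.n_vaccinated,
        counts.expected_events_unvaccinated,
        counts.n_unvaccinated_active,
    )
    return bias_metrics(ve_true, ve)


def run_scenarios(scenario: VEScenario) -> dict[str, dict[str, float]]:
    """Scenario A/B/C results as a JSON-ready mapping (1 d.p. reporting)."""
    counts = scenario_counts(scenario)
    a = ve_crude(counts, include_inactive=False)
    b = ve_crude(counts, include_inactive=True)
    c = ve_weighted(counts, scenario.weight_active, scenario.weight_inactive)
    return {
        "A_truth": a.rounded().to_dict(),
        "B_inactive_included": b.rounded().to_dict(),
        "C_weighted": c.rounded().to_dict(),
    }


def inflation_sweep(
    base: VEScenario, inactive_fractions: list[float]
) -> pd.DataFrame:
    """Bias of the naive and weighted estimates across inflation levels.

    One row per inactive fraction with the true, naive (inactive
    included) and weighted VE plus the naive estimate's absolute and
    relative bias.
    """
    rows = []
    for f in inactive_fractions:
        if not 0.0 <= f < 1.0:
            raise ValueError(f"inactive fraction must be in [0, 1), got {f}")
        s = VEScenario(
            n_total=base.n_total,
            inactive_fraction=f,
            coverage_active=base.coverage_active,
            true_rate_ratio=base.true_rate_ratio,
            risk_unvaccinated=base.risk_unvaccinated,
            weight_active=base.weight_active,
            weight_inactive=base.weight_inactive,
        )
        counts = scenario_counts(s)
        biased = ve_crude(counts, include_inactive=True)
        corrected = ve_weighted(counts, s.weight_active, s.weight_inactive)
        rows.append(
            {
                "inactive_fraction": f,
                "ve_true": biased.ve_true_pct,
                "ve_biased": biased.ve_estimated_pct,
                "ve_weighted": corrected.ve_estimated_pct,
                "absolute_bias": biased.absolute_bias_pct_points,
                "relative_bias": biased.relative_bias_pct,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "inactive_fraction", "ve_true", "ve_biased", "ve_weighted",
            "absolute_bias", "relative_bias",
        ],
    )


def ve_crude_stochastic(
    scenario: VEScenario,
    include_inactive: bool,
    n_replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo VE estimates with integer binomial event draws.

    Group sizes are rounded to integers; each replicate draws binomial
    event counts in both arms and computes the crude VE.  Replicates
    with zero unvaccinated events are returned as NaN.
    """
    counts = scenario_counts(scenario)
    n_v = int(round(counts.n_vaccinated))
    n_u_active = int(round(counts.n_unvaccinated_active))
    n_inactive = int(round(counts.n_inactive))
    risk_v = scenario.risk_unvaccinated * scenario.true_rate_ratio
    ev_v = rng.binomial(n_v, risk_v, size=n_replicates).astype(float)
    ev_u = rng.binomial(n_u_active, scenario.risk_unvaccinated, size=n_replicates).astype(float)
    denom_u = n_u_active + (n_inactive if include_inactive else 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ve = 100.0 * (1.0 - (ev_v / n_v) / (ev_u / denom_u))
    ve[ev_u == 0] = np.nan
    return ve
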