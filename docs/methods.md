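# Methods

## Model and procedure

The package corrects the population denominator of a patient registry
against a census-style reference, cross-classified by single year of
age (18–89, with an open 90+ stratum) × sex (F/M) × seven NHS regions
(1,022 strata). The pipeline is:

1. **De-duplication.** One row is kept per pseudonymized identifier:
   the row with the latest event date across the five event streams,
   ties broken by the smallest row id. Rows with no events sort last.
   The keep-rule is a determinism convention; which member of a
   duplicate set survives does not change stratum counts.
2. **Exclusions.** Rows missing age or sex are dropped first, then
   rows under the minimum age (default 18). The two counts in the
   exclusion log are disjoint by that order; the total excluded is
   order-invariant.
3. **Engagement flag.** A record is *engaged* if any of GP
   consultation, hospitalization, laboratory result, COVID-19 test or
   COVID-19 vaccination falls in the closed interval
   [window start, index date] (defaults 2019-01-01 and 2021-10-01).
4. **Initial weights.** Every record in stratum *s* receives
   *w* = *N(s)*/*n(s)*, the reference-to-cohort count ratio. Weights
   then sum to the reference mass of the strata the cohort covers,
   *S_w*.
5. **Engagement reset.** Engaged records get weight exactly 1
   (bitwise), including records in under-represented strata whose
   initial weight exceeded 1. This makes global, not per-stratum,
   totals correct — an information loss inherent to the scheme.
6. **Renormalization.** Non-engaged records' initial weights are
   multiplied by the common factor *c* = (*S_w* − *S_h*)/*S_w,nh*
   (*S_h* = engaged count, *S_w,nh* = non-engaged initial-weight sum),
   restoring the grand total to *S_w* exactly.

### Domain of validity

The scheme requires *S_h* ≤ *S_w*: once the verifiably active records
alone outweigh the reference total, *c* turns negative and non-engaged
records would receive negative weights. The pipeline raises a
contract error in that case rather than emitting them. This is a real
constraint, not a corner case: a registry whose net inflation exceeds
its non-engaged share (as heavily inflated national extracts can)
falls outside the domain. The synthetic defaults are chosen inside it
(net inflation ≈ +1.0% against a 2.4% non-engaged share, a ≥5σ margin
at 100,000 reference adults).

Degenerate inputs are handled explicitly rather than smeared:
reference strata with no cohort records keep their mass out of *S_w*
(logged as uncovered mass — no reallocation rule is defensible and
silent reallocation would hide data problems); cohort records in
strata with zero reference count get weight 0 (retained, logged);
*S_w,nh* = 0 leaves nothing to rescale and warns that the total stays
at *S_h*. Weights are double-precision floats throughout, no rounding;
the conservation contract is |Σw − S_w|/S_w < 1e-9.

## Synthetic registry

No public analogue of the real access-controlled extract exists, so
the generator *invents* a generative model that reproduces the
pathologies the method must handle, with per-record ground truth:

* **Reference population.** One multinomial draw of
  `n_reference_adults` (default 100,000) over the 1,022 strata. The
  single-year age pyramid spreads a realistic banded adult age
  distribution uniformly within bands; region shares approximate the
  seven NHS regions' adult populations; sexes split 51/49.
* **Registry counts.** Reference counts scaled by `overrep_factor`
  (default 1.08) at ages 30–45 and `underrep_factor` (default 0.92) at
  ages 65–75, then Poisson-perturbed (`count_noise=False` disables the
  perturbation, giving exact scaled counts for fidelity tests).
* **Inactive records** (default 2.4% marginally) are drawn per record
  with a relative rate `inactive_rate_ratio` (default 3.0) inside the
  over-represented age range, normalized so the marginal share equals
  `inactive_fraction`. Inactive records are never vaccinated and carry
  no in-window events (they may show a pre-window GP contact).
* **Events.** Engaged active records draw each stream at realistic
  marginal rates (GP 0.97, COVID test 0.62, hospitalization 0.28, lab
  0.24), dates uniform in-window; a GP visit is forced if no stream
  fired, so engagement is guaranteed. Vaccinated records (82% of
  active) get a vaccination date in the rollout-to-index interval.
  `active_silent_fraction` (default 0) lets a share of unvaccinated
  active records carry no in-window events, for studying mis-flagging.
* **Duplicates** (default 5% of base rows) re-emit an existing row
  under the same pseudonymized id — exact copies, copies with fewer
  events, or (for engaged originals only) copies with a later contact.
  **Missing demographics** (default 0.5%) blank age, sex or both.

All randomness flows from one integer seed through two child streams
of a single numpy `SeedSequence` (one per generator operation), so
identical configs give byte-identical CSVs.

**What the generator does not emulate:** ethnicity, deprivation,
mortality and migration dynamics, per-practice clustering, correlated
event histories, age-dependent vaccination coverage, and the real
data's regime where net inflation exceeds the non-engaged share (see
*Domain of validity*). Passing tests therefore demonstrate the
arithmetic and directional behaviour of the correction under
controlled conditions, not its adequacy on any particular real
registry.

### Defaults worth knowing

| Parameter | Default | Why |
|---|---|---|
| `inactive_fraction` | 0.024 | reported non-engaged share of adult records |
| `vaccination_coverage` | 0.82 | reported coverage among adult records |
| `overrep_age_range` / `underrep_age_range` | 30–45 / 65–75 | reported most over/under-represented ages |
| `overrep_factor` / `underrep_factor` | 1.08 / 0.92 | direction is reported, magnitude is not; chosen to keep net inflation (≈+1.0%) below the non-engaged share so the renormalization stays defined |
| `inactive_rate_ratio` | 3.0 | the down-weighted population is markedly younger; age-specific rates are unreported, so a single relative-rate knob is exposed instead of a guessed profile |
| window / index date | 2019-01-01 / 2021-10-01 | the engagement lookback and data-extract date |

## Validation outputs

Distribution tables band ages into 18-25, then five-year bands to
85-90, then 90+ (half-open intervals; the upper label is exclusive —
the only non-overlapping reading of adjacent labels). Reference,
unweighted (record-count) and weighted (final-weight-sum)
distributions are each normalized within themselves; the discrepancy
metric is the total variation distance, TVD = ½·Σ|p−q|, chosen because
it bounds the difference in mass any set of bands can show. The
unvaccinated-profile comparison restricts to unvaccinated records and
takes the reference profile as an input table (the generator emits the
truly-active unvaccinated profile from its truth labels).

## Bias analysis

VE is risk-ratio based: VE = 100 × (1 − RR). The default scenario uses
10,000 records, 3% inactive (all unvaccinated, zero events — the
structural signature of inactivity), 60% coverage among active
records, true RR 0.3 and an unvaccinated risk of 5%. Expected
(fractional) event counts are used by default; `ve_crude_stochastic`
is an opt-in binomial mode. Scenario C multiplies active records'
denominators and events by the mean active weight (0.9) — which
cancels in the vaccinated arm — and the inactive denominator
contribution by the mean inactive weight (0.2). Reported percentages
are rounded to one decimal, round-half-even; internal values are
unrounded.

Two parameterizations are accepted: `true_rate_ratio` +
`risk_unvaccinated`, or `VEScenario.from_risks(risk_v, risk_u)`. A 1%
vaccinated / 5% unvaccinated risk pair implies RR 0.2 (VE 80%), which
is *not* the same scenario as true VE 70%; the default uses RR 0.3
because the scenario's downstream quantities (diluted VE 67.7%,
weighted VE 69.5%, biases 2.3/−3.3 and 0.5/−0.7) are mutually
consistent only under that value.

Numerical notes: the crude VE is a ratio estimator, so in the
stochastic mode its Monte-Carlo mean sits below the closed form by a
second-order Jensen term (≈0.17 points at the default scenario); the
convergence test compares against the delta-method-corrected
expectation. The absolute bias of the naive estimate is strictly
increasing in the inactive fraction (the diluted denominator enters
the rate ratio linearly), which the inflation sweep checks
numerically.

## Problem sizes used in the test suite

Unit tests run on 30,000-adult references; the distribution-recovery
and parameter-recovery checks use the full default of 100,000 adults,
with 100 seeded replicates for the distribution property and 100
randomized configurations (20,000–40,000 adults, inactive fractions
0.08–0.25 sampled inside the method's domain) for the conservation
property. These sizes give per-stratum expected counts ≥ ~20, keeping
uncovered reference mass negligible while the suite stays quick.

## Known limitations

* Age, sex, region only; no ethnicity or deprivation axes.
* The reference is taken as error-free; census undercount propagates
  directly into the weights.
* Engagement is a proxy: active non-attenders are down-weighted like
  inactive records, and nothing distinguishes the two.
* The engagement reset discards per-stratum calibration for engaged
  records; only global totals are conserved.
* The renormalization is undefined when engaged records outweigh the
  covered reference total (error by contract, see above).
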