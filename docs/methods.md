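# Methods

## Decision problem and model structure

The model compares two strategies for uncomplicated great-saphenous-vein
varicosis — endovenous laser ablation (EVLT) and high ligation with
stripping (HL/S) — from a payer-plus-productivity perspective over a
1-to-6-month horizon. Survival is assumed identical, adverse-event
disutilities and costs are assumed equivalent between strategies, and
nothing is discounted (all costs and effects fall within six months).
The comparison is therefore driven entirely by (a) each strategy's
expected cost and (b) its expected quality-adjusted life years over the
scenario's interval.

A *scenario* is a named pairing of one cost set with one utility set.
The shipped parameter document defines 25: three base cases (direct
costs, SF-36-derived utilities at 1, 3 and 6 months) and 22
alternatives that vary the utility source (different trials, time
points, and VAS-based pain decrements) and the costing basis (direct
only, or totals including productivity loss from time to return to
work, TRW). Scenario `alt20` is evaluated like any other but is
excluded from the three-way membership count, which covers the 21
scenarios the published dominance tables enumerate.

## Utilities and QALYs

Three derivation pathways, all in `varicea.utility`:

* **SF-36 → HUI2**: a linear map `u = β₀ + Σ_d β_d·SF36_d` over the
  eight 0–100 domain scores. Coefficients are *injected*: the registry
  treats trial-level HUI2 scores as inputs, because the source trials'
  domain scores are not public and several published coefficient sets
  exist. Imputed scores above 1 are carried unclamped — the registry's
  scores (up to 1.52) sit above the conventional dead/perfect-health
  anchoring, and clamping them would silently change every downstream
  quantity.
* **VAS → SG**: `u = 1 − (1 − VAS/100)^k`. The exponent defaults to
  2.27, the conventional population-level power-curve estimate; it is a
  config parameter (`model.sg_exponent`).
* **VAS pain decrement**: `Δu = −slope · VAS_mm`, slope 0.035 per mm by
  default (from a published EQ-5D regression in low-back-pain patients;
  its transfer to varicose-vein patients is an assumption of the model,
  not a measured fact). Decrements are nonpositive by construction.

QALYs are `u · f(t)` with year fractions `months/12`, `weeks/52` and
`days/364`. The 364-day (52-week) year is forced by the published
arithmetic: −0.28 held for 7 days gives −0.28·7/364 = −0.0053846
exactly, which a 365-day year does not reproduce. The day-28 utility
rows are stored with a one-month interval because their published QALYs
equal `u/12` (e.g. −0.039 → −0.00325 exactly), not `u·28/364`.

Three printed QALY cells cannot be reproduced as utility ×
year-fraction under any convention (one day-7 cell consistent with a
different utility score, and the alternative 6-month pair, whose QALY
column repeats the base-case 0.735). They are catalogued in
`varicea.params.CATALOGUED_QALY_INCONSISTENCIES`, flagged by
`qaly_consistency_frame`, and excluded from reproduction checks; the
engine always recomputes QALYs from the utility scores, which is what
resolves the equal-printed-QALY scenarios (16/17) to the correct
dominance side. The remaining 19 cells reproduce within 2×10⁻⁴ of the
printed precision.

## Costs

`C_total = C_direct + TRW · r`. The daily productivity rate r is not
printed anywhere; €285.00/day is reverse-engineered exactly from the
four totals that pair a direct cost with an integer TRW (2530.66,
5769.00, 7090.66, 4914.00 — all reconstruct to the cent). It is a
config parameter. Two trial-reported totals are *not* consistent with
this rate (they imply TRW 7.04 and 7.58 days rather than the printed
7.0/7.6); the loader keeps the printed totals, logs a warning, and
records it in `Registry.warnings` — printed figures are authoritative
over reconstruction throughout.

Several trade-off scenarios carry a second, `reported`, set of per-arm
expected costs and QALYs that differ from the input tables (e.g.
1363.55/924.67 versus 1390.66/924.00). The published ICERs are only
reproducible from the reported figures, so the ICER-table builder uses
them where present (`use_reported=True`), while dominance
classification and the PSA always run from the input parameters. Both
sets live side by side in the parameter document.

## Incremental analysis and dominance

Deltas follow the reporting convention *costlier strategy minus
cheaper*. The ICER is a typed value: defined only for genuine
trade-offs with ΔE ≠ 0; otherwise it carries a reason ("dominance" or
"zero effect") instead of a number, so division by zero or sign-nonsense
ratios cannot leak into reports. Negative-QALY trade-offs (both arms
worse than baseline, EVLT less so) keep the ratio of deltas, matching
the published treatment.

Dominance is *weak*: strategy X is dominated when it is no better on
either axis and strictly worse on at least one. Equal-effect,
unequal-cost scenarios (the 6-month comparisons) therefore resolve to
"dominated" rather than to an undefined ICER, which is what makes the
membership counts 8 / 5 / 8 over the 21 table scenarios. An
equal-cost-and-effect pair is a trade-off (nothing separates the
strategies), and NMB ties resolve to HL/S, the comparator.

Where a utility set carries two laser settings (12 W pulsed vs 14 W
continuous), classification uses the first variant (`EVLT1`) by
default; the variant policy is per-scenario configuration.

## Probabilistic sensitivity analysis

Parameter uncertainty uses triangular distributions:

* `triangular_from_quartiles(mean, q1, q3)`: min/max at *twice* the
  mean-to-quartile distance, mode at the mean.
* `triangular_from_sd(mean, f)`: symmetric around the mean with
  SD = f·|mean| (default f = 0.5), i.e. half-width SD·√6 (a symmetric
  triangular of full width w has variance w²/24). This is the fallback
  for lone point estimates, and — because the source trials' quartiles
  are not public — it is what the default PSA uses for every cost and
  utility parameter.

Each iteration draws both strategies' cost and utility, recomputes
QALYs and the (ΔC, ΔE) pair through the same deterministic engine, and
the run aggregates: quadrant fractions on the cost-effectiveness plane
(ΔE = 0 with ΔC > 0 counts toward the comparator-dominates quadrant,
as does the origin; the north-east quadrant splits at ICER ≤ λ),
P(EVLT cost-effective at λ) = P(λ·ΔE − ΔC > 0), and the CEAC on a grid
of 0…€100,000 in €1,000 steps. The certainty at threshold is by
construction the CEAC value at λ. Sampling is vectorised NumPy with a
seeded `default_rng`; identical (scenario, n_iter, seed) gives
bit-identical results. A "two-dimensional" outer/inner split is
exposed (`n_inner`) but the model is deterministic given its
parameters, so inner replicates are identical and the default single
loop is exact.

Because the default spreads are an assumption (SD = 0.5 × mean), the
published certainty percentages are not reproducible numbers; what is
reproducible is their direction, and the test suite asserts exactly
that: over a ten-seed sweep at 10,000 iterations, P(EVLT cost-effective
at €50,000/QALY) stays below 0.5 for base case 2 and above 0.5 for
alternative 11, in every run. Utilities may sample above 1 and are not
clamped, consistent with the inputs.

## Synthetic trial cohorts

`varicea.synthetic` generates patient-level records (TRW, VAS, eight
SF-36 domains, per-patient costs) from arm-level designs. Bounded
variables use a truncated normal whose *location is solved* (bracketed
root find) so the truncated mean equals the design mean — naive
truncation at TRW 7.0 ± 6.0 on [1, 31] days would shift the mean to
≈ 8.7 and break parameter recovery. SF-36 domains are drawn
independently per domain; real SF-36 data are strongly correlated
across domains, so passing recovery tests says nothing about
correlation-sensitive analyses (none are performed here — every
downstream map is linear in the domain means). Two designs ship:
Danish-trial-like (TRW 7.0 vs 7.6 days) and UK-trial-like (7.0 vs
12.4 days). The shipped SF-36 → HUI2 coefficient set is labelled
illustrative/synthetic: it exists so the end-to-end pipeline has a
concrete linear map, not as a published mapping.

The end-to-end recovery check generates 10,000 patients per arm,
summarises, and pushes the summaries through the cost and utility
pipeline; expected cost and QALY land within 1% of the design-implied
values (cost error ≈ 0.4% typical at that n, dominated by TRW
sampling noise).

## Problem sizes and numerics

Defaults throughout are the analysis's own: 10,000 Monte Carlo
iterations per scenario, 10⁵ draws for sampler-moment checks, 10⁴
patients per arm for recovery, 500 per arm for the illustrative
drivers. The full test suite runs in a few seconds on one CPU. Money
is kept as floats in euros with comparisons at cent precision (±€0.01);
QALY-cell reproduction uses 2×10⁻⁴ plus half an ulp of the printed
precision (printed cells are themselves rounded); ICER reproduction
uses 0.1% relative tolerance. Degenerate inputs are typed errors, not
NaNs: zero-width quartile spreads, zero-mean SD-rule distributions,
empty sample sets and empty cohorts all raise `DomainError`.

## Known limitations

* No adverse-event or reintervention modelling, no discounting, no
  horizon beyond six months — by design, mirroring the model's scope.
* Two comparators only; no extended dominance frontier.
* No correlation between sampled parameters (none is specifiable from
  the published summaries).
* The Kovacs pain-decrement slope is borrowed from a different patient
  population; the VAS→SG exponent is a convention. Both are config
  parameters precisely because they are assumptions.
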