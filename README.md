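# varicea

Decision-analytic cost-utility analysis of **endovenous laser ablation
(EVLT)** versus **high ligation and stripping (HL/S)** of the great
saphenous vein for uncomplicated primary varicose veins.

Varicose-vein surgery is a high-volume procedure, and laser ablation is
the popular minimally-invasive alternative — but it carries the cost of
the laser generator and disposables. Whether that extra cost buys
enough quality of life is a question for a cost-utility model, not a
single trial. This package implements such a model for health
economists and HTA analysts: it maps trial quality-of-life summaries to
utilities, converts them to QALYs, and runs deterministic and
probabilistic cost-effectiveness comparisons across 25 named scenarios
(3 base cases and 22 alternatives combining different utility sources,
time points and costing assumptions).

## The model

For each scenario *s* and strategy *j* ∈ {EVLT, HL/S}:

* **Utilities.** Either an SF-36-derived HUI2 score (linear imputation
  `u = β₀ + Σ_d β_d · SF36_d` with injected coefficients), a
  standard-gamble utility from a VAS rating (`u = 1 − (1 − VAS/100)^k`,
  default k = 2.27), or a linear VAS pain decrement
  (`Δu = −0.035 / mm`).
* **QALYs.** `QALY = u · f(t)` with year fractions `months/12`,
  `weeks/52`, `days/364` (a 52-week year).
* **Costs.** `C = C_direct + TRW · r`, where TRW is time to return to
  work (days) and r = €285/day is the productivity rate implied
  exactly by the published totals.
* **Comparison.** Incremental cost `ΔC`, incremental effect `ΔE`,
  `ICER = ΔC/ΔE` when the scenario is a genuine trade-off, a weak
  dominance label otherwise (no better on either axis, strictly worse
  on one), and net monetary benefit `NMB = λ·E − C` at willingness to
  pay λ (default €50,000/QALY).
* **Uncertainty.** Monte Carlo recalculation with triangular parameter
  distributions, built from quartiles (doubling the mean-to-quartile
  arms) or, when only a point estimate exists, from an assumed
  SD = 0.5 × mean (half-width SD·√6). Outputs: cost-effectiveness-plane
  quadrant fractions split at the λ line, P(EVLT cost-effective), and
  the acceptability curve (CEAC).

A synthetic-trial module (`varicea.synthetic`) generates patient-level
cohorts (SF-36 domains, VAS pain, TRW, costs) from arm-level designs
via moment-matched truncated normals, so the whole pipeline is testable
end-to-end without any trial data.

## Worked example

```bash
$ varicea run --scenario alt10 --wtp 50000 --iterations 10000 --seed 1 --out results/alt10
EVLT_dominated: 0
HLS_dominated: 0
tradeoff: 1
wrote results/alt10_scenarios.csv
wrote results/alt10_icer_table.csv
wrote results/alt10_summary.json
wrote results/alt10_alt10_scatter.csv
wrote results/alt10_alt10_ceac.csv
```

Scenario `alt10` compares the strategies on direct costs with 6-week
SF-36-derived utilities. The ICER table (`results/alt10_icer_table.csv`)
shows HL/S at €924.67 for 0.1605 QALYs and EVLT at €1363.55 for
0.1709 QALYs — an extra €438.88 for an extra 0.0104 QALYs, i.e. an
ICER of €42,200/QALY. That is below the €50,000/QALY threshold, so
EVLT is optimal deterministically, but the Monte Carlo run shows the
decision is uncertain (P(EVLT cost-effective) = 0.5012 for this seed
under the default spreads). In the three base cases the same command reports EVLT as
dominated: €466.66 extra cost for an incremental effect of −0.0075
QALYs (3 months) or 0.0 (6 months).

The full analysis lives in numbered drivers:

```bash
python analysis/01_simulate_trial.py    # synthetic cohorts + summaries
python analysis/02_deterministic_cea.py # all 25 scenarios, dominance split 8/5/8
python analysis/03_icer_table.py        # trade-off ICER table
python analysis/04_psa.py               # 10,000-iteration PSA + CEACs
```

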