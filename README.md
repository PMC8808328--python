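# larc-cea

A Markov cohort cost-effectiveness model comparing two neoadjuvant
strategies for locally advanced (T3–T4 or node-positive) rectal
adenocarcinoma:

* **SCRT-TNT** — short-course radiotherapy (25 Gy in 5 fractions) followed
  by total neoadjuvant consolidation chemotherapy, then total mesorectal
  excision (TME);
* **LCCRT** — conventional long-course chemoradiotherapy (50.4 Gy in 28
  fractions with concurrent capecitabine), then TME, with adjuvant
  chemotherapy.

The package is aimed at health-economics and radiation-oncology researchers
who want a fully scripted, testable version of this comparison: every input
is a typed parameter in a YAML config, every analysis is a library function
with a CLI wrapper, and an independent patient-level microsimulation
cross-checks the cohort arithmetic.

## Model

After surgery the cohort enters a five-state discrete-time Markov process
with 3-month cycles over a 5-year horizon: no evidence of disease (NED),
resectable locoregional recurrence (LRR), unresectable LRR, distant
metastasis (DM), and all-cause death (absorbing). Recurrence entering the
model splits instantaneously into resectable/unresectable (37%/63%).
Transition inputs are cumulative probabilities over stated horizons (for
example NED→DM of 20% at 3 years for SCRT-TNT, 26.8% for LCCRT) and are
converted to per-cycle probabilities under a constant-hazard assumption;
competing exits from a state are allocated so that either the stated
cumulative incidences are reproduced exactly (shared horizon, jointly
feasible) or by cause-specific rate decomposition.

Rewards follow standard cost-effectiveness conventions. With per-cycle
state occupancy `s_k`, utility vector `u`, and discount factor
`d(k) = 1.03^(−k·Δt)`:

```
QALYs = Σ_k d(k) · [(s_k + s_{k+1})/2] · u · Δt        (half-cycle corrected)
Cost  = t0 + Σ_k d(k) · [membership_k + entry-bundle_k]
ICER  = ΔCost / ΔQALY        NMB = QALY · WTP − Cost
```

Up-front therapy and surgery costs are charged at t0; surveillance accrues
per cycle in NED, ostomy maintenance per year alive on the
abdominoperineal-resection pathway, and workup/salvage/palliative bundles
on entry into the recurrence and metastasis states. Utilities are
surgery-specific in NED (0.59 after low anterior resection, 0.50 after
abdominoperineal resection) and disease-specific elsewhere. Arm results
weight the two surgery pathways by each arm's published surgery mix. All
costs are 2020 USD; the default willingness to pay is $50,000/QALY.

## Worked example

```
$ cea run-base --out out/
Base case:
  LCCRT_ADJ cost $56,253.57  QALY 2.11  NMB $48,999.82
  SCRT_TNT  cost $43,040.19  QALY 2.20  NMB $66,941.49
  incremental cost $-13,213.39, incremental QALY 0.0946, ICER $-139,726.97/QALY (SCRT_TNT dominant)
  preferred at WTP $50,000/QALY: SCRT_TNT
```

SCRT-TNT costs about $13,200 less per patient and yields slightly more
quality-adjusted life (0.09 QALYs): it *dominates* the long-course
strategy, so the negative ICER is reported only for transparency and the
decision rests on the net monetary benefit, which favours SCRT-TNT by
roughly $17,900 per patient. The threshold analysis shows how robust this
is to the one genuinely uncertain price:

```
$ cea threshold --out out/ --lo 9960.93 --hi 60000
scrt_tnt.course preference flips at $27,902.61 (2.80x base)
```

i.e. the SCRT-TNT course cost would have to nearly triple before the
long-course strategy became preferred. Equivalent library calls:

```python
from larc_cea import base_case_parameters, evaluate_strategy, compare_strategies, StrategyArm

p = base_case_parameters()
a = evaluate_strategy(p, StrategyArm.SCRT_TNT)
b = evaluate_strategy(p, StrategyArm.LCCRT_ADJ)
print(compare_strategies(a, b, wtp=50_000.0))
```

Other subcommands: `cea tornado` (one-way ±25% sensitivity), `cea two-way`
(preferred-arm grid over two parameters), `cea microsim` (patient-level
Monte-Carlo agreement check), `cea synth` (random valid model configs),
and `cea run-all` (everything, with a manifest).

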