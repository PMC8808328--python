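# Methods

## Model structure

The model is a decision tree feeding a discrete-time Markov cohort process.
The tree assigns each strategy's cohort to a definitive-surgery pathway —
abdominoperineal resection (APR, permanent colostomy) with probability
35.7% after SCRT-TNT and 40.7% after LCCRT, otherwise low anterior
resection (LAR, temporary ileostomy with planned reversal). After surgery
the whole cohort enters the disease-free state (NED) of a five-state Markov
process — NED, resectable locoregional recurrence (LRR), unresectable LRR,
distant metastasis (DM), death (absorbing) — with a 3-month cycle length
and a 5-year horizon (20 cycles). The horizon reflects the assumption that
oncologic outcomes of the two strategies converge five years after
treatment; no background other-cause mortality is applied from NED, since
the disease inputs carry no such component and five years is short on the
relevant age scale.

Locoregional recurrence is modelled as a *temporary* state: mass leaving
NED toward LRR resolves in the same transition into resectable (37%) or
unresectable (63%) recurrence, which carry the distinct salvage/palliative
reward bundles. A one-cycle tunnel state would double-count occupancy time,
so the split is instantaneous.

Surgery pathway affects rewards only (utilities and stoma-related costs),
never transitions, so one cohort trace per arm serves both pathways and
arm totals are the surgery-mix-weighted average of the two reward ledgers.

## Probability conversions

All disease inputs are cumulative probabilities over stated horizons
(2, 3 or 5 years). Per-cycle probabilities assume a constant hazard:
`p = 1 − (1 − P)^(Δt/H)`.

Competing exits from one state are handled two ways:

* **Incidence-preserving allocation** (NED row). The two NED exits share a
  3-year horizon and sum well below 1, so the per-cycle exit is the
  conversion of the *summed* marginals, allocated in proportion to them.
  With this choice the cohort's cumulative incidence of each exit over the
  horizon reproduces the stated input exactly — the model's 3-year
  recurrence rates equal the trial values they were taken from, which is
  the behaviour the calibration block checks.
* **Rate decomposition** (all other rows). Marginals are converted to
  cause-specific rates, summed, and the joint exit `1 − exp(−Σλ·Δt)` is
  allocated proportionally to the rates. This is the only coherent choice
  when horizons differ (unresectable→DM is stated over 2 years,
  unresectable→death over 5) or when the marginals are jointly infeasible
  (resectable→DM 75% + resectable→death 49% over 5 years), and it
  guarantees row sums below 1 under any sensitivity perturbation.

A cumulative probability of exactly 1 (reachable at the top of sensitivity
ranges, where 1.25× a large value clamps to 1) has no finite hazard; the
matrix builder treats such an event as immediate — it takes the entire
row's exit mass in the next cycle — and logs a warning. The conversion
primitives themselves stay strict and raise.

## Rewards, discounting, half-cycle correction

Costs (2020 USD) carry explicit timing semantics:

* **t0** — therapy course (SCRT-TNT $9,960.93; LCCRT $17,270.86 plus
  adjuvant chemotherapy $6,885.21), TME ($11,514.07 APR / $11,807.84 LAR),
  and ileostomy reversal ($11,582.50, all LAR patients), charged
  undiscounted before cycle 0. The Markov clock starts after surgery;
  discounting over the preceding treatment window would be a hidden knob
  with negligible effect.
* **Membership** — routine surveillance while in NED ($400 per cycle, see
  below) and ostomy maintenance on the APR pathway ($2,000/year prorated to
  $500/cycle, in *every* alive state: the colostomy persists through
  recurrence). Accrued on half-cycle-corrected occupancy and discounted.
* **On entry** — charged on the flow mass entering a state at the entry
  cycle's discount factor: resectable LRR receives workup $1,328.65 +
  reirradiation $17,530.95 + concurrent capecitabine $269.32 + salvage
  surgery $17,924.01 (the mean of the three printed salvage operations,
  since no case mix is stated); unresectable LRR receives workup +
  palliative reirradiation $17,530.95 + one year of palliative capecitabine
  $4,517.17 front-loaded as a single bundle; DM receives workup $1,318.73 +
  the capecitabine bundle. Front-loading the 1-year course avoids crediting
  chemotherapy to patients who die mid-year; spreading it over four cycles
  changes arm totals by well under 1%.
* The printed palliative diverting-ostomy cost ($11,163.14) has no stated
  recipient population and ships disabled.

The routine surveillance cost is the one input not printed per item; $400
per 3-month NED cycle is a calibration default (marked `CALIBRATION` in the
fixture) representing a typical office-visit + imaging + CEA panel cadence,
and it is varied ±25% like every other cost in sensitivity analyses.

QALYs weight half-cycle-corrected occupancy by state utilities (NED 0.59
after LAR, 0.50 after APR; resectable LRR 0.45; unresectable LRR 0.40; DM
0.25; death 0). Costs, QALYs and utilities are discounted at 3% per year.
Every reward accrued during cycle k — trapezoid membership time
`(s_k + s_{k+1})/2` and entry flows alike — is discounted at
`d(k) = 1.03^(−k·Δt)`; the patient-level simulator uses the same index, so
the two routes agree in expectation exactly, not just asymptotically.

Surveillance stops on leaving NED (recurrence workup/treatment bundles take
over), and the QALY clock runs exactly 20 cycles from surgery.

## Decision metrics

Incremental cost and QALYs are computed on unrounded totals — the published
ICER is reproducible only that way, since rounding the increments first
shifts it by several thousand dollars per QALY. When one arm is cheaper and
more effective it is flagged dominant; the ICER is still reported but not
interpreted. Preference is always the net-monetary-benefit maximizer at the
stated willingness to pay ($50,000/QALY default, swept to $100k/$150k).

## Sensitivity analyses

One-way analyses scale each probability, utility and cost parameter to
±25% of base and record the incremental NMB at both bounds (tornado
ordering by spread). Complementary splits (APR/LAR, resectable/
unresectable) are stored as pairs whose members renormalize each other, so
scaling one member reassigns mass rather than breaking the simplex.
Incremental NMB is affine in any single cost parameter, which the threshold
search exploits: a plain bisection stops when the incremental NMB at the
midpoint is below $0.01. The two-way analysis maps the preferred arm on a
41×41 grid (default: LCCRT course cost × probability of LAR after LCCRT).
No probabilistic sensitivity analysis is performed — the source analysis
defines none, and the parameter table carries ranges, not distributions.

## Microsimulation cross-check

`simulate_patients` walks individual patients through the identical
transition matrix and reward rules, with the half-cycle correction applied
as half a cycle's credit in the old and new state at each transition.
Patient i consumes row i of a `(n, cycles+1)` uniform block from a seeded
PCG64 generator, so enlarging n never reshuffles earlier patients. The
agreement report requires cohort cost and QALY within 3 standard errors of
the Monte-Carlo mean and every per-cycle state frequency within 3 binomial
standard errors (at the default n = 100,000 this is a sub-percent check).
At small n (a few thousand) occasional cells sit just outside 3 SE, as
expected from ~100 simultaneous comparisons.

## Synthetic models

`generate_random_model` randomizes every value on the fixed five-state
topology — cumulative probabilities in (0, 0.95) with horizons drawn from
{1, 2, 3, 5} years, splits redrawn on the simplex, utilities redrawn with
death pinned at 0 and (by default) sorted by disease severity so
monotonicity properties are meaningful, costs redrawn across the timing
classes — and always passes validation. It emulates the *statistical
structure* of the published inputs, not their clinical plausibility: it
contains no correlation between probabilities and costs, no time-varying
hazards, and no background mortality, so property tests passing on
synthetic models demonstrate engine correctness, not real-world validity.
The two-state closed form (geometric survival × trapezoid × discount
series) provides an exact oracle the matrix engine must match to 1e-10.

## Numerical choices and edge cases

* Transition matrices are validated to row sums within 1e-12; occupancy
  conservation is held to 1e-9 over 20 cycles.
* Probabilities perturbed above 1 clamp to 1 (logged); below 0 clamp to 0.
  Perturbing a value stretches its stored sensitivity range so the record
  stays internally consistent.
* A zero-QALY difference below 1e-9 marks the ICER undefined; NMB is still
  computed.
* Ties in NMB prefer the SCRT-TNT arm only through the ≥ comparison; exact
  ties are reported as equal NMB.
* Problem sizes used by the shipped tests: cohort runs of 20 cycles,
  microsimulation at n = 100,000 (acceptance properties) and n = 40,000
  (unit tests), 1,000-seed generator sweeps.

## Known limitations

Transition probabilities are time-homogeneous over the horizon; there are
no cycle-dependent hazards, no age-dependent background mortality, no
toxicity disutilities, no second-line regimens beyond capecitabine, and the
perspective is payer-only (no societal costs). The equal-efficacy scenario
and all sensitivity conclusions inherit the constant-hazard conversion
convention; alternatives (e.g. uniform-incidence conversion) would shift
absolute totals slightly but none of the ordinal conclusions, which the
±25% sweeps bound.
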