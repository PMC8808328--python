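"""Synthetic model generation and closed-form miniature oracles.

Two kinds of test scaffolding live here:

* :func:`generate_random_model` draws a random but structurally valid
  :class:`~larc_cea.parameters.ParameterSet` on the five-state disease
  topology — random cumulative probabilities with random horizons, utilities
  respecting the death-equals-zero convention (and, by default, disease
  severity ordering), and nonnegative costs spread across the timing
  classes — so every engine invariant can be exercised without the published
  inputs.

* :func:`closed_form_two_state` evaluates an alive→dead chain analytically
  (geometric survival, trapezoid half-cycle correction, per-cycle
  discounting), giving an exact series the matrix engine must match to
  numerical precision.

:func:`write_base_fixture` emits the shipped base-case configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .parameters import (
    PER_EVENT,
    CostParam,
    CostTiming,
    HealthState,
    ParameterSet,
    SurgeryType,
    base_case_parameters,
    save_model_config,
)

_HORIZON_CHOICES = (1.0, 2.0, 3.0, 5.0)


@dataclass
class SyntheticSpec:
    """Knobs for random model generation; deterministic under ``seed``."""

    seed: int = 0
    horizon_years: float = 5.0
    cycle_years: float = 0.25
    cost_scale: float = 10_000.0
    utility_low: float = 0.05
    utility_high: float = 0.95
    ordered_utilities: bool = True
    max_cumulative_probability: float = 0.95
    n_extra_costs: int = 3


def generate_random_model(spec: SyntheticSpec) -> ParameterSet:
    """Random valid ParameterSet on the five-state topology.

    Starts from the base-case structure (so every name the engine references
    exists) and randomizes all values: cumulative probabilities are drawn in
    (0, ``max_cumulative_probability``) with horizons from {1, 2, 3, 5}
    years, splits are redrawn on the simplex, utilities are redrawn and
    (by default) sorted so severity ordering holds, and costs are redrawn
    with a few extra parameters cycling through the timing classes.
    """
    rng = np.random.default_rng(spec.seed)
    p = base_case_parameters()

    # transition probabilities; keep NED-exit pairs jointly feasible
    for name, prob in p.probabilities.items():
        if prob.horizon_years == PER_EVENT:
            continue
        prob.value = float(rng.uniform(0.005, spec.max_cumulative_probability))
        prob.horizon_years = float(rng.choice(_HORIZON_CHOICES))
        prob.low, prob.high = 0.75 * prob.value, min(1.0, 1.25 * prob.value)
    for prefix in ("scrt", "lccrt"):
        lrr = p.probabilities[f"{prefix}.ned_to_lrr"]
        dm = p.probabilities[f"{prefix}.ned_to_dm"]
        total = lrr.value + dm.value
        if total >= spec.max_cumulative_probability:
            shrink = spec.max_cumulative_probability / total * rng.uniform(0.5, 0.95)
            lrr.value *= shrink
            dm.value *= shrink
            for prob in (lrr, dm):
                prob.low, prob.high = 0.75 * prob.value, min(1.0, 1.25 * prob.value)
    for a, b in p.splits:
        v = float(rng.uniform(0.05, 0.95))
        for name, val in ((a, v), (b, 1.0 - v)):
            prob = p.probabilities[name]
            prob.value = val
            prob.low, prob.high = 0.75 * val, min(1.0, 1.25 * val)

    # utilities: death stays 0; optionally sorted by severity
    draws = rng.uniform(spec.utility_low, spec.utility_high, size=5)
    if spec.ordered_utilities:
        draws = np.sort(draws)[::-1]
    order = ["utility.ned.lar", "utility.ned.apr", "utility.lrr_resectable",
             "utility.lrr_unresectable", "utility.dm"]
    for key, val in zip(order, draws):
        u = p.utilities[key]
        u.value = float(val)
        u.low, u.high = 0.75 * u.value, min(1.0, 1.25 * u.value)

    # costs: redraw values, add a few extra parameters over the timing classes
    for c in p.costs.values():
        c.value = float(rng.exponential(spec.cost_scale))
        c.low, c.high = 0.75 * c.value, 1.25 * c.value
    timings = [CostTiming.ONE_TIME_T0, CostTiming.ON_ENTRY,
               CostTiming.PER_CYCLE_WHILE_IN, CostTiming.PER_YEAR_WHILE_ALIVE]
    non_death = [s for s in HealthState if s != HealthState.DEATH]
    for i in range(spec.n_extra_costs):
        timing = timings[int(rng.integers(len(timings)))]
        states = []
        if timing in (CostTiming.ON_ENTRY, CostTiming.PER_CYCLE_WHILE_IN):
            states = [non_death[int(rng.integers(len(non_death)))]]
        surgery = None
        if rng.random() < 0.3:
            surgery = SurgeryType.APR if rng.random() < 0.5 else SurgeryType.LAR
        value = float(rng.exponential(spec.cost_scale))
        name = f"synthetic.extra_{i}"
        p.costs[name] = CostParam(
            name=name, value=value, timing=timing, states=states, surgery=surgery,
            low=0.75 * value, high=1.25 * value, source="synthetic",
        )

    n = max(4, int(round(spec.horizon_years / spec.cycle_years)))
    p.cycle_length_years = spec.cycle_years
    p.horizon_years = n * spec.cycle_years
    p.discount_rate_annual = float(rng.uniform(0.0, 0.06))
    p.wtp_per_qaly = float(rng.uniform(20_000.0, 200_000.0))
    return p


def closed_form_two_state(
    q: float,
    u: float,
    c: float,
    n_cycles: int,
    r: float,
    cycle_years: float,
) -> tuple[float, float]:
    """Exact discounted totals for an alive→dead chain.

    With per-cycle death probability ``q``, survival at cycle boundary k is
    ``s_k = (1 − q)^k``; half-cycle-corrected membership time in cycle k is
    ``(s_k + s_{k+1})/2``, discounted at ``d(k) = (1 + r)^(−k·Δt)``.  The
    per-cycle cost ``c`` accrues per cycle of membership; utility ``u``
    accrues per year, so QALYs carry the Δt factor.

    Returns ``(cost, qaly)``.
    """
    if not (0.0 <= q <= 1.0):
        raise ValueError("q must be in [0, 1]")
    k = np.arange(n_cycles)
    s = (1.0 - q) ** np.arange(n_cycles + 1)
    d = (1.0 + r) ** (-k * cycle_years)
    half = 0.5 * (s[:-1] + s[1:])
    cost = float((d * half * c).sum())
    qaly = float((d * half * u).sum() * cycle_years)
    return cost, qaly


def write_base_fixture(path: str | Path) -> Path:
    """Write the base-case model definition (canonical YAML fixture)."""
    return save_model_config(base_case_parameters(), path)
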