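"""Reward accumulation and cost-effectiveness roll-up.

Costs and utilities are attached to the cohort trace in three ledgers:

* ``t0`` — therapy course, definitive surgery, and (for LAR) ileostomy
  reversal, charged undiscounted when the cohort enters the model (the
  Markov clock starts after surgery, so these precede cycle 0);
* ``membership`` — per-cycle and per-year-while-alive costs and all QALYs,
  accrued on half-cycle-corrected occupancy and discounted;
* ``on_entry`` — workup/salvage/palliative bundles charged on the flow mass
  entering a state, discounted at the cycle of entry.

Strategy-level results weight the APR and LAR surgery pathways by the
published surgery mix of each arm.  Calibration summaries (3-year
locoregional recurrence, cumulative distant metastasis, overall survival)
are computed from the surgery-independent trace: cumulative entry flows for
the event rates, point prevalence for survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .markov import (
    CohortTrace,
    build_transition_matrix,
    discount_vector,
    half_cycle_weights,
    run_cohort,
)
from .parameters import (
    ARM_PREFIX,
    STATE_INDEX,
    STATE_ORDER,
    CostTiming,
    HealthState,
    ParameterSet,
    StrategyArm,
    SurgeryType,
)

_RES = STATE_INDEX[HealthState.LRR_RESECTABLE]
_UNRES = STATE_INDEX[HealthState.LRR_UNRESECTABLE]
_DM = STATE_INDEX[HealthState.DM]
_DEATH = STATE_INDEX[HealthState.DEATH]


@dataclass
class CalibrationSummary:
    """Model-predicted 3-year event rates (fractions, not percentages)."""

    lrr_3y: float
    dm_cum_3y: float
    os_3y: float


@dataclass
class StrategyOutcome:
    arm: StrategyArm
    total_cost: float
    total_qaly: float
    undiscounted_cost: float
    undiscounted_qaly: float
    cost_t0: float
    cost_membership: float
    cost_on_entry: float
    calib: CalibrationSummary
    surgery: Optional[SurgeryType] = None
    trace: Optional[CohortTrace] = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {
            "arm": self.arm.value,
            "total_cost": self.total_cost,
            "total_qaly": self.total_qaly,
            "undiscounted_cost": self.undiscounted_cost,
            "undiscounted_qaly": self.undiscounted_qaly,
            "cost_t0": self.cost_t0,
            "cost_membership": self.cost_membership,
            "cost_on_entry": self.cost_on_entry,
            "calibration": {
                "lrr_3y": self.calib.lrr_3y,
                "dm_cum_3y": self.calib.dm_cum_3y,
                "os_3y": self.calib.os_3y,
            },
        }


@dataclass
class CEAComparison:
    """Incremental comparison of arm_a relative to arm_b."""

    arm_a: StrategyArm
    arm_b: StrategyArm
    delta_cost: float
    delta_qaly: float
    icer: Optional[float]
    icer_defined: bool
    dominant: Optional[StrategyArm]
    nmb: dict[StrategyArm, float]
    preferred_arm: StrategyArm
    wtp: float


def _matches(cost_arm, cost_surgery, arm: StrategyArm, surgery: SurgeryType) -> bool:
    if cost_arm is not None and cost_arm != arm:
        return False
    if cost_surgery is not None and cost_surgery != surgery:
        return False
    return True


def _calibration(trace: CohortTrace, at_years: float = 3.0) -> CalibrationSummary:
    k = int(round(at_years / trace.cycle_length_years))
    k = min(k, trace.n_cycles)
    entries = trace.entries()
    return CalibrationSummary(
        lrr_3y=float(entries[:k, _RES].sum() + entries[:k, _UNRES].sum()),
        dm_cum_3y=float(entries[:k, _DM].sum()),
        os_3y=float(1.0 - trace.occupancy[k, _DEATH]),
    )


def accumulate_rewards(
    trace: CohortTrace, p: ParameterSet, arm: StrategyArm, surgery: SurgeryType
) -> StrategyOutcome:
    """Roll up discounted cost and QALY ledgers for one surgery pathway."""
    n = trace.n_cycles
    dt = trace.cycle_length_years
    disc = discount_vector(n, p.discount_rate_annual, dt)
    ones = np.ones(n)
    hc = half_cycle_weights(trace)
    entries = trace.entries()
    alive = hc[:, :_DEATH].sum(axis=1)

    util = np.array(p.utility_vector(surgery))
    qaly_per_cycle = (hc @ util) * dt
    total_qaly = float(qaly_per_cycle @ disc)
    undisc_qaly = float(qaly_per_cycle @ ones)

    cost_t0 = 0.0
    member_per_cycle = np.zeros(n)
    entry_per_cycle = np.zeros(n)
    for c in p.costs.values():
        if not c.enabled or not _matches(c.arm, c.surgery, arm, surgery):
            continue
        if c.timing == CostTiming.ONE_TIME_T0:
            cost_t0 += c.value
        elif c.timing == CostTiming.PER_CYCLE_WHILE_IN:
            idx = [STATE_INDEX[s] for s in c.states]
            member_per_cycle += hc[:, idx].sum(axis=1) * c.value
        elif c.timing == CostTiming.PER_YEAR_WHILE_ALIVE:
            member_per_cycle += alive * c.value * dt
        elif c.timing == CostTiming.ON_ENTRY:
            idx = [STATE_INDEX[s] for s in c.states]
            entry_per_cycle += entries[:, idx].sum(axis=1) * c.value
        # BUNDLED costs carry no accrual rule and are never charged

    cost_membership = float(member_per_cycle @ disc)
    cost_on_entry = float(entry_per_cycle @ disc)
    total_cost = cost_t0 + cost_membership + cost_on_entry
    undisc_cost = cost_t0 + float(member_per_cycle @ ones) + float(entry_per_cycle @ ones)

    return StrategyOutcome(
        arm=arm,
        total_cost=total_cost,
        total_qaly=total_qaly,
        undiscounted_cost=undisc_cost,
        undiscounted_qaly=undisc_qaly,
        cost_t0=cost_t0,
        cost_membership=cost_membership,
        cost_on_entry=cost_on_entry,
        calib=_calibration(trace),
        surgery=surgery,
        trace=trace,
    )


def evaluate_strategy(p: ParameterSet, arm: StrategyArm) -> StrategyOutcome:
    """Surgery-mix-weighted outcome for one arm.

    Transitions are surgery-independent, so a single trace serves both
    pathways; only the reward ledgers differ.
    """
    m = build_transition_matrix(p, arm)
    trace = run_cohort(m, p.n_cycles, cycle_length_years=p.cycle_length_years)
    prefix = ARM_PREFIX[arm]
    weights = {
        SurgeryType.APR: p.probability(f"{prefix}.apr"),
        SurgeryType.LAR: p.probability(f"{prefix}.lar"),
    }
    parts = {s: accumulate_rewards(trace, p, arm, s) for s in weights}

    def mix(attr: str) -> float:
        return sum(weights[s] * getattr(parts[s], attr) for s in weights)

    return StrategyOutcome(
        arm=arm,
        total_cost=mix("total_cost"),
        total_qaly=mix("total_qaly"),
        undiscounted_cost=mix("undiscounted_cost"),
        undiscounted_qaly=mix("undiscounted_qaly"),
        cost_t0=mix("cost_t0"),
        cost_membership=mix("cost_membership"),
        cost_on_entry=mix("cost_on_entry"),
        calib=_calibration(trace),
        surgery=None,
        trace=trace,
    )


def compare_strategies(
    a: StrategyOutcome, b: StrategyOutcome, wtp: float
) -> CEAComparison:
    """ICER / net-monetary-benefit comparison of two arm outcomes.

    The ICER is computed on unrounded totals.  When one arm is both cheaper
    and more effective it dominates; the ICER is still reported for
    transparency but is not interpretable as a price.
    """
    delta_cost = a.total_cost - b.total_cost
    delta_qaly = a.total_qaly - b.total_qaly
    icer_defined = abs(delta_qaly) >= 1e-9
    icer = delta_cost / delta_qaly if icer_defined else None
    dominant: Optional[StrategyArm] = None
    if delta_cost < 0 and delta_qaly > 0:
        dominant = a.arm
    elif delta_cost > 0 and delta_qaly < 0:
        dominant = b.arm
    nmb = {
        a.arm: a.total_qaly * wtp - a.total_cost,
        b.arm: b.total_qaly * wtp - b.total_cost,
    }
    preferred = a.arm if nmb[a.arm] >= nmb[b.arm] else b.arm
    return CEAComparison(
        arm_a=a.arm, arm_b=b.arm,
        delta_cost=delta_cost, delta_qaly=delta_qaly,
        icer=icer, icer_defined=icer_defined, dominant=dominant,
        nmb=nmb, preferred_arm=preferred, wtp=wtp,
    )


def evaluate_comparison(p: ParameterSet, wtp: float | None = None) -> CEAComparison:
    """SCRT-TNT vs LCCRT comparison on one ParameterSet."""
    wtp = p.wtp_per_qaly if wtp is None else wtp
    a = evaluate_strategy(p, StrategyArm.SCRT_TNT)
    b = evaluate_strategy(p, StrategyArm.LCCRT_ADJ)
    return compare_strategies(a, b, wtp)


def scenario_equal_efficacy(
    p: ParameterSet, lrr_3y: float = 0.08, dm_3y: float = 0.25
) -> CEAComparison:
    """Hypothetical scenario with identical recurrence rates in both arms.

    Both arms are assigned the same 3-year probabilities of locoregional
    recurrence and distant metastasis (8% and 25% by default) while keeping
    the full adjuvant-chemotherapy cost in the LCCRT arm, isolating the
    up-front cost difference between the strategies.
    """
    from .parameters import set_parameter

    q = p
    for prefix in ("scrt", "lccrt"):
        q = set_parameter(q, f"{prefix}.ned_to_lrr", lrr_3y)
        q = set_parameter(q, f"{prefix}.ned_to_dm", dm_3y)
    return evaluate_comparison(q)
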