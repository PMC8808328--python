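"""Patient-level Monte-Carlo cross-check of the cohort engine.

Each simulated patient draws a surgery pathway from the arm's surgery mix,
then walks the same per-cycle transition matrix the cohort engine uses,
accruing the identical reward structure: one-time costs before cycle 0,
on-entry bundles discounted at the cycle of the transition, and membership
rewards credited with a half-cycle rule (the average of the start- and
end-of-cycle state indicator), which converges to the cohort trapezoid
correction.  Agreement between the two routes — an exact linear-algebra
computation and an independent sampling one — validates both.

Per-patient draws are laid out so that patient ``i`` consumes a fixed block
of the random stream: enlarging ``n`` never reshuffles earlier patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .markov import build_transition_matrix, discount_vector
from .outcomes import StrategyOutcome
from .parameters import (
    ARM_PREFIX,
    STATE_INDEX,
    CostTiming,
    HealthState,
    ParameterSet,
    StrategyArm,
    SurgeryType,
)

_DEATH = STATE_INDEX[HealthState.DEATH]


@dataclass
class MicrosimEstimate:
    arm: StrategyArm
    n: int
    seed: int
    mean_cost: float
    se_cost: float
    mean_qaly: float
    se_qaly: float
    state_frequency: np.ndarray = field(repr=False)  # (n_cycles + 1, n_states)

    def as_dict(self) -> dict:
        return {
            "arm": self.arm.value,
            "n": self.n,
            "seed": self.seed,
            "mean_cost": self.mean_cost,
            "se_cost": self.se_cost,
            "mean_qaly": self.mean_qaly,
            "se_qaly": self.se_qaly,
        }


def simulate_patients(
    p: ParameterSet, arm: StrategyArm, n: int, seed: int
) -> MicrosimEstimate:
    """Simulate ``n`` independent patients through one arm of the model."""
    if n < 1:
        raise ValueError("n must be at least 1")
    tm = build_transition_matrix(p, arm)
    M = tm.matrix
    n_states = M.shape[0]
    n_cycles = p.n_cycles
    dt = p.cycle_length_years
    disc = discount_vector(n_cycles, p.discount_rate_annual, dt)
    prefix = ARM_PREFIX[arm]
    p_apr = p.probability(f"{prefix}.apr")

    rng = np.random.default_rng(seed)
    # row i of the draw block belongs to patient i regardless of n
    draws = rng.random((n, n_cycles + 1))
    is_apr = draws[:, 0] < p_apr

    cum = np.cumsum(M, axis=1)
    states = np.zeros((n, n_cycles + 1), dtype=np.int8)
    for k in range(n_cycles):
        u = draws[:, k + 1]
        states[:, k + 1] = (u[:, None] >= cum[states[:, k]]).sum(axis=1)

    # --- QALYs: half-cycle credit, surgery-specific utility vector
    u_lar = np.array(p.utility_vector(SurgeryType.LAR))
    u_apr = np.array(p.utility_vector(SurgeryType.APR))
    u_states = np.where(is_apr[:, None], u_apr[states], u_lar[states])
    half = 0.5 * (u_states[:, :-1] + u_states[:, 1:])
    qalys = (half * disc[None, :]).sum(axis=1) * dt

    # --- costs
    costs = np.zeros(n)
    entered = states[:, 1:] != states[:, :-1]  # transition during cycle k
    alive = (states != _DEATH).astype(float)
    alive_half = 0.5 * (alive[:, :-1] + alive[:, 1:])
    for c in p.costs.values():
        if not c.enabled:
            continue
        if c.arm is not None and c.arm != arm:
            continue
        if c.surgery is not None:
            mask = is_apr if c.surgery == SurgeryType.APR else ~is_apr
        else:
            mask = np.ones(n, dtype=bool)
        if c.timing == CostTiming.ONE_TIME_T0:
            costs += mask * c.value
        elif c.timing == CostTiming.PER_CYCLE_WHILE_IN:
            idx = np.array([STATE_INDEX[s] for s in c.states])
            in_state = np.isin(states, idx).astype(float)
            half_in = 0.5 * (in_state[:, :-1] + in_state[:, 1:])
            costs += mask * (half_in * disc[None, :]).sum(axis=1) * c.value
        elif c.timing == CostTiming.PER_YEAR_WHILE_ALIVE:
            costs += mask * (alive_half * disc[None, :]).sum(axis=1) * c.value * dt
        elif c.timing == CostTiming.ON_ENTRY:
            idx = np.array([STATE_INDEX[s] for s in c.states])
            events = entered & np.isin(states[:, 1:], idx)
            costs += mask * (events * disc[None, :]).sum(axis=1) * c.value

    freq = np.stack(
        [np.bincount(states[:, k], minlength=n_states) / n for k in range(n_cycles + 1)]
    )
    return MicrosimEstimate(
        arm=arm,
        n=n,
        seed=seed,
        mean_cost=float(costs.mean()),
        se_cost=float(costs.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        mean_qaly=float(qalys.mean()),
        se_qaly=float(qalys.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        state_frequency=freq,
    )


@dataclass
class AgreementReport:
    arm: StrategyArm
    z_cost: float
    z_qaly: float
    max_frequency_deviation: float
    frequency_within_3se: bool
    passed: bool


def agreement_report(
    cohort: StrategyOutcome, micro: MicrosimEstimate, z_limit: float = 3.0
) -> AgreementReport:
    """Compare cohort totals and occupancy against the microsim estimate.

    Cost and QALY must agree within ``z_limit`` standard errors; every
    per-cycle state frequency must sit within ``z_limit`` binomial standard
    errors of the cohort occupancy.
    """
    if cohort.arm != micro.arm:
        raise ValueError(f"arm mismatch: cohort {cohort.arm} vs microsim {micro.arm}")
    if cohort.trace is None:
        raise ValueError("cohort outcome carries no trace")
    se_cost = micro.se_cost if micro.se_cost > 0 else 1e-12
    se_qaly = micro.se_qaly if micro.se_qaly > 0 else 1e-12
    z_cost = (micro.mean_cost - cohort.total_cost) / se_cost
    z_qaly = (micro.mean_qaly - cohort.total_qaly) / se_qaly

    occ = cohort.trace.occupancy
    freq = micro.state_frequency
    dev = np.abs(freq - occ)
    se_freq = np.sqrt(freq * (1.0 - freq) / micro.n)
    within = bool(np.all(dev <= z_limit * se_freq + 1e-12))
    passed = abs(z_cost) <= z_limit and abs(z_qaly) <= z_limit and within
    return AgreementReport(
        arm=cohort.arm,
        z_cost=float(z_cost),
        z_qaly=float(z_qaly),
        max_frequency_deviation=float(dev.max()),
        frequency_within_3se=within,
        passed=passed,
    )
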