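"""Engine mechanics: probability conversions, competing risks, matrix
construction, cohort propagation, discounting, half-cycle correction."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from larc_cea import (
    HealthState,
    StrategyArm,
    TransitionMatrix,
    build_transition_matrix,
    competing_cycle_probabilities,
    cumulative_to_cycle_probability,
    discount_factor,
    half_cycle_weights,
    incidence_preserving_cycle_probabilities,
    run_cohort,
)
from larc_cea.parameters import STATE_INDEX, STATE_ORDER

NED = STATE_INDEX[HealthState.NED]
RES = STATE_INDEX[HealthState.LRR_RESECTABLE]
UNRES = STATE_INDEX[HealthState.LRR_UNRESECTABLE]
DM = STATE_INDEX[HealthState.DM]
DEATH = STATE_INDEX[HealthState.DEATH]


class TestCumulativeToCycle:
    @pytest.mark.parametrize(
        "P, H, c, expected",
        [
            (0.87, 5.0, 0.25, 1 - 0.13 ** 0.05),   # ≈ 0.09698 per 3-month cycle
            (0.20, 3.0, 0.25, 1 - 0.80 ** (1 / 12)),  # ≈ 0.018423
            (0.0, 3.0, 0.25, 0.0),
            (0.5, 1.0, 1.0, 0.5),  # full-horizon identity
        ],
    )
    def test_known_conversions(self, P, H, c, expected):
        assert cumulative_to_cycle_probability(P, H, c) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_certain_event(self):
        assert cumulative_to_cycle_probability(1.0, 5.0, 0.25) == 1.0

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            cumulative_to_cycle_probability(1.2, 5.0, 0.25)
        with pytest.raises(ValueError):
            cumulative_to_cycle_probability(0.5, 0.0, 0.25)

    @given(
        P=st.floats(min_value=0.0, max_value=0.999),
        H=st.sampled_from([1.0, 2.0, 3.0, 5.0]),
    )
    def test_compounding_recovers_cumulative(self, P, H):
        """Compounding the per-cycle probability over the horizon gives P back."""
        c = 0.25
        p = cumulative_to_cycle_probability(P, H, c)
        n = int(round(H / c))
        assert 1 - (1 - p) ** n == pytest.approx(P, abs=1e-10)


class TestCompetingRisks:
    def test_single_risk_reduces_to_marginal_conversion(self):
        (p,) = competing_cycle_probabilities([(0.5, 1.0)], 0.25)
        assert p == pytest.approx(cumulative_to_cycle_probability(0.5, 1.0, 0.25), abs=1e-14)

    def test_zero_risks(self):
        assert competing_cycle_probabilities([(0.0, 3.0), (0.0, 3.0)], 0.25) == [0.0, 0.0]

    def test_certain_event_rejected(self):
        with pytest.raises(ValueError):
            competing_cycle_probabilities([(1.0, 3.0)], 0.25)

    def test_against_continuous_time_oracle(self):
        """Cause-specific exit mass over one cycle, by numerical integration
        of the competing exponential densities."""
        events = [(0.083, 3.0), (0.20, 3.0)]
        dt = 0.25
        lam = [-math.log(1 - P) / H for P, H in events]
        total = sum(lam)
        expected = [quad(lambda t, l=l: l * math.exp(-total * t), 0.0, dt)[0] for l in lam]
        got = competing_cycle_probabilities(events, dt)
        assert got == pytest.approx(expected, abs=1e-12)
        # frozen values from the oracle
        assert got[0] == pytest.approx(0.0071282435, abs=1e-9)
        assert got[1] == pytest.approx(0.0183573206, abs=1e-9)

    def test_total_exit_mass(self):
        events = [(0.3, 2.0), (0.6, 5.0), (0.1, 1.0)]
        dt = 0.25
        lam = sum(-math.log(1 - P) / H for P, H in events)
        assert sum(competing_cycle_probabilities(events, dt)) == pytest.approx(
            1 - math.exp(-lam * dt), abs=1e-12
        )

    def test_incidence_preserving_reproduces_marginals(self):
        """Per-cycle exits calibrated so cohort cumulative incidence over the
        horizon equals each stated marginal."""
        events = [(0.083, 3.0), (0.20, 3.0)]
        dt = 0.25
        a, b = incidence_preserving_cycle_probabilities(events, dt)
        n = 12
        stay = (1 - a - b) ** np.arange(n)
        assert (a * stay).sum() == pytest.approx(0.083, abs=1e-12)
        assert (b * stay).sum() == pytest.approx(0.20, abs=1e-12)

    def test_incidence_preserving_falls_back_on_mixed_horizons(self):
        events = [(0.16, 2.0), (0.87, 5.0)]
        assert incidence_preserving_cycle_probabilities(
            events, 0.25
        ) == competing_cycle_probabilities(events, 0.25)

    def test_incidence_preserving_falls_back_on_infeasible_sum(self):
        events = [(0.75, 5.0), (0.49, 5.0)]
        assert incidence_preserving_cycle_probabilities(
            events, 0.25
        ) == competing_cycle_probabilities(events, 0.25)


class TestTransitionMatrix:
    @pytest.mark.parametrize("arm", list(StrategyArm))
    def test_rows_stochastic_and_death_absorbing(self, base, arm):
        m = build_transition_matrix(base, arm)
        np.testing.assert_allclose(m.matrix.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(m.matrix >= 0) and np.all(m.matrix <= 1)
        expected_death = np.zeros(5)
        expected_death[DEATH] = 1.0
        np.testing.assert_array_equal(m.matrix[DEATH], expected_death)

    def test_only_disease_free_row_is_arm_specific(self, base):
        a = build_transition_matrix(base, StrategyArm.SCRT_TNT).matrix
        b = build_transition_matrix(base, StrategyArm.LCCRT_ADJ).matrix
        assert not np.allclose(a[NED], b[NED])
        np.testing.assert_array_equal(a[1:], b[1:])

    def test_dm_to_death_per_cycle(self, base):
        m = build_transition_matrix(base, StrategyArm.SCRT_TNT)
        assert m.matrix[DM, DEATH] == pytest.approx(1 - 0.13 ** 0.05, abs=1e-12)

    def test_recurrence_entry_split(self, base):
        m = build_transition_matrix(base, StrategyArm.SCRT_TNT).matrix
        ratio = m[NED, RES] / (m[NED, RES] + m[NED, UNRES])
        assert ratio == pytest.approx(0.37, abs=1e-12)

    def test_ned_exits_reproduce_three_year_incidence(self, base):
        """Over 12 cycles of pure NED residence the cumulative incidences
        equal the stated 3-year probabilities."""
        m = build_transition_matrix(base, StrategyArm.SCRT_TNT).matrix
        exit_lrr = m[NED, RES] + m[NED, UNRES]
        exit_dm = m[NED, DM]
        stay = m[NED, NED] ** np.arange(12)
        assert (exit_lrr * stay).sum() == pytest.approx(0.083, abs=1e-10)
        assert (exit_dm * stay).sum() == pytest.approx(0.20, abs=1e-10)

    def test_invalid_parameters_rejected(self, base):
        broken = base.copy_deep()
        broken.probabilities["scrt.apr"].value = 0.9
        with pytest.raises(ValueError, match="sums to"):
            build_transition_matrix(broken, StrategyArm.SCRT_TNT)

    def test_non_stochastic_matrix_rejected(self):
        bad = np.eye(5)
        bad[0, 0] = 0.9
        with pytest.raises(ValueError):
            TransitionMatrix(states=list(STATE_ORDER), matrix=bad)


class TestCohortTrace:
    def test_identity_matrix_static_cohort(self):
        m = TransitionMatrix(states=list(STATE_ORDER), matrix=np.eye(5))
        trace = run_cohort(m, 20)
        assert np.all(trace.occupancy[:, NED] == 1.0)
        assert np.all(trace.entries() == 0.0)

    @pytest.mark.parametrize("arm", list(StrategyArm))
    def test_occupancy_conserved_and_recursion_holds(self, base, arm):
        m = build_transition_matrix(base, arm)
        trace = run_cohort(m, 20)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        for k in (0, 7, 19):
            np.testing.assert_allclose(
                trace.occupancy[k + 1], trace.occupancy[k] @ m.matrix, atol=1e-15
            )
            np.testing.assert_allclose(trace.flows[k].sum(axis=1), trace.occupancy[k], atol=1e-15)

    def test_death_occupancy_monotone(self, base):
        m = build_transition_matrix(base, StrategyArm.SCRT_TNT)
        trace = run_cohort(m, 20)
        assert np.all(np.diff(trace.occupancy[:, DEATH]) >= -1e-15)

    def test_survival_decreases_with_higher_metastasis_risk(self, base):
        from larc_cea import scale_parameter

        m0 = build_transition_matrix(base, StrategyArm.SCRT_TNT)
        m1 = build_transition_matrix(
            scale_parameter(base, "scrt.ned_to_dm", 1.25), StrategyArm.SCRT_TNT
        )
        os0 = 1 - run_cohort(m0, 20).occupancy[12, DEATH]
        os1 = 1 - run_cohort(m1, 20).occupancy[12, DEATH]
        assert os1 < os0

    def test_trace_dataframe_shape(self, base):
        m = build_transition_matrix(base, StrategyArm.SCRT_TNT)
        df = run_cohort(m, 20).to_dataframe()
        assert len(df) == 21
        assert "NED" in df.columns and "entry_DM" in df.columns


class TestDiscountingAndHalfCycle:
    @pytest.mark.parametrize(
        "k, expected",
        [(0, 1.0), (4, 1 / 1.03), (20, 1.03 ** -5)],
    )
    def test_discount_factor(self, k, expected):
        assert discount_factor(k, 0.03, 0.25) == pytest.approx(expected, abs=1e-12)

    def test_zero_rate_is_flat(self):
        assert discount_factor(13, 0.0, 0.25) == 1.0

    def test_half_cycle_constant_occupancy(self):
        m = TransitionMatrix(states=list(STATE_ORDER), matrix=np.eye(5))
        trace = run_cohort(m, 10)
        np.testing.assert_array_equal(half_cycle_weights(trace), trace.occupancy[:-1])

    def test_half_cycle_midpoint_on_full_transition(self, base):
        m = build_transition_matrix(base, StrategyArm.SCRT_TNT)
        trace = run_cohort(m, 5)
        # overwrite with an all-NED -> all-DEATH jump at cycle 0
        trace.occupancy[0] = np.eye(5)[NED]
        trace.occupancy[1] = np.eye(5)[DEATH]
        hc = half_cycle_weights(trace)
        assert hc[0, NED] == 0.5 and hc[0, DEATH] == 0.5

    def test_half_cycle_conserves_mass(self, base):
        m = build_transition_matrix(base, StrategyArm.LCCRT_ADJ)
        hc = half_cycle_weights(run_cohort(m, 20))
        np.testing.assert_allclose(hc.sum(axis=1), 1.0, atol=1e-9)
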