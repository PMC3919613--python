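import math

import numpy as np
import pytest

from topoproof.energetics import EnergeticsModel, equilibrium_distribution
from topoproof.ensemble import (
    ProtocolEvent,
    apply_protocol,
    estimate_alpha,
    one_step_capture_assay,
    simulate_population,
    stationary_closed_form,
    stationary_numeric,
)
from topoproof.gate_cycle import CGateStatus, EnzymeMode, GateModel, NGateAgent
from topoproof import lk_stats

ATP_INTACT = EnzymeMode(NGateAgent.ATP, CGateStatus.INTACT)
ATP_DELETED = EnzymeMode(NGateAgent.ATP, CGateStatus.DELETED)

# parameters small enough that no probability overflows anywhere on the
# default supports, so the strict (unclipped) chain is exactly reversible
SMALL_GATE = GateModel(p0=0.002, alpha=0.66, pi0=0.01)


class TestStationaryClosedForm:
    def test_alpha_zero_equals_equilibrium(self, energetics_4k, eq_4k):
        stat = stationary_closed_form(energetics_4k, GateModel(alpha=0.0))
        np.testing.assert_allclose(stat.fractions, eq_4k.fractions, rtol=1e-12)

    def test_adjacent_ratio_is_boltzmann_power(self, energetics_4k):
        stat = stationary_closed_form(energetics_4k, GateModel(alpha=0.66))
        expected = (math.exp(-4 / (2 * energetics_4k.sigma2_eq))) ** 1.66
        assert stat.fraction(-2) / stat.fraction(0) == pytest.approx(expected, rel=1e-9)

    def test_variance_narrowed_by_one_plus_alpha(self, energetics_4k, eq_4k):
        stat = stationary_closed_form(energetics_4k, GateModel(alpha=0.66))
        assert eq_4k.variance() / stat.variance() == pytest.approx(1.66, abs=1e-4)

    def test_r_lk_monotone_in_alpha(self, energetics_4k, eq_4k):
        r = [
            eq_4k.variance()
            / stationary_closed_form(energetics_4k, GateModel(alpha=a)).variance()
            for a in (0.0, 0.3, 0.6, 1.2)
        ]
        assert r[0] == pytest.approx(1.0, abs=1e-9)
        assert all(b > a for a, b in zip(r, r[1:]))


class TestStationaryNumeric:
    def test_matches_closed_form_for_full_cycle(self, energetics_8k):
        support = range(-15, 16)  # 31 states
        num = stationary_numeric(energetics_8k, SMALL_GATE, ATP_INTACT, support)
        closed = stationary_closed_form(energetics_8k, SMALL_GATE, support)
        assert np.abs(num.fractions - closed.fractions).max() < 1e-8

    def test_deleted_cgate_recovers_equilibrium(self, energetics_4k):
        support = range(-12, 13)
        num = stationary_numeric(energetics_4k, SMALL_GATE, ATP_DELETED, support)
        eq = equilibrium_distribution(energetics_4k, support)
        assert np.abs(num.fractions - eq.fractions).max() < 1e-8

    def test_single_state_support(self, energetics_4k):
        num = stationary_numeric(energetics_4k, SMALL_GATE, ATP_INTACT, [0])
        assert num.fraction(0) == pytest.approx(1.0)

    def test_locked_cgate_has_no_stationary(self, energetics_4k):
        with pytest.raises(ValueError, match="locked"):
            stationary_numeric(
                energetics_4k, SMALL_GATE, EnzymeMode(NGateAgent.ATP, CGateStatus.LOCKED)
            )


class TestSimulatePopulation:
    def test_zero_cycles_returns_initial(self, energetics_4k, eq_4k, calibrated_gate):
        traj = simulate_population(eq_4k, 500, 0, ATP_INTACT, calibrated_gate, energetics_4k, seed=5)
        assert len(traj) == 1 and traj[0].cycle_index == 0
        assert traj[0].n_molecules == 500

    def test_molecule_and_parity_conservation(self, energetics_4k, eq_4k, calibrated_gate):
        traj = simulate_population(
            eq_4k, 800, 50, ATP_INTACT, calibrated_gate, energetics_4k, seed=5
        )
        totals = [st.parity_totals() for st in traj]
        assert all(t == totals[0] for t in totals)
        assert all(st.n_molecules == 800 for st in traj)

    def test_bitwise_reproducible_given_seed(self, energetics_4k, eq_4k, calibrated_gate):
        t1 = simulate_population(eq_4k, 300, 40, ATP_INTACT, calibrated_gate, energetics_4k, seed=9)
        t2 = simulate_population(eq_4k, 300, 40, ATP_INTACT, calibrated_gate, energetics_4k, seed=9)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.counts, b.counts)

    def test_seed_is_mandatory(self, energetics_4k, eq_4k, calibrated_gate):
        with pytest.raises(ValueError):
            simulate_population(eq_4k, 10, 5, ATP_INTACT, calibrated_gate, energetics_4k)

    def test_deleted_cgate_relaxes_to_equilibrium(self, energetics_4k, eq_4k, calibrated_gate):
        traj = simulate_population(
            eq_4k, 4000, 200, ATP_DELETED, calibrated_gate, energetics_4k, seed=3
        )
        r = lk_stats.r_lk(eq_4k, traj[-1].distribution())
        assert r == pytest.approx(1.0, abs=0.12)

    def test_alpha_recovery_from_stationary_ratios(self, energetics_4k, eq_4k, calibrated_gate):
        traj = simulate_population(
            eq_4k, 10_000, 300, ATP_INTACT, calibrated_gate, energetics_4k, seed=21
        )
        alpha_hat = estimate_alpha(traj[-1].distribution(), eq_4k)
        assert alpha_hat == pytest.approx(calibrated_gate.alpha, abs=0.12)


class TestOneStepCaptureAssay:
    def test_conversion_fractions(self, energetics_4k, calibrated_gate):
        from_minus2 = one_step_capture_assay(-2, 10_000, calibrated_gate, energetics_4k, seed=2)
        from_zero = one_step_capture_assay(0, 10_000, calibrated_gate, energetics_4k, seed=3)
        assert from_minus2[0] == pytest.approx(0.50, abs=0.02)
        assert from_zero[-2] == pytest.approx(0.18, abs=0.02)
        assert sum(from_zero.values()) == pytest.approx(1.0, abs=1e-12)

    def test_single_passage_only_reaches_adjacent_states(self, energetics_4k, calibrated_gate):
        fr = one_step_capture_assay(0, 1000, calibrated_gate, energetics_4k, seed=4)
        assert set(fr) == {-2, 0, 2}


class TestApplyProtocol:
    def test_events_must_be_ordered_and_in_range(
        self, pbr322, energetics_4k, calibrated_gate
    ):
        bad_order = [
            ProtocolEvent(10, "shift_temperature", 40.0),
            ProtocolEvent(5, "shift_temperature", 15.0),
        ]
        with pytest.raises(ValueError, match="ordered"):
            apply_protocol(
                0, 100, 20, ATP_INTACT, calibrated_gate, energetics_4k, bad_order,
                seed=1, plasmid=pbr322, temperature_C=25.0,
            )
        with pytest.raises(ValueError, match="beyond"):
            apply_protocol(
                0, 100, 20, ATP_INTACT, calibrated_gate, energetics_4k,
                [ProtocolEvent(21, "shift_temperature", 40.0)],
                seed=1, plasmid=pbr322, temperature_C=25.0,
            )

    def test_temperature_inversion_reverses_trapped_segments(
        self, pbr322, energetics_4k, calibrated_gate
    ):
        # cold phase: center above the start, trapped segments at +2;
        # hot phase: center below, ATP lets them backtrack and re-trap at −2
        result = apply_protocol(
            0, 3000, 120,
            EnzymeMode(NGateAgent.ATP, CGateStatus.LOCKED),
            calibrated_gate, energetics_4k,
            [ProtocolEvent(60, "shift_temperature", 40.0)],
            seed=17, plasmid=pbr322, temperature_C=15.0,
        )
        cold, hot = result.phases[0].final, result.phases[1].final
        assert cold.fraction(2) > 0.1
        assert hot.fraction(2) < cold.fraction(2) / 3
        assert hot.fraction(-2) > cold.fraction(-2) * 3

    def test_locked_gates_freeze_when_ngate_cannot_reopen(
        self, pbr322, energetics_4k, calibrated_gate
    ):
        result = apply_protocol(
            0, 3000, 120,
            EnzymeMode(NGateAgent.AMPPNP, CGateStatus.LOCKED),
            calibrated_gate, energetics_4k,
            [ProtocolEvent(60, "shift_temperature", 40.0)],
            seed=17, plasmid=pbr322, temperature_C=15.0,
        )
        cold, hot = result.phases[0].final, result.phases[1].final
        assert cold.fraction(2) > 0.1  # one passage per enzyme did occur
        np.testing.assert_array_equal(cold.fractions, hot.fractions)

    def test_mode_switch_applies_to_subsequent_cycles(
        self, energetics_4k, eq_4k, calibrated_gate
    ):
        result = apply_protocol(
            eq_4k, 2000, 100, ATP_INTACT, calibrated_gate, energetics_4k,
            [ProtocolEvent(80, "switch_n_gate_agent", "AMPPNP")],
            seed=8,
        )
        assert result.phases[0].mode.n_gate_agent is NGateAgent.ATP
        assert result.phases[1].mode.n_gate_agent is NGateAgent.AMPPNP
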