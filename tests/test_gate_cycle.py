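import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from topoproof.energetics import EnergeticsModel, free_energy
from topoproof.gate_cycle import (
    CaptureOverflowError,
    CGateStatus,
    EnzymeMode,
    GateModel,
    NGateAgent,
    OutcomeKind,
    calibrate_p0,
    capture_probabilities,
    cycle_step,
    release_probability,
)


class TestCaptureProbabilities:
    def test_calibrated_capture_matches_benchmarks(self, energetics_4k):
        p0 = calibrate_p0(0.50, -2, 0, energetics_4k)
        gate = GateModel(p0=p0)
        assert capture_probabilities(-2, energetics_4k, gate)[+2] == pytest.approx(0.50)
        # same p0 from the relaxed center: ~0.18 (printed estimate 0.17)
        assert capture_probabilities(0, energetics_4k, gate)[-2] == pytest.approx(0.18, abs=0.01)

    def test_symmetric_at_center(self, energetics_4k):
        probs = capture_probabilities(0, energetics_4k, GateModel(p0=0.3))
        assert probs[+2] == pytest.approx(probs[-2], rel=1e-12)

    @given(k=st.integers(-10, 10), sigma2=st.floats(1.0, 5.0))
    @settings(deadline=None, derandomize=True)
    def test_detailed_balance_for_every_adjacent_pair(self, k, sigma2):
        en = EnergeticsModel(sigma2_eq=sigma2)
        gate = GateModel(p0=1e-6)  # small enough to be valid over the range
        fwd = capture_probabilities(k, en, gate)[+2]
        rev = capture_probabilities(k + 2, en, gate)[-2]
        dg = free_energy(k + 2, en) - free_energy(k, en)
        assert fwd / rev == pytest.approx(math.exp(-dg), rel=1e-12)

    def test_overflow_raises_naming_state(self, energetics_4k):
        with pytest.raises(CaptureOverflowError, match="delta_lk=10"):
            capture_probabilities(10, energetics_4k, GateModel(p0=0.3))

    def test_clip_produces_valid_pair(self, energetics_4k):
        probs = capture_probabilities(10, energetics_4k, GateModel(p0=0.3), clip=True)
        assert 0 <= probs[+2] <= 1 and 0 <= probs[-2] <= 1
        assert probs[+2] + probs[-2] <= 1 + 1e-12


class TestReleaseProbability:
    def test_alpha_zero_is_topology_blind(self):
        gate = GateModel(alpha=0.0, pi0=0.4)
        for dg in (-2.0, 0.0, 3.0):
            assert release_probability(dg, gate) == pytest.approx(0.4)

    def test_forward_reverse_ratio(self):
        gate = GateModel(alpha=0.69, pi0=0.3)
        dg = 1.02
        ratio = release_probability(dg, gate) / release_probability(-dg, gate)
        assert ratio == pytest.approx(math.exp(-0.69 * 1.02), rel=1e-10)

    def test_clipping_is_logged_not_raised(self):
        gate = GateModel(alpha=2.0, pi0=0.9)
        with pytest.warns(RuntimeWarning):
            import topoproof.gate_cycle as gc

            gc._clip_warned = False
            assert release_probability(-10.0, gate) == 1.0


class TestCalibrateP0:
    def test_benchmark_value(self, energetics_4k):
        assert calibrate_p0(0.50, -2, 0, energetics_4k) == pytest.approx(0.2998, abs=1e-3)

    def test_round_trip_identity(self, energetics_4k):
        p0 = calibrate_p0(0.37, 0, 2, energetics_4k)
        gate = GateModel(p0=p0)
        assert capture_probabilities(0, energetics_4k, gate)[+2] == pytest.approx(0.37, abs=1e-12)

    def test_raw_boltzmann_half_factor_gives_unit_p0(self, energetics_4k):
        dg = free_energy(-2, energetics_4k) - free_energy(0, energetics_4k)
        target = math.exp(-dg / 2.0)  # uphill move, so this is a valid probability
        assert calibrate_p0(target, 0, -2, energetics_4k) == pytest.approx(1.0)

    def test_invalid_targets_rejected(self, energetics_4k):
        with pytest.raises(ValueError):
            calibrate_p0(0.5, 0, 3, energetics_4k)
        with pytest.raises(ValueError):
            calibrate_p0(0.99, 0, -2, energetics_4k)  # would need p0 > 1


class TestCycleStep:
    def test_requires_rng(self, energetics_4k, calibrated_gate):
        with pytest.raises(ValueError):
            cycle_step(0, EnzymeMode(), calibrated_gate, energetics_4k)

    @pytest.mark.parametrize(
        "mode,allowed",
        [
            (EnzymeMode(NGateAgent.ATP, CGateStatus.INTACT),
             {OutcomeKind.NO_CAPTURE, OutcomeKind.TRANSPORTED, OutcomeKind.BACKTRACKED}),
            (EnzymeMode(NGateAgent.AMPPNP, CGateStatus.INTACT),
             {OutcomeKind.NO_CAPTURE, OutcomeKind.TRANSPORTED}),
            (EnzymeMode(NGateAgent.ICRF193, CGateStatus.INTACT),
             {OutcomeKind.NO_CAPTURE, OutcomeKind.TRANSPORTED}),
            (EnzymeMode(NGateAgent.ATP, CGateStatus.LOCKED),
             {OutcomeKind.NO_CAPTURE, OutcomeKind.TRAPPED_CHAMBER}),
            (EnzymeMode(NGateAgent.AMPPNP, CGateStatus.LOCKED),
             {OutcomeKind.NO_CAPTURE, OutcomeKind.TRAPPED_CHAMBER}),
            (EnzymeMode(NGateAgent.ATP, CGateStatus.DELETED),
             {OutcomeKind.NO_CAPTURE, OutcomeKind.TRANSPORTED}),
        ],
    )
    def test_outcome_kinds_by_mode(self, energetics_4k, calibrated_gate, rng, mode, allowed):
        seen = set()
        for _ in range(400):
            out = cycle_step(0, mode, calibrated_gate, energetics_4k, rng=rng)
            seen.add(out.kind)
            # step-size invariant: Lk never changes by anything but 0 or ±2
            assert out.new_delta_lk - 0 in (0, -2, 2)
            if out.kind in (OutcomeKind.TRANSPORTED, OutcomeKind.TRAPPED_CHAMBER):
                assert abs(out.new_delta_lk) == 2
            else:
                assert out.new_delta_lk == 0
        assert seen <= allowed
        assert OutcomeKind.NO_CAPTURE in seen  # capture is never certain here

    def test_parity_conserved_by_every_outcome(self, energetics_4k, calibrated_gate, rng):
        for start in (-3, 0, 2):
            for _ in range(100):
                out = cycle_step(
                    start, EnzymeMode(), calibrated_gate, energetics_4k, rng=rng
                )
                assert (out.new_delta_lk - start) % 2 == 0

    def test_backtracked_means_net_zero(self, energetics_4k, rng):
        # strong proofreading + uphill moves: backtracks must occur and revert
        gate = GateModel(p0=0.3, alpha=3.0, pi0=0.5)
        outcomes = [
            cycle_step(0, EnzymeMode(), gate, energetics_4k, rng=rng) for _ in range(500)
        ]
        backtracked = [o for o in outcomes if o.kind is OutcomeKind.BACKTRACKED]
        assert backtracked, "expected at least one backtrack"
        assert all(o.new_delta_lk == 0 for o in backtracked)


def test_amppnp_and_icrf_are_equivalent_blocks():
    for agent in (NGateAgent.AMPPNP, NGateAgent.ICRF193):
        assert not EnzymeMode(agent, CGateStatus.INTACT).n_gate_can_reopen
    assert EnzymeMode(NGateAgent.ATP, CGateStatus.INTACT).n_gate_can_reopen
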