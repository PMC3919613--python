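"""Single-encounter gate cycle of topoisomerase II with post-passage proofreading.

One enzyme–DNA encounter runs through three protein gates:

1. *Capture* at the N-gate.  The probability of capturing a T-segment whose
   passage would change ΔLk by ±2 obeys detailed balance with the
   supercoiling free energy: p(k→k±2) = p0·exp(−[G(k±2)−G(k)]/2).
2. *Passage* across the DNA-gate.  Once the N-gate has closed on a captured
   T-segment, passage is unidirectional and always completes.
3. *Release vs. backtrack* at the C-gate.  With ATP and an intact C-gate the
   passed segment exits with probability π(ΔG) = pi0·exp(−α·ΔG/2); otherwise
   the N-gate reopens first and the segment backtracks, cancelling net
   transport.  α is the proofreading strength: the stationary distribution of
   the resulting birth–death chain is ∝ exp(−(1+α)G), i.e. narrowed by a
   factor 1+α relative to equilibrium.

Non-hydrolysable AMPPNP and the inhibitor ICRF-193 both lock the N-gate
closed, so backtracking is impossible and at most one passage per enzyme can
occur.  A disulfide-locked C-gate traps the passed segment in the central
chamber; a deleted C-gate removes the release challenge altogether.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .energetics import EnergeticsModel, LkState, free_energy

__all__ = [
    "NGateAgent",
    "CGateStatus",
    "EnzymeMode",
    "GateModel",
    "OutcomeKind",
    "CycleOutcome",
    "CaptureOverflowError",
    "capture_probabilities",
    "release_probability",
    "cycle_step",
    "calibrate_p0",
    "STEP",
]

#: Type-II enzymes change Lk in steps of two.
STEP = 2


class NGateAgent(str, enum.Enum):
    ATP = "ATP"
    AMPPNP = "AMPPNP"
    ICRF193 = "ICRF193"


class CGateStatus(str, enum.Enum):
    INTACT = "intact"
    LOCKED = "disulfide_locked"
    DELETED = "deleted"


@dataclass(frozen=True)
class EnzymeMode:
    """N-gate nucleotide agent plus C-gate configuration.

    AMPPNP and ICRF-193 are simulator-equivalent (both forbid N-gate
    reopening) but kept as distinct labels for reporting.
    """

    n_gate_agent: NGateAgent = NGateAgent.ATP
    c_gate: CGateStatus = CGateStatus.INTACT

    @property
    def n_gate_can_reopen(self) -> bool:
        return self.n_gate_agent is NGateAgent.ATP

    def describe(self) -> str:
        return f"{self.n_gate_agent.value}/{self.c_gate.value}"


class CaptureOverflowError(ValueError):
    """Capture probability exceeded 1 (or the pair summed past 1) at a state."""


@dataclass(frozen=True)
class GateModel:
    """Proofreading-cycle parameters.

    Parameters
    ----------
    p0 : float
        Baseline capture efficiency per N-gate closure, in (0, 1].
    alpha : float
        Release exponent (proofreading strength); 0 means release is
        topology-blind and no narrowing occurs.
    pi0 : float
        Baseline release probability at ΔG = 0, in (0, 1].
    trapped_backtrack_prob : float
        Per-cycle probability that a chamber-trapped T-segment (locked
        C-gate, ATP) backtracks once the N-gate reopens.
    """

    p0: float = 0.3
    alpha: float = 0.0
    pi0: float = 0.5
    trapped_backtrack_prob: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 <= 1.0:
            raise ValueError(f"p0 must be in (0, 1], got {self.p0}")
        if self.alpha < 0.0:
            raise ValueError(f"alpha must be nonnegative, got {self.alpha}")
        if not 0.0 < self.pi0 <= 1.0:
            raise ValueError(f"pi0 must be in (0, 1], got {self.pi0}")
        if not 0.0 <= self.trapped_backtrack_prob <= 1.0:
            raise ValueError("trapped_backtrack_prob must be a probability")

    step: int = STEP


class OutcomeKind(str, enum.Enum):
    NO_CAPTURE = "no_capture"
    TRANSPORTED = "transported"
    BACKTRACKED = "backtracked"
    TRAPPED_CHAMBER = "trapped_chamber"


@dataclass(frozen=True)
class CycleOutcome:
    kind: OutcomeKind
    direction: int  # ±2, or 0 when no net passage direction applies
    new_delta_lk: int


def _as_delta_lk(state) -> int:
    return state.delta_lk if isinstance(state, LkState) else int(state)


def capture_probabilities(
    state,
    energetics: EnergeticsModel,
    gate: GateModel,
    lk0_offset: float = 0.0,
    clip: bool = False,
) -> dict[int, float]:
    """Detailed-balance capture probabilities toward ΔLk ± 2.

    p(k→k±2) = p0 · exp(−[G(k±2) − G(k)] / 2), so forward/reverse capture
    stands in the full Boltzmann ratio.  Remaining mass is "no capture".

    With ``clip=False`` a probability above 1 (or a pair summing past 1)
    raises :class:`CaptureOverflowError` naming the state; with
    ``clip=True`` the probabilities are clipped to a valid pair (used by the
    population engine, where such states lie far in the Boltzmann tail).
    """
    k = _as_delta_lk(state)
    g0 = free_energy(k, energetics, lk0_offset)
    probs = {}
    for d in (+STEP, -STEP):
        dg = free_energy(k + d, energetics, lk0_offset) - g0
        probs[d] = gate.p0 * math.exp(-dg / 2.0)
    total = probs[+STEP] + probs[-STEP]
    if max(probs.values()) > 1.0 or total > 1.0:
        if not clip:
            raise CaptureOverflowError(
                f"capture probabilities at delta_lk={k} invalid: "
                f"p(+2)={probs[+STEP]:.4g}, p(-2)={probs[-STEP]:.4g} "
                f"(p0={gate.p0}); reduce p0 or narrow the working support"
            )
        probs = {d: min(p, 1.0) for d, p in probs.items()}
        total = probs[+STEP] + probs[-STEP]
        if total > 1.0:
            probs = {d: p / total for d, p in probs.items()}
    return probs


_clip_warned = False


def release_probability(delta_g_transport: float, gate: GateModel) -> float:
    """C-gate release probability π(ΔG) = min(1, pi0·exp(−α·ΔG/2)).

    ΔG is the free-energy change of the transport being challenged (in kT).
    1 − π is the backtrack probability.  Clipping at 1 is logged once.
    """
    raw = gate.pi0 * math.exp(-gate.alpha * delta_g_transport / 2.0)
    if raw > 1.0:
        global _clip_warned
        if not _clip_warned:
            warnings.warn(
                f"release probability clipped to 1 (raw {raw:.3g} at "
                f"dG={delta_g_transport:.3g} kT); ratios are distorted where clipping occurs",
                RuntimeWarning,
                stacklevel=2,
            )
            _clip_warned = True
        return 1.0
    return raw


def cycle_step(
    state,
    mode: EnzymeMode,
    gate: GateModel,
    energetics: EnergeticsModel,
    lk0_offset: float = 0.0,
    rng: np.random.Generator | None = None,
) -> CycleOutcome:
    """One enzyme–DNA encounter: capture, obligatory passage, then release.

    Outcome semantics by mode:

    - intact C-gate + ATP: transported with probability π(ΔG), else
      backtracked (net zero within the encounter);
    - intact C-gate + AMPPNP/ICRF-193: transported on every capture (the
      N-gate cannot reopen, so backtracking is impossible);
    - locked C-gate: the passed segment is trapped in the chamber
      (``trapped_chamber``, ΔLk already changed); with ATP later cycles may
      backtrack and recapture — that bookkeeping lives in the population
      engine, which tracks per-molecule trap state;
    - deleted C-gate: transported on every capture (no release challenge).
    """
    if rng is None:
        raise ValueError("cycle_step requires a seeded numpy Generator")
    k = _as_delta_lk(state)
    probs = capture_probabilities(k, energetics, gate, lk0_offset, clip=True)
    u = rng.random()
    if u < probs[-STEP]:
        direction = -STEP
    elif u < probs[-STEP] + probs[+STEP]:
        direction = +STEP
    else:
        return CycleOutcome(OutcomeKind.NO_CAPTURE, 0, k)

    # Passage across the DNA-gate always follows capture.
    new_k = k + direction

    if mode.c_gate is CGateStatus.DELETED:
        return CycleOutcome(OutcomeKind.TRANSPORTED, direction, new_k)
    if mode.c_gate is CGateStatus.LOCKED:
        return CycleOutcome(OutcomeKind.TRAPPED_CHAMBER, direction, new_k)
    # intact C-gate
    if not mode.n_gate_can_reopen:
        return CycleOutcome(OutcomeKind.TRANSPORTED, direction, new_k)
    dg = free_energy(new_k, energetics, lk0_offset) - free_energy(k, energetics, lk0_offset)
    if rng.random() < release_probability(dg, gate):
        return CycleOutcome(OutcomeKind.TRANSPORTED, direction, new_k)
    return CycleOutcome(OutcomeKind.BACKTRACKED, direction, k)


def calibrate_p0(
    target_probability: float,
    from_state: int,
    to_state: int,
    energetics: EnergeticsModel,
    lk0_offset: float = 0.0,
) -> float:
    """p0 such that capture_probabilities(from)[to−from] equals the target.

    Inverts p = p0·exp(−ΔG/2) for the single transition from→to.
    """
    if abs(to_state - from_state) != STEP:
        raise ValueError("from_state and to_state must differ by exactly 2")
    if not 0.0 < target_probability < 1.0:
        raise ValueError("target_probability must be in (0, 1)")
    dg = free_energy(to_state, energetics, lk0_offset) - free_energy(
        from_state, energetics, lk0_offset
    )
    p0 = target_probability * math.exp(dg / 2.0)
    if not 0.0 < p0 <= 1.0:
        raise ValueError(
            f"calibrated p0={p0:.4g} lies outside (0, 1]; the target capture "
            f"probability {target_probability} is unreachable for this transition"
        )
    return p0
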