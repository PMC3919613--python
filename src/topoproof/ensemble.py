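"""Population-level dynamics of topoisomer ensembles under enzyme action.

The per-encounter gate cycle induces a birth–death Markov chain on integer
ΔLk states (steps of ±2, so odd and even parity classes evolve
independently).  This module provides

- the closed-form stationary distribution ∝ exp(−(1+α)·G/kT) for the
  ATP / intact-C-gate cycle, narrowed by the proofreading factor 1+α;
- an independent numerical stationary solver built from the per-cycle
  transition matrix;
- seeded Monte Carlo ensembles of plasmid molecules, including the
  single-passage (AMPPNP) capture assay and mid-run perturbation protocols
  (nucleotide switches, temperature shifts, enzyme-ratio changes).

Stoichiometry: with ATP, each molecule undergoes an enzyme encounter per
cycle with probability min(1, E/DNA).  When the N-gate is locked by AMPPNP
or ICRF-193, each molecule instead carries an integer enzyme budget with
mean E/DNA; each enzyme closes its N-gate exactly once, transporting iff a
T-segment is captured at that closure, so post-block transports per
molecule are at most — and proportional to — the enzyme-to-DNA ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .energetics import (
    EnergeticsModel,
    LkDistribution,
    LkState,
    PlasmidSpec,
    default_support,
    free_energy,
    lk0_temperature_shift,
)
from .gate_cycle import (
    STEP,
    CGateStatus,
    EnzymeMode,
    GateModel,
    NGateAgent,
    capture_probabilities,
    release_probability,
)

__all__ = [
    "PopulationState",
    "ProtocolEvent",
    "PhaseReport",
    "ProtocolResult",
    "stationary_closed_form",
    "stationary_numeric",
    "simulate_population",
    "one_step_capture_assay",
    "apply_protocol",
    "estimate_alpha",
    "PopulationEngine",
]


@dataclass(frozen=True)
class PopulationState:
    """Snapshot of an ensemble: molecule counts per ΔLk at one cycle."""

    support: np.ndarray
    counts: np.ndarray
    cycle_index: int
    seed: int
    mode: EnzymeMode
    enzyme_to_dna_ratio: float

    @property
    def n_molecules(self) -> int:
        return int(self.counts.sum())

    def distribution(self) -> LkDistribution:
        return LkDistribution(self.support, self.counts.astype(float), normalize=True)

    def parity_totals(self) -> dict[str, int]:
        even = int(self.counts[self.support % 2 == 0].sum())
        return {"even": even, "odd": self.n_molecules - even}


@dataclass(frozen=True)
class ProtocolEvent:
    """A mid-run perturbation applied at the start of cycle ``at_cycle``."""

    at_cycle: int
    action: str  # switch_n_gate_agent | shift_temperature | set_enzyme_ratio
    payload: object

    _ACTIONS = ("switch_n_gate_agent", "shift_temperature", "set_enzyme_ratio")

    def __post_init__(self) -> None:
        if self.action not in self._ACTIONS:
            raise ValueError(f"unknown protocol action {self.action!r}")


# --------------------------------------------------------------------------
# Stationary distributions
# --------------------------------------------------------------------------


def stationary_closed_form(
    energetics: EnergeticsModel,
    gate: GateModel,
    support=None,
    lk0_offset: float = 0.0,
    parity_masses: dict[str, float] | None = None,
) -> LkDistribution:
    """Flux-balance stationary distribution of the ATP / intact-C-gate cycle.

    Capture (∝ exp(−ΔG/2)) times release (∝ exp(−αΔG/2)) gives detailed
    balance with effective energy (1+α)·G, hence a Gaussian-weighted integer
    distribution with variance σ²_eq/(1+α).

    By default the weights are normalized jointly over the support (so
    α = 0 reproduces the equilibrium distribution exactly).  Because
    type-II dynamics conserve parity, the odd/even mass split is a
    convention; pass ``parity_masses={"even": m_e, "odd": m_o}`` to impose
    the split inherited from a particular initial condition.
    """
    if support is None:
        support = default_support(energetics, center=lk0_offset)
    support = np.asarray(support, dtype=int)
    g = np.array([free_energy(k, energetics, lk0_offset) for k in support])
    w = np.exp(-(1.0 + gate.alpha) * (g - g.min()))
    if parity_masses is not None:
        w = _impose_parity_masses(support, w, parity_masses)
    return LkDistribution(support, w, normalize=True)


def _impose_parity_masses(support, weights, parity_masses):
    w = weights.astype(float).copy()
    for label, sel in (("even", support % 2 == 0), ("odd", support % 2 != 0)):
        m = w[sel].sum()
        target = parity_masses.get(label, 0.0)
        if m > 0:
            w[sel] *= target / m
        elif target > 0:
            raise ValueError(f"cannot place mass on empty {label} parity class")
    return w


def _raw_move_weights(energetics, gate, mode, support, lk0_offset):
    """Unnormalized per-cycle move weights up (k→k+2) and down (k→k−2).

    Capture weight p0·exp(−ΔG/2), times the release factor pi0·exp(−αΔG/2)
    for the ATP / intact-C-gate cycle; may exceed 1 in the downhill tails.
    """
    support = np.asarray(support, dtype=int)
    n = len(support)
    up = np.zeros(n)
    down = np.zeros(n)
    intact_atp = mode.c_gate is CGateStatus.INTACT and mode.n_gate_can_reopen
    for i, k in enumerate(support):
        g0 = free_energy(k, energetics, lk0_offset)
        for d, arr in ((+STEP, up), (-STEP, down)):
            j = i + d
            if not 0 <= j < n:
                continue
            dg = free_energy(k + d, energetics, lk0_offset) - g0
            w = gate.p0 * math.exp(-dg / 2.0)
            if intact_atp:
                w *= gate.pi0 * math.exp(-gate.alpha * dg / 2.0)
            arr[i] = w
    return up, down


def balanced_move_tables(energetics, gate, mode, support, lk0_offset=0.0):
    """Valid per-cycle move probabilities preserving every detailed-balance ratio.

    Raw move weights can exceed 1 far downhill.  Scaling *both* directions of
    an overflowing edge by the same factor caps them without touching the
    up/down ratio across any edge, so the stationary distribution of the
    birth–death chain is exactly unchanged; a final global damping factor
    keeps each state's total exit probability at or below 1.  The price is a
    uniformly slower clock, not a different steady state.
    """
    up, down = _raw_move_weights(energetics, gate, mode, support, lk0_offset)
    n = len(up)
    for i in range(n - STEP):
        s = max(1.0, up[i], down[i + STEP])
        up[i] /= s
        down[i + STEP] /= s
    lam = max(1.0, float((up + down).max()))
    return up / lam, down / lam


def _transition_probs(energetics, gate, mode, support, lk0_offset, clip):
    """Per-cycle move probabilities; strict mode raises on probability overflow."""
    if clip:
        return balanced_move_tables(energetics, gate, mode, support, lk0_offset)
    support = np.asarray(support, dtype=int)
    n = len(support)
    up = np.zeros(n)
    down = np.zeros(n)
    for i, k in enumerate(support):
        probs = capture_probabilities(k, energetics, gate, lk0_offset, clip=False)
        p_up, p_dn = probs[+STEP], probs[-STEP]
        if mode.c_gate is CGateStatus.INTACT and mode.n_gate_can_reopen:
            g0 = free_energy(k, energetics, lk0_offset)
            p_up *= release_probability(free_energy(k + STEP, energetics, lk0_offset) - g0, gate)
            p_dn *= release_probability(free_energy(k - STEP, energetics, lk0_offset) - g0, gate)
        up[i] = p_up if i + STEP < n else 0.0
        down[i] = p_dn if i - STEP >= 0 else 0.0
    return up, down


def stationary_numeric(
    energetics: EnergeticsModel,
    gate: GateModel,
    mode: EnzymeMode,
    support=None,
    lk0_offset: float = 0.0,
    parity_masses: dict[str, float] | None = None,
    clip: bool = False,
) -> LkDistribution:
    """Stationary vector of the per-cycle transition matrix, by linear solve.

    Independent of the closed form: builds the chain from the same outcome
    probabilities the simulator uses (capture × release; backtracking and
    no-capture are self-transitions) and solves π = πP within each parity
    class.  Modes with a locked C-gate have no ergodic chain (trapped states
    absorb) and are rejected.

    The odd/even mass split is a conserved quantity of the dynamics, not a
    property of the chain; by default it is taken from the closed-form
    stationary weights of the same mode so the two routes are directly
    comparable state by state.
    """
    if mode.c_gate is CGateStatus.LOCKED:
        raise ValueError("no stationary distribution: locked C-gate traps every passed segment")
    if support is None:
        support = default_support(energetics, center=lk0_offset)
    support = np.asarray(support, dtype=int)
    up, down = _transition_probs(energetics, gate, mode, support, lk0_offset, clip)

    effective_alpha = (
        gate.alpha if (mode.c_gate is CGateStatus.INTACT and mode.n_gate_can_reopen) else 0.0
    )
    if parity_masses is None:
        ref = stationary_closed_form(
            energetics,
            GateModel(p0=gate.p0, alpha=effective_alpha, pi0=gate.pi0),
            support,
            lk0_offset,
        )
        parity_masses = {
            "even": float(ref.fractions[support % 2 == 0].sum()),
            "odd": float(ref.fractions[support % 2 != 0].sum()),
        }

    fractions = np.zeros(len(support))
    for label, sel in (("even", support % 2 == 0), ("odd", support % 2 != 0)):
        idx = np.flatnonzero(sel)
        if len(idx) == 0:
            continue
        pi = _solve_parity_chain(support, up, down, idx)
        fractions[idx] = pi * parity_masses.get(label, 0.0)
    return LkDistribution(support, fractions, normalize=True)


def _solve_parity_chain(support, up, down, idx):
    m = len(idx)
    if m == 1:
        return np.ones(1)
    interior_up = up[idx[:-1]]
    interior_down = down[idx[1:]]
    if np.any(interior_up <= 0) or np.any(interior_down <= 0):
        bad = support[idx[np.argmin(np.minimum(np.r_[interior_up, 1], np.r_[1, interior_down]))]]
        raise ValueError(
            f"reducible chain: zero transition probability disconnects state {bad} "
            "within its parity class"
        )
    # transition matrix on this parity class (self-transitions absorb the rest)
    p = np.zeros((m, m))
    for j in range(m):
        if j + 1 < m:
            p[j, j + 1] = up[idx[j]]
        if j - 1 >= 0:
            p[j, j - 1] = down[idx[j]]
        p[j, j] = 1.0 - p[j].sum()
    a = p.T - np.eye(m)
    a[-1, :] = 1.0
    b = np.zeros(m)
    b[-1] = 1.0
    pi = np.linalg.solve(a, b)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def estimate_alpha(
    dist_stationary: LkDistribution,
    dist_equilibrium: LkDistribution,
    state_a: int = -2,
    state_b: int = 0,
) -> float:
    """Recover α from adjacent-topoisomer ratios: 1+α = ln(r_ss)/ln(r_eq)."""
    r_ss = dist_stationary.fraction(state_a) / dist_stationary.fraction(state_b)
    r_eq = dist_equilibrium.fraction(state_a) / dist_equilibrium.fraction(state_b)
    if r_ss <= 0 or r_eq <= 0 or r_eq == 1.0:
        raise ValueError("ratios must be positive and the equilibrium ratio != 1")
    return math.log(r_ss) / math.log(r_eq) - 1.0


# --------------------------------------------------------------------------
# Monte Carlo engine
# --------------------------------------------------------------------------


class PopulationEngine:
    """Vectorized ensemble simulator; carries molecule state across phases."""

    def __init__(
        self,
        energetics: EnergeticsModel,
        gate: GateModel,
        mode: EnzymeMode,
        support,
        states: np.ndarray,
        rng: np.random.Generator,
        seed: int,
        enzyme_to_dna_ratio: float = 0.5,
        lk0_offset: float = 0.0,
    ):
        self.energetics = energetics
        self.gate = gate
        self.support = np.asarray(support, dtype=int)
        self.rng = rng
        self.seed = seed
        self.lk0_offset = lk0_offset
        self.enzyme_to_dna_ratio = float(enzyme_to_dna_ratio)
        self.idx = np.asarray(states, dtype=np.int64) - int(self.support[0])
        if np.any(self.idx < 0) or np.any(self.idx >= len(self.support)):
            raise ValueError("initial states fall outside the support")
        self.trap_dir = np.zeros(len(self.idx), dtype=np.int64)
        self.cycle_index = 0
        self.transports = 0
        self._set_mode(mode, fresh=True)
        self._build_tables()

    # -- configuration ----------------------------------------------------

    def _set_mode(self, mode: EnzymeMode, fresh: bool) -> None:
        self.mode = mode
        n = len(self.idx)
        ratio = self.enzyme_to_dna_ratio
        if not mode.n_gate_can_reopen and mode.c_gate is not CGateStatus.LOCKED:
            # one transport per enzyme: integer budget with mean E/DNA
            base = int(math.floor(ratio))
            frac = ratio - base
            self.budget = base + (self.rng.random(n) < frac).astype(np.int64)
        else:
            self.budget = None
        if mode.c_gate is CGateStatus.LOCKED and fresh:
            # a clamped enzyme stays with its molecule
            self.has_enzyme = self.rng.random(n) < min(1.0, ratio)
        elif mode.c_gate is not CGateStatus.LOCKED:
            self.has_enzyme = None

    def set_mode(self, mode: EnzymeMode) -> None:
        """Switch nucleotide agent / C-gate for subsequent cycles (fresh enzymes)."""
        self._set_mode(mode, fresh=self.mode.c_gate is not CGateStatus.LOCKED)
        self._build_tables()

    def set_enzyme_ratio(self, ratio: float) -> None:
        self.enzyme_to_dna_ratio = float(ratio)
        self._set_mode(self.mode, fresh=False)

    def set_lk0_offset(self, offset: float) -> None:
        self.lk0_offset = float(offset)
        self._build_tables()

    def _build_tables(self) -> None:
        # valid per-cycle move probabilities with every detailed-balance
        # ratio preserved exactly (edge-paired clipping + global damping)
        self.p_up, self.p_dn = balanced_move_tables(
            self.energetics, self.gate, self.mode, self.support, self.lk0_offset
        )

    # -- dynamics ----------------------------------------------------------

    def _capture_draw(self, active: np.ndarray):
        u = self.rng.random(len(self.idx))
        pm = self.p_dn[self.idx]
        pp = self.p_up[self.idx]
        cap_dn = active & (u < pm)
        cap_up = active & ~cap_dn & (u < pm + pp)
        return cap_up, cap_dn

    def step_cycle(self) -> None:
        mode, gate, rng = self.mode, self.gate, self.rng
        n = len(self.idx)
        if mode.c_gate is CGateStatus.LOCKED:
            trapped = self.trap_dir != 0
            if mode.n_gate_can_reopen:
                bt = trapped & (rng.random(n) < gate.trapped_backtrack_prob)
                self.idx[bt] -= self.trap_dir[bt]
                self.trap_dir[bt] = 0
            free = (self.trap_dir == 0) & self.has_enzyme
            cap_up, cap_dn = self._capture_draw(free)
            self.idx[cap_up] += STEP
            self.idx[cap_dn] -= STEP
            self.trap_dir[cap_up] = +STEP
            self.trap_dir[cap_dn] = -STEP
            if not mode.n_gate_can_reopen:
                # single N-gate closure per AMPPNP-bound enzyme
                self.has_enzyme = self.has_enzyme & ~free
        elif mode.n_gate_can_reopen:
            # move tables already fold capture × release for the intact
            # C-gate; a failed release (backtrack) leaves the state unchanged
            enc = rng.random(n) < min(1.0, self.enzyme_to_dna_ratio)
            cap_up, cap_dn = self._capture_draw(enc)
            self.idx[cap_up] += STEP
            self.idx[cap_dn] -= STEP
            self.transports += int(cap_up.sum() + cap_dn.sum())
        else:
            # AMPPNP / ICRF-193 with intact or deleted C-gate: each enzyme
            # closes its N-gate exactly once — transport iff a T-segment is
            # captured at that closure, and never any backtracking
            active = self.budget > 0
            cap_up, cap_dn = self._capture_draw(active)
            self.idx[cap_up] += STEP
            self.idx[cap_dn] -= STEP
            self.budget[active] -= 1
            self.transports += int(cap_up.sum() + cap_dn.sum())
        self.cycle_index += 1

    def snapshot(self) -> PopulationState:
        counts = np.bincount(self.idx, minlength=len(self.support))
        return PopulationState(
            support=self.support.copy(),
            counts=counts,
            cycle_index=self.cycle_index,
            seed=self.seed,
            mode=self.mode,
            enzyme_to_dna_ratio=self.enzyme_to_dna_ratio,
        )

    def run(self, n_cycles: int, record_every: int = 1) -> list[PopulationState]:
        out = []
        for c in range(1, n_cycles + 1):
            self.step_cycle()
            if c % record_every == 0 or c == n_cycles:
                out.append(self.snapshot())
        return out


def _initial_states(initial, n_molecules: int, support, rng) -> np.ndarray:
    support = np.asarray(support, dtype=int)
    if isinstance(initial, LkDistribution):
        probs = np.zeros(len(support))
        for k, f in zip(initial.support, initial.fractions):
            j = k - support[0]
            if f > 0 and (j < 0 or j >= len(support)):
                raise ValueError(f"initial distribution state {k} outside support")
            if 0 <= j < len(support):
                probs[j] = f
        probs = probs / probs.sum()
        counts = rng.multinomial(n_molecules, probs)
        return np.repeat(support, counts)
    if isinstance(initial, (int, np.integer, LkState)):
        k = initial.delta_lk if isinstance(initial, LkState) else int(initial)
        return np.full(n_molecules, k, dtype=np.int64)
    raise TypeError(f"unsupported initial population: {type(initial)!r}")


def simulate_population(
    initial,
    n_molecules: int,
    n_cycles: int,
    mode: EnzymeMode,
    gate: GateModel,
    energetics: EnergeticsModel,
    enzyme_to_dna_ratio: float = 0.5,
    seed: int | None = None,
    lk0_offset: float = 0.0,
    support=None,
    record_every: int = 1,
) -> list[PopulationState]:
    """Seeded Monte Carlo trajectory of an ensemble of plasmid molecules.

    ``initial`` is an :class:`LkDistribution` (multinomially sampled) or a
    single integer ΔLk for a pure topoisomer population.  Returns snapshots
    at cycle 0, every ``record_every`` cycles, and the final cycle.
    """
    if n_molecules < 1 or n_cycles < 0:
        raise ValueError("n_molecules must be >= 1 and n_cycles >= 0")
    if seed is None:
        raise ValueError("seed is mandatory for reproducibility")
    if support is None:
        support = default_support(energetics, center=lk0_offset)
    rng = np.random.default_rng(seed)
    states = _initial_states(initial, n_molecules, support, rng)
    engine = PopulationEngine(
        energetics,
        gate,
        mode,
        support,
        states,
        rng,
        seed,
        enzyme_to_dna_ratio=enzyme_to_dna_ratio,
        lk0_offset=lk0_offset,
    )
    trajectory = [engine.snapshot()]
    trajectory += engine.run(n_cycles, record_every=record_every)
    return trajectory


def one_step_capture_assay(
    topoisomer,
    n_molecules: int,
    gate: GateModel,
    energetics: EnergeticsModel,
    seed: int | None = None,
    lk0_offset: float = 0.0,
) -> dict[int, float]:
    """Single-passage capture assay: N-gate locked by AMPPNP, one draw per enzyme.

    Starting from a pure topoisomer population bound to enzyme, returns the
    fraction of molecules converted to each ΔLk ± 2 and the fraction
    unchanged, keyed by destination ΔLk.
    """
    if seed is None:
        raise ValueError("seed is mandatory for reproducibility")
    k = topoisomer.delta_lk if isinstance(topoisomer, LkState) else int(topoisomer)
    rng = np.random.default_rng(seed)
    probs = capture_probabilities(k, energetics, gate, lk0_offset, clip=True)
    u = rng.random(n_molecules)
    n_dn = int((u < probs[-STEP]).sum())
    n_up = int(((u >= probs[-STEP]) & (u < probs[-STEP] + probs[+STEP])).sum())
    return {
        k - STEP: n_dn / n_molecules,
        k + STEP: n_up / n_molecules,
        k: (n_molecules - n_dn - n_up) / n_molecules,
    }


# --------------------------------------------------------------------------
# Protocols
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseReport:
    start_cycle: int
    end_cycle: int
    mode: EnzymeMode
    temperature_C: float | None
    lk0_offset: float
    enzyme_to_dna_ratio: float
    final: LkDistribution
    transports: int


@dataclass(frozen=True)
class ProtocolResult:
    phases: list[PhaseReport]
    trajectory: list[PopulationState]

    @property
    def final(self) -> LkDistribution:
        return self.phases[-1].final


def apply_protocol(
    initial,
    n_molecules: int,
    n_cycles: int,
    mode: EnzymeMode,
    gate: GateModel,
    energetics: EnergeticsModel,
    events: Sequence[ProtocolEvent],
    enzyme_to_dna_ratio: float = 0.5,
    seed: int | None = None,
    plasmid: PlasmidSpec | None = None,
    temperature_C: float | None = None,
    support=None,
    record_every: int = 1,
) -> ProtocolResult:
    """Run a simulation with mid-run perturbations, reporting per-phase summaries.

    Temperature shifts require a ``plasmid`` and act by moving the relaxed
    center Lk⁰ (the free-energy minimum) via the helical unwinding
    coefficient; mode and ratio switches apply to subsequent cycles only.
    Molecule identity (including chamber-trapped segments) is carried across
    events.
    """
    events = list(events)
    if any(events[i].at_cycle >= events[i + 1].at_cycle for i in range(len(events) - 1)):
        raise ValueError("protocol events must be strictly ordered by at_cycle")
    if events and (events[0].at_cycle < 0 or events[-1].at_cycle > n_cycles):
        raise ValueError("protocol event scheduled beyond the simulated cycles")
    if seed is None:
        raise ValueError("seed is mandatory for reproducibility")

    lk0_offset = 0.0
    if temperature_C is not None:
        if plasmid is None:
            raise ValueError("temperature control requires a PlasmidSpec")
        lk0_offset = lk0_temperature_shift(plasmid, temperature_C, energetics)
    if support is None:
        support = default_support(energetics)
    rng = np.random.default_rng(seed)
    states = _initial_states(initial, n_molecules, support, rng)
    engine = PopulationEngine(
        energetics,
        gate,
        mode,
        support,
        states,
        rng,
        seed,
        enzyme_to_dna_ratio=enzyme_to_dna_ratio,
        lk0_offset=lk0_offset,
    )

    trajectory = [engine.snapshot()]
    phases: list[PhaseReport] = []
    boundaries = [e.at_cycle for e in events] + [n_cycles]
    start = 0
    temp = temperature_C
    for i, end in enumerate(boundaries):
        t0 = engine.transports
        if end > start:
            trajectory += engine.run(end - start, record_every=record_every)
        phases.append(
            PhaseReport(
                start_cycle=start,
                end_cycle=end,
                mode=engine.mode,
                temperature_C=temp,
                lk0_offset=engine.lk0_offset,
                enzyme_to_dna_ratio=engine.enzyme_to_dna_ratio,
                final=engine.snapshot().distribution(),
                transports=engine.transports - t0,
            )
        )
        if i < len(events):
            ev = events[i]
            if ev.action == "switch_n_gate_agent":
                agent = NGateAgent(ev.payload)
                engine.set_mode(EnzymeMode(agent, engine.mode.c_gate))
            elif ev.action == "shift_temperature":
                if plasmid is None:
                    raise ValueError("temperature control requires a PlasmidSpec")
                temp = float(ev.payload)
                engine.set_lk0_offset(lk0_temperature_shift(plasmid, temp, energetics))
            elif ev.action == "set_enzyme_ratio":
                engine.set_enzyme_ratio(float(ev.payload))
        start = end
    return ProtocolResult(phases=phases, trajectory=trajectory)
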