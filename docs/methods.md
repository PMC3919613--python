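# Methods

## Model

The simulator tracks an ensemble of covalently closed plasmid molecules,
each labelled by its integer linking-number deviation ΔLk from the relaxed
center Lk⁰ at the reference temperature (25 °C). Lk⁰ itself is real-valued:
heating unwinds the double helix, shifting the free-energy minimum by
ΔLk⁰ = −h·N·ΔT/360 with h = 0.011° of twist per bp per °C, while the
topoisomer states stay integer.

Supercoiling free energy is quadratic, G(ΔLk)/kT = (nk/N)·(ΔLk − δ)², with
nk = 1100 kT·bp (the long-plasmid consensus value; it reproduces the
measured equilibrium ratio C₋₂/C₀ ≈ 0.35 for a 4.3-kb plasmid) and δ the
thermal offset of Lk⁰. The equilibrium topoisomer variance is
σ² = N/(2·nk): 1.954 for 4.3 kb, 3.591 for 7.9 kb. The quadratic regime
requires N ≥ ~1 kb and moderate |ΔLk|; sequence- and salt-dependent
stiffness corrections, twist/writhe partition, and high-|σ| nonlinearities
are out of scope.

One enzyme–DNA encounter (one "cycle" for that molecule) consists of

1. **Capture** at the N-gate with p(k→k±2) = p₀·exp(−[G(k±2)−G(k)]/2).
   The symmetric exponent split is the minimal form satisfying detailed
   balance; only the forward/reverse *ratio* is constrained by the
   steady-state relation C₋₂/C₀ = k(0,−2)/k(−2,0).
2. **Passage**, unidirectional after N-gate closure (a captured T-segment
   cannot re-exit through the closed N-gate before crossing the DNA-gate).
3. **Release vs. backtrack** at the C-gate, π(ΔG) = min(1, π₀·exp(−α·ΔG/2)).
   A single competition exponent replaces explicit reopening/dissociation
   rate constants because only the competition's outcome, not its
   timescale, is observable in the data this model addresses. A backtrack
   consumes the encounter with net zero Lk change.

Capture × release gives effective move weights ∝ exp(−(1+α)·ΔG/2) in each
direction, so the ATP / intact-C-gate chain is reversible with stationary
distribution ∝ exp(−(1+α)·G/kT) and R_Lk = 1 + α exactly.

Enzyme modes map the biochemical perturbations: AMPPNP and ICRF-193 both
forbid N-gate reopening and are simulator-identical (distinct labels kept
for reporting); the C-gate can be intact, disulfide-locked (passed segments
trapped in the chamber) or deleted (release always succeeds). Time is
discretized into encounter cycles; absolute reaction timescales and ATP
concentration dependence are not modelled.

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| nk | quadratic free-energy coefficient | 1100 | kT·bp |
| h | helical unwinding coefficient | 0.011 | °/(bp·°C) |
| p₀ | baseline capture efficiency per N-gate closure | 0.2997 | — |
| α | release exponent (proofreading strength) | 0.6879 | — |
| π₀ | baseline release probability at ΔG = 0 | 0.5 | — |
| E/DNA | enzyme-to-DNA molar ratio | 0.5 | — |
| — | ensemble size / cycles | 5000 / 300 | — |

p₀ is calibrated so the single-passage conversion probability of ΔLk = −2
into ΔLk = 0 on the 4.3-kb energetics equals the measured 0.50; α from the
measured ratio pair via 1+α = ln(0.17)/ln(0.35). π₀ = 0.5 is a free scale
that cancels from every stationary quantity (it only rescales the clock).
The ΔLk support is the contiguous integer range within ⌈8σ⌉ of the center,
with a hard check that the truncated Gaussian tail mass is below 1e−10.
σ² is held constant across temperature (the measured narrowing ratio is
stable from 10–45 °C); temperature enters only through the Lk⁰ offset.

## Stoichiometry and mode semantics

With ATP, each molecule undergoes an encounter per cycle with probability
min(1, E/DNA). When the N-gate is blocked (AMPPNP/ICRF-193), each molecule
instead carries an integer enzyme budget (⌊E/DNA⌋ plus a Bernoulli remainder)
and **each enzyme closes its N-gate exactly once**: transport happens iff a
T-segment is captured at that closure, and can never backtrack. Expected
post-block transports per molecule are therefore E/DNA × (mean capture
probability) — at most, and exactly proportional to, the enzyme-to-DNA
ratio. An alternative in which an enzyme retries until it captures was
rejected: it turns the post-block dynamics into a fixed-move-count jump
chain whose occupancy overweights high-|ΔLk| states and drives the variance
*beyond* equilibrium, which is both unphysical and contrary to the observed
saturating broadening.

With a locked C-gate and ATP, a trapped T-segment backtracks with a
per-cycle probability (default 1.0 once the N-gate reopens — the data show
near-complete reversal but do not quantify a rate, so this is exposed as a
parameter); the enzyme then stays with its molecule and may recapture.
Within a cycle, trapped molecules resolve backtracking before free enzymes
attempt capture. With a locked C-gate and AMPPNP the first trapped segment
freezes the molecule permanently. Reverse passage in through an open,
deleted C-gate is not modelled.

## Numerical choices

- **Probability overflow.** p₀·exp(−ΔG/2) exceeds 1 for strongly downhill
  transitions in the tails of wide supports. The direct
  `capture_probabilities` call raises an error naming the offending state;
  the population engine instead uses `balanced_move_tables`: both directions
  of an overflowing edge are scaled by the same factor (preserving every
  Boltzmann ratio, hence the exact stationary distribution) and a global
  damping factor keeps each state's total exit probability ≤ 1. The cost is
  a uniformly slower clock, not a different steady state. Naive per-state
  clipping was measurably wrong (it inflated the tails and pushed simulated
  variances past equilibrium) and is not used anywhere.
- **Stationary solver.** `stationary_numeric` builds the per-cycle
  transition matrix (strict probabilities by default, the engine's balanced
  tables with `clip=True`) and solves π = πP per parity class by linear
  algebra. Odd and even ΔLk evolve independently, so the chain over the
  full support is reducible by construction; the odd/even mass split is a
  conserved quantity of the initial condition, not of the chain. By default
  both the closed form and the numeric solver normalize jointly over the
  support (so α = 0 reproduces the equilibrium distribution exactly), and
  an explicit `parity_masses` argument imposes a trajectory-inherited split.
- **Variance conventions.** `fitted_center` (default) takes the second
  central moment about the weighted mean — the variance-minimizing center,
  so it never exceeds the `reference_topoisomer` convention
  Σpᵢ(Lkᵢ−Lk_ref)²/Σpᵢ about an integer reference. The reference convention
  is retained as the densitometry-literal option; since R_Lk is a ratio, a
  consistent convention matters more than the absolute value. Which
  topoisomer anchors a given gel is the user's choice.
- **Distribution center.** Lk^S is read by a parity-aware log-quadratic
  (Gaussian) fit: shared center and curvature, separate odd/even
  amplitudes, mass-weighted least squares; weighted-mean fallback (with a
  warning) when fewer than three states carry weight or the fit is not
  concave.
- **Degenerate inputs.** Empty distributions, zero denominators, supports
  that truncate more than 1e−10 of tail mass, out-of-support references and
  unordered protocol events all raise; an empty parity class in
  `parity_split` is flagged, not raised.

## Synthetic gel layer

Lanes are rendered as sums of Gaussian bands (area ∝ topoisomer fraction,
width `band_sigma`) at positions gain·s/(1+s/saturation) with
s = |ΔLk + chloroquine offset| — mobility depends on writhe magnitude, as
on a chloroquine gel where relaxed topoisomers run as positive writhers
ahead of nicked circles — plus a flat baseline and seeded Gaussian noise.
Quantification subtracts the 10th-percentile baseline and fits a
nonnegative combination of known-position, known-width Gaussians (bounded
least squares, with a free-sign constant absorbing residual baseline),
which apportions overlapping bands; bands with no local maximum above the
noise floor are flagged at zero intensity. Bands at equal |ΔLk + offset|
comigrate exactly as on a real gel; the experiment pipelines therefore use
an offset of max(support)+2 so every topoisomer has a distinct mobility.
The generator emulates band spacing compression, baseline, additive noise
and out-of-model contaminant bands (nicked/linear species); it does *not*
emulate gel smiles, streaking, lane-to-lane distortion, saturation of the
imager, or chloroquine-concentration physics — round-trip fidelity results
bound densitometry error only within this idealized family.

## What the synthetic data can and cannot show

The generator produces exactly the study conditions the model assumes:
Boltzmann-weighted integer topoisomer populations of 4.3-kb and 7.9-kb
plasmids, ideal detailed-balance capture, a single release exponent.
Passing tests therefore demonstrate internal consistency (the simulator
realizes the stated chain, the statistics recover its parameters, the gel
loop is faithful) and that the calibrated model reproduces the measured
benchmark numbers. They cannot rule out alternative mechanisms with the
same stationary law, nor validate the quadratic energy model outside the
near-relaxed regime, nor quantify the reduced thermal deviation of Lk^S
(the apparent shortening of the free DNA length during proofreading),
which is deliberately left unmodelled.

## Problem sizes

Default ensembles are 5000 molecules × 300 cycles (10000 for parameter
recovery), the capture assay uses 10000 molecules per start state, and the
stationary solver handles supports up to ~33 states — sizes chosen so every
analysis reproduces its statistics well within Monte Carlo error while
running in seconds on one CPU.
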