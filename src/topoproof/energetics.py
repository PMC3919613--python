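"""Equilibrium thermodynamics of DNA linking-number topoisomers.

A covalently closed plasmid of N base pairs relaxed by a type-I
topoisomerase reaches a Boltzmann distribution over integer linking-number
deviations ΔLk from the relaxed center Lk⁰, with quadratic free energy

    G(ΔLk)/kT = (nk/N) · (ΔLk − δ)²  =  (ΔLk − δ)² / (2σ²),

where σ² = N/(2·nk) is the equilibrium topoisomer variance ⟨ΔLk²⟩_eq and
δ is the (real-valued) offset of Lk⁰ from its value at the reference
temperature.  Heating unwinds the double helix, so Lk⁰ shifts by
−h·N·ΔT/360 with h the helical unwinding coefficient in degrees of twist
per base pair per °C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PlasmidSpec",
    "EnergeticsModel",
    "LkState",
    "LkDistribution",
    "DEFAULT_NK_COEFFICIENT",
    "DEFAULT_HELICAL_TEMP_COEFF",
    "equilibrium_variance",
    "free_energy",
    "equilibrium_distribution",
    "lk0_temperature_shift",
    "default_support",
    "TruncationError",
]

#: Quadratic supercoiling free-energy coefficient nk (kT·bp), literature
#: consensus for plasmids longer than ~2 kb.
DEFAULT_NK_COEFFICIENT = 1100.0

#: Helical unwinding of B-DNA, degrees of twist per bp per °C.
DEFAULT_HELICAL_TEMP_COEFF = 0.011


class TruncationError(ValueError):
    """Raised when a requested ΔLk support leaves too much tail mass out."""


@dataclass(frozen=True)
class PlasmidSpec:
    """A covalently closed circular plasmid.

    Parameters
    ----------
    name : str
        Label used in reports.
    length_bp : int
        Plasmid size in base pairs; must be ≥ 1000 so the quadratic
        (long-plasmid) free-energy regime applies.
    reference_temperature_C : float
        Temperature at which ΔLk = 0 coincides with the relaxed center Lk⁰.
    """

    name: str
    length_bp: int
    reference_temperature_C: float = 25.0

    def __post_init__(self) -> None:
        if self.length_bp < 1000:
            raise ValueError(
                f"length_bp={self.length_bp}: the quadratic free-energy model "
                "assumes plasmids of at least 1000 bp"
            )


#: The two plasmids used throughout the study conditions.
PBR322 = PlasmidSpec("pBR322", 4300)
YCP50 = PlasmidSpec("YCp50", 7900)


def equilibrium_variance(plasmid: PlasmidSpec, nk_coefficient: float = DEFAULT_NK_COEFFICIENT) -> float:
    """Equilibrium topoisomer variance ⟨ΔLk²⟩_eq = N / (2·nk)."""
    if nk_coefficient <= 0:
        raise ValueError(f"nk_coefficient must be positive, got {nk_coefficient}")
    return plasmid.length_bp / (2.0 * nk_coefficient)


@dataclass(frozen=True)
class EnergeticsModel:
    """Quadratic free-energy model G/kT = ΔLk²/(2·sigma2_eq) for one plasmid."""

    sigma2_eq: float
    nk_coefficient: float = DEFAULT_NK_COEFFICIENT
    helical_temp_coeff: float = DEFAULT_HELICAL_TEMP_COEFF
    reference_temperature_C: float = 25.0

    def __post_init__(self) -> None:
        if self.sigma2_eq <= 0:
            raise ValueError(f"sigma2_eq must be positive, got {self.sigma2_eq}")
        if self.nk_coefficient <= 0:
            raise ValueError(f"nk_coefficient must be positive, got {self.nk_coefficient}")

    @classmethod
    def from_plasmid(
        cls,
        plasmid: PlasmidSpec,
        nk_coefficient: float = DEFAULT_NK_COEFFICIENT,
        helical_temp_coeff: float = DEFAULT_HELICAL_TEMP_COEFF,
    ) -> "EnergeticsModel":
        return cls(
            sigma2_eq=equilibrium_variance(plasmid, nk_coefficient),
            nk_coefficient=nk_coefficient,
            helical_temp_coeff=helical_temp_coeff,
            reference_temperature_C=plasmid.reference_temperature_C,
        )


@dataclass(frozen=True)
class LkState:
    """A single integer topoisomer state ΔLk relative to Lk⁰ at T_ref."""

    delta_lk: int

    @property
    def parity(self) -> str:
        return "even" if self.delta_lk % 2 == 0 else "odd"


def free_energy(delta_lk: float, model: EnergeticsModel, lk0_offset: float = 0.0) -> float:
    """Supercoiling free energy in kT: (ΔLk − δ)² / (2·σ²_eq).

    ``lk0_offset`` is the real-valued displacement of the relaxed center
    Lk⁰ from the reference-temperature center (e.g. a thermal shift).
    Zero at the energy minimum by construction.
    """
    d = delta_lk - lk0_offset
    return d * d / (2.0 * model.sigma2_eq)


class LkDistribution:
    """Normalized probability distribution over contiguous integer ΔLk states.

    The support runs in steps of 1 so that both parity classes are
    representable; type-II dynamics only ever connect states two apart.
    """

    __slots__ = ("support", "fractions")

    def __init__(self, support, fractions, *, normalize: bool = False):
        support = np.asarray(support, dtype=int)
        fractions = np.asarray(fractions, dtype=float)
        if support.shape != fractions.shape or support.ndim != 1:
            raise ValueError("support and fractions must be 1-D arrays of equal length")
        if len(support) == 0:
            raise ValueError("empty distribution")
        if np.any(np.diff(support) != 1):
            raise ValueError("support must be contiguous integers in steps of 1")
        if np.any(fractions < 0) or not np.all(np.isfinite(fractions)):
            raise ValueError("fractions must be finite and nonnegative")
        total = fractions.sum()
        if normalize:
            if total <= 0:
                raise ValueError("cannot normalize: total weight is zero")
            fractions = fractions / total
        elif abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total!r}, not 1 within 1e-9")
        self.support = support
        self.fractions = fractions

    def __len__(self) -> int:
        return len(self.support)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LkDistribution)
            and np.array_equal(self.support, other.support)
            and np.array_equal(self.fractions, other.fractions)
        )

    def fraction(self, delta_lk: int) -> float:
        """Fraction at a given ΔLk; 0 outside the support."""
        idx = delta_lk - int(self.support[0])
        if idx < 0 or idx >= len(self.support):
            return 0.0
        return float(self.fractions[idx])

    def mean(self) -> float:
        return float(np.dot(self.support, self.fractions))

    def variance(self) -> float:
        m = self.mean()
        return float(np.dot((self.support - m) ** 2, self.fractions))

    def shifted(self, offset: int) -> "LkDistribution":
        return LkDistribution(self.support + int(offset), self.fractions)

    # -- serialization: two-column TSV `delta_lk<TAB>fraction` with header --

    def to_tsv(self, path) -> None:
        lines = ["delta_lk\tfraction"]
        lines += [f"{int(k)}\t{f:.17g}" for k, f in zip(self.support, self.fractions)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "LkDistribution":
        text = Path(path).read_text().strip().splitlines()
        header = text[0].split("\t")
        if header[:2] != ["delta_lk", "fraction"]:
            raise ValueError(f"{path}: expected header 'delta_lk\\tfraction'")
        ks, fs = [], []
        for line in text[1:]:
            a, b = line.split("\t")[:2]
            ks.append(int(a))
            fs.append(float(b))
        return cls(ks, fs, normalize=True)


def default_support(model: EnergeticsModel, center: float = 0.0) -> np.ndarray:
    """Contiguous integer states with |ΔLk − center| ≤ ceil(8·σ)."""
    half = math.ceil(8.0 * math.sqrt(model.sigma2_eq))
    c = int(round(center))
    return np.arange(c - half, c + half + 1)


def equilibrium_distribution(
    model: EnergeticsModel,
    support=None,
    lk0_offset: float = 0.0,
    max_tail_mass: float = 1e-10,
) -> LkDistribution:
    """Boltzmann distribution ∝ exp(−G(ΔLk)/kT) over the integer support.

    Raises :class:`TruncationError` when the Gaussian tail mass outside the
    requested support exceeds ``max_tail_mass``.
    """
    if support is None:
        support = default_support(model, center=lk0_offset)
    support = np.asarray(support, dtype=int)
    sigma = math.sqrt(model.sigma2_eq)
    # Gaussian tail mass outside [min-0.5, max+0.5] around the center
    lo = (support[0] - 0.5 - lk0_offset) / sigma
    hi = (support[-1] + 0.5 - lk0_offset) / sigma
    tail = 0.5 * math.erfc(hi / math.sqrt(2)) + 0.5 * math.erfc(-lo / math.sqrt(2))
    if tail > max_tail_mass:
        raise TruncationError(
            f"support [{support[0]}, {support[-1]}] leaves tail mass {tail:.3g} "
            f"> {max_tail_mass:.3g} for sigma={sigma:.3g}, center={lk0_offset:.3g}"
        )
    g = np.array([free_energy(k, model, lk0_offset) for k in support])
    w = np.exp(-(g - g.min()))
    return LkDistribution(support, w, normalize=True)


def lk0_temperature_shift(
    plasmid: PlasmidSpec,
    temperature_C: float,
    model: EnergeticsModel | None = None,
) -> float:
    """Thermal shift of the relaxed center: ΔLk⁰ = −h·N·(T − T_ref)/360.

    Heating unwinds the helix (positive ΔT gives a negative shift).
    """
    coeff = model.helical_temp_coeff if model is not None else DEFAULT_HELICAL_TEMP_COEFF
    t_ref = (
        model.reference_temperature_C if model is not None else plasmid.reference_temperature_C
    )
    return -coeff * plasmid.length_bp * (temperature_C - t_ref) / 360.0
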