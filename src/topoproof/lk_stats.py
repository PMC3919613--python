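"""Topoisomer-distribution statistics: ⟨ΔLk²⟩, R_Lk, Lk^S, ΔLk^S, ratios.

These are the quantities read off gel lane plots: the variance of a
topoisomer distribution, the ratio R_Lk = ⟨ΔLk²⟩_eq / ⟨ΔLk²⟩_test that
quantifies narrowing below equilibrium (R_Lk > 1 means simplification),
the distribution center Lk^S and its offset ΔLk^S = Lk^S − Lk⁰ from the
equilibrium center, and adjacent-topoisomer concentration ratios such as
C₋₂/C₀.

Two variance conventions are supported.  ``fitted_center`` (default) takes
the second central moment about the estimated (weighted-mean) center.
``reference_topoisomer`` is the densitometry-literal convention
Σ pᵢ·(Lkᵢ − Lk_ref)² / Σ pᵢ about an integer reference topoisomer near the
center; it never undershoots the central-moment value, so a consistent
convention matters when forming ratios.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np

from .energetics import LkDistribution

__all__ = [
    "SummaryStats",
    "lk_variance",
    "distribution_center",
    "r_lk",
    "delta_lk_s",
    "adjacent_topoisomer_ratio",
    "parity_split",
    "ParitySplit",
    "summarize",
]


def _states_weights(dist) -> tuple[np.ndarray, np.ndarray]:
    """Extract (states, weights) from an LkDistribution, a BandTable, or arrays."""
    if isinstance(dist, LkDistribution):
        return dist.support.astype(float), dist.fractions.astype(float)
    if hasattr(dist, "delta_lk") and hasattr(dist, "intensity"):
        return np.asarray(dist.delta_lk, dtype=float), np.asarray(dist.intensity, dtype=float)
    states, weights = dist
    return np.asarray(states, dtype=float), np.asarray(weights, dtype=float)


def lk_variance(dist, center_mode: str = "fitted_center", reference: int | None = None) -> float:
    """Topoisomer variance ⟨ΔLk²⟩ = Σ pᵢ (Lkᵢ − c)² / Σ pᵢ.

    ``center_mode="fitted_center"``: c is the estimated center (weighted
    mean), giving the true second central moment.
    ``center_mode="reference_topoisomer"``: c is an explicit integer
    reference near the center of the distribution.
    """
    states, weights = _states_weights(dist)
    total = weights.sum()
    if len(weights) == 0 or total <= 0:
        raise ValueError("distribution has no nonzero weight")
    if center_mode == "fitted_center":
        c = float(np.dot(states, weights) / total)
    elif center_mode == "reference_topoisomer":
        if reference is None:
            raise ValueError("reference_topoisomer mode requires an explicit reference")
        if not (states.min() <= reference <= states.max()):
            raise ValueError(f"reference {reference} lies outside the support")
        c = float(reference)
    else:
        raise ValueError(f"unknown center_mode {center_mode!r}")
    return float(np.dot(weights, (states - c) ** 2) / total)


def distribution_center(dist, min_weight: float = 1e-12) -> float:
    """Center Lk^S of a distribution by a parity-aware Gaussian (log-quadratic) fit.

    Fits log weights to a shared quadratic with separate amplitudes for the
    odd and even parity classes (their masses are independently conserved by
    type-II dynamics, but they share one physical center).  Falls back to
    the weighted mean, with a warning, when fewer than three states carry
    weight or the fit is not concave.
    """
    states, weights = _states_weights(dist)
    total = weights.sum()
    if total <= 0:
        raise ValueError("distribution has no nonzero weight")
    mean = float(np.dot(states, weights) / total)
    informative = weights > min_weight * weights.max()
    if informative.sum() < 3:
        warnings.warn(
            "fewer than 3 informative states; falling back to weighted mean",
            RuntimeWarning,
            stacklevel=2,
        )
        return mean
    k = states[informative]
    w = weights[informative]
    logw = np.log(w)
    even = (np.round(k).astype(int) % 2 == 0).astype(float)
    cols = [even, 1.0 - even, k, k * k]
    design = np.column_stack([c for c in cols])
    sw = np.sqrt(w)  # weight the fit by band mass so tails do not dominate
    coef, *_ = np.linalg.lstsq(design * sw[:, None], logw * sw, rcond=None)
    a, b = coef[3], coef[2]
    if not np.isfinite(a) or a >= 0:
        warnings.warn(
            "log-quadratic fit is not concave; falling back to weighted mean",
            RuntimeWarning,
            stacklevel=2,
        )
        return mean
    return float(-b / (2.0 * a))


def r_lk(
    dist_equilibrium,
    dist_test,
    center_mode: str = "fitted_center",
    reference_equilibrium: int | None = None,
    reference_test: int | None = None,
) -> float:
    """Narrowing ratio R_Lk = ⟨ΔLk²⟩_eq / ⟨ΔLk²⟩_test."""
    v_eq = lk_variance(dist_equilibrium, center_mode, reference_equilibrium)
    v_test = lk_variance(dist_test, center_mode, reference_test)
    if v_test == 0:
        raise ValueError("test distribution has zero variance")
    return v_eq / v_test


def delta_lk_s(dist_test, dist_equilibrium) -> float:
    """ΔLk^S = Lk^S − Lk⁰: fitted center of the test minus the equilibrium center."""
    return distribution_center(dist_test) - distribution_center(dist_equilibrium)


def adjacent_topoisomer_ratio(dist, state_a: int, state_b: int) -> float:
    """Concentration ratio C_a / C_b of two topoisomers (e.g. C₋₂/C₀)."""
    states, weights = _states_weights(dist)
    lookup = {int(s): w for s, w in zip(states, weights)}
    if state_a not in lookup or state_b not in lookup:
        raise ValueError(f"states {state_a}, {state_b} must both be in the support")
    if lookup[state_b] <= 0:
        raise ValueError(f"zero weight at denominator state {state_b}")
    return lookup[state_a] / lookup[state_b]


ParitySplit = namedtuple("ParitySplit", ["odd", "even", "odd_mass", "even_mass"])


def parity_split(dist: LkDistribution) -> ParitySplit:
    """Split into renormalized odd and even sub-distributions.

    Each sub-distribution keeps the full contiguous support with zeros on
    the opposite parity, so ``odd_mass·odd + even_mass·even`` reproduces the
    input exactly.  An empty parity class yields ``None`` for that member.
    """
    out = {}
    masses = {}
    for label in ("odd", "even"):
        sel = (dist.support % 2 != 0) if label == "odd" else (dist.support % 2 == 0)
        mass = float(dist.fractions[sel].sum())
        masses[label] = mass
        if mass <= 0:
            out[label] = None
            continue
        fr = np.where(sel, dist.fractions, 0.0)
        out[label] = LkDistribution(dist.support, fr / mass)
    return ParitySplit(out["odd"], out["even"], masses["odd"], masses["even"])


@dataclass(frozen=True)
class SummaryStats:
    variance: float
    center: float
    r_lk: float | None = None
    delta_lk_s: float | None = None
    ratios: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be nonnegative")
        if self.r_lk is not None and self.r_lk <= 0:
            raise ValueError("r_lk must be positive")

    def to_dict(self) -> dict:
        return {
            "variance": self.variance,
            "center": self.center,
            "r_lk": self.r_lk,
            "delta_lk_s": self.delta_lk_s,
            "ratios": {f"{a}/{b}": v for (a, b), v in self.ratios.items()},
        }


def summarize(dist, dist_equilibrium=None, ratio_pairs=((-2, 0),)) -> SummaryStats:
    """One-stop summary of a topoisomer distribution (vs. equilibrium if given)."""
    ratios = {}
    for a, b in ratio_pairs:
        try:
            ratios[(a, b)] = adjacent_topoisomer_ratio(dist, a, b)
        except ValueError:
            pass
    return SummaryStats(
        variance=lk_variance(dist),
        center=distribution_center(dist),
        r_lk=r_lk(dist_equilibrium, dist) if dist_equilibrium is not None else None,
        delta_lk_s=delta_lk_s(dist, dist_equilibrium) if dist_equilibrium is not None else None,
        ratios=ratios,
    )
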