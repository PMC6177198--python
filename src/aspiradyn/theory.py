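"""Closed-form weak-selection machinery: the sigma rule.

Under weak selection (beta -> 0) on a regular network of degree d-1, the
stationary abundance of strategy A exceeds 1/2 if and only if

    sum_k sigma_k * (a_k - b_{d-1-k}) > 0,

where the structure coefficients sigma_k depend on the population
structure, population size and decision functions but on neither the
payoff entries nor the individual aspiration levels. For identical
decision functions with nonvanishing derivative at zero the coefficients
take the closed form sigma_k = binomial(d-1, k) — the same for rings and
well-mixed populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import comb

from .model_core import AspirationProfile, DecisionFunction, PayoffTable

__all__ = [
    "SigmaVector",
    "sigma_theoretical",
    "criterion_lhs",
    "verdict",
    "critical_entry",
    "weak_selection_bound",
]

#: |criterion| below this is reported as a tie ("neutral"), not a winner
TIE_TOLERANCE = 1e-12


@dataclass(frozen=True)
class SigmaVector:
    """Structure coefficients sigma_0..sigma_{d-1} of the linear criterion."""

    sigma: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma, dtype=float)
        if s.ndim != 1 or len(s) < 2:
            raise ValueError("sigma must be a vector of length d >= 2")
        if np.any(s < 0) or not np.any(s > 0):
            raise ValueError("sigma coefficients must be non-negative with at least one positive")
        object.__setattr__(self, "sigma", s)

    @property
    def d(self) -> int:
        return len(self.sigma)


def sigma_theoretical(d: int) -> SigmaVector:
    """The closed-form coefficients sigma_k = binomial(d-1, k)."""
    if d < 2:
        raise ValueError(f"group size d must be >= 2, got {d}")
    return SigmaVector(sigma=comb(d - 1, np.arange(d)))


def criterion_lhs(table: PayoffTable, sigma: SigmaVector | None = None) -> float:
    """Evaluate sum_k sigma_k (a_k - b_{d-1-k}).

    Positive means strategy A is more abundant than B in the stationary
    regime under weak selection; negative favors B.
    """
    if sigma is None:
        sigma = sigma_theoretical(table.d)
    if sigma.d != table.d:
        raise ValueError(f"sigma has d={sigma.d} but payoff table has d={table.d}")
    return float(np.dot(sigma.sigma, table.a - table.b[::-1]))


def verdict(table: PayoffTable, sigma: SigmaVector | None = None) -> str:
    """"A", "B" or "neutral" according to the sign of the criterion."""
    lhs = criterion_lhs(table, sigma)
    if abs(lhs) <= TIE_TOLERANCE:
        return "neutral"
    return "A" if lhs > 0 else "B"


def critical_entry(
    table: PayoffTable, which: str, sigma: SigmaVector | None = None
) -> float:
    """Value of one payoff entry at which the criterion crosses zero.

    ``which`` names an entry like "a0" or "b2". All other entries are held
    fixed; the criterion is linear in each entry, so the threshold is
    exact. Raises if the entry's sigma coefficient is zero (the criterion
    does not depend on it).
    """
    if sigma is None:
        sigma = sigma_theoretical(table.d)
    row, idx = which[0], int(which[1:])
    if row not in "ab" or not 0 <= idx < table.d:
        raise ValueError(f"invalid entry id {which!r}")
    # coefficient of the chosen entry in the criterion
    coef = sigma.sigma[idx] if row == "a" else -sigma.sigma[table.d - 1 - idx]
    if coef == 0.0:
        raise ValueError(f"sigma coefficient of {which} is zero; no finite threshold")
    current = table.a[idx] if row == "a" else table.b[idx]
    lhs = criterion_lhs(table, sigma)
    return float(current - lhs / coef)


def weak_selection_bound(
    g: DecisionFunction, profile: AspirationProfile, table: PayoffTable
) -> float:
    """Scale below which the selection intensity is safely "weak".

    Returns g'(0) / (|g''(0)| * (max|e_i| + max{|a_k|, |b_k|})), the scale
    that beta must fall well below for the first-order (sigma-rule)
    analysis to govern the dynamics. When g''(0) = 0 (e.g. the Fermi
    function) the second-order term vanishes identically and the bound is
    +infinity. This is a scale, not a hard threshold.
    """
    if g.derivative_at_zero <= 0:
        raise ValueError("decision function must have positive derivative at zero")
    if profile.n == 0:
        raise ValueError("empty aspiration profile")
    if g.second_derivative_at_zero == 0.0:
        return float("inf")
    scale = float(np.max(np.abs(profile.e))) + float(
        max(np.max(np.abs(table.a)), np.max(np.abs(table.b)))
    )
    return g.derivative_at_zero / (abs(g.second_derivative_at_zero) * scale)
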