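"""Domain types for two-strategy d-player games under aspiration-based updating.

The model: each of N individuals holds one of two strategies, A or B. A
focal individual playing a d-player game receives payoff ``a_k`` (if it
plays A) or ``b_k`` (if it plays B) when exactly ``k`` of its d-1 coplayers
play A. After collecting payoff ``pi``, the individual switches strategy
with probability ``g(beta * (e - pi))`` where ``e`` is its personal
aspiration, ``beta >= 0`` the selection intensity, and ``g`` a decision
function that is differentiable, strictly increasing and bounded in (0, 1).

This module houses the payoff table, the decision function with its
axioms, per-individual aspiration profiles (and samplers for the standard
aspiration distributions), and the binary population state.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PayoffTable",
    "DecisionFunction",
    "AspirationProfile",
    "random_state",
    "validate_state",
    "fermi_function",
    "switch_probability",
    "sample_aspirations",
    "load_aspirations",
    "save_aspirations",
]


@dataclass(frozen=True)
class PayoffTable:
    """Payoff matrix of a two-strategy d-player game.

    ``a[k]`` is the payoff to an A-player and ``b[k]`` the payoff to a
    B-player when k of the d-1 coplayers use strategy A, k = 0..d-1.
    Payoffs are in arbitrary (dimensionless) payoff units.
    """

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.ndim != 1 or b.ndim != 1 or len(a) != len(b):
            raise ValueError("a and b must be 1-d vectors of equal length d")
        if len(a) < 2:
            raise ValueError("group size d must be at least 2")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("payoff entries must be finite")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def d(self) -> int:
        """Group size: the focal player plus d-1 coplayers."""
        return len(self.a)

    def payoff(self, strategy: int, k: int) -> float:
        """Payoff of a focal player (1 = A, 0 = B) facing k A-coplayers."""
        return float(self.a[k]) if strategy == 1 else float(self.b[k])

    def swapped(self) -> "PayoffTable":
        """Relabel strategies: A becomes B.

        An A-player with k A-coplayers becomes a B-player with d-1-k
        "A"-coplayers, so the rows swap and reverse.
        """
        return PayoffTable(a=self.b[::-1].copy(), b=self.a[::-1].copy())

    @classmethod
    def constant(cls, d: int, h: float) -> "PayoffTable":
        """All entries equal h: the neutral-mutant game."""
        return cls(a=np.full(d, float(h)), b=np.full(d, float(h)))


@dataclass(frozen=True)
class DecisionFunction:
    """A switching-probability function g with the model's axioms.

    Axioms: g is differentiable on the real line with g' > 0 (strictly
    increasing) and 0 < g(x) < 1 everywhere, so every individual retains a
    nonzero probability of changing strategy in every state and the
    dynamics have no absorbing state.
    """

    evaluate: Callable[[np.ndarray], np.ndarray]
    derivative_at_zero: float
    second_derivative_at_zero: float
    name: str = "custom"

    def __call__(self, x):
        return self.evaluate(x)

    def check_axioms(self, grid: np.ndarray | None = None, *, strict: bool = True) -> bool:
        """Check bounds, monotonicity and g(0) > 0 on a finite grid."""
        if grid is None:
            # +/-30 keeps the logistic representable strictly inside (0, 1)
            grid = np.linspace(-30.0, 30.0, 501)
        vals = np.asarray(self.evaluate(grid), dtype=float)
        ok = (
            bool(np.all((vals > 0.0) & (vals < 1.0)))
            and bool(np.all(np.diff(vals) > -1e-15))
            and float(self.evaluate(np.array(0.0))) > 0.0
            and self.derivative_at_zero > 0.0
        )
        if strict and not ok:
            raise ValueError(f"decision function {self.name!r} violates the axioms")
        return ok


def fermi_function() -> DecisionFunction:
    """The Fermi (logistic) decision function g(x) = 1 / (1 + exp(-x)).

    g'(0) = 1/4 and g''(0) = 0; the vanishing curvature at the origin makes
    the weak-selection expansion particularly well behaved.
    """
    from scipy.special import expit

    return DecisionFunction(
        evaluate=expit,
        derivative_at_zero=0.25,
        second_derivative_at_zero=0.0,
        name="fermi",
    )


def switch_probability(
    g: DecisionFunction, beta: float, aspiration: float, payoff: float
) -> float:
    """Probability g(beta * (aspiration - payoff)) that the focal switches.

    With beta = 0 this is g(0) regardless of aspiration and payoff: pure
    neutral drift.
    """
    if beta < 0:
        raise ValueError(f"selection intensity beta must be >= 0, got {beta}")
    return float(g.evaluate(np.asarray(beta * (aspiration - payoff))))


@dataclass(frozen=True)
class AspirationProfile:
    """Per-individual aspiration levels e_i (payoff units).

    ``source`` records the generating distribution (or "file" for loaded
    profiles). Aspirations may be negative or exceed every payoff entry;
    no clipping is applied.
    """

    e: np.ndarray
    source: str = "unspecified"

    def __post_init__(self) -> None:
        e = np.asarray(self.e, dtype=float)
        if e.ndim != 1 or len(e) == 0:
            raise ValueError("aspiration vector must be a non-empty 1-d array")
        if not np.all(np.isfinite(e)):
            raise ValueError("aspirations must be finite")
        object.__setattr__(self, "e", e)

    def __len__(self) -> int:
        return len(self.e)

    @property
    def n(self) -> int:
        return len(self.e)


# --- population state -------------------------------------------------------

def random_state(n: int, fraction_a: float, rng: np.random.Generator) -> np.ndarray:
    """Initial strategy vector: each individual independently A (=1) with
    probability ``fraction_a``, else B (=0)."""
    if not 0.0 <= fraction_a <= 1.0:
        raise ValueError("fraction_a must lie in [0, 1]")
    return (rng.random(n) < fraction_a).astype(np.int8)


def validate_state(state: np.ndarray, n: int) -> np.ndarray:
    state = np.asarray(state)
    if state.shape != (n,) or not np.isin(state, (0, 1)).all():
        raise ValueError("state must be a length-N vector of 0/1 indicators")
    return state.astype(np.int8)


# --- aspiration samplers -----------------------------------------------------

_SPEC_RE = re.compile(r"^\s*([a-z_]+)\s*(?:\(\s*([^)]*)\s*\))?\s*$")

#: mixture weights and component parameters of the bimodal aspiration
#: distribution 0.4 N(2.5, 0.5^2) + 0.6 N(4.5, 0.5^2)
BIMODAL_WEIGHTS = (0.4, 0.6)
BIMODAL_MEANS = (2.5, 4.5)
BIMODAL_SD = 0.5


def parse_distribution(spec: str) -> tuple[str, tuple[float, ...]]:
    """Parse a distribution spec string such as ``"uniform(0,5)"``.

    Recognised families: ``homogeneous(c)``, ``uniform(lo,hi)``,
    ``bimodal``, ``powerlaw``.
    """
    m = _SPEC_RE.match(spec)
    if m is None:
        raise ValueError(f"cannot parse distribution spec {spec!r}")
    name = m.group(1)
    args = tuple(float(x) for x in m.group(2).split(",")) if m.group(2) else ()
    if name not in {"homogeneous", "uniform", "bimodal", "powerlaw"}:
        raise ValueError(f"unknown aspiration distribution {name!r}")
    if name == "homogeneous" and len(args) != 1:
        raise ValueError("homogeneous requires one parameter, e.g. homogeneous(2)")
    if name == "uniform":
        if len(args) != 2:
            raise ValueError("uniform requires two parameters, e.g. uniform(0,5)")
        if args[0] >= args[1]:
            raise ValueError(f"uniform lower bound must be < upper bound, got {args}")
    if name in {"bimodal", "powerlaw"} and args:
        raise ValueError(f"{name} takes no parameters")
    return name, args


def sample_aspirations(
    dist_spec: str, n: int, rng_seed: int | np.random.Generator | None = None
) -> AspirationProfile:
    """Draw n i.i.d. aspirations from a named distribution.

    Families (with the conventions used throughout):

    - ``homogeneous(c)``  — every individual aspires to the constant c;
    - ``uniform(lo,hi)``  — continuous uniform on [lo, hi];
    - ``bimodal``         — mixture 0.4 N(2.5, 0.5^2) + 0.6 N(4.5, 0.5^2),
      components not truncated;
    - ``powerlaw``        — density f(x) = 2 x^-3 on x >= 1, sampled by
      inverse CDF x = (1 - u)^(-1/2) (CDF F(x) = 1 - x^-2), so the minimum
      possible draw is 1.0 and the median is sqrt(2).
    """
    name, args = parse_distribution(dist_spec)
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator
    ) else rng_seed
    if name == "homogeneous":
        e = np.full(n, args[0])
    elif name == "uniform":
        e = rng.uniform(args[0], args[1], size=n)
    elif name == "bimodal":
        comp = rng.random(n) < BIMODAL_WEIGHTS[1]  # True -> second component
        means = np.where(comp, BIMODAL_MEANS[1], BIMODAL_MEANS[0])
        e = rng.normal(means, BIMODAL_SD)
    else:  # powerlaw
        u = rng.random(n)
        e = (1.0 - u) ** -0.5
    return AspirationProfile(e=e, source=dist_spec)


def powerlaw_cdf(x):
    """CDF F(x) = 1 - x^-2 of the aspiration power law f(x) = 2 x^-3, x >= 1."""
    x = np.asarray(x, dtype=float)
    return np.where(x < 1.0, 0.0, 1.0 - x ** -2.0)


# --- aspiration file I/O -----------------------------------------------------
# CSV layout: header "individual_index,aspiration" with 1-based contiguous
# indices, one row per individual.

def load_aspirations(path) -> AspirationProfile:
    """Load a per-individual aspiration table from CSV."""
    df = pd.read_csv(path)
    expected = ["individual_index", "aspiration"]
    if list(df.columns) != expected:
        raise ValueError(f"aspiration CSV must have columns {expected}, got {list(df.columns)}")
    idx = pd.to_numeric(df["individual_index"], errors="raise").astype(int)
    vals = pd.to_numeric(df["aspiration"], errors="raise").astype(float)
    n = len(idx)
    if idx.duplicated().any():
        dupes = sorted(idx[idx.duplicated()].unique().tolist())
        raise ValueError(f"duplicate individual_index values: {dupes}")
    if sorted(idx.tolist()) != list(range(1, n + 1)):
        raise ValueError("individual_index must be a permutation of 1..N")
    e = np.empty(n, dtype=float)
    e[idx.to_numpy() - 1] = vals.to_numpy()
    return AspirationProfile(e=e, source="file")


def save_aspirations(profile: AspirationProfile, path) -> None:
    """Write a profile in the same CSV layout that :func:`load_aspirations` reads."""
    df = pd.DataFrame(
        {
            "individual_index": np.arange(1, profile.n + 1),
            "aspiration": profile.e,
        }
    )
    df.to_csv(path, index=False)
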