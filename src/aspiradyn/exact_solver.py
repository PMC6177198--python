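"""Exact small-population solver: the verification engine.

For populations small enough to enumerate (N <= 14, i.e. at most 16384
states) the aspiration dynamics are a finite ergodic Markov chain whose
2^N x 2^N transition matrix can be written down explicitly and whose
stationary distribution kappa can be solved exactly. This module builds
that chain, computes the exact stationary abundance of strategy A, and
differentiates the abundance with respect to the selection intensity by
central finite differences — the machinery used to check the neutrality
results, the aspiration-independence of the weak-selection criterion, and
the closed-form structure coefficients.

Supported exactly: regular networks with degree d-1 (group composition is
deterministic given the state) and well-mixed populations (the coplayer
draw is marginalised inside the flip probability with hypergeometric
weights). Non-regular networks are only handled by Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.stats import hypergeom

from .model_core import AspirationProfile, DecisionFunction, PayoffTable
from .structures import PopulationStructure

__all__ = [
    "ExactChain",
    "build_chain",
    "exact_abundance",
    "abundance_derivative",
    "derive_sigma_numeric",
]

#: hard cap on the enumerable population size (2^14 = 16384 states)
MAX_EXACT_N = 14

#: default step for central finite differences in beta
DEFAULT_H_BETA = 1e-4


@dataclass
class ExactChain:
    """The fully enumerated chain: transition matrix and stationary law."""

    n: int
    transition_matrix: sp.csr_matrix
    stationary: np.ndarray

    def residual(self) -> float:
        """Stationarity residual ||kappa^T P - kappa^T||_inf."""
        k = self.stationary
        return float(np.max(np.abs(k @ self.transition_matrix - k)))


def _as_g_list(g_list, n: int) -> list[DecisionFunction]:
    if isinstance(g_list, DecisionFunction):
        return [g_list] * n
    g_list = list(g_list)
    if len(g_list) != n:
        raise ValueError(f"need one decision function per individual ({n}), got {len(g_list)}")
    return g_list


def _state_matrix(n: int) -> np.ndarray:
    """All 2^n strategy vectors; row m is the bit pattern of integer m."""
    idx = np.arange(2**n, dtype=np.int64)
    return ((idx[:, None] >> np.arange(n)) & 1).astype(np.int64)


def _flip_probabilities(
    structure: PopulationStructure,
    table: PayoffTable,
    profile: AspirationProfile,
    g_list,
    beta: float,
    payoff_scheme: str,
) -> np.ndarray:
    """Matrix p[state, i]: probability individual i switches given it is focal."""
    n = structure.n
    d = table.d
    gs = _as_g_list(g_list, n)
    e = profile.e
    if len(e) != n:
        raise ValueError(f"aspiration profile has length {len(e)}, population has {n}")
    states = _state_matrix(n)
    m_states = states.shape[0]
    p = np.empty((m_states, n), dtype=float)

    if structure.mode == "well_mixed":
        if payoff_scheme != "single_game":
            raise ValueError("well-mixed exact mode only supports the single-game scheme")
        if n < d:
            raise ValueError("population too small for the game")
        # Expected flip probability over the hypergeometric coplayer draw:
        # k A-coplayers among d-1 drawn from the N-1 others, of which m use A.
        ks = np.arange(d)
        pmf = np.array(
            [hypergeom.pmf(ks, n - 1, m, d - 1) for m in range(n)]
        )  # (n, d); rows are m = #A among the others
        n_a = states.sum(axis=1)
        for i in range(n):
            g = gs[i]
            ga = np.asarray(g.evaluate(beta * (e[i] - table.a)), dtype=float)
            gb = np.asarray(g.evaluate(beta * (e[i] - table.b)), dtype=float)
            m_i = n_a - states[:, i]  # #A among the others
            p[:, i] = np.where(states[:, i] == 1, pmf[m_i] @ ga, pmf[m_i] @ gb)
        return p

    # network mode: require a regular graph of degree exactly d-1 so the
    # game group is the full neighborhood and the payoff is deterministic
    degs = np.array([structure.degree(i) for i in range(n)])
    if not np.all(degs == d - 1):
        raise ValueError(
            "exact network mode needs a regular structure of degree d-1 "
            f"(d={d}); got degrees {sorted(set(degs.tolist()))}"
        )
    adj = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        adj[i, structure.neighbors(i)] = 1
    k_counts = states @ adj  # k_counts[s, i] = #A among i's neighbors

    if payoff_scheme == "single_game":
        for i in range(n):
            k = k_counts[:, i]
            pi = np.where(states[:, i] == 1, table.a[k], table.b[k])
            p[:, i] = np.asarray(gs[i].evaluate(beta * (e[i] - pi)), dtype=float)
    elif payoff_scheme == "averaged_d_games":
        # focal takes part in d games: its own plus one organised by each
        # neighbor; in the game organised by o the focal's coplayers are
        # o's closed neighborhood minus the focal itself
        t = k_counts + states  # t[s, o] = #A in o's closed neighborhood
        for i in range(n):
            organizers = np.concatenate(([i], structure.neighbors(i)))
            k_per_game = t[:, organizers] - states[:, [i]]
            pi = np.where(
                states[:, [i]] == 1, table.a[k_per_game], table.b[k_per_game]
            ).mean(axis=1)
            p[:, i] = np.asarray(gs[i].evaluate(beta * (e[i] - pi)), dtype=float)
    else:
        raise ValueError(f"unknown payoff scheme {payoff_scheme!r}")
    return p


def build_transition_matrix(flip_p: np.ndarray) -> sp.csr_matrix:
    """Assemble the sparse row-stochastic transition matrix from flip
    probabilities (one uniformly chosen focal per step)."""
    m_states, n = flip_p.shape
    rows = np.tile(np.arange(m_states, dtype=np.int64), n)
    cols = np.concatenate(
        [np.arange(m_states, dtype=np.int64) ^ (1 << i) for i in range(n)]
    )
    data = (flip_p / n).ravel(order="F")
    diag = 1.0 - flip_p.sum(axis=1) / n
    rows = np.concatenate([rows, np.arange(m_states, dtype=np.int64)])
    cols = np.concatenate([cols, np.arange(m_states, dtype=np.int64)])
    data = np.concatenate([data, diag])
    return sp.csr_matrix((data, (rows, cols)), shape=(m_states, m_states))


def solve_stationary(p_mat: sp.csr_matrix) -> np.ndarray:
    """Solve kappa^T P = kappa^T, kappa >= 0, sum kappa = 1 by a sparse
    linear solve of (P^T - I) with one equation replaced by normalisation."""
    m = p_mat.shape[0]
    a = (p_mat.T - sp.identity(m, format="csr")).tolil()
    a[m - 1, :] = 1.0
    rhs = np.zeros(m)
    rhs[m - 1] = 1.0
    kappa = spla.spsolve(a.tocsc(), rhs)
    kappa = np.maximum(kappa, 0.0)
    return kappa / kappa.sum()


def solve_stationary_eig(p_mat: sp.csr_matrix) -> np.ndarray:
    """Independent route: dominant left eigenvector via dense eigendecomposition
    (cross-check only; dense, so keep the state space small)."""
    w, v = np.linalg.eig(p_mat.T.toarray())
    idx = int(np.argmin(np.abs(w - 1.0)))
    kappa = np.real(v[:, idx])
    kappa = np.abs(kappa)
    return kappa / kappa.sum()


def build_chain(
    structure: PopulationStructure,
    table: PayoffTable,
    profile: AspirationProfile,
    g_list,
    beta: float,
    payoff_scheme: str = "single_game",
) -> ExactChain:
    """Enumerate the 2^N-state chain and solve its stationary distribution."""
    n = structure.n
    if n > MAX_EXACT_N:
        raise ValueError(f"N={n} exceeds the exact-enumeration cap of {MAX_EXACT_N}")
    flip_p = _flip_probabilities(structure, table, profile, g_list, beta, payoff_scheme)
    p_mat = build_transition_matrix(flip_p)
    return ExactChain(n=n, transition_matrix=p_mat, stationary=solve_stationary(p_mat))


def exact_abundance(chain: ExactChain) -> float:
    """Expected stationary fraction of strategy A: sum_s kappa_s (sum_i s_i)/N."""
    counts = _state_matrix(chain.n).sum(axis=1)
    return float(chain.stationary @ counts) / chain.n


def abundance_derivative(
    structure: PopulationStructure,
    table: PayoffTable,
    profile: AspirationProfile,
    g_list,
    payoff_scheme: str = "single_game",
    h_beta: float = DEFAULT_H_BETA,
) -> float:
    """d(abundance of A)/d(beta) at beta = 0, by central differences.

    The sign of this derivative decides which strategy is more abundant
    under weak selection; its value is what the sigma rule linearises.
    """
    x_plus = exact_abundance(
        build_chain(structure, table, profile, g_list, h_beta, payoff_scheme)
    )
    x_minus = exact_abundance(
        build_chain(structure, table, profile, g_list, -h_beta, payoff_scheme)
    )
    deriv = (x_plus - x_minus) / (2.0 * h_beta)
    if not np.isfinite(deriv):
        raise ArithmeticError("non-finite abundance derivative")
    return float(deriv)


def derive_sigma_numeric(
    structure: PopulationStructure,
    g_list,
    payoff_scheme: str = "single_game",
    d: int = 3,
    profile: AspirationProfile | None = None,
    h_beta: float = DEFAULT_H_BETA,
) -> np.ndarray:
    """Recover the structure coefficients numerically, one basis game at a time.

    Because the weak-selection criterion is linear in the payoff entries
    with payoff-independent coefficients, sigma_k is proportional to the
    abundance derivative of the basis game with a_k = 1 and every other
    entry zero. The d derivatives are rescaled so the k = 0 entry equals
    binomial(d-1, 0) = 1 (the coefficients are only defined up to a
    positive factor).
    """
    if profile is None:
        profile = AspirationProfile(e=np.zeros(structure.n), source="homogeneous(0)")
    derivs = np.empty(d)
    for k in range(d):
        a = np.zeros(d)
        a[k] = 1.0
        tbl = PayoffTable(a=a, b=np.zeros(d))
        derivs[k] = abundance_derivative(
            structure, tbl, profile, g_list, payoff_scheme, h_beta
        )
    if abs(derivs[0]) < 1e-12:
        raise ArithmeticError("basis derivative for k=0 vanishes; cannot normalise")
    return derivs / derivs[0]
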