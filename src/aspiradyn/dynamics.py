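"""The aspiration-dynamics Markov chain: elementary updates and Monte Carlo.

One elementary time step (a "generation"): a focal individual is chosen
uniformly at random, collects a payoff pi from one d-player game (or the
average over d games, see below), and switches to the opposite strategy
with probability g_i(beta * (e_i - pi)). The chain has no absorbing state
and is ergodic, so the long-run average fraction of A-players estimates
the stationary abundance of strategy A.

Payoff schemes:

- ``single_game``: the focal plays one game with d-1 coplayers drawn from
  its neighborhood (or from the whole population when well-mixed, with
  fresh one-shot coplayers at every evaluation).
- ``averaged_d_games``: on a regular network of degree d-1, the focal
  participates in d games — one organised by itself and one by each
  neighbor, each game comprising the organiser's closed neighborhood —
  and its payoff is the average over those d games. This makes the payoff
  depend on the second-nearest neighborhood as well.

Runs with the Fermi decision function for everyone are dispatched to
numba-compiled kernels; heterogeneous or custom decision functions use
the pure-Python reference loop (same semantics, much slower).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model_core import (
    AspirationProfile,
    DecisionFunction,
    PayoffTable,
    random_state,
)
from .structures import PopulationStructure, sample_coplayers

__all__ = [
    "SimulationConfig",
    "StationaryResult",
    "focal_payoff_single",
    "focal_payoff_averaged",
    "step",
    "run_chain",
]

#: number of batches used for the batch-means standard error
N_BATCHES = 50


@dataclass(frozen=True)
class SimulationConfig:
    """Run configuration for a single Monte-Carlo chain."""

    beta: float
    n_steps: int
    burn_in: int = 0
    init_fraction_a: float = 0.5
    payoff_scheme: str = "single_game"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("selection intensity beta must be >= 0")
        if not 0 <= self.burn_in < self.n_steps:
            raise ValueError("need 0 <= burn_in < n_steps")
        if not 0.0 <= self.init_fraction_a <= 1.0:
            raise ValueError("init_fraction_a must lie in [0, 1]")
        if self.payoff_scheme not in {"single_game", "averaged_d_games"}:
            raise ValueError(f"unknown payoff scheme {self.payoff_scheme!r}")


@dataclass(frozen=True)
class StationaryResult:
    """Estimated stationary abundance of strategy A with its uncertainty."""

    mean_abundance_a: float
    std_error: float
    n_samples: int
    batch_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_abundance_a <= 1.0:
            raise ValueError("abundance must lie in [0, 1]")
        if self.std_error < 0:
            raise ValueError("standard error must be non-negative")


def focal_payoff_single(
    structure: PopulationStructure,
    state: np.ndarray,
    table: PayoffTable,
    focal: int,
    rng: np.random.Generator,
) -> float:
    """Payoff from one d-player game: a_k or b_k with k the number of
    sampled coplayers using strategy A."""
    coplayers = sample_coplayers(structure, focal, table.d, rng)
    k = int(state[coplayers].sum())
    return table.payoff(int(state[focal]), k)


def focal_payoff_averaged(
    structure: PopulationStructure,
    state: np.ndarray,
    table: PayoffTable,
    focal: int,
) -> float:
    """Mean payoff over the d games organised by the focal and by each of
    its neighbors (regular structures of degree d-1 only — on other
    graphs the organisers' game sizes would differ)."""
    d = table.d
    if structure.mode != "network":
        raise ValueError("averaged payoff scheme requires a network structure")
    nbrs = structure.neighbors(focal)
    if len(nbrs) != d - 1 or not structure.is_regular:
        raise ValueError(
            "averaged payoff scheme is defined only on regular structures of degree d-1"
        )
    s_focal = int(state[focal])
    total = 0.0
    for organizer in (focal, *nbrs):
        group = structure.neighbors(organizer)
        k = int(state[group].sum()) + int(state[organizer]) - s_focal
        total += table.payoff(s_focal, k)
    return total / d


def step(
    structure: PopulationStructure,
    state: np.ndarray,
    table: PayoffTable,
    profile: AspirationProfile,
    g_list,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One elementary update, in place; returns the (mutated) state."""
    gs = _as_g_list(g_list, structure.n)
    focal = int(rng.integers(structure.n))
    if config.payoff_scheme == "single_game":
        pi = focal_payoff_single(structure, state, table, focal, rng)
    else:
        pi = focal_payoff_averaged(structure, state, table, focal)
    p = float(gs[focal].evaluate(np.asarray(config.beta * (profile.e[focal] - pi))))
    if rng.random() < p:
        state[focal] = 1 - state[focal]
    return state


def _as_g_list(g_list, n: int) -> list[DecisionFunction]:
    if isinstance(g_list, DecisionFunction):
        return [g_list] * n
    g_list = list(g_list)
    if len(g_list) != n:
        raise ValueError(f"need one decision function per individual ({n}), got {len(g_list)}")
    return g_list


def _all_fermi(g_list, n: int) -> bool:
    gs = _as_g_list(g_list, n)
    return all(g.name == "fermi" for g in gs)


def _result_from_batches(batch_means: np.ndarray, n_samples: int) -> StationaryResult:
    mean = float(batch_means.mean())
    n_b = len(batch_means)
    se = float(batch_means.std(ddof=1) / np.sqrt(n_b)) if n_b > 1 else 0.0
    return StationaryResult(
        mean_abundance_a=mean,
        std_error=se,
        n_samples=n_samples,
        batch_means=batch_means,
    )


def run_chain(
    structure: PopulationStructure,
    table: PayoffTable,
    profile: AspirationProfile,
    g_list,
    config: SimulationConfig,
    initial_state: np.ndarray | None = None,
) -> StationaryResult:
    """Run the chain and estimate the stationary abundance of strategy A.

    The chain starts from an independent Bernoulli(init_fraction_a) state
    (unless ``initial_state`` is given), iterates n_steps elementary
    updates and averages the A-fraction over the post-burn-in steps. The
    standard error comes from batch means over 50 contiguous batches,
    which absorbs the serial correlation of the single run.
    """
    n = structure.n
    if profile.n != n:
        raise ValueError("aspiration profile length must equal the population size")
    if config.payoff_scheme == "averaged_d_games":
        if structure.mode != "network" or not structure.is_regular:
            raise ValueError("averaged payoff scheme requires a regular network")
        if structure.min_degree() != table.d - 1:
            raise ValueError("averaged payoff scheme requires degree exactly d-1")
    elif structure.mode == "network" and structure.min_degree() < table.d - 1:
        raise ValueError("every node needs degree >= d-1 to play the game")

    rng = np.random.default_rng(config.rng_seed)
    if initial_state is None:
        state = random_state(n, config.init_fraction_a, rng)
    else:
        state = np.asarray(initial_state, dtype=np.int8).copy()
        if state.shape != (n,):
            raise ValueError("initial_state must have length N")

    n_post = config.n_steps - config.burn_in
    n_batches = min(N_BATCHES, n_post)
    n_samples = (n_post // n_batches) * n_batches

    if _all_fermi(g_list, n):
        from . import _kernels

        kernel_seed = int(rng.integers(0, 2**31 - 1))
        a = np.ascontiguousarray(table.a, dtype=np.float64)
        b = np.ascontiguousarray(table.b, dtype=np.float64)
        e = np.ascontiguousarray(profile.e, dtype=np.float64)
        st = state.astype(np.int64)
        if structure.mode == "well_mixed":
            batches = _kernels.run_well_mixed_single(
                a, b, e, config.beta, st, config.n_steps, config.burn_in, n_batches, kernel_seed
            )
        else:
            indptr, indices = structure.csr()
            if config.payoff_scheme == "averaged_d_games":
                batches = _kernels.run_network_averaged(
                    indptr, indices, a, b, e, config.beta, st,
                    config.n_steps, config.burn_in, n_batches, kernel_seed,
                )
            else:
                batches = _kernels.run_network_single(
                    indptr, indices, a, b, e, config.beta, st,
                    config.n_steps, config.burn_in, n_batches, kernel_seed,
                )
        return _result_from_batches(np.asarray(batches), n_samples)

    # reference loop for arbitrary decision functions
    gs = _as_g_list(g_list, n)
    batch_size = n_post // n_batches
    batches = np.zeros(n_batches)
    n_a = int(state.sum())
    t_post = 0
    for t in range(config.n_steps):
        focal = int(rng.integers(n))
        if config.payoff_scheme == "single_game":
            pi = focal_payoff_single(structure, state, table, focal, rng)
        else:
            pi = focal_payoff_averaged(structure, state, table, focal)
        p = float(gs[focal].evaluate(np.asarray(config.beta * (profile.e[focal] - pi))))
        if rng.random() < p:
            n_a += 1 - 2 * state[focal]
            state[focal] = 1 - state[focal]
        if t >= config.burn_in and t_post < n_samples:
            batches[t_post // batch_size] += n_a
            t_post += 1
    return _result_from_batches(batches / (batch_size * n), n_samples)
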