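"""Estimating the structure coefficients sigma_k by regression.

Protocol: fix all b entries to zero, simulate the stationary abundance
x(a) of strategy A for a design of a-vectors under weak selection, and
regress the deviation y = x - 1/2 on (a_0, ..., a_{d-1}) with an
intercept by ordinary least squares. To first order in beta the response
is proportional to sum_k sigma_k a_k, so the fitted coefficients recover
sigma up to a common positive factor and the intercept is zero. The fit
is reported both raw and ratio-normalised (divided by the coefficient on
a_0, fixing sigma_0 = 1) — the coefficients are only identified up to a
positive rescaling, and the normalised pattern for d = 3 on rings and
well-mixed populations is (1, 2, 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .model_core import AspirationProfile, PayoffTable
from .dynamics import SimulationConfig, run_chain
from .structures import PopulationStructure

__all__ = ["SigmaFit", "build_design", "fit_sigma"]


@dataclass(frozen=True)
class SigmaFit:
    """OLS estimate of the structure coefficients from simulated abundances."""

    coefficients: np.ndarray  # raw fitted coefficients on a_0..a_{d-1}
    intercept: float
    margins_of_error: np.ndarray  # 95% CI half-widths: d coefficients then intercept
    normalized: np.ndarray  # coefficients / coefficients[0]
    normalized_margins: np.ndarray  # delta-method 95% half-widths of the ratios
    design: list[np.ndarray]
    abundances: np.ndarray
    std_errors: np.ndarray
    normalization: str = "ratio (sigma_0 = 1)"

    @property
    def d(self) -> int:
        return len(self.coefficients)


def build_design(
    d: int, grid: tuple[float, ...] = (-1.0, 0.0, 1.0), rng_seed: int | None = None
) -> list[np.ndarray]:
    """Full-factorial payoff design over the a-entries (b held at zero).

    The default grid {-1, 0, 1}^d minus the all-zero point gives 26
    design points for d = 3. The all-zero table is excluded: with every
    entry equal the two strategies are exactly equally abundant, so the
    point carries no signal. Raises if the design matrix (with intercept)
    is rank deficient.
    """
    if len(set(grid)) < 2:
        raise ValueError("grid must contain at least two distinct levels")
    points = [
        np.array(pt, dtype=float)
        for pt in itertools.product(grid, repeat=d)
        if any(v != 0.0 for v in pt)
    ]
    x = np.column_stack([np.ones(len(points)), np.array(points)])
    if np.linalg.matrix_rank(x) < d + 1:
        raise ValueError("rank-deficient payoff design")
    if rng_seed is not None:
        np.random.default_rng(rng_seed).shuffle(points)
    return points


def fit_sigma(
    structure: PopulationStructure,
    profile: AspirationProfile,
    g_list,
    beta: float,
    design: list[np.ndarray],
    sim_config: SimulationConfig,
) -> SigmaFit:
    """Simulate every design point and fit the sigma coefficients by OLS.

    Each design point a gets its own chain (sequential seeds derived from
    ``sim_config.rng_seed``) with payoff table (a, b=0) at the given
    selection intensity. Margins of error are 95% OLS confidence
    half-widths; the ratio-normalised margins propagate the coefficient
    covariance through the division (delta method).
    """
    d = len(design[0])
    abundances = np.empty(len(design))
    std_errors = np.empty(len(design))
    for j, a_vec in enumerate(design):
        table = PayoffTable(a=a_vec, b=np.zeros(d))
        cfg = SimulationConfig(
            beta=beta,
            n_steps=sim_config.n_steps,
            burn_in=sim_config.burn_in,
            init_fraction_a=sim_config.init_fraction_a,
            payoff_scheme=sim_config.payoff_scheme,
            rng_seed=sim_config.rng_seed + j,
        )
        res = run_chain(structure, table, profile, g_list, cfg)
        abundances[j] = res.mean_abundance_a
        std_errors[j] = res.std_error

    y = abundances - 0.5
    x = sm.add_constant(np.array(design))
    fit = sm.OLS(y, x).fit()
    params = fit.params  # [intercept, a_0, ..., a_{d-1}]
    ci = fit.conf_int(alpha=0.05)
    margins = (ci[:, 1] - ci[:, 0]) / 2.0
    coefs = params[1:]
    intercept = float(params[0])

    c0 = coefs[0]
    if abs(c0) <= margins[1]:
        raise ArithmeticError(
            "coefficient on a_0 is not significantly different from zero; "
            "cannot ratio-normalise (increase the simulation budget or beta)"
        )
    normalized = coefs / c0
    # delta method for r_k = c_k / c_0 using the OLS coefficient covariance
    cov = fit.cov_params()[1:, 1:]
    tcrit = margins[1] / np.sqrt(cov[0, 0])
    norm_margins = np.empty(d)
    for k in range(d):
        var = (
            cov[k, k] / c0**2
            + coefs[k] ** 2 * cov[0, 0] / c0**4
            - 2.0 * coefs[k] * cov[k, 0] / c0**3
        )
        norm_margins[k] = tcrit * np.sqrt(max(var, 0.0))

    return SigmaFit(
        coefficients=coefs,
        intercept=intercept,
        margins_of_error=np.concatenate([margins[1:], margins[:1]]),
        normalized=normalized,
        normalized_margins=norm_margins,
        design=[np.asarray(a, dtype=float) for a in design],
        abundances=abundances,
        std_errors=std_errors,
    )
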