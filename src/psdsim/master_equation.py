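"""Birth-death master equation for the globally cooperative synapse.

When cooperativity acts on the whole synapse rather than between lattice
neighbors (``chi -> S/M``), the size ``S`` performs a one-dimensional
birth-death process on ``{0, ..., M}`` with

    W+(S) = (M - S) * (lambda_on * S / M + alpha)          (birth, S -> S+1)
    W-(S) = S * (lambda_off * (1 - S / M) + beta)          (death, S -> S-1)

With ``beta = 0`` the full state ``S = M`` is absorbing (``W-(M) = 0``), so
a weak non-cooperative unbinding ``beta > 0`` is used for the stationary
analysis; the canonical choice here is ``beta = alpha``.

Two stationary solutions are provided: the exact detailed-balance product
solution of the chain (computed in log space), and the stationary density
of the diffusion (Fokker-Planck) approximation with drift
``A = W+ - W-`` and diffusion ``D = (W+ + W-) / 2``,

    p(x)  proportional to  exp( integral_0^x A/D dx' ) / D(x),

evaluated by trapezoidal quadrature on a fine grid and reported on integer
sizes.  The exact solution serves as the oracle for the approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.special import logsumexp

from .params import (
    DEFAULT_ALPHA,
    DEFAULT_LAMBDA_OFF,
    DEFAULT_LAMBDA_ON,
    KineticParams,
)

__all__ = [
    "BirthDeathRates",
    "birth_death_rates",
    "stationary_exact",
    "fokker_planck_stationary",
    "distribution_moments",
    "distribution_skewness",
    "params_for_cooperativity",
    "scan_cooperativity",
]


@dataclass(frozen=True)
class BirthDeathRates:
    """Transition rates of the global model's birth-death chain.

    ``birth[S]`` is W+(S) for S = 0..M (with ``birth[M] == 0``) and
    ``death[S]`` is W-(S) (with ``death[0] == 0``).
    """

    birth: np.ndarray
    death: np.ndarray

    @property
    def M(self) -> int:
        return len(self.birth) - 1


def birth_death_rates(params: KineticParams, M: int) -> BirthDeathRates:
    """Birth/death rate arrays of the global-cooperativity chain."""
    if M < 1:
        raise ValueError("M must be >= 1")
    S = np.arange(M + 1, dtype=float)
    birth = (M - S) * (params.lambda_on * S / M + params.alpha)
    death = S * (params.lambda_off * (1.0 - S / M) + params.beta)
    return BirthDeathRates(birth=birth, death=death)


def stationary_exact(rates: BirthDeathRates) -> np.ndarray:
    """Exact stationary distribution p(S) of the birth-death chain.

    Detailed balance gives p(S) proportional to the product of
    W+(k-1)/W-(k) for k = 1..S; the cumulative sum of log-ratios is
    normalized with logsumexp for stability at large M.
    """
    M = rates.M
    if np.any(rates.death[1:] <= 0):
        raise ValueError(
            "all interior death rates must be positive (chain irreducible); "
            "use beta > 0"
        )
    log_ratio = np.log(rates.birth[:-1]) - np.log(rates.death[1:])
    log_p = np.concatenate(([0.0], np.cumsum(log_ratio)))
    log_p -= logsumexp(log_p)
    return np.exp(log_p)


def fokker_planck_stationary(
    params: KineticParams,
    M: int,
    grid_mult: int = 10,
) -> np.ndarray:
    """Stationary distribution of the diffusion approximation, on S = 0..M.

    Requires ``beta > 0`` so the diffusion coefficient is positive across
    the whole interval.  The continuous density is computed on a grid of
    ``grid_mult * M + 1`` points and then aggregated onto integer sizes.
    """
    if params.beta <= 0:
        raise ValueError("Fokker-Planck stationary solution requires beta > 0")
    if M < 2:
        raise ValueError("M must be >= 2")
    x = np.linspace(0.0, M, grid_mult * M + 1)
    w_plus = (M - x) * (params.lambda_on * x / M + params.alpha)
    w_minus = x * (params.lambda_off * (1.0 - x / M) + params.beta)
    drift = w_plus - w_minus
    diff = 0.5 * (w_plus + w_minus)
    if np.any(diff <= 0):
        raise ValueError("diffusion coefficient vanishes on the interval")
    potential = cumulative_trapezoid(drift / diff, x, initial=0.0)
    log_density = potential - np.log(diff)
    log_density -= log_density.max()
    density = np.exp(log_density)
    density /= np.trapezoid(density, x)
    # report on integer sizes: the density is smooth on the scale of one
    # site, so its value at integer x is the probability mass of that size
    p = density[::grid_mult].copy()
    return p / p.sum()


def distribution_moments(p: np.ndarray, support: np.ndarray | None = None):
    """(mean, sd, skewness) of a discrete distribution from exact moments."""
    p = np.asarray(p, dtype=float)
    if support is None:
        support = np.arange(len(p), dtype=float)
    mean = float(np.sum(support * p))
    var = float(np.sum((support - mean) ** 2 * p))
    sd = np.sqrt(var)
    if sd == 0:
        raise ValueError("degenerate distribution has no skewness")
    skew = float(np.sum((support - mean) ** 3 * p) / sd**3)
    return mean, sd, skew


def distribution_skewness(p: np.ndarray) -> float:
    return distribution_moments(p)[2]


def params_for_cooperativity(
    C: float,
    alpha: float = DEFAULT_ALPHA,
    beta: float | None = None,
    on_off_ratio: float = DEFAULT_LAMBDA_ON / DEFAULT_LAMBDA_OFF,
) -> KineticParams:
    """Kinetic parameters realizing cooperativity ratio ``C``.

    Holds ``alpha`` (and ``beta``, default equal to ``alpha``) fixed, keeps
    ``lambda_on/lambda_off`` at the default ratio, and scales their sum to
    ``C * alpha``.
    """
    if C < 0:
        raise ValueError("C must be >= 0")
    total = C * alpha
    lam_off = total / (1.0 + on_off_ratio)
    lam_on = total - lam_off
    return KineticParams(
        model="bidirectional",
        lambda_on=lam_on,
        lambda_off=lam_off,
        alpha=alpha,
        beta=alpha if beta is None else beta,
    )


def scan_cooperativity(
    C_values,
    M: int,
    alpha: float = DEFAULT_ALPHA,
    beta: float | None = None,
    method: str = "fokker_planck",
):
    """Stationary distribution and skewness along a scan of C.

    Returns a list of ``(C, params, p, skewness)`` tuples, with ``p`` the
    stationary distribution over S = 0..M computed either by the
    Fokker-Planck approximation (default) or the exact product solution.
    """
    C_values = list(C_values)
    if not C_values:
        raise ValueError("C_values must be non-empty")
    out = []
    for C in C_values:
        params = params_for_cooperativity(C, alpha=alpha, beta=beta)
        if method == "fokker_planck":
            p = fokker_planck_stationary(params, M)
        elif method == "exact":
            p = stationary_exact(birth_death_rates(params, M))
        else:
            raise ValueError(f"unknown method {method!r}")
        out.append((C, params, p, distribution_skewness(p)))
    return out
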