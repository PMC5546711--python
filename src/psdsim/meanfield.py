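"""Continuum (mean-field) analysis of the binding/unbinding kinetics.

Neglecting fluctuations and spatial correlations, the occupied fraction
``s = S/M`` of a synapse obeys

    ds/dt = k_on(s) * (1 - s) - k_off(s) * s

with the neighbor fraction ``chi`` replaced by the global occupancy ``s``.
For the bidirectional scheme this gives

    ds/dt = (lambda_on*s + alpha) * (1 - s) - (lambda_off*(1 - s) + beta) * s

With ``beta = 0`` the right-hand side factorizes as
``(1 - s) * (alpha - (lambda_off - lambda_on) * s)``: an interior stationary
occupancy ``s* = alpha / (lambda_off - lambda_on)`` exists and is stable
precisely when ``alpha < lambda_off - lambda_on``; otherwise the full
lattice ``s = 1`` is the attractor.

The strength of cooperative relative to non-cooperative kinetics is
summarized by the cooperativity ratio

    C = (lambda_on + lambda_off) / alpha

which controls the shape (skewness) of stationary size distributions: the
non-cooperative limit C << 1 behaves like independent adsorption (Gaussian
sizes), while C >> 1 yields broad, rightward-skewed distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .params import KineticParams

__all__ = [
    "meanfield_rhs",
    "FixedPoint",
    "fixed_points",
    "cooperativity_ratio",
    "integrate_meanfield",
]

_TOL = 1e-10


def meanfield_rhs(params: KineticParams, s) -> np.ndarray | float:
    """ds/dt at occupancy fraction ``s`` (array-aware)."""
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0) or np.any(s_arr > 1):
        raise ValueError("occupancy fraction s must lie in [0, 1]")
    if params.model == "langmuir":
        out = params.alpha * (1.0 - s_arr) - params.beta * s_arr
    elif params.model == "contact":
        out = (params.lambda_on * s_arr + params.alpha) * (1.0 - s_arr) \
            - params.beta * s_arr
    else:
        out = (params.lambda_on * s_arr + params.alpha) * (1.0 - s_arr) \
            - (params.lambda_off * (1.0 - s_arr) + params.beta) * s_arr
    return out if np.ndim(s) else float(out)


def _rhs_derivative(params: KineticParams, s: float, h: float = 1e-7) -> float:
    lo, hi = max(0.0, s - h), min(1.0, s + h)
    return (meanfield_rhs(params, hi) - meanfield_rhs(params, lo)) / (hi - lo)


@dataclass(frozen=True)
class FixedPoint:
    s: float
    stability: str  # "stable" | "unstable" | "marginal"

    @property
    def stable(self) -> bool:
        return self.stability == "stable"


def fixed_points(params: KineticParams, n_scan: int = 4001) -> list[FixedPoint]:
    """All roots of the mean-field rhs in [0, 1], with linear stability.

    A dense scan brackets sign changes which are refined by Brent's method;
    endpoints and scan points where the rhs vanishes to tolerance are kept
    as roots as well.  Stability is the sign of d(rhs)/ds at the root.
    """
    grid = np.linspace(0.0, 1.0, n_scan)
    vals = meanfield_rhs(params, grid)
    roots: list[float] = []
    for i in range(n_scan - 1):
        a, b = grid[i], grid[i + 1]
        fa, fb = vals[i], vals[i + 1]
        if abs(fa) < _TOL:
            roots.append(float(a))
        elif fa * fb < 0:
            roots.append(float(brentq(lambda x: meanfield_rhs(params, x), a, b,
                                      xtol=_TOL)))
    if abs(vals[-1]) < _TOL:
        roots.append(1.0)
    # merge near-duplicates from adjacent brackets
    uniq: list[float] = []
    for r in sorted(roots):
        if not uniq or r - uniq[-1] > 1e-8:
            uniq.append(r)
    out = []
    for r in uniq:
        d = _rhs_derivative(params, r)
        if abs(d) < 1e-9:
            stability = "marginal"
        else:
            stability = "stable" if d < 0 else "unstable"
        out.append(FixedPoint(s=r, stability=stability))
    return out


def cooperativity_ratio(params: KineticParams) -> float:
    """C = (lambda_on + lambda_off) / alpha."""
    if params.alpha <= 0:
        raise ValueError("cooperativity ratio undefined for alpha <= 0")
    return (params.lambda_on + params.lambda_off) / params.alpha


def integrate_meanfield(
    params: KineticParams,
    s0: float,
    t_end: float,
    n_points: int = 200,
):
    """Integrate the mean-field equation from ``s0``; returns (t, s(t)).

    The trajectory is clipped to [0, 1] against integrator round-off.
    """
    if not 0.0 <= s0 <= 1.0:
        raise ValueError("s0 must lie in [0, 1]")
    if not np.isfinite(t_end) or t_end <= 0:
        raise ValueError("t_end must be finite and > 0")
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        lambda _t, y: [meanfield_rhs(params, float(np.clip(y[0], 0.0, 1.0)))],
        (0.0, t_end),
        [s0],
        t_eval=t_eval,
        rtol=1e-9,
        atol=1e-12,
        method="LSODA",
    )
    return sol.t, np.clip(sol.y[0], 0.0, 1.0)
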