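"""Kinetic parameter sets and neighborhood specifications.

The simulator describes a patch of postsynaptic membrane as a bounded
rectangular lattice of binding sites for scaffold molecules.  Three kinetic
schemes are supported, differing in how a site's binding/unbinding
probability depends on the fraction ``chi`` of its occupied nearest
neighbors:

``langmuir``
    Independent adsorption/desorption: ``k_on = alpha``, ``k_off = beta``.
``contact``
    Cooperative binding, independent unbinding: ``k_on = lambda_on*chi +
    alpha``, ``k_off = beta``.  With ``alpha = 0`` the empty lattice is an
    absorbing state (the classic contact process).
``bidirectional``
    Cooperative binding *and* unbinding: ``k_on = lambda_on*chi + alpha``,
    ``k_off = lambda_off*(1 - chi) + beta``.

Rates are per unit time; multiplied by the step duration ``dt`` they become
per-step probabilities (clipped to [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

MODELS = ("langmuir", "contact", "bidirectional")

#: Default kinetic parameters for the bidirectional cooperativity model:
#: strong, nearly balanced cooperative rates and a weak non-specific seeding
#: term, chosen to yield a few hundred bound scaffold molecules on a 50x50
#: patch.
DEFAULT_LAMBDA_OFF = 0.5
DEFAULT_LAMBDA_ON = 0.493
DEFAULT_ALPHA = 0.0007

DEFAULT_ROWS = 50
DEFAULT_COLS = 50
DEFAULT_N_SYNAPSES = 3500
DEFAULT_N_STEPS = 1500
#: Growth from an empty lattice plateaus after roughly 900 steps at the
#: default parameters; stationary analyses discard this transient.
DEFAULT_BURN_IN = 900


@dataclass(frozen=True)
class KineticParams:
    """Rates of one kinetic scheme.

    Parameters
    ----------
    model : {"langmuir", "contact", "bidirectional"}
    lambda_on, lambda_off : float
        Cooperative binding/unbinding strengths (maximal rates), per unit
        time.  Ignored where the model does not use them.
    alpha : float
        Non-cooperative (seeding) binding rate per unit time.
    beta : float
        Non-cooperative unbinding rate per unit time.  Defaults to 0 for the
        bidirectional scheme; a small positive value is needed for the
        analytic birth-death treatment to be irreducible.
    dt : float
        Time-step duration; ``rate * dt`` is the per-step flip probability.
    prob_rule : {"linear", "exponential"}
        How a rate maps to a per-step probability: ``clip(rate*dt, 0, 1)``
        (default) or the exponential waiting-time form ``1 - exp(-rate*dt)``.
    """

    model: str = "bidirectional"
    lambda_on: float = DEFAULT_LAMBDA_ON
    lambda_off: float = DEFAULT_LAMBDA_OFF
    alpha: float = DEFAULT_ALPHA
    beta: float = 0.0
    dt: float = 1.0
    prob_rule: str = "linear"

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        for name in ("lambda_on", "lambda_off", "alpha", "beta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not np.isfinite(self.dt) or self.dt <= 0:
            raise ValueError(f"dt must be finite and > 0, got {self.dt}")
        if self.prob_rule not in ("linear", "exponential"):
            raise ValueError(f"unknown prob_rule {self.prob_rule!r}")

    def replace(self, **kwargs) -> "KineticParams":
        return replace(self, **kwargs)

    def to_probability(self, rate):
        """Per-step flip probability for a given rate (array-aware)."""
        rate = np.asarray(rate, dtype=float)
        if self.prob_rule == "exponential":
            return 1.0 - np.exp(-rate * self.dt)
        return np.clip(rate * self.dt, 0.0, 1.0)


@dataclass(frozen=True)
class NeighborSpec:
    """Neighborhood definition on the bounded lattice.

    mode : {"moore8", "vonneumann4", "global"}
        Eight neighbors (including diagonals), four axial neighbors, or
        global coupling where every site sees ``chi = S / M`` (the
        whole-synapse occupancy, as in the analytically tractable global
        cooperativity model).
    full_denominator : bool
        If True (default), ``chi`` always divides by the maximal neighbor
        count (8 or 4), so edge and corner sites see out-of-bounds
        positions as permanently vacant; if False, the denominator is the
        number of neighbors that actually exist for the site.  The maximal
        convention is the canonical one: it reproduces the reported
        stationary mean occupancy, whereas the edge-adjusted variant
        inflates binding at the boundary and overshoots it by ~70%.
    """

    mode: str = "moore8"
    full_denominator: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("moore8", "vonneumann4", "global"):
            raise ValueError(f"unknown neighborhood mode {self.mode!r}")

    @property
    def offsets(self) -> tuple[tuple[int, int], ...]:
        if self.mode == "global":
            raise ValueError("global coupling has no neighbor offsets")
        if self.mode == "moore8":
            return tuple(
                (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
            )
        return ((-1, 0), (1, 0), (0, -1), (0, 1))

    @property
    def max_neighbors(self) -> int:
        if self.mode == "global":
            raise ValueError("global coupling has no neighbor count")
        return 8 if self.mode == "moore8" else 4

    def denominator(self, rows: int, cols: int) -> np.ndarray:
        """Per-site chi denominator for a rows x cols lattice."""
        if self.full_denominator:
            return np.full((rows, cols), float(self.max_neighbors))
        return _existing_neighbors(self.mode, rows, cols).astype(float).copy()


@lru_cache(maxsize=32)
def _existing_neighbors(mode: str, rows: int, cols: int) -> np.ndarray:
    spec = NeighborSpec(mode=mode)
    ones = np.ones((rows, cols), dtype=np.int64)
    return shifted_sum(ones, spec.offsets)


def shifted_sum(grid: np.ndarray, offsets) -> np.ndarray:
    """Sum of ``grid`` over the given offsets with zero-padded boundaries.

    Works on the last two axes, so an ensemble stack (n, rows, cols) is
    handled in one call.
    """
    grid = np.asarray(grid)
    rows, cols = grid.shape[-2], grid.shape[-1]
    pad = [(0, 0)] * (grid.ndim - 2) + [(1, 1), (1, 1)]
    padded = np.pad(grid, pad)
    out = np.zeros(grid.shape, dtype=np.int64 if grid.dtype != float else float)
    for dr, dc in offsets:
        out += padded[..., 1 + dr : 1 + dr + rows, 1 + dc : 1 + dc + cols]
    return out
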