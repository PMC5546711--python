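"""Shared-molecule-pool simulation: many synapses, one cytosolic reservoir.

The cooperative binding strength of the basic model implicitly lumps in the
concentration of free scaffold molecules.  Here that dependence is explicit:
all synapses of a cell compete for a finite pool of ``n_total`` molecules,
and the cooperative binding rate at a vacant site is

    k_on = N_free * lambda_on_star * chi + alpha

with ``N_free = N_total - N_bound`` updated after every step.  The product
``lambda_on_effective = N_free * lambda_on_star`` self-tunes: when it
exceeds ``lambda_off`` synapses grow and deplete the pool, when it falls
below they shrink and replenish it, so at steady state it settles close to
``lambda_off`` over a wide range of ``n_total`` while mean synaptic size
scales with the pool.

The weak seeding term ``alpha`` is kept pool-independent by default; with
``scale_alpha=True`` it too is multiplied by ``N_free`` (the literal
mean-field form), which at realistic pool sizes saturates the per-step
probability and destroys the self-tuning regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import KineticParams, NeighborSpec, shifted_sum
from .lattice import EnsembleTrajectory, neighbor_fraction_grid

__all__ = ["SharedPoolResult", "shared_pool_simulate"]

#: Per-molecule cooperative binding constant used in the pool sweeps; with a
#: free pool of ~1e5 molecules it reproduces the basic model's lambda_on.
DEFAULT_LAMBDA_ON_STAR = 5e-6


@dataclass
class SharedPoolResult:
    """Outcome of a shared-pool run."""

    trajectory: EnsembleTrajectory
    n_total: int
    n_free: np.ndarray  # free molecules after each step, length n_steps + 1
    lambda_on_effective: np.ndarray  # N_free * lambda_on_star, same length
    lambda_on_star: float

    def final_lambda_on_effective(self, window: int = 10) -> float:
        """Mean of lambda_on_effective over the last ``window`` steps."""
        return float(self.lambda_on_effective[-window:].mean())


def shared_pool_simulate(
    n_total: int,
    params: KineticParams,
    spec: NeighborSpec = NeighborSpec(),
    rows: int = 50,
    cols: int = 50,
    n_synapses: int = 1000,
    n_steps: int = 1500,
    master_seed: int = 0,
    lambda_on_star: float = DEFAULT_LAMBDA_ON_STAR,
    scale_alpha: bool = False,
) -> SharedPoolResult:
    """Simulate ``n_synapses`` lattices coupled through one molecule pool.

    All lattices start vacant.  Binding attempts in a step are capped by the
    available pool: if more sites attempt to bind than there are free
    molecules, a uniformly random subset of attempts of size ``N_free``
    succeeds, so ``N_free`` never goes negative and
    ``N_free + N_bound == N_total`` holds after every step.
    """
    if n_total < 0:
        raise ValueError("n_total must be >= 0")
    if n_synapses < 1 or n_steps < 1:
        raise ValueError("n_synapses and n_steps must be >= 1")
    rng = np.random.Generator(
        np.random.Philox(np.random.SeedSequence(master_seed, spawn_key=(1,)))
    )
    occ = np.zeros((n_synapses, rows, cols), dtype=bool)
    sizes = np.zeros((n_synapses, n_steps + 1), dtype=np.int64)
    n_free = np.empty(n_steps + 1, dtype=np.int64)
    n_free[0] = n_total
    for t in range(1, n_steps + 1):
        chi = neighbor_fraction_grid(occ, spec)
        free = n_free[t - 1]
        coop = free * lambda_on_star * chi
        if scale_alpha:
            rate_on = free * (lambda_on_star * chi + params.alpha)
        else:
            rate_on = coop + params.alpha
        p_on = params.to_probability(rate_on)
        p_off = params.to_probability(
            params.lambda_off * (1.0 - chi) + params.beta
        )
        u = rng.random(occ.shape)
        bind = ~occ & (p_on > u)
        unbind = occ & (p_off > u)
        n_attempt = int(bind.sum())
        if n_attempt > free:
            # pool exhausted: accept a uniform subset of binding attempts
            idx = np.flatnonzero(bind.ravel())
            keep = rng.choice(idx, size=int(free), replace=False)
            bind = np.zeros(occ.size, dtype=bool)
            bind[keep] = True
            bind = bind.reshape(occ.shape)
        occ = occ ^ bind ^ unbind
        sizes[:, t] = occ.sum(axis=(1, 2))
        n_free[t] = n_total - sizes[:, t].sum()
    traj = EnsembleTrajectory(
        sizes=sizes,
        snapshots={},
        master_seed=master_seed,
        params=params,
        spec=spec,
        rows=rows,
        cols=cols,
    )
    return SharedPoolResult(
        trajectory=traj,
        n_total=n_total,
        n_free=n_free,
        lambda_on_effective=n_free * lambda_on_star,
        lambda_on_star=lambda_on_star,
    )
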