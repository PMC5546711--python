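"""Shared fixtures: heavy stationary-regime simulations are session-scoped
so the ensemble-level checks reuse a single run."""

from __future__ import annotations

import numpy as np
import pytest

from psdsim import KineticParams, NeighborSpec, simulate_ensemble


@pytest.fixture(scope="session")
def methods_ensemble():
    """Bidirectional cooperativity at default parameters, 500 synapses on
    50x50 over 1500 steps from an empty start, final snapshot recorded."""
    return simulate_ensemble(
        KineticParams(),
        NeighborSpec(),
        n_synapses=500,
        n_steps=1500,
        master_seed=20240,
        snapshot_times=(1500,),
    )


@pytest.fixture(scope="session")
def small_stationary_ensemble():
    """Cheap stationary ensemble on a 20x20 patch for statistics tests."""
    return simulate_ensemble(
        KineticParams(),
        NeighborSpec(),
        rows=20,
        cols=20,
        n_synapses=200,
        n_steps=1200,
        master_seed=7,
    )


@pytest.fixture(scope="session")
def lambda_on_sweep():
    """Stationary samples across a lambda_on sweep plus a same-parameter
    replicate, for the scaling-collapse analysis."""
    samples = {}
    for lam in (0.480, 0.487, 0.493):
        traj = simulate_ensemble(
            KineticParams(lambda_on=lam),
            NeighborSpec(),
            n_synapses=300,
            n_steps=1500,
            master_seed=3000 + int(lam * 1000),
        )
        samples[lam] = traj.sizes[:, -1]
    replicates = [
        simulate_ensemble(
            KineticParams(),
            NeighborSpec(),
            n_synapses=300,
            n_steps=1500,
            master_seed=seed,
        ).sizes[:, -1]
        for seed in (9999, 8888)
    ]
    return samples, replicates
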