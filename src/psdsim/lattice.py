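"""Synchronous Monte Carlo dynamics of scaffold binding on a bounded lattice.

One synapse is a boolean occupancy grid.  At every time step, the fraction
of occupied nearest neighbors ``chi`` is evaluated for all sites on the
*current* configuration; a vacant site then binds with probability
``k_on(chi)*dt`` and an occupied site unbinds with probability
``k_off(chi)*dt``, each compared against an independent uniform draw.  All
flips are applied simultaneously (synchronous update), which makes a
trajectory a deterministic function of the parameters and the random
stream.

Ensembles of synapses are independent realizations; synapse ``i`` draws its
randomness from a dedicated substream spawned from ``(master_seed, i)``, so
any row of an ensemble can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .params import KineticParams, NeighborSpec, shifted_sum

__all__ = [
    "LatticeState",
    "EnsembleTrajectory",
    "neighbor_fraction",
    "neighbor_fraction_grid",
    "binding_probability",
    "unbinding_probability",
    "step_synchronous",
    "simulate_lattice",
    "simulate_ensemble",
    "synapse_rng",
]


@dataclass
class LatticeState:
    """Occupancy snapshot of one synapse (boolean grid of binding sites)."""

    occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 2:
            raise ValueError("occupancy must be a 2-D grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.occupancy.shape

    @property
    def n_sites(self) -> int:
        return self.occupancy.size

    @property
    def size(self) -> int:
        """Synaptic size S: the number of bound molecules."""
        return int(self.occupancy.sum())

    def occupied_coords(self) -> np.ndarray:
        """(n_occupied, 2) array of 0-based (row, col) pairs."""
        return np.argwhere(self.occupancy)

    @classmethod
    def empty(cls, rows: int, cols: int) -> "LatticeState":
        return cls(np.zeros((rows, cols), dtype=bool))

    @classmethod
    def full(cls, rows: int, cols: int) -> "LatticeState":
        return cls(np.ones((rows, cols), dtype=bool))


@dataclass
class EnsembleTrajectory:
    """Sizes of an ensemble of independently simulated synapses.

    Attributes
    ----------
    sizes : (n_synapses, n_steps + 1) int array
        ``sizes[i, t]`` is the number of bound molecules of synapse ``i``
        after ``t`` steps (column 0 is the initial condition).
    snapshots : dict mapping step -> (n_synapses, rows, cols) bool array
        Full configurations recorded at the requested times.
    master_seed : int
    params : KineticParams
    spec : NeighborSpec
    """

    sizes: np.ndarray
    snapshots: dict
    master_seed: int
    params: KineticParams
    spec: NeighborSpec
    rows: int
    cols: int

    @property
    def n_synapses(self) -> int:
        return self.sizes.shape[0]

    @property
    def n_steps(self) -> int:
        return self.sizes.shape[1] - 1

    def stationary_sample(self, t: int | None = None) -> np.ndarray:
        """Sizes of all synapses at one time point (default: final step)."""
        return self.sizes[:, -1 if t is None else t].copy()

    def snapshot_states(self, t: int) -> list[LatticeState]:
        return [LatticeState(g) for g in self.snapshots[t]]


def neighbor_fraction_grid(
    occupancy: np.ndarray, spec: NeighborSpec = NeighborSpec()
) -> np.ndarray:
    """chi for every site: occupied neighbors / neighbors that exist there.

    Accepts a single grid or an (n, rows, cols) stack.
    """
    occ = np.asarray(occupancy, dtype=bool)
    if spec.mode == "global":
        m = occ.shape[-2] * occ.shape[-1]
        frac = occ.sum(axis=(-2, -1), keepdims=True) / m
        return np.broadcast_to(frac, occ.shape).copy()
    counts = shifted_sum(occ, spec.offsets)
    denom = spec.denominator(occ.shape[-2], occ.shape[-1])
    return counts / denom


def neighbor_fraction(
    state: LatticeState, row: int, col: int, spec: NeighborSpec = NeighborSpec()
) -> float:
    """Fraction of occupied nearest neighbors of one site.

    The denominator follows ``spec``: the maximal neighbor count by
    default, or the number of in-bounds neighbors when
    ``full_denominator=False``.
    """
    rows, cols = state.shape
    if not (0 <= row < rows and 0 <= col < cols):
        raise IndexError(f"site ({row}, {col}) outside {rows}x{cols} lattice")
    if spec.mode == "global":
        return state.size / state.n_sites
    occ = state.occupancy
    n_occ = 0
    n_exist = 0
    for dr, dc in spec.offsets:
        r, c = row + dr, col + dc
        if 0 <= r < rows and 0 <= c < cols:
            n_exist += 1
            n_occ += int(occ[r, c])
    denom = spec.max_neighbors if spec.full_denominator else n_exist
    return n_occ / denom


def _binding_rate(params: KineticParams, chi):
    if params.model == "langmuir":
        return np.broadcast_to(params.alpha, np.shape(chi)).astype(float) \
            if np.ndim(chi) else float(params.alpha)
    return params.lambda_on * np.asarray(chi, dtype=float) + params.alpha


def _unbinding_rate(params: KineticParams, chi):
    if params.model in ("langmuir", "contact"):
        return np.broadcast_to(params.beta, np.shape(chi)).astype(float) \
            if np.ndim(chi) else float(params.beta)
    return params.lambda_off * (1.0 - np.asarray(chi, dtype=float)) + params.beta


def _check_chi(chi) -> None:
    chi = np.asarray(chi, dtype=float)
    if np.any(chi < 0) or np.any(chi > 1):
        raise ValueError("chi must lie in [0, 1]")


def binding_probability(params: KineticParams, chi):
    """Per-step probability that a vacant site binds, given chi."""
    _check_chi(chi)
    return params.to_probability(_binding_rate(params, chi))


def unbinding_probability(params: KineticParams, chi):
    """Per-step probability that an occupied site unbinds, given chi."""
    _check_chi(chi)
    return params.to_probability(_unbinding_rate(params, chi))


def step_synchronous(
    state: LatticeState,
    params: KineticParams,
    spec: NeighborSpec = NeighborSpec(),
    rng: np.random.Generator | None = None,
    uniforms: np.ndarray | None = None,
) -> LatticeState:
    """Advance one synapse by a single synchronous Monte Carlo step.

    All chi values come from the input configuration; a site flips when its
    flip probability exceeds its uniform draw.  The input state is not
    modified.  Either ``rng`` or a pre-drawn ``uniforms`` grid (one draw per
    site) must be given.
    """
    occ = state.occupancy
    if uniforms is None:
        if rng is None:
            raise ValueError("provide rng or uniforms")
        uniforms = rng.random(occ.shape)
    new_occ = _step_grid(occ, params, spec, uniforms)
    return LatticeState(new_occ)


def _step_grid(occ, params, spec, uniforms):
    """Synchronous update of a grid or an (n, rows, cols) stack."""
    chi = neighbor_fraction_grid(occ, spec)
    p_on = params.to_probability(_binding_rate(params, chi))
    p_off = params.to_probability(_unbinding_rate(params, chi))
    p_flip = np.where(occ, p_off, p_on)
    return occ ^ (p_flip > uniforms)


def _initial_grid(initial, rows, cols, rng) -> np.ndarray:
    if isinstance(initial, LatticeState):
        return initial.occupancy.copy()
    if isinstance(initial, np.ndarray):
        return initial.astype(bool).copy()
    if initial == "empty":
        return np.zeros((rows, cols), dtype=bool)
    if initial == "full":
        return np.ones((rows, cols), dtype=bool)
    p = float(initial)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"initial occupancy fraction must be in [0, 1], got {p}")
    return rng.random((rows, cols)) < p


def synapse_rng(master_seed: int, index: int) -> np.random.Generator:
    """Independent random stream for synapse ``index`` of an ensemble."""
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence(master_seed, spawn_key=(index,)))
    )


def simulate_lattice(
    params: KineticParams,
    spec: NeighborSpec = NeighborSpec(),
    rows: int = 50,
    cols: int = 50,
    n_steps: int = 1500,
    rng: np.random.Generator | None = None,
    initial="empty",
    snapshot_times: Sequence[int] = (),
    _chunk: int = 128,
):
    """Simulate one synapse; return (sizes array, {step: occupancy grid}).

    ``sizes`` has length ``n_steps + 1`` with the initial size first.
    Uniform draws are consumed in row-major site order, one grid per step,
    so trajectories are reproducible from the generator state alone.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    snap_set = set(int(t) for t in snapshot_times)
    if snap_set and (min(snap_set) < 0 or max(snap_set) > n_steps):
        raise ValueError(f"snapshot times must lie in [0, {n_steps}]")
    occ = _initial_grid(initial, rows, cols, rng)
    sizes = np.empty(n_steps + 1, dtype=np.int64)
    sizes[0] = occ.sum()
    snaps = {}
    if 0 in snap_set:
        snaps[0] = occ.copy()
    t = 0
    while t < n_steps:
        # uniforms drawn in blocks of steps: fewer generator calls, same stream
        block = min(_chunk, n_steps - t)
        u = rng.random((block, rows, cols))
        for k in range(block):
            occ = _step_grid(occ, params, spec, u[k])
            t += 1
            sizes[t] = occ.sum()
            if t in snap_set:
                snaps[t] = occ.copy()
    return sizes, snaps


def simulate_ensemble(
    params: KineticParams,
    spec: NeighborSpec = NeighborSpec(),
    rows: int = 50,
    cols: int = 50,
    n_synapses: int = 100,
    n_steps: int = 1500,
    master_seed: int = 0,
    snapshot_times: Sequence[int] = (),
    initial="empty",
) -> EnsembleTrajectory:
    """Simulate an ensemble of independent synapses.

    Each synapse starts from the same initial condition (all-vacant by
    default) and evolves under its own random substream derived from
    ``(master_seed, synapse_index)``.
    """
    if n_synapses < 1:
        raise ValueError("n_synapses must be >= 1")
    snapshot_times = sorted(set(int(t) for t in snapshot_times))
    if snapshot_times and (snapshot_times[0] < 0 or snapshot_times[-1] > n_steps):
        raise ValueError(f"snapshot times must lie in [0, {n_steps}]")
    sizes = np.empty((n_synapses, n_steps + 1), dtype=np.int64)
    snaps = {t: np.empty((n_synapses, rows, cols), dtype=bool) for t in snapshot_times}
    for i in range(n_synapses):
        rng = synapse_rng(master_seed, i)
        s, sn = simulate_lattice(
            params, spec, rows, cols, n_steps, rng, initial, snapshot_times
        )
        sizes[i] = s
        for t, grid in sn.items():
            snaps[t][i] = grid
    return EnsembleTrajectory(
        sizes=sizes,
        snapshots=snaps,
        master_seed=master_seed,
        params=params,
        spec=spec,
        rows=rows,
        cols=cols,
    )
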