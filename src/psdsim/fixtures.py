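"""Synthetic lattice snapshots with known ground truth.

These generators produce the null and planted-structure inputs used to
validate the spatial analyses: i.i.d. random occupancy (for which
``g(r) = 1`` in expectation) and lattices with a known number of compact
clusters planted on a sparse background (for which nanocluster detection
should recover the planted count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import LatticeState

__all__ = ["Fixture", "generate_random_state", "generate_planted_clusters"]


@dataclass
class Fixture:
    state: LatticeState
    seed: int
    occupancy_p: float | None = None
    n_planted: int | None = None
    cluster_centers: np.ndarray | None = None


def generate_random_state(rows: int, cols: int, p: float, seed: int = 0) -> Fixture:
    """i.i.d. Bernoulli(p) occupancy."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"occupancy probability must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    occ = rng.random((rows, cols)) < p
    return Fixture(state=LatticeState(occ), seed=seed, occupancy_p=p)


def generate_planted_clusters(
    rows: int,
    cols: int,
    n_clusters: int,
    cluster_size: int = 12,
    spread: float = 1.5,
    background_p: float = 0.0,
    seed: int = 0,
    min_separation: float | None = None,
) -> Fixture:
    """Plant compact Gaussian blobs of occupied sites on a sparse background.

    Cluster centers are drawn uniformly (away from edges) subject to a
    pairwise separation of at least ``min_separation`` (default
    ``8 * spread``); each cluster occupies ``cluster_size`` distinct sites
    from an isotropic Gaussian of SD ``spread`` around its center.  Raises
    if the requested clusters cannot be packed in 1000 attempts.
    """
    if n_clusters < 0:
        raise ValueError("n_clusters must be >= 0")
    if not 0.0 <= background_p <= 1.0:
        raise ValueError("background_p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    min_separation = 8.0 * spread if min_separation is None else min_separation
    margin = max(2, int(np.ceil(3 * spread)))
    if rows - 2 * margin <= 0 or cols - 2 * margin <= 0:
        raise ValueError("lattice too small for the requested cluster spread")
    centers: list[np.ndarray] = []
    for _ in range(1000):
        if len(centers) == n_clusters:
            break
        cand = np.array(
            [rng.uniform(margin, rows - margin), rng.uniform(margin, cols - margin)]
        )
        if all(np.linalg.norm(cand - c) >= min_separation for c in centers):
            centers.append(cand)
    if len(centers) < n_clusters:
        raise ValueError(
            f"could not place {n_clusters} clusters with separation "
            f"{min_separation} on a {rows}x{cols} lattice"
        )
    occ = rng.random((rows, cols)) < background_p
    for center in centers:
        placed = 0
        while placed < cluster_size:
            r, c = np.rint(rng.normal(center, spread)).astype(int)
            if 0 <= r < rows and 0 <= c < cols and not occ[r, c]:
                occ[r, c] = True
                placed += 1
    return Fixture(
        state=LatticeState(occ),
        seed=seed,
        occupancy_p=background_p,
        n_planted=n_clusters,
        cluster_centers=np.array(centers).reshape(-1, 2),
    )
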