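"""Spatial organization of bound molecules: autocorrelation and nanoclusters.

Bound scaffold molecules in the cooperative regime organize into a small
number of dense sub-assemblies ("nanoclusters") rather than spreading
uniformly.  Two quantifications are provided:

* the spatial autocorrelation ``g(r)`` — the density of occupied sites at
  distance ``r`` from an occupied site, relative to the overall density of
  the patch.  For randomly placed molecules ``g(r) = 1``; clustering shows
  up as ``g(r) > 1`` at short range.
* nanocluster detection — agglomerative hierarchical clustering (single
  linkage, Euclidean) of the occupied coordinates, cutting the dendrogram
  at a data-driven height: the mean nearest-neighbor distance between
  occupied sites plus two standard deviations.  Groups smaller than a
  minimum size are treated as sparse molecules, not clusters.

Distances are Euclidean in lattice units; ``g(r)`` uses unit-width annuli
centered on integer radii (``r = 0`` is excluded as trivially 1) and counts
only in-bounds sites in its denominators, so no periodic wrap is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist

from .lattice import LatticeState

__all__ = [
    "AutocorrelationCurve",
    "spatial_autocorrelation",
    "average_autocorrelation",
    "nn_cutoff",
    "ClusterSet",
    "detect_nanoclusters",
    "track_clusters",
]

DEFAULT_MIN_CLUSTER_SIZE = 15


@dataclass(frozen=True)
class AutocorrelationCurve:
    r: np.ndarray  # integer-centered annulus radii, r >= 1
    g: np.ndarray  # dimensionless density ratio per annulus

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r": self.r, "g": self.g})


def _as_state(state) -> LatticeState:
    return state if isinstance(state, LatticeState) else LatticeState(state)


def spatial_autocorrelation(state, r_max: int = 10) -> AutocorrelationCurve:
    """g(r) of one snapshot over annuli r = 1..r_max.

    For each occupied site the fraction of in-bounds lattice sites at
    (rounded) distance ``r`` that are occupied is computed; ``g(r)`` is the
    mean of these fractions over occupied sites divided by the overall
    occupancy density.  Annuli with no in-bounds sites for any occupied
    site yield NaN.
    """
    st = _as_state(state)
    pts = st.occupied_coords().astype(float)
    if len(pts) == 0:
        raise ValueError("autocorrelation undefined for an empty lattice")
    rows, cols = st.shape
    density = len(pts) / st.n_sites
    all_sites = np.indices((rows, cols)).reshape(2, -1).T.astype(float)
    occ_flat = st.occupancy.ravel()
    d = np.rint(cdist(pts, all_sites)).astype(np.int64)  # (n_occ, M)
    r_vals = np.arange(1, r_max + 1)
    g = np.empty(len(r_vals))
    for j, r in enumerate(r_vals):
        mask = d == r
        totals = mask.sum(axis=1)  # in-bounds sites at distance r, per site
        occ_counts = (mask & occ_flat[None, :]).sum(axis=1)
        valid = totals > 0
        if not valid.any():
            g[j] = np.nan
            continue
        g[j] = (occ_counts[valid] / totals[valid]).mean() / density
    return AutocorrelationCurve(r=r_vals, g=g)


def average_autocorrelation(states, r_max: int = 10) -> AutocorrelationCurve:
    """Ensemble-average g(r) over many snapshots (NaN-aware mean)."""
    curves = [spatial_autocorrelation(s, r_max) for s in states]
    stacked = np.vstack([c.g for c in curves])
    return AutocorrelationCurve(
        r=curves[0].r, g=np.nanmean(stacked, axis=0)
    )


def nn_cutoff(points: np.ndarray) -> float:
    """Dendrogram cutoff: mean nearest-neighbor distance + 2 SD.

    ``points`` is an (n, 2) array of occupied-site coordinates; the SD uses
    the n-1 denominator.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) < 2:
        raise ValueError("nearest-neighbor cutoff needs at least 2 points")
    tree = cKDTree(points)
    dists, _ = tree.query(points, k=2)
    nn = dists[:, 1]
    sd = nn.std(ddof=1) if len(nn) > 1 else 0.0
    return float(nn.mean() + 2.0 * sd)


@dataclass
class ClusterSet:
    """Partition of one snapshot's occupied sites into nanoclusters.

    ``labels[i]`` is the cluster id of ``points[i]`` (ids are arbitrary but
    contiguous); ``n_clusters`` counts only groups with at least
    ``min_size`` members, the rest being sparse molecules.
    """

    points: np.ndarray
    labels: np.ndarray
    cutoff: float
    min_size: int

    @property
    def cluster_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    @property
    def nanocluster_ids(self) -> list[int]:
        return [cid for cid, n in self.cluster_sizes.items() if n >= self.min_size]

    @property
    def n_clusters(self) -> int:
        return len(self.nanocluster_ids)

    def member_sites(self, cid: int) -> set[tuple[int, int]]:
        pts = self.points[self.labels == cid]
        return {(int(r), int(c)) for r, c in pts}

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for cid in self.nanocluster_ids:
            pts = self.points[self.labels == cid]
            rows.append(
                {
                    "cluster_id": cid,
                    "size": len(pts),
                    "centroid_row": pts[:, 0].mean(),
                    "centroid_col": pts[:, 1].mean(),
                }
            )
        return pd.DataFrame(rows, columns=["cluster_id", "size", "centroid_row", "centroid_col"])


def detect_nanoclusters(
    state,
    min_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    cutoff: float | None = None,
) -> ClusterSet:
    """Partition occupied sites into nanoclusters.

    Single-linkage agglomerative clustering of the occupied coordinates,
    with the dendrogram cut at ``cutoff`` (default: mean NN distance + 2
    SD of this snapshot).  Snapshots with fewer than two occupied sites
    yield an empty ClusterSet with zero clusters.
    """
    st = _as_state(state)
    pts = st.occupied_coords()
    if len(pts) < 2:
        return ClusterSet(
            points=pts.reshape(-1, 2),
            labels=np.zeros(len(pts), dtype=int),
            cutoff=0.0,
            min_size=min_size,
        )
    if cutoff is None:
        cutoff = nn_cutoff(pts)
    Z = linkage(pdist(pts.astype(float)), method="single")
    labels = fcluster(Z, t=cutoff, criterion="distance")
    return ClusterSet(points=pts, labels=labels, cutoff=float(cutoff), min_size=min_size)


def track_clusters(a: ClusterSet, b: ClusterSet):
    """Greedy maximal-overlap matching of nanoclusters between two frames.

    Returns a DataFrame with one row per match or lone cluster: columns
    ``cluster_a``, ``cluster_b`` (nullable ints), ``overlap`` (shared
    occupied sites) and ``status`` in {"matched", "died", "born"}.
    """
    sites_a = {cid: a.member_sites(cid) for cid in a.nanocluster_ids}
    sites_b = {cid: b.member_sites(cid) for cid in b.nanocluster_ids}
    overlaps = [
        (len(sa & sb), ca, cb)
        for ca, sa in sites_a.items()
        for cb, sb in sites_b.items()
        if sa & sb
    ]
    overlaps.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    rows = []
    for ov, ca, cb in overlaps:
        if ca in used_a or cb in used_b:
            continue
        used_a.add(ca)
        used_b.add(cb)
        rows.append({"cluster_a": ca, "cluster_b": cb, "overlap": ov, "status": "matched"})
    for ca in sites_a:
        if ca not in used_a:
            rows.append({"cluster_a": ca, "cluster_b": None, "overlap": 0, "status": "died"})
    for cb in sites_b:
        if cb not in used_b:
            rows.append({"cluster_a": None, "cluster_b": cb, "overlap": 0, "status": "born"})
    return pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "overlap", "status"])
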