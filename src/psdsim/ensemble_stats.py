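"""Population-level statistics of simulated synaptic ensembles.

Covers the descriptive analyses applied to ensembles of size trajectories:
empirical size distributions (PDF/CDF), standardization for scaling
collapse, sample skewness, and the size-dependence of size changes
(regressions of S(t0 + T) or of dS = S(t0 + T) - S(t0) on S(t0), swept over
the interval T).  In the stationary regime of the cooperative model the
dS-vs-S slope is negative — small synapses tend to grow and large ones to
shrink — and as the interval grows the S(t1)-vs-S(t0) slope and R^2 decay
toward the memoryless limit while the normalized offset rises toward the
population mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lattice import EnsembleTrajectory

__all__ = [
    "SizeSample",
    "empirical_distribution",
    "empirical_cdf",
    "scale_sample",
    "sample_skewness",
    "RegressionSummary",
    "delta_regression",
    "regression_vs_interval",
    "ks_distance",
]


@dataclass(frozen=True)
class SizeSample:
    """Sizes of an ensemble at one time point."""

    sizes: np.ndarray
    time: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sizes", np.asarray(self.sizes))
        if self.sizes.size == 0:
            raise ValueError("empty size sample")


def _values(sample) -> np.ndarray:
    arr = sample.sizes if isinstance(sample, SizeSample) else np.asarray(sample)
    arr = np.asarray(arr, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty sample")
    return arr


def empirical_distribution(sample, bins="auto"):
    """Histogram PDF and CDF of a size sample.

    Returns a DataFrame with bin centers, normalized ``pdf`` (probability
    mass per bin, summing to 1) and the corresponding ``cdf``.
    """
    values = _values(sample)
    counts, edges = np.histogram(values, bins=bins)
    pmf = counts / counts.sum()
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "bin_center": 0.5 * (edges[:-1] + edges[1:]),
            "pdf": pmf,
            "cdf": np.cumsum(pmf),
        }
    )


def empirical_cdf(sample):
    """Exact step CDF: returns (sorted unique values, P(X <= value))."""
    values = np.sort(_values(sample))
    uniq, counts = np.unique(values, return_counts=True)
    return uniq, np.cumsum(counts) / values.size


def scale_sample(sample):
    """Standardize to mean 0, SD 1 (the scaling-collapse transform)."""
    values = _values(sample)
    sd = values.std()
    if sd == 0:
        raise ValueError("cannot scale a zero-variance sample")
    return (values - values.mean()) / sd


def sample_skewness(values) -> float:
    """Third standardized moment g1 = m3 / m2^(3/2) (bias-uncorrected)."""
    arr = _values(values)
    if arr.size < 3:
        raise ValueError("skewness needs at least 3 observations")
    if arr.std() == 0:
        raise ValueError("skewness undefined for a constant sample")
    return float(stats.skew(arr, bias=True))


def ks_distance(a, b) -> float:
    """Two-sample Kolmogorov-Smirnov statistic."""
    return float(stats.ks_2samp(_values(a), _values(b)).statistic)


@dataclass(frozen=True)
class RegressionSummary:
    """OLS summaries of size change versus initial size at one interval.

    ``slope_next``/``offset_next`` regress S(t0 + T) on S(t0);
    ``slope_delta`` regresses dS on S(t0) (``slope_delta == slope_next - 1``
    and the offsets coincide).  ``offset_norm`` is the offset divided by the
    mean size over the window, and ``r_squared`` is shared by both forms.
    """

    interval: int
    slope_next: float
    offset_next: float
    slope_delta: float
    offset_delta: float
    offset_norm: float
    r_squared: float
    mean_size: float


def _pairs(traj, t0: int, interval: int):
    sizes = traj.sizes if isinstance(traj, EnsembleTrajectory) else np.asarray(traj)
    if t0 < 0 or t0 + interval > sizes.shape[1] - 1:
        raise ValueError("t0 + interval exceeds trajectory length")
    return sizes[:, t0].astype(float), sizes[:, t0 + interval].astype(float)


def delta_regression(traj, t0: int, interval: int) -> RegressionSummary:
    """Regress sizes after ``interval`` steps on sizes at ``t0``.

    For ``interval == 0`` the identity regression (slope 1, offset 0,
    R^2 = 1) is returned directly.
    """
    s0, s1 = _pairs(traj, t0, interval)
    if s0.std() == 0:
        raise ValueError("zero variance in predictor S(t0)")
    mean_size = float(np.concatenate([s0, s1]).mean())
    if interval == 0:
        return RegressionSummary(0, 1.0, 0.0, 0.0, 0.0, 0.0, 1.0, mean_size)
    fit = stats.linregress(s0, s1)
    slope_next = float(fit.slope)
    offset_next = float(fit.intercept)
    return RegressionSummary(
        interval=interval,
        slope_next=slope_next,
        offset_next=offset_next,
        slope_delta=slope_next - 1.0,
        offset_delta=offset_next,
        offset_norm=offset_next / mean_size if mean_size else np.nan,
        r_squared=float(fit.rvalue**2),
        mean_size=mean_size,
    )


def delta_pairs(traj, t0: int, interval: int):
    """Per-synapse (S(t0), dS) pairs underlying the regression."""
    s0, s1 = _pairs(traj, t0, interval)
    return s0, s1 - s0


def regression_vs_interval(traj, t0: int, max_interval: int, step: int = 1):
    """Regression summaries for intervals 1..max_interval (DataFrame)."""
    rows = [
        delta_regression(traj, t0, T)
        for T in range(step, max_interval + 1, step)
    ]
    return pd.DataFrame(
        {
            "interval": [r.interval for r in rows],
            "slope": [r.slope_next for r in rows],
            "offset": [r.offset_next for r in rows],
            "offset_norm": [r.offset_norm for r in rows],
            "slope_delta": [r.slope_delta for r in rows],
            "r_squared": [r.r_squared for r in rows],
        }
    )
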