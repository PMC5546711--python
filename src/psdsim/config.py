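"""Run configuration: a YAML-serializable bundle of model, geometry,
run and analysis settings with validation and full defaults.

An empty config resolves to the canonical study conditions: bidirectional
cooperativity with lambda_off = 0.5, lambda_on = 0.493, alpha = 0.0007 on a
50x50 lattice with 8 neighbors, 3500 synapses over 1500 steps from an
empty start, with a 900-step burn-in for stationary analyses.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .params import (
    DEFAULT_BURN_IN,
    DEFAULT_COLS,
    DEFAULT_N_STEPS,
    DEFAULT_N_SYNAPSES,
    DEFAULT_ROWS,
    KineticParams,
    NeighborSpec,
)

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    params: KineticParams = field(default_factory=KineticParams)
    spec: NeighborSpec = field(default_factory=NeighborSpec)
    rows: int = DEFAULT_ROWS
    cols: int = DEFAULT_COLS
    n_synapses: int = DEFAULT_N_SYNAPSES
    n_steps: int = DEFAULT_N_STEPS
    seed: int = 0
    burn_in: int = DEFAULT_BURN_IN
    snapshot_times: tuple = ()
    initial: str | float = "empty"
    # analysis settings
    bins: int | str = "auto"
    r_max: int = 10
    min_cluster_size: int = 15

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("lattice dimensions must be >= 1")
        if self.n_synapses < 1 or self.n_steps < 1:
            raise ValueError("n_synapses and n_steps must be >= 1")
        if self.burn_in < 0 or self.burn_in > self.n_steps:
            raise ValueError("burn_in must lie in [0, n_steps]")
        if any(t < 0 or t > self.n_steps for t in self.snapshot_times):
            raise ValueError("snapshot times must lie in [0, n_steps]")
        if self.r_max < 1 or self.min_cluster_size < 1:
            raise ValueError("r_max and min_cluster_size must be >= 1")

    def to_dict(self) -> dict:
        return {
            "model": asdict(self.params),
            "geometry": {
                "rows": self.rows,
                "cols": self.cols,
                "neighbors": asdict(self.spec),
            },
            "run": {
                "n_synapses": self.n_synapses,
                "n_steps": self.n_steps,
                "seed": self.seed,
                "burn_in": self.burn_in,
                "snapshot_times": list(self.snapshot_times),
                "initial": self.initial,
            },
            "analysis": {
                "bins": self.bins,
                "r_max": self.r_max,
                "min_cluster_size": self.min_cluster_size,
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {"model", "geometry", "run", "analysis"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        model = dict(data.get("model") or {})
        geom = dict(data.get("geometry") or {})
        run = dict(data.get("run") or {})
        analysis = dict(data.get("analysis") or {})
        params = KineticParams(**_only(model, KineticParams))
        spec = NeighborSpec(**_only(dict(geom.get("neighbors") or {}), NeighborSpec))
        kwargs = dict(
            params=params,
            spec=spec,
            rows=int(geom.get("rows", DEFAULT_ROWS)),
            cols=int(geom.get("cols", DEFAULT_COLS)),
            n_synapses=int(run.get("n_synapses", DEFAULT_N_SYNAPSES)),
            n_steps=int(run.get("n_steps", DEFAULT_N_STEPS)),
            seed=int(run.get("seed", 0)),
            burn_in=int(run.get("burn_in", DEFAULT_BURN_IN)),
            snapshot_times=tuple(run.get("snapshot_times", ()) or ()),
            initial=run.get("initial", "empty"),
            bins=analysis.get("bins", "auto"),
            r_max=int(analysis.get("r_max", 10)),
            min_cluster_size=int(analysis.get("min_cluster_size", 15)),
        )
        return cls(**kwargs)


def _only(d: dict, cls) -> dict:
    fields = set(cls.__dataclass_fields__)
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return d


def load_config(path) -> RunConfig:
    """Read a YAML run configuration; missing keys fall back to defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
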