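# psdsim

Stochastic lattice models of cooperative scaffold-protein binding at the
postsynaptic density (PSD).

Synapses are dynamic molecular assemblies: scaffold proteins such as PSD-95
continuously bind to and unbind from a confined patch of postsynaptic
membrane, yet synaptic populations maintain stable, rightward-skewed size
distributions that rescale under perturbations, and individual PSDs are
organized into a handful of short-lived nanoclusters. `psdsim` implements a
mesoscopic model family that ties these population-level features to the
microscopic kinetics, for computational neuroscientists and biophysicists
studying synaptic tenacity and remodeling.

## The model

The PSD is a bounded grid of `M = rows × cols` binding sites; synaptic size
`S` is the number of occupied sites. Each time step Δt, every site flips
state stochastically with probabilities set by the local fraction χ of
occupied nearest neighbors (8-neighborhood by default, χ always divided by
the maximal neighbor count):

| model           | k_on            | k_off           |
|-----------------|-----------------|-----------------|
| `langmuir`      | α               | β               |
| `contact`       | λ_on·χ + α      | β               |
| `bidirectional` | λ_on·χ + α      | λ_off·(1−χ) + β |

All sites update synchronously from the pre-step configuration. The default
parameters (λ_off = 0.5, λ_on = 0.493, α = 0.0007, Δt = 1, 50×50 lattice)
put the bidirectional model in the cooperativity-dominated regime,
`C = (λ_on + λ_off)/α ≈ 1419 ≫ 1`, where stationary size distributions are
broad and skewed; the mean-field occupancy fixed point is
`s* = α/(λ_off − λ_on) = 0.1`, stable precisely when `α < λ_off − λ_on`.

Beyond the simulator, the package provides:

- **meanfield** — the rate equation ds/dt = k_on(s)(1−s) − k_off(s)s, its
  fixed points and stability, and the cooperativity ratio C;
- **master_equation** — the globally coupled variant (χ → S/M) as a
  birth–death chain with exact stationary solution and a Fokker–Planck
  approximation, plus scans of stationary skewness versus C;
- **ensemble_stats** — size distributions, mean/SD standardization for
  scaling collapse, skewness, and regressions of S(t₀+T) on S(t₀);
- **spatial** — spatial autocorrelation g(r) and nanocluster detection by
  single-linkage clustering with a mean-NN+2SD dendrogram cutoff;
- **pool** — a shared-molecule-pool variant in which all synapses of a cell
  compete for a finite reservoir, making the cooperative binding rate
  self-tuning;
- **fixtures / io / cli** — synthetic ground-truth lattices, CSV/YAML I/O,
  and a `psdsim` command-line tool (`simulate`, `meanfield`, `fp-scan`,
  `analyze`, `autocorr`, `clusters`, `fixtures`).

## Worked example

```python
import numpy as np
from psdsim import (KineticParams, simulate_ensemble, detect_nanoclusters,
                    sample_skewness, cooperativity_ratio)

params = KineticParams()           # bidirectional model, default rates
traj = simulate_ensemble(params, n_synapses=100, n_steps=1500,
                         master_seed=1, snapshot_times=(1500,))
plateau = traj.sizes[:, 1000:].mean()
skew = sample_skewness(traj.sizes[:, -1])
clusters = np.mean([detect_nanoclusters(g).n_clusters
                    for g in traj.snapshots[1500]])
print(f"C = {cooperativity_ratio(params):.1f}")
print(f"stationary mean size = {plateau:.1f} molecules")
print(f"size-distribution skewness = {skew:.2f}")
print(f"nanoclusters per synapse = {clusters:.2f}")
```

Output:

```
C = 1418.6
stationary mean size = 211.8 molecules
size-distribution skewness = 1.08
nanoclusters per synapse = 3.35
```

Starting from an empty lattice, growth plateaus after roughly 900 steps at
about 210-230 bound molecules — below the mean-field prediction of 250 because
local occupancy correlations make the effective χ seen by bound molecules
higher than the global average. The stationary distribution is clearly
right-skewed (a Langmuir control at matched mean would give skewness ≈ 0),
and bound molecules organize into ~3.5 nanoclusters per synapse.

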