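# Methods

## Model

The postsynaptic density is represented as a bounded rectangular lattice of
`M = rows × cols` binding sites for a single scaffold species. A site is
either vacant or occupied; synaptic size `S(t)` is the number of occupied
sites. Per unit time, a vacant site binds a molecule with rate `k_on` and an
occupied site releases one with rate `k_off`. Cooperativity enters through
the neighbor fraction χ — the number of occupied nearest neighbors divided
by the maximal neighbor count:

- `langmuir`: `k_on = α`, `k_off = β` (independent sites; stationary sizes
  are exactly Binomial(M, α/(α+β)));
- `contact`: `k_on = λ_on·χ + α`, `k_off = β` (cooperative binding only;
  with α = 0 the empty lattice is absorbing);
- `bidirectional`: `k_on = λ_on·χ + α`, `k_off = λ_off·(1−χ) + β`
  (cooperative binding *and* unbinding).

Assumptions: one molecular species; no in-plane diffusion (molecules appear
from and vanish to an implicit well-mixed pool); linear dependence of the
rates on χ; a rigid, non-periodic lattice.

### Discrete-time update

At each step all sites evaluate χ on the current configuration, convert
rates to per-step probabilities `p = clip(rate·Δt, 0, 1)` (an exponential
waiting-time form `1 − exp(−rate·Δt)` is available via
`KineticParams(prob_rule="exponential")`), and flip when `p` exceeds an
independent uniform draw. Updates are synchronous: flips are applied
simultaneously, which makes trajectories order-independent and exactly
reproducible. Halving Δt while doubling the step count leaves stationary
means unchanged within Monte Carlo error (tested).

### Boundary convention

χ always divides by the maximal neighbor count (8 for the Moore
neighborhood, 4 for von Neumann), so sites beyond the boundary count as
permanently vacant neighbors. This is the convention that yields the
canonical stationary mean (~220 of 2500 sites at default parameters). The
alternative — dividing by the number of in-bounds neighbors — makes the
boundary sticky (more binding, less unbinding at edges) and raises the
stationary mean by roughly 70%; it is available via
`NeighborSpec(full_denominator=False)` but is not the default.

### Parameters and defaults

| parameter | default | units | meaning |
|-----------|---------|-------|---------|
| λ_on      | 0.493   | 1/time | maximal cooperative binding rate |
| λ_off     | 0.5     | 1/time | maximal cooperative unbinding rate |
| α         | 0.0007  | 1/time | non-cooperative (seeding) binding |
| β         | 0       | 1/time | non-cooperative unbinding |
| Δt        | 1       | time  | step duration |
| lattice   | 50×50   | sites | ~PSD diameter / molecule size |
| neighbors | moore8  |       | 8-site neighborhood |

The regime λ_on ≲ λ_off with α tiny puts the model where an interior
mean-field fixed point `s* = α/(λ_off − λ_on)` exists (stability condition
`α < λ_off − λ_on`) and cooperative kinetics dominate
(`C = (λ_on + λ_off)/α ≈ 1419`). β = 0 in simulations; the analytic
treatment below needs β > 0.

All ensembles start from an all-vacant lattice (the seeding term α
nucleates growth); the growth transient plateaus after ~900 steps, so
stationary analyses use steps ≥ 1000 of 1500-step runs. Random numbers come
from counter-based Philox streams; synapse `i` of an ensemble uses the
substream spawned from `(master_seed, i)`, so any single trajectory can be
regenerated in isolation.

## Mean-field and global-cooperativity analyses

Replacing χ by the global occupancy fraction `s = S/M` gives the rate
equation `ds/dt = k_on(s)(1−s) − k_off(s)s`. Roots in [0, 1] are located by
a 4001-point scan plus Brent refinement (tolerance 1e-10) and classified by
the sign of the derivative (|d rhs/ds| < 1e-9 is reported as marginal).

With global coupling the size is a birth–death chain on {0..M} with
`W⁺(S) = (M−S)(λ_on S/M + α)` and `W⁻(S) = S(λ_off(1−S/M) + β)`. Its exact
stationary law is the detailed-balance product, computed as a cumulative
sum of log rate-ratios and normalized with logsumexp; β > 0 is required
(β = 0 makes S = M absorbing), and the canonical analytic choice is β = α.
The Fokker–Planck approximation uses drift `A = W⁺ − W⁻` and diffusion
`D = (W⁺ + W⁻)/2`, giving `p(x) ∝ exp(∫₀ˣ A/D)/D`, integrated by the
trapezoid rule on a grid of 10 points per site and read off at integer
sizes (the density is smooth on the single-site scale; aggregating grid
points into unit bins instead introduces a rounding sawtooth that dominates
the error). Agreement with the exact chain is within total-variation
distance 2e-4 for M = 500 across C from 0.1 to 1000.

Cooperativity scans hold α (and β = α) fixed, keep λ_on/λ_off at the
default ratio 0.493/0.5, and scale λ_on + λ_off = C·α. Skewness of a
distribution is computed from its exact moments, not from samples.

## Shared molecule pool

In the pool variant all synapses of a cell draw on one reservoir of
`N_total` molecules, and the cooperative binding rate of a vacant site is
`N_free·λ*_on·χ + α` with `N_free = N_total − N_bound` updated every step.
The seeding term α is deliberately *not* multiplied by `N_free`: at
realistic pool sizes (`N_free ≈ λ_off/λ*_on = 10⁵` for the default
`λ*_on = 5·10⁻⁶`) a pool-scaled α would saturate every per-step binding
probability and abolish the self-tuning equilibrium the variant exists to
demonstrate; the literal pool-scaled form is available via
`scale_alpha=True`. If more sites attempt to bind in one step than there
are free molecules, a uniformly random subset of attempts of size `N_free`
succeeds, so molecule number is conserved exactly. The diagnostic output
`λ_on_effective = N_free·λ*_on` settles close to λ_off over a several-fold
range of `N_total` while the mean synaptic size grows linearly with the
pool.

## Statistical analyses

- **Distributions**: histogram PDFs (mass normalized to 1) and exact step
  CDFs. Scaling collapse standardizes samples to mean 0, SD 1.
- **Skewness**: bias-uncorrected g1 = m₃/m₂^{3/2}; at ensemble sizes of
  hundreds to thousands the small-sample correction is negligible.
- **Size-change regressions**: ordinary least squares of both
  `S(t₀+T)` on `S(t₀)` and `ΔS = S(t₀+T) − S(t₀)` on `S(t₀)` (the two
  slopes differ by exactly 1 and share the offset); offsets are optionally
  normalized by the mean size over the window. Swept over T, slope and R²
  decay and the normalized offset rises toward the memoryless limit —
  trends assessed by Spearman rank correlation, not strict monotonicity.
- **Collapse metric**: two-sample KS distance between standardized
  samples, judged against the replicate-to-replicate KS baseline at fixed
  parameters (the collapse itself is a visual property; the baseline
  anchors the tolerance).

## Spatial analyses

- **Autocorrelation** g(r): for each occupied site, the fraction of
  in-bounds lattice sites at Euclidean distance r (unit-width annuli
  centered on integers, r = 0 excluded) that are occupied; averaged over
  occupied sites and divided by the overall density. Random placement gives
  g ≈ 1 (up to an O(1/N) conditioning bias); clustering gives g > 1 at
  short range. No periodic wrap.
- **Nanoclusters**: single-linkage agglomerative clustering (scipy) of the
  occupied coordinates, dendrogram cut at the mean nearest-neighbor
  distance + 2 SD (SD with n−1 denominator), per snapshot. Groups with
  fewer than `min_size = 15` sites count as sparse molecules, not
  clusters. The linkage method and the minimum size are not uniquely
  dictated by the underlying analysis description; single linkage is the
  natural reading of a dendrogram height cutoff, and min_size = 15 is
  calibrated so the default-parameter ensemble reproduces the reported
  ~3.4 ± 1.5 nanoclusters per synapse (min_size = 5 would give ≈ 7).
  Both are exposed as arguments, and counts are sensitive to min_size.
- **Tracking**: greedy maximal-overlap matching of nanoclusters between
  frames; unmatched clusters are flagged born/died.

## Synthetic fixtures

`generate_random_state` draws i.i.d. Bernoulli occupancy — the null for
g(r). `generate_planted_clusters` places well-separated Gaussian blobs of
occupied sites on a sparse background with the planted count recorded as
ground truth. These fixtures validate the spatial estimators; they do not
emulate the correlated, morphing structures the cooperative dynamics
produce, so estimator tests on fixtures complement (not replace) the
end-to-end simulation checks.

## Problem sizes and determinism

Ensemble analyses in the test suite and acceptance script use 500 synapses
(stationary mean, nanocluster count, regression trends), 300 synapses per
parameter value (scaling collapse), 250 synapses per pool size, and
M = 500 for the analytic scans — sizes at which the sampling error of each
reported quantity is several times smaller than the tolerance band it is
judged against. All randomness derives from explicit integer seeds; equal
seeds give bit-identical results on any platform with IEEE doubles.

## Known limitations

- Single species, rigid lattice, no lateral diffusion or multi-site
  molecular footprints.
- Linear rate-versus-χ kinetics; other cooperativity forms are out of
  scope.
- The discrete-time synchronous scheme with Δt = 1 allows per-step flip
  probabilities up to 0.5; it converges to the continuous-time master
  equation only as Δt → 0, and global-coupling comparisons against the
  exact chain are made at reduced Δt with generous tolerances.
- The nanocluster count depends on the unstated minimum-size filter (see
  above); conclusions should rest on trends, not its absolute value.
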