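# Methods

## Model and assumptions

The circuit is a fully connected network of `N` binary neurons with
symmetric binary synapses and no self-couplings.  It is not
biologically realistic: there are no separate excitatory/inhibitory
populations, no spiking, and the stimulus-driven and spontaneous
regimes are strictly exclusive (during stimulus presentation the
internal current is zero; during probing the external current,
plasticity and adaptation are off).  Stimuli are univariate, valued in
(0,1).

Discrete time is used throughout.  In the stimulus-driven stage one
time step is one trial (one stimulus presentation); the spontaneous
stage nominally steps at ~10 ms, but in a discrete synchronous update
this has no computational consequence and is not represented.

## Stimulus densities

`p(α) ∝ (Σ_{k=0}^{4} c_k cos(kπα))²`, with `c_k` i.i.d. standard
normal, normalised by trapezoidal quadrature on a uniform grid
(default 10⁴ points).  Squaring a truncated series guarantees a smooth
non-negative density; the cosine basis avoids artificial periodicity on
(0,1).  The coefficient law and basis are package choices — any smooth
density family would do, and `from_coefficients` accepts user-supplied
coefficients.  Sampling is by inverse-CDF interpolation on the grid,
deterministic given the random stream.  Densities of this family
typically have a few modes and touch zero at isolated points, which
matters for equalization timescales (below).

## Plasticity

Potentiation/depression probabilities `(1 ± x_i x_j)/2τ` mean exactly:
an aligned synapse (`J_ij = x_i x_j`) never changes; a misaligned one
flips with probability `1/τ`.  The implementation therefore draws
`K ~ Binomial(M, 1/τ)` of the `M = N(N−1)/2` upper-triangle pairs
uniformly (an `O(K)` distinct-subset draw) and assigns
`J_ij = J_ji = x_i x_j` there; the assignment is idempotent on aligned
pairs, so the per-pair transition law is reproduced exactly while the
per-trial cost drops from `O(N²)` to `O(N²/τ)`.  Symmetry is enforced
by construction (half the synapses are drawn, the mirror is assigned),
and the diagonal is never touched.  Draw order per trial: one uniform
for the stimulus, then the binomial count, then the subset indices —
one shared generator per simulation, so runs are bit-reproducible from
`(density_seed, sim_seed)`.

`τ ≥ 1` is required (probabilities stay in [0,1]).  The same τ is used
for plasticity and adaptation.

## Adaptation

`μ_i ← μ_i + [μ_i⁰ − Θ(μ_i − α)]/τ` with `Θ(z) = 1 for z ≥ 0` (the
value at exactly zero is a convention; the update is otherwise
undefined there).  Offsets are then re-sorted ascending — a full sort,
the closure of the pairwise-swap reordering; only the offsets are
permuted, `μ⁰` stays attached to the neuron index.  Offsets are not
clamped to (0,1): excursions are bounded by `1/τ` per step and
self-correcting.

The stationary point of the mean drift is `F(μ_i) = μ_i⁰`, i.e. the
offsets converge to the quantiles of the stimulus distribution — this
is the equalization mechanism that makes the effective stimulus
ensemble uniform.  Two finite-τ caveats, both confirmed in
simulation:

- *Relaxation is locally rate-limited by the density*: the linearised
  relaxation time of the quantile at `μ` is `τ/p(μ)`, so regions where
  `p` nearly vanishes converge much more slowly than τ.
- *A stationary fluctuation floor*: all offsets respond to the same
  stimulus stream, so empirical-CDF fluctuations do not average out
  across neurons; the stationary KS distance between offsets and
  stimulus CDF scales like `~1/√τ` and is essentially independent of
  N (measured: ~0.03–0.10 at τ=100, ~0.015–0.05 at τ=1000).  Offset
  equalization to KS < 0.05 is therefore reliable at τ ≈ 1000 but
  marginal at τ = 100 regardless of how long the simulation runs.

## Spontaneous dynamics and the attractor census

Probing uses the synchronous (parallel) update
`x' = sign(J x / 2N)` with the fixed convention `sign(0) = +1`; no
serial schedule is assumed, and for symmetric `J` parallel dynamics
settles into a fixed point or a 2-cycle (enforced empirically with a
`4N`-step cap; non-convergence is reported, never dropped).  2-cycles
are logged but excluded from the census, since an attractor is a state
that does not change between steps.

Initial conditions are all realisable retrieved patterns: the `N+1`
step patterns (sigmoidal tuning) or all half-ring rotations (periodic
tuning, one per constant-pattern arc of ν).  This is a superset of any
"several initial conditions" protocol and guarantees every conforming
attractor is found, since each is its own start.

**Classification.** At finite N, a stable state is generically a step
pattern with a small number of defect neurons near the step boundary:
there the mean internal current vanishes linearly in rank distance
(slope ~1/N) while the stochastic synaptic matrix contributes
`~1/√N` noise, so `O(√N)` boundary neurons sit at near-zero current
and freeze in noise-determined states.  Exact conformity to
`ξ_i(ν) = sign(ν − μ_i)` holds only in the large-N, large-τ limit.
Each recorded state is therefore labelled with the ν of its
minimum-Hamming retrieved pattern (computed in closed form for step
patterns, by candidate search over arcs for half-rings; ν is reported
as the midpoint of the admissible interval, with (0, μ₁) and (μ_N, 1)
at the boundaries); `conforming` flags an exact match and `defects`
counts the mismatched neurons.  States with more than
`2⌈√N⌉` defects are not retrieved patterns — most prominently the
global sign-flip twins of step attractors, which symmetric dynamics
always stabilises but which sit `O(N)` from every retrieved pattern —
and are tallied as spurious rather than recorded.  At very small N
(≲ 30) the two scales are not separated and the cap is conservative.

Attractors are distinct iff their binary patterns differ; ν is a
derived label.  For counting *attractor locations* early in learning —
when attractors are sparse and separated by `O(N)` — defect variants of
one retrieved pattern are merged by single-linkage clustering at the
same `2⌈√N⌉` Hamming radius.  At stationarity neighbouring attractors
are spaced `~N^(1/3)` apart, comparable to the defect scale, so no
merging is done there and the raw state count is the reported
quantity.

Probing is side-effect free; the state entering the next stimulus
block is exactly the state that left the previous one.

## Experiments and sweeps

A run is configured by `(N, T, τ, tuning, density_seed, sim_seed,
n_sessions, grid_size)`; `T` must be divisible by `n_sessions`
(default 10).  Sweeps derive per-cell/replicate seed pairs from a
master seed through `SeedSequence` spawn keys (counter-based, so
re-running a sweep assigns identical seeds and cells are independent).

Problem sizes used by the test suite and acceptance script — chosen so
each claim is measured at the smallest scale where it is stable:
session-1 locations at `N=1000, τ=1000, T=10⁴` (5 replicates); the
scaling sweep over `N ∈ {125, 250, 500, 1000}` with `τ=N`, `T=20τ`
(stationarity operationalised as `τ ≥ N` and `t ≥ 20τ`; counts
averaged over sessions 8–10 and 5 replicates); growth trends and
generative sampling at `N=500, T=10⁴` with 10 replicates.  Measured at
these scales: scaling exponent ≈ 0.56–0.58 (the `~2/3` law is an
asymptotic statement; the reduced sweep sits at its lower shoulder),
late-session pooled KS ≈ 0.03–0.05, session growth ratio ≈ 9 at
τ=1000.

## What the synthetic data does and does not show

All experiments are self-generated: the stimulus generator *is* the
study condition, and passing tests show that plasticity plus adaptation
sample the squared-Fourier density family under the stated protocol.
They do not show robustness to multivariate stimuli, temporally
correlated stimulus streams, asymmetric or graded synapses, mixed
regimes where internal and external currents act together, or
noise-driven transitions between attractors — none of which are
modelled.

## Known limitations

- Under a *sustained* single stimulus with adaptation active, all
  offsets collapse toward the stimulus and the evoked pattern's
  boundary oscillates indefinitely (the count of offsets below the
  stimulus hovers near N/2), so the synaptic matrix keeps churning in
  an `O(√N)` boundary band and never equals one pattern's outer sign
  structure exactly.  Exact absorption holds when the enforced activity
  is constant, which is how the sustained-stimulus check is
  implemented (plasticity steps at the pattern evoked at stimulus
  onset).
- Offset equalization at τ=100 is limited by the `~1/√τ` stationary
  fluctuation floor described above.
- The defect cap and location-merging radius share one `2⌈√N⌉` scale;
  it separates defect variants from sign-flip twins cleanly for
  N ≳ 100 but is heuristic at toy sizes.
- `find_fixed_point` counts the update that confirms stability, so an
  already-stable start reports `steps = 1`.
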