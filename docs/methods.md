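# Methods

## The model

`drifthmm` treats a locus's population allele frequency `q(t)` as the latent
state of a hidden Markov model and the Pool-Seq read counts as its
observations. At sampling generation `t_k` a locus contributes the data pair
`D(t_k) = {n(t_k), C(t_k)}` — variant reads and total depth — linked to the
latent frequency by a binomial emission

    P(D(t_k) | q(t_k)) = Binom(n(t_k); C(t_k), q(t_k)).

Between sampling instants the frequency evolves under one of two drift
kernels:

- **Wright–Fisher (parameter N).** Each generation resamples 2N gene copies
  binomially from the current frequency. The one-generation kernel on the
  frequency grid is exact; the inter-sample propagator is its `Δt`-th matrix
  power. Drift variance is frequency dependent, `q(1−q)/2N` per generation,
  and the boundaries 0 and 1 are naturally absorbing.
- **Gaussian diffusion (parameter σ_G).** Additive normal increments with a
  frequency-independent per-generation standard deviation σ_G. The
  inter-sample kernel is analytic: a normal of standard deviation
  σ_Δt = σ_G·√Δt, truncated at ±3σ_Δt, with the mass falling below 0 (Π₀)
  or above 1 (Π₁) assigned to absorbing boundary states and the row
  renormalized. Sources at 0 or 1 are exact fixed points.

The marginal likelihood of a trajectory follows from the scaled forward
(predict–update) recursion; per-locus log likelihoods are summed over the
panel, and the scalar drift parameter (N or σ_G) is maximized by a bounded
derivative-free search. Model choice between the families uses the
likelihood difference per locus per sampling instant,

    delta_l = (log L_WF − log L_Gaussian) / (L · K),

with positive values favouring Wright–Fisher.

## Discretization

All distributions live as probability masses on an evenly spaced frequency
grid on [0, 1]; the default is 401 points (resolution 1/400). Integrals over
frequency are sums of point masses, so transition kernels are row-stochastic
matrices and no separate quadrature weights are needed. The default prior at
the first sampling instant is the uniform density discretized with trapezoid
weights — the endpoints represent half-width cells — which keeps
single-observation marginals (`∫ Binom(n; C, q) dq = 1/(C+1)`) accurate to
second order in the spacing; the first observation is scored against this
prior, so the likelihood sums over all K sampling instants. A delta prior at
a chosen frequency is available for sensitivity checks.

The Wright–Fisher row for source frequency `q_i` evaluates the binomial pmf
of 2N draws at the destination counts `2N·q_j`. When a destination count is
not an integer, the two flanking integer-count pmf values are combined with
inverse-distance weights (equivalent to linear interpolation in the count)
and the row is renormalized; the pmf itself is computed through log-gamma
functions, which makes every row — and hence the likelihood — a smooth
function of N. The optimizer therefore searches continuous N without integer
rounding, and the search runs on log θ with relative tolerance 1e−3
(bootstrap workloads use 1e−2; the likelihood is smooth and single-peaked in
all regimes we simulate, so the coarser tolerance costs well under a percent
in θ). Default bounds are N ∈ [50, 50000] and σ_G ∈ [1e−4, 0.5]; an optimum
within two tolerances of a bound is flagged in the diagnostics.

Matrix powers use binary powering with a final row renormalization to absorb
floating-point drift. Propagators are built once per distinct sampling gap
and shared across loci; loci sharing a schedule are filtered as one batched
matrix recursion, and emissions (which do not depend on θ) are precomputed
once per dataset and reused across all optimizer evaluations.

## Emission variants

Besides the simple binomial emission, a two-stage Pool-Seq emission is
available for experiments that sequence a finite pool of individuals: the
pool composition is drawn binomially from the population frequency
(`pool_genomes` genomes, default 1000, i.e. 500 diploid females) and reads
are then drawn binomially from the pool frequency. The marginal emission
sums over all pool compositions and converges to the simple binomial as the
pool grows.

## The simulator

The generator reproduces the study conditions under which the method is
characterized:

- **Neutral panels** (the default): independent loci, exact Wright–Fisher
  binomial resampling, starting frequency `q0 = 0.5`, `T = 300` generations
  sampled every `Δt = 10` at depth `C = 100`, `L = 300` loci. Population
  sizes of interest span [100, 5000].
- **Selection**: a `selected_fraction` of loci (1% or 10% in the standard
  designs) receive coefficients drawn uniformly from [−0.01, 0.01], applied
  each generation as the haploid relative-fitness update
  `q' = q(1+s)/(1+qs)` before resampling. This parametrization is standard
  for one-locus WF selection; at |s| ≤ 0.01 alternative forms are
  indistinguishable at our test tolerances.
- **Mutation**: per-copy Poisson flips in both directions — upward flips
  `~ Poisson(μ·(2N−k))`, downward `~ Poisson(μ·k)`, clipped to availability.
  This choice (rather than a count-independent Poisson flux) is what yields
  the Beta-shaped stationary law whose shape transition across
  μN ∈ {0.1, 0.5, 1, 10} the simulator is required to reproduce: spikes at
  the boundaries for small μN, a mode at 0.5 for large μN. Without mutation
  the boundaries are absorbing.
- **Gaussian panels**: per-generation normal increments of scale σ_G
  (0.006 and 0.018 are the reference scales), absorbed on first exit from
  (0, 1).
- **Linked panels**: a founder pool of haplotypes is generated by a neutral
  coalescent with recombination (msprime; Drosophila-scale rates
  μ = 3×10⁻⁹/bp/gen, ρ = 10⁻⁸/bp/gen) or read from an ms-format file. The
  starting population holds 2N/F copies of each of F founders (F = 20 by
  default) and is resampled multinomially each generation with no
  within-experiment recombination or mutation, so only founder types ever
  segregate and the copy-number vector over founders is a sufficient state.
- **Sequencing**: binomial reads at depth C each sampling instant, with the
  two-stage pool option; read noise is independent across loci even when
  latent frequencies coincide.

Per-locus randomness is spawned from the config seed independently of the
selection assignment, so two batches differing only in `selected_fraction`
share the noise of their unselected loci — bias-direction comparisons on
matched seeds are then nearly deterministic.

What the generator does not emulate: migration, within-experiment
recombination, combined linkage+mutation+selection scenarios, variable
depth across loci and instants, and sequencing error. Passing recovery
tests on these panels therefore shows that the estimator is correct under
its own assumptions and robust in the specific violation regimes tested,
not that real E&R data meet those assumptions.

## Experiment-scale analyses

The identifiability sweep simulates WF panels at each (N, T) cell, averages
delta_l over replicates, smooths along the T axis with an exponential
moving average (span 3 cells — the span is a free choice; smoothing exists
to stabilize contour extraction, not to alter levels), and extracts
threshold contours (0.01 and 0.05 by default) by linear interpolation on
(log₁₀ N, T). Failed cells are recorded as missing rather than aborting the
sweep.

The bootstrap resamples loci **with replacement** (the standard bootstrap;
an exact-subsample option exists so that fraction 1.0 without replacement
reproduces the point estimate bit-for-bit) in sets of `round(fraction·L)`
loci, 100 sets of a tenth of the loci by default, and summarizes the
resulting delta_l and parameter distributions as boxplot statistics
(median, quartiles, Tukey whiskers).

Fixed loci — observed at 0 or full depth at every instant — are retained by
default, since absorption events are themselves informative about the drift
model; `exclude_fixed` repeats the analysis without them as a sensitivity
check.

## Numerical choices and degenerate inputs

- Per-step normalization with log-space accumulation of the normalizers
  protects against underflow at high depth and many instants.
- An all-zero update weight (data impossible under the model, e.g. variant
  reads against a delta prior at 0) raises an error naming the locus and
  generation rather than returning −inf silently.
- Delta distributions snap to the nearest grid point, ties toward the lower
  index, for determinism.
- Noiseless constant-frequency data drives θ to the minimal-drift bound
  (largest N, smallest σ_G); this is flagged in diagnostics, not an error.
- The Gaussian kernel's ±3σ truncation makes a row's standard deviation
  ≈ 0.9866·σ_Δt (the truncated-normal factor); tests oracle against the
  truncated moments, not the untruncated normal.
- Transition-matrix row sums are enforced to 1 within 1e−9; forward and
  forward–backward marginals agree within 1e−9 by construction.

## Problem sizes

The validation suite runs the experiment-scale checks at L = 300–1000 loci
with 10 replicate panels per recovery design, 10⁶ draws for the
simulator/kernel goodness-of-fit, and 100 bootstrap resamples; these sizes
give comfortable statistical resolution for ±15% recovery bands and sign
checks while keeping a full run in the minutes range on one core.

## Known limitations

- The Wright–Fisher kernel lives on the fixed 401-point grid, not on the
  2N+1 count lattice; for very small N (≲ 25) the grid is finer than the
  lattice and interpolation smooths genuinely discrete structure.
- For very large N and short horizons the two drift families are genuinely
  indistinguishable (that regime is the point of the identifiability
  analysis); estimates near the bounds should be read as censored.
- The sweep's contour positions inherit simulation noise; increase
  `replicates_per_cell` for publication-quality contours.
- Inference assumes neutrality (μ = 0, s = 0); the bias analyses quantify
  the direction of the error when that assumption fails, not its size for
  arbitrary parameter values.
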