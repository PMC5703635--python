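# drifthmm

Hidden-Markov evaluation of genetic drift models in time-series
allele-frequency data.

Evolve-and-Resequence (E&R) experiments follow a population through time,
periodically Pool-Sequencing it so that each polymorphic locus yields a
trajectory of variant read counts `n(t_k)` out of depth `C(t_k)`. Two
questions arise from such data: **how strong is genetic drift** — i.e. what
effective population size N (or diffusion scale σ_G) explains the
frequency fluctuations — and **which drift model** actually describes the
dynamics: the discrete-generation Wright–Fisher process with its
frequency-dependent variance `q(1−q)/2N` and natural absorption at 0 and 1,
or a computationally cheaper Gaussian diffusion with additive,
frequency-independent noise.

`drifthmm` answers both with a continuous state-space HMM. The latent
frequency lives on a 401-point grid on [0, 1]; between sampling instants it
is propagated by either the exact Wright–Fisher kernel (the one-generation
binomial transition matrix raised to the Δt-th power, smooth in N so the
maximum-likelihood search never rounds) or the analytic Gaussian kernel
with absorbing boundaries; observations enter through a binomial (or
two-stage Pool-Seq) emission. The forward recursion gives each locus's
marginal log likelihood

    L(θ | D) = Σ_loci Σ_k log ∫ dq P(D(t_k) | q) P(q | D(t_1:k−1), θ),

maximized over θ = N or σ_G. Model choice uses the likelihood difference
per locus per sampling instant, `delta_l = (log L_WF − log L_Gauss)/(L·K)`;
positive values favour Wright–Fisher.

The package also ships the full simulation machinery used to characterize
the method — neutral/mutation/selection Wright–Fisher panels, Gaussian
panels, linked propagation from coalescent founder haplotypes, Pool-Seq
sampling — plus identifiability sweeps over (N, T), a locus bootstrap,
readers for popoolation2-style sync files and a simple trajectory TSV, and
a thin CLI (`drifthmm simulate|infer|compare|sweep|bootstrap`).

## Worked example

```python
from drifthmm import SimulationConfig, infer_drift_parameter, simulate_batch

cfg = SimulationConfig(N=400, q0=0.5, T=300, delta_t=10, C=100, L=300, seed=1)
batch = simulate_batch(cfg)
n_hat, log_lik, diag = infer_drift_parameter(batch.data, "WF")
print(n_hat, log_lik)
```

prints (see `examples/01_simulate_and_infer.py`):

```
true N           : 400
estimated N      : 409.1
log likelihood   : -31990.1
```

300 loci observed at depth 100 every 10 generations for 300 generations
recover the drift parameter to within ~2%: the read counts alone pin down
the effective size of the population that generated them.

Model comparison in the informative regime (small N, low starting
frequency; `examples/02_compare_drift_models.py`):

```
fitted WF size N^        : 99.0     (truth 100)
fitted Gaussian sigma_G^ : 0.0258
delta_l                  : +0.0150
```

`delta_l > 0` says the Wright–Fisher kernel fits each locus-instant better
than the best Gaussian diffusion — here by 0.015 nats per locus per
sampling instant, a decisive margin over a 200-locus panel. On Gaussian-simulated
data the sign flips; at large N and short T it collapses toward zero and
the models are not distinguishable.

The other examples cover posterior smoothing of single trajectories,
(N, T) identifiability sweeps with threshold contours, bootstrap
uncertainty, and linked founder-haplotype panels.

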