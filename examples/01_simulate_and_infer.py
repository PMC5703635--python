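"""Simulate a Wright-Fisher experiment and recover the population size.

A panel of 300 independent loci starts at frequency 0.5 in a population of
N=400 and drifts for 300 generations; every 10 generations the population
is Pool-Sequenced at depth 100.  Maximum-likelihood inference on the noisy
read counts should recover N to within a few percent.
"""

from drifthmm import SimulationConfig, infer_drift_parameter, simulate_batch

cfg = SimulationConfig(N=400, q0=0.5, T=300, delta_t=10, C=100, L=300, seed=1)
batch = simulate_batch(cfg)

n_hat, log_lik, diag = infer_drift_parameter(batch.data, "WF")

print(f"true N           : {cfg.N}")
print(f"estimated N      : {n_hat:.1f}")
print(f"log likelihood   : {log_lik:.1f}")
print(f"optimizer evals  : {diag['n_evaluations']}")
# n_hat is the effective size of the idealized Wright-Fisher population
# whose drift variance best explains the observed frequency changes.
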