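"""Forward simulation of allele-frequency time series with Pool-Seq sampling.

Covers every generative regime used to characterize drift-model
identifiability: neutral Wright-Fisher propagation, recurrent mutation,
uniform selection over a fraction of loci, multilocus propagation of linked
founder haplotypes, Gaussian diffusion with absorbing boundaries, and
binomial (optionally two-stage) sequencing of the population.

All randomness flows from a single seeded :class:`numpy.random.Generator`
per run; batch simulations always return the hidden truth (true frequency
paths, per-locus selection coefficients) alongside the observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hmm import AlleleTrajectory, TrajectorySet

__all__ = [
    "SimulationConfig",
    "HaplotypePopulation",
    "simulate_wf_path",
    "simulate_gaussian_path",
    "sample_sequencing",
    "generate_founder_haplotypes",
    "read_ms_haplotypes",
    "simulate_linked_population",
    "simulate_batch",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters for one simulation batch.

    Defaults reflect a typical Evolve-and-Resequence design: read depth
    C=100, sampling every 10 generations over T=300 generations, starting
    frequency 0.5.
    """

    N: int = 400
    q0: float = 0.5
    T: int = 300
    delta_t: int = 10
    C: int = 100
    L: int = 300
    mu: float = 0.0
    s_range: tuple[float, float] = (-0.01, 0.01)
    selected_fraction: float = 0.0
    F: int = 20
    n_founder_sequences: int = 2000
    rho: float = 1e-8
    seed: int = 0
    two_stage: bool = False
    pool_genomes: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.q0 <= 1.0:
            raise ValueError("q0 must lie in [0, 1]")
        if not (self.T >= self.delta_t >= 1):
            raise ValueError("need T >= delta_t >= 1")
        if self.L < 1:
            raise ValueError("need at least one locus")
        if not 0.0 <= self.selected_fraction <= 1.0:
            raise ValueError("selected_fraction must lie in [0, 1]")
        if self.N < 2:
            raise ValueError("population size must be >= 2")


@dataclass
class HaplotypePopulation:
    """Binary founder haplotypes: rows are genomes, columns are loci."""

    haplotypes: np.ndarray = field(repr=False)
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        H = np.asarray(self.haplotypes)
        if H.ndim != 2 or not np.isin(H, (0, 1)).all():
            raise ValueError("haplotypes must be a binary matrix")
        self.haplotypes = H.astype(np.int8)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (H.shape[1],):
            raise ValueError("positions must match the number of loci")

    @property
    def n_sequences(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_wf_path(
    N: int,
    q0: float,
    T: int,
    s: float = 0.0,
    mu: float = 0.0,
    seed=0,
) -> np.ndarray:
    """One Wright-Fisher frequency path over generations 0..T (length T+1).

    Each generation applies deterministic selection q' = q(1+s)/(1+qs),
    then per-copy Poisson mutation in both directions (counts of flips drawn
    as Poisson(mu * available copies), clipped to availability), then an
    exact Binomial(2N, q'') resampling.  Without mutation the boundaries are
    absorbing.
    """
    rng = _rng(seed)
    M = 2 * N
    path = np.empty(T + 1)
    path[0] = q0
    k = int(round(q0 * M))
    q = k / M if abs(k / M - q0) < 1e-12 else q0  # exact count when q0 is on the lattice
    for t in range(1, T + 1):
        if mu == 0.0 and (q <= 0.0 or q >= 1.0):
            path[t:] = round(q)
            return path
        q_sel = q * (1.0 + s) / (1.0 + q * s) if s != 0.0 else q
        count = q_sel * M
        if mu > 0.0:
            up = min(rng.poisson(mu * (M - count)), M - count)
            down = min(rng.poisson(mu * count), count)
            count = count + up - down
        q_prime = min(max(count / M, 0.0), 1.0)
        q = rng.binomial(M, q_prime) / M
        path[t] = q
    return path


def simulate_gaussian_path(sigma_g: float, q0: float, T: int, seed=0) -> np.ndarray:
    """Gaussian-diffusion path: additive N(0, sigma_g^2) increments,
    absorbed on first exit from (0, 1)."""
    if sigma_g <= 0:
        raise ValueError("sigma_g must be positive")
    rng = _rng(seed)
    path = np.empty(T + 1)
    path[0] = q0
    q = q0
    for t in range(1, T + 1):
        if q <= 0.0 or q >= 1.0:
            path[t:] = 0.0 if q <= 0.0 else 1.0
            return path
        q = q + rng.normal(0.0, sigma_g)
        q = min(max(q, 0.0), 1.0)
        path[t] = q
    return path


def sample_sequencing(
    path: np.ndarray,
    C: int,
    delta_t: int,
    seed=0,
    two_stage: bool = False,
    pool_genomes: int = 1000,
    locus_id: str = "locus_0",
) -> AlleleTrajectory:
    """Pool-Seq observation of a frequency path at every ``delta_t`` generations.

    Simple mode draws n ~ Binomial(C, q); two-stage mode first draws the
    pool composition n_hat ~ Binomial(pool_genomes, q) and then reads
    n ~ Binomial(C, n_hat/pool_genomes).
    """
    rng = _rng(seed)
    path = np.asarray(path, dtype=float)
    times = np.arange(0, path.size, delta_t)
    q = path[times]
    if two_stage:
        n_hat = rng.binomial(pool_genomes, q)
        n = rng.binomial(C, n_hat / pool_genomes)
    else:
        n = rng.binomial(C, q)
    return AlleleTrajectory(locus_id, tuple(times), tuple(n), tuple(np.full(times.size, C)))


# ---------------------------------------------------------------------------
# Founder haplotypes and linked propagation


def read_ms_haplotypes(path) -> HaplotypePopulation:
    """Parse the first sample block of an ms-format (Hudson) haplotype file."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    try:
        start = next(i for i, ln in enumerate(lines) if ln.startswith("//"))
    except StopIteration:
        raise ValueError(f"{path}: no '//' sample block found") from None
    positions = None
    haplos: list[list[int]] = []
    for ln in lines[start + 1 :]:
        if ln.startswith("segsites"):
            continue
        if ln.startswith("positions:"):
            positions = [float(x) for x in ln.split()[1:]]
            continue
        if ln.startswith("//"):
            break
        if ln and set(ln) <= {"0", "1"}:
            haplos.append([int(ch) for ch in ln])
    if not haplos:
        raise ValueError(f"{path}: no haplotype lines found")
    H = np.array(haplos, dtype=np.int8)
    if positions is None:
        positions = np.arange(H.shape[1], dtype=float)
    return _drop_monomorphic(HaplotypePopulation(H, np.asarray(positions)))


def _drop_monomorphic(pop: HaplotypePopulation) -> HaplotypePopulation:
    freq = pop.haplotypes.mean(axis=0)
    poly = (freq > 0) & (freq < 1)
    n_dropped = int((~poly).sum())
    if n_dropped:
        import logging

        logging.getLogger(__name__).info("dropped %d monomorphic loci", n_dropped)
    if not poly.any():
        raise ValueError("all founder loci are monomorphic")
    return HaplotypePopulation(pop.haplotypes[:, poly], pop.positions[poly])


def generate_founder_haplotypes(
    n_sequences: int = 2000,
    L: int = 5000,
    mu: float = 3e-9,
    rho: float = 1e-8,
    seed: int = 0,
    input_file=None,
    sequence_length: float | None = None,
) -> HaplotypePopulation:
    """Founder haplotype pool: read from an ms-format file, or simulate one.

    The internal generator runs a neutral coalescent with recombination
    (msprime) and keeps the first L polymorphic sites; the sequence length
    is chosen so the expected number of segregating sites comfortably
    exceeds L at the requested per-bp mutation rate.
    """
    if input_file is not None:
        return read_ms_haplotypes(input_file)

    import msprime  # deferred: only needed for internal founder generation

    # expected segregating sites: theta * harmonic(n-1); inflate by 1.5x
    harmonic = np.sum(1.0 / np.arange(1, n_sequences))
    Ne = 1e6  # Drosophila-scale coalescent effective size
    if sequence_length is None:
        sequence_length = max(1.5 * L / (4 * Ne * mu * harmonic), 1000.0)
    sequence_length = float(np.ceil(sequence_length))
    ts = msprime.sim_ancestry(
        samples=n_sequences // 2,
        population_size=Ne,
        recombination_rate=rho,
        sequence_length=sequence_length,
        random_seed=int(seed) % (2**31 - 1) + 1,
    )
    mts = msprime.sim_mutations(
        ts,
        rate=mu,
        random_seed=int(seed) % (2**31 - 1) + 2,
        model=msprime.BinaryMutationModel(),
    )
    H = mts.genotype_matrix().T  # (sequences, sites)
    H = np.minimum(H, 1).astype(np.int8)
    positions = np.array([s.position for s in mts.sites()])
    pop = _drop_monomorphic(HaplotypePopulation(H, positions))
    if pop.n_loci > L:
        pop = HaplotypePopulation(pop.haplotypes[:, :L], pop.positions[:L])
    return pop


def simulate_linked_population(
    founders: HaplotypePopulation,
    F: int,
    N: int,
    T: int,
    delta_t: int,
    C: int,
    seed=0,
    replicate_id: str | None = None,
    return_truth: bool = False,
):
    """Propagate a population founded from F haplotypes, fully linked.

    The starting population of 2N genomes holds 2N/F copies of each of F
    founder haplotypes drawn without replacement; every generation resamples
    2N genomes multinomially.  With no recombination or mutation only the F
    founder types ever exist, so the state is the copy-number vector over
    founders; per-locus frequencies follow by projection onto the founder
    allele matrix.  All loci are sequenced binomially at depth C every
    delta_t generations.
    """
    rng = _rng(seed)
    if F > founders.n_sequences:
        raise ValueError(f"F={F} exceeds the {founders.n_sequences} available founders")
    M = 2 * N
    copies, rem = divmod(M, F)
    if rem:
        import logging

        logging.getLogger(__name__).warning(
            "2N=%d not divisible by F=%d; first %d founders get an extra copy", M, F, rem
        )
    chosen = rng.choice(founders.n_sequences, size=F, replace=False)
    counts = np.full(F, copies, dtype=np.int64)
    counts[:rem] += 1

    Hf = founders.haplotypes[chosen].astype(float)  # (F, L)
    times = np.arange(0, T + 1, delta_t)
    sampled = {0: counts.copy()}
    for t in range(1, T + 1):
        counts = rng.multinomial(M, counts / M)
        if t in times:
            sampled[t] = counts.copy()

    trajs = []
    freqs = np.array([sampled[t] @ Hf / M for t in times])  # (K, L)
    n = rng.binomial(C, freqs)  # (K, L)
    for j in range(founders.n_loci):
        trajs.append(
            AlleleTrajectory(
                f"locus_{j}",
                tuple(times),
                tuple(n[:, j]),
                tuple(np.full(times.size, C)),
            )
        )
    out = TrajectorySet(trajs, replicate_id)
    return (out, freqs) if return_truth else out


# ---------------------------------------------------------------------------
# Batch orchestration


@dataclass
class BatchResult:
    """Observed trajectories plus the hidden generative truth."""

    data: TrajectorySet
    true_paths: np.ndarray  # (L, T+1) frequency paths
    selection_coefficients: np.ndarray  # (L,)
    config: SimulationConfig


def simulate_batch(config: SimulationConfig, family: str = "WF", sigma_g: float | None = None) -> BatchResult:
    """Independent-locus batch under the configured regime.

    With ``family="WF"`` each locus follows its own Wright-Fisher path with
    the configured mutation rate; a ``selected_fraction`` of loci (exact
    count, random placement) receive selection coefficients drawn uniformly
    from ``s_range``.  With ``family="Gaussian"`` loci follow Gaussian
    diffusion with scale ``sigma_g``.  Sequencing is binomial at depth C
    every delta_t generations.

    Per-locus randomness comes from seed streams spawned off the config
    seed independently of the selection assignment, so batches differing
    only in ``selected_fraction`` share the noise of their unselected loci.
    """
    L, T = config.L, config.T
    root = np.random.SeedSequence(config.seed)
    sel_ss, path_ss, seq_ss = root.spawn(3)

    s = np.zeros(L)
    n_sel = int(round(config.selected_fraction * L))
    if n_sel:
        sel_rng = np.random.default_rng(sel_ss)
        which = sel_rng.choice(L, size=n_sel, replace=False)
        s[which] = sel_rng.uniform(config.s_range[0], config.s_range[1], size=n_sel)

    path_seeds = path_ss.spawn(L)
    seq_seeds = seq_ss.spawn(L)
    paths = np.empty((L, T + 1))
    trajs = []
    for i in range(L):
        path_rng = np.random.default_rng(path_seeds[i])
        if family == "WF":
            paths[i] = simulate_wf_path(config.N, config.q0, T, s=s[i], mu=config.mu, seed=path_rng)
        elif family == "Gaussian":
            if sigma_g is None:
                raise ValueError("sigma_g required for a Gaussian batch")
            paths[i] = simulate_gaussian_path(sigma_g, config.q0, T, seed=path_rng)
        else:
            raise ValueError(f"unknown family {family!r}")
        trajs.append(
            sample_sequencing(
                paths[i],
                config.C,
                config.delta_t,
                seed=np.random.default_rng(seq_seeds[i]),
                two_stage=config.two_stage,
                pool_genomes=config.pool_genomes,
                locus_id=f"locus_{i}",
            )
        )
    return BatchResult(TrajectorySet(trajs), paths, s, config)
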