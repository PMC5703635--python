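"""Continuous state-space HMM for allele-frequency time series.

The latent state is the population allele frequency q(t), propagated between
sampling instants by a drift model (exact Wright-Fisher or Gaussian
diffusion) and observed through binomial read sampling at finite depth.
The forward (predict-update) recursion yields the marginal likelihood of a
trajectory; summing per-locus log likelihoods over a panel of loci gives the
objective maximized to estimate the drift parameter (N or sigma_G).

Emissions do not depend on the drift parameter, so they are precomputed once
per dataset and reused across likelihood evaluations during optimization;
loci sharing a sampling schedule are filtered as one batched matrix
recursion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import binom

from .gaussian import gaussian_propagator
from .grid import FrequencyGrid, GridDistribution, make_grid, uniform_distribution
from .wright_fisher import TransitionMatrix, wf_one_generation_matrix

__all__ = [
    "AlleleTrajectory",
    "TrajectorySet",
    "DriftModelSpec",
    "ForwardResult",
    "emission_probability",
    "emission_two_stage",
    "forward_filter",
    "forward_backward",
    "total_log_likelihood",
    "infer_drift_parameter",
    "DEFAULT_WF_BOUNDS",
    "DEFAULT_GAUSSIAN_BOUNDS",
]

EmissionMode = Literal["simple", "two_stage"]

DEFAULT_WF_BOUNDS = (50.0, 50_000.0)
DEFAULT_GAUSSIAN_BOUNDS = (1e-4, 0.5)
DEFAULT_POOL_GENOMES = 1000


class DegenerateLikelihoodError(RuntimeError):
    """All-zero update weight: the data are impossible under the model."""


@dataclass(frozen=True)
class AlleleTrajectory:
    """Observed (variant reads, total depth) pairs for one locus over time."""

    locus_id: str
    times: tuple[int, ...]
    n: tuple[int, ...]
    C: tuple[int, ...]

    def __post_init__(self) -> None:
        times = tuple(int(t) for t in self.times)
        n = tuple(int(v) for v in self.n)
        C = tuple(int(v) for v in self.C)
        if not (len(times) == len(n) == len(C)) or len(times) < 1:
            raise ValueError("times, n, C must be equal-length and non-empty")
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("sampling generations must be strictly increasing")
        if any(ni < 0 or Ci < 0 or ni > Ci for ni, Ci in zip(n, C)):
            raise ValueError(f"locus {self.locus_id}: need 0 <= n <= C at every time")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "C", C)

    @property
    def n_times(self) -> int:
        return len(self.times)

    def observed_frequencies(self) -> np.ndarray:
        C = np.asarray(self.C, dtype=float)
        return np.where(C > 0, np.asarray(self.n, dtype=float) / np.maximum(C, 1), 0.0)

    def is_fixed(self) -> bool:
        """True when every sample is all-reference or all-variant reads."""
        return all(ni == 0 for ni in self.n) or all(ni == Ci for ni, Ci in zip(self.n, self.C))


@dataclass
class TrajectorySet:
    """A panel of locus trajectories, optionally tagged with a replicate label."""

    trajectories: list[AlleleTrajectory]
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        self.trajectories = list(self.trajectories)
        if not self.trajectories:
            raise ValueError("a TrajectorySet must contain at least one trajectory")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    @property
    def n_loci(self) -> int:
        return len(self.trajectories)

    def n_sampling_instants(self) -> int:
        """Maximum number of sampling instants across loci (K)."""
        return max(t.n_times for t in self.trajectories)

    def without_fixed(self) -> "TrajectorySet":
        """Drop loci observed at 0 or C reads at every sampling instant."""
        kept = [t for t in self.trajectories if not t.is_fixed()]
        if not kept:
            raise ValueError("all loci are fixed; nothing left to analyse")
        return TrajectorySet(kept, self.replicate_id)

    def subset(self, indices: Sequence[int]) -> "TrajectorySet":
        return TrajectorySet([self.trajectories[i] for i in indices], self.replicate_id)


@dataclass(frozen=True)
class DriftModelSpec:
    """Drift model family plus its scalar parameter (N or sigma_G)."""

    family: Literal["WF", "Gaussian"]
    theta: float

    def __post_init__(self) -> None:
        if self.family not in ("WF", "Gaussian"):
            raise ValueError(f"unknown drift family {self.family!r}")
        if self.family == "WF" and self.theta < 2:
            raise ValueError("WF population size must be >= 2")
        if self.family == "Gaussian" and self.theta <= 0:
            raise ValueError("sigma_G must be positive")

    def propagators(
        self, delta_ts: Iterable[int], grid: FrequencyGrid
    ) -> dict[int, TransitionMatrix]:
        """Build the interval propagator for each distinct sampling gap.

        For WF the one-generation kernel is built once and powered per
        interval; the Gaussian kernel is analytic per interval.
        """
        delta_ts = sorted(set(int(d) for d in delta_ts))
        out: dict[int, TransitionMatrix] = {}
        if self.family == "WF":
            one = wf_one_generation_matrix(self.theta, grid)
            for dt in delta_ts:
                if dt == 1:
                    out[dt] = one
                    continue
                R = np.linalg.matrix_power(one.rows, dt)
                np.maximum(R, 0.0, out=R)
                R /= R.sum(axis=1, keepdims=True)
                out[dt] = TransitionMatrix(grid, dt, R, "WF", self.theta)
        else:
            for dt in delta_ts:
                out[dt] = gaussian_propagator(self.theta, dt, grid)
        return out


@dataclass
class ForwardResult:
    """Total and per-locus forward log likelihoods, plus optional filtered states."""

    log_likelihood: float
    per_locus_log_likelihood: dict[str, float]
    filtered: list[GridDistribution] | None = None


# ---------------------------------------------------------------------------
# Emission models


def emission_probability(n: int, C: int, q) -> np.ndarray | float:
    """Binomial read-sampling emission P(n | C, q); vectorized over q."""
    if n < 0 or n > C:
        raise ValueError(f"need 0 <= n <= C, got n={n}, C={C}")
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("frequency outside [0, 1]")
    out = binom.pmf(n, C, q)
    return float(out) if out.ndim == 0 else out


def emission_two_stage(
    n: int, C: int, q, pool_genomes: int = DEFAULT_POOL_GENOMES
) -> np.ndarray | float:
    """Two-stage Pool-Seq emission: genomes sampled into the pool, then reads.

    Marginalizes the intermediate pool frequency q_hat = n_hat/pool_genomes:
    P(n | C, q) = sum_{n_hat} Binom(n_hat; pool_genomes, q) Binom(n; C, n_hat/pool_genomes).
    """
    if pool_genomes < 1:
        raise ValueError("pool_genomes must be >= 1")
    if n < 0 or n > C:
        raise ValueError(f"need 0 <= n <= C, got n={n}, C={C}")
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("frequency outside [0, 1]")
    n_hat = np.arange(pool_genomes + 1)
    read_pmf = binom.pmf(n, C, n_hat / pool_genomes)  # (P+1,)
    pool_pmf = binom.pmf(n_hat[None, :], pool_genomes, q.reshape(-1, 1))  # (Q, P+1)
    out = pool_pmf @ read_pmf
    return float(out[0]) if np.ndim(q) == 0 else out.reshape(np.shape(q))


def _emission_matrix(
    n: np.ndarray,
    C: np.ndarray,
    grid: FrequencyGrid,
    mode: EmissionMode,
    pool_genomes: int,
) -> np.ndarray:
    """Per-locus emission vectors over the grid for one sampling instant."""
    q = grid.points
    if mode == "simple":
        return binom.pmf(n[:, None], C[:, None], q[None, :])
    if mode == "two_stage":
        n_hat = np.arange(pool_genomes + 1)
        pool_pmf = binom.pmf(n_hat[None, :], pool_genomes, q[:, None])  # (G, P+1)
        read_pmf = binom.pmf(n[:, None], C[:, None], (n_hat / pool_genomes)[None, :])
        return read_pmf @ pool_pmf.T
    raise ValueError(f"unknown emission mode {mode!r}")


# ---------------------------------------------------------------------------
# Grouped data: emissions precomputed once, reused across theta evaluations


class _GroupedData:
    """Loci grouped by sampling schedule with precomputed emission matrices."""

    def __init__(
        self,
        data: TrajectorySet,
        grid: FrequencyGrid,
        emission_mode: EmissionMode = "simple",
        pool_genomes: int = DEFAULT_POOL_GENOMES,
    ) -> None:
        self.grid = grid
        self.groups: list[dict] = []
        by_times: dict[tuple[int, ...], list[AlleleTrajectory]] = {}
        for traj in data:
            by_times.setdefault(traj.times, []).append(traj)
        for times, trajs in by_times.items():
            n = np.array([t.n for t in trajs])  # (L, K)
            C = np.array([t.C for t in trajs])
            emissions = [
                _emission_matrix(n[:, k], C[:, k], grid, emission_mode, pool_genomes)
                for k in range(len(times))
            ]
            self.groups.append(
                {
                    "times": times,
                    "delta_ts": tuple(np.diff(times).tolist()),
                    "locus_ids": [t.locus_id for t in trajs],
                    "emissions": emissions,  # list of (L, G) arrays per instant
                }
            )

    def delta_ts(self) -> set[int]:
        out: set[int] = set()
        for g in self.groups:
            out.update(g["delta_ts"])
        return out


def _forward_group(
    group: dict,
    propagators: dict[int, TransitionMatrix],
    prior_mass: np.ndarray,
    keep_filtered: bool = False,
):
    """Batched scaled forward recursion for one schedule group.

    Returns (per-locus log likelihood, filtered masses per instant or None).
    Each update's normalizer is accumulated in log space, including the
    first observation scored against the prior.
    """
    emissions = group["emissions"]
    L = emissions[0].shape[0]
    ll = np.zeros(L)
    filtered: list[np.ndarray] | None = [] if keep_filtered else None

    f = prior_mass[None, :] * emissions[0]
    for k in range(len(emissions)):
        if k > 0:
            dt = group["delta_ts"][k - 1]
            f = (f @ propagators[dt].rows) * emissions[k]
        norm = f.sum(axis=1)
        if np.any(norm <= 0):
            bad = int(np.argmax(norm <= 0))
            raise DegenerateLikelihoodError(
                f"zero likelihood at locus {group['locus_ids'][bad]}, "
                f"generation {group['times'][k]}"
            )
        ll += np.log(norm)
        f = f / norm[:, None]
        if filtered is not None:
            filtered.append(f.copy())
    return ll, filtered


def _resolve_prior(
    prior: GridDistribution | str | None, grid: FrequencyGrid
) -> np.ndarray:
    if prior is None or prior == "uniform":
        return uniform_distribution(grid).mass
    if isinstance(prior, GridDistribution):
        if prior.grid != grid:
            raise ValueError("prior grid does not match the working grid")
        return prior.mass
    raise ValueError(f"unknown prior rule {prior!r}")


# ---------------------------------------------------------------------------
# Public forward / smoothing / likelihood API


def forward_filter(
    traj: AlleleTrajectory,
    model: DriftModelSpec,
    grid: FrequencyGrid | None = None,
    prior: GridDistribution | str | None = None,
    emission_mode: EmissionMode = "simple",
    pool_genomes: int = DEFAULT_POOL_GENOMES,
    keep_filtered: bool = True,
) -> ForwardResult:
    """Predict-update filtering of a single locus trajectory.

    Returns the marginal log likelihood and (optionally) the filtered
    frequency distribution at each sampling instant.
    """
    grid = grid or make_grid()
    grouped = _GroupedData(TrajectorySet([traj]), grid, emission_mode, pool_genomes)
    props = model.propagators(grouped.delta_ts(), grid)
    prior_mass = _resolve_prior(prior, grid)
    ll, filtered = _forward_group(grouped.groups[0], props, prior_mass, keep_filtered)
    dists = [GridDistribution(grid, m[0]) for m in filtered] if filtered else None
    return ForwardResult(float(ll[0]), {traj.locus_id: float(ll[0])}, dists)


def forward_backward(
    traj: AlleleTrajectory,
    model: DriftModelSpec,
    grid: FrequencyGrid | None = None,
    prior: GridDistribution | str | None = None,
    emission_mode: EmissionMode = "simple",
    pool_genomes: int = DEFAULT_POOL_GENOMES,
) -> list[GridDistribution]:
    """Smoothed posteriors P(q(t_k) | all data) for one trajectory."""
    grid = grid or make_grid()
    grouped = _GroupedData(TrajectorySet([traj]), grid, emission_mode, pool_genomes)
    group = grouped.groups[0]
    props = model.propagators(grouped.delta_ts(), grid)
    prior_mass = _resolve_prior(prior, grid)
    _, filtered = _forward_group(group, props, prior_mass, keep_filtered=True)
    assert filtered is not None

    K = len(group["emissions"])
    G = grid.n_points
    beta = np.ones(G)
    posteriors: list[np.ndarray] = [np.empty(G)] * K
    for k in range(K - 1, -1, -1):
        post = filtered[k][0] * beta
        posteriors[k] = post / post.sum()
        if k > 0:
            dt = group["delta_ts"][k - 1]
            msg = (group["emissions"][k][0] * beta) @ propagator_transpose(props[dt])
            beta = msg / msg.max()  # scale for stability only
    return [GridDistribution(grid, p) for p in posteriors]


def propagator_transpose(tm: TransitionMatrix) -> np.ndarray:
    return tm.rows.T


def total_log_likelihood(
    data: TrajectorySet,
    model: DriftModelSpec,
    grid: FrequencyGrid | None = None,
    prior_rule: GridDistribution | str | None = None,
    emission_mode: EmissionMode = "simple",
    pool_genomes: int = DEFAULT_POOL_GENOMES,
) -> ForwardResult:
    """Sum of per-locus forward log likelihoods over a trajectory panel.

    Propagators are built once per distinct sampling gap and shared across
    loci.
    """
    grid = grid or make_grid()
    grouped = _GroupedData(data, grid, emission_mode, pool_genomes)
    return _total_from_grouped(grouped, model, prior_rule)


def _total_from_grouped(
    grouped: _GroupedData,
    model: DriftModelSpec,
    prior_rule: GridDistribution | str | None = None,
) -> ForwardResult:
    props = model.propagators(grouped.delta_ts(), grouped.grid)
    prior_mass = _resolve_prior(prior_rule, grouped.grid)
    per_locus: dict[str, float] = {}
    total = 0.0
    for group in grouped.groups:
        ll, _ = _forward_group(group, props, prior_mass)
        total += float(ll.sum())
        per_locus.update(zip(group["locus_ids"], ll.astype(float)))
    return ForwardResult(total, per_locus)


def infer_drift_parameter(
    data: TrajectorySet,
    family: Literal["WF", "Gaussian"],
    bounds: tuple[float, float] | None = None,
    grid: FrequencyGrid | None = None,
    emission_mode: EmissionMode = "simple",
    prior_rule: GridDistribution | str | None = None,
    pool_genomes: int = DEFAULT_POOL_GENOMES,
    rel_tol: float = 1e-3,
) -> tuple[float, float, dict]:
    """Maximum-likelihood estimate of the drift parameter for one family.

    A bounded scalar search is run on log(theta) (Brent-type, derivative
    free); for WF the continuous optimum uses the interpolated-N kernel, so
    N is never rounded during the search.  Returns (theta_hat, max log
    likelihood, diagnostics); an optimum pinned at a bound is flagged in the
    diagnostics rather than raised.
    """
    if bounds is None:
        bounds = DEFAULT_WF_BOUNDS if family == "WF" else DEFAULT_GAUSSIAN_BOUNDS
    lo, hi = bounds
    if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
        raise ValueError(f"bounds must be finite, positive and ordered, got {bounds}")
    grid = grid or make_grid()
    grouped = _GroupedData(data, grid, emission_mode, pool_genomes)

    n_evals = 0

    def negloglik(x: float) -> float:
        nonlocal n_evals
        n_evals += 1
        model = DriftModelSpec(family, float(np.exp(x)))
        ll = _total_from_grouped(grouped, model, prior_rule).log_likelihood
        if not np.isfinite(ll):
            raise RuntimeError(f"non-finite likelihood at theta={np.exp(x)}")
        return -ll

    res = minimize_scalar(
        negloglik,
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": rel_tol},
    )
    theta_hat = float(np.exp(res.x))
    margin = 2.0 * rel_tol
    at_bound = theta_hat <= lo * (1 + margin) or theta_hat >= hi * (1 - margin)
    diagnostics = {
        "family": family,
        "n_evaluations": n_evals,
        "converged": bool(res.success),
        "at_bound": at_bound,
        "bounds": (float(lo), float(hi)),
    }
    return theta_hat, float(-res.fun), diagnostics
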