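"""Exact Wright-Fisher transition matrices on the frequency grid.

The one-generation kernel is the binomial law of 2N draws at the source
frequency, evaluated at the destination grid frequencies: row ``i`` of the
matrix is ``Binom(2N * q_j ; 2N, q_i)`` over destinations ``j``, renormalized.
When ``2N * q_j`` is not an integer the two nearest integer-count pmf values
are combined with inverse-distance weights; the pmf itself is evaluated
through log-gamma functions so the construction is continuous in N, which the
likelihood optimizer relies on.  Multi-generation propagators are integer
matrix powers of the one-generation kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .grid import FrequencyGrid, GridDistribution

__all__ = [
    "WrightFisherParams",
    "TransitionMatrix",
    "wf_one_generation_matrix",
    "wf_propagator",
    "wf_moments",
    "clear_propagator_cache",
]

ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class WrightFisherParams:
    """Wright-Fisher population parameters.

    N is the (haploid-equivalent 2N genomes) population size; mu the
    per-copy per-generation mutation probability; s a selection coefficient.
    Inference always runs the neutral kernel (mu=0, s=0); mu and s exist for
    the simulator and moment utilities.
    """

    N: float
    mu: float = 0.0
    s: float = 0.0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"population size must be >= 2, got {self.N}")
        if not 0.0 <= self.mu < 1.0:
            raise ValueError(f"mutation rate must be in [0, 1), got {self.mu}")
        if abs(self.s) >= 1.0:
            raise ValueError(f"|s| must be < 1, got {self.s}")


@dataclass
class TransitionMatrix:
    """Row-stochastic grid-to-grid propagator for one inter-sample interval.

    ``rows[i, j]`` is the probability of moving from grid frequency ``q_i``
    to ``q_j`` over ``delta_t`` generations. ``model_tag`` is ``"WF"`` or
    ``"Gaussian"``; ``theta`` the drift parameter (N or sigma_G).
    """

    grid: FrequencyGrid
    delta_t: int
    rows: np.ndarray = field(repr=False)
    model_tag: str = "WF"
    theta: float = 0.0

    def __post_init__(self) -> None:
        R = np.asarray(self.rows, dtype=float)
        G = self.grid.n_points
        if R.shape != (G, G):
            raise ValueError("transition matrix shape does not match grid")
        if np.any(R < 0):
            raise ValueError("negative transition probability")
        sums = R.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > ROW_SUM_TOL):
            raise ValueError("rows are not stochastic")
        self.rows = R

    def propagate(self, dist: GridDistribution) -> GridDistribution:
        """Push a distribution forward through the matrix (one interval)."""
        out = dist.mass @ self.rows
        return GridDistribution(self.grid, out / out.sum())


def _binom_logpmf(k: np.ndarray, n: float, p: np.ndarray) -> np.ndarray:
    """log Binom(k; n, p) via log-gamma; valid for non-integer n and k >= 0.

    p must be strictly inside (0, 1); boundary p handled by the caller.
    """
    k = np.asarray(k, dtype=float)
    return (
        gammaln(n + 1.0)
        - gammaln(k + 1.0)
        - gammaln(n - k + 1.0)
        + k * np.log(p)
        + (n - k) * np.log1p(-p)
    )


def wf_one_generation_matrix(N: float, grid: FrequencyGrid) -> TransitionMatrix:
    """Exact one-generation Wright-Fisher kernel on ``grid``.

    Row ``i`` evaluates the binomial pmf of 2N draws with success probability
    ``q_i`` at the destination counts ``2N * q_j``; non-integral counts are
    interpolated inverse-distance between the flanking integer counts, and
    each row is renormalized.  Sources q=0 and q=1 are exactly absorbing.
    """
    if N < 2:
        raise ValueError(f"population size must be >= 2, got {N}")
    q = grid.points
    G = grid.n_points
    M = 2.0 * N  # number of genomes drawn each generation

    c = M * q  # target counts at destination grid points, possibly non-integral
    k_lo = np.floor(c)
    frac = c - k_lo
    # inverse-distance weights between floor and ceil counts; exact hits get
    # full weight on the floor value
    w_hi = frac
    w_lo = 1.0 - frac
    k_hi = np.minimum(k_lo + 1.0, np.floor(M))

    interior = (q > 0.0) & (q < 1.0)
    p = q[interior][:, None]  # source success probabilities, strictly interior

    pmf_lo = np.exp(_binom_logpmf(k_lo[None, :], M, p))
    pmf_hi = np.exp(_binom_logpmf(k_hi[None, :], M, p))
    rows_int = w_lo[None, :] * pmf_lo + w_hi[None, :] * pmf_hi
    rows_int /= rows_int.sum(axis=1, keepdims=True)

    R = np.zeros((G, G))
    R[interior] = rows_int
    R[0, 0] = 1.0
    R[-1, -1] = 1.0
    return TransitionMatrix(grid, 1, R, model_tag="WF", theta=float(N))


_PROPAGATOR_CACHE: dict[tuple[float, int, int], TransitionMatrix] = {}


def clear_propagator_cache() -> None:
    _PROPAGATOR_CACHE.clear()


def wf_propagator(
    N: float, delta_t: int, grid: FrequencyGrid, *, cache: bool = True
) -> TransitionMatrix:
    """Wright-Fisher propagator over ``delta_t`` generations.

    The one-generation kernel raised to the ``delta_t`` power (binary
    powering), rows renormalized to absorb floating-point drift. Results are
    memoized by (N, delta_t, grid size); the cache is transparent.
    """
    if int(delta_t) != delta_t or delta_t < 1:
        raise ValueError(f"delta_t must be a positive integer, got {delta_t}")
    delta_t = int(delta_t)
    key = (float(N), delta_t, grid.n_points)
    if cache and key in _PROPAGATOR_CACHE:
        return _PROPAGATOR_CACHE[key]
    if cache and len(_PROPAGATOR_CACHE) >= 64:  # bound memory during sweeps
        _PROPAGATOR_CACHE.pop(next(iter(_PROPAGATOR_CACHE)))

    one = wf_one_generation_matrix(N, grid)
    if delta_t == 1:
        out = one
    else:
        R = np.linalg.matrix_power(one.rows, delta_t)
        np.maximum(R, 0.0, out=R)
        R /= R.sum(axis=1, keepdims=True)
        out = TransitionMatrix(grid, delta_t, R, model_tag="WF", theta=float(N))
    if cache:
        _PROPAGATOR_CACHE[key] = out
    return out


def wf_moments(q0: float, N: float, t: float) -> tuple[float, float]:
    """Closed-form neutral Wright-Fisher moments after ``t`` generations.

    mean = q0; variance = q0 (1 - q0) (1 - (1 - 1/(2N))^t).
    """
    if not 0.0 <= q0 <= 1.0:
        raise ValueError("q0 outside [0, 1]")
    var = q0 * (1.0 - q0) * (1.0 - (1.0 - 1.0 / (2.0 * N)) ** t)
    return q0, var
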