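"""Gaussian-diffusion propagator with absorbing boundaries at 0 and 1.

The interval kernel is the analytic solution of the pure-diffusion
Fokker-Planck equation: a normal increment with standard deviation
``sigma_dt = sigma_g * sqrt(delta_t)``, truncated to a +/- 3 sigma window.
The normal mass falling below 0 (Pi_0) is assigned to the absorbed state
q=0, the mass above 1 (Pi_1) to q=1, and each row is renormalized to absorb
the truncation of the tails.  Unlike the Wright-Fisher kernel the increment
variance does not depend on the current frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .grid import FrequencyGrid
from .wright_fisher import TransitionMatrix

__all__ = ["GaussianParams", "gaussian_row", "gaussian_propagator"]


@dataclass(frozen=True)
class GaussianParams:
    """Per-generation diffusion scale sigma_g (frequency units per sqrt-generation)."""

    sigma_g: float

    def __post_init__(self) -> None:
        if self.sigma_g <= 0:
            raise ValueError(f"sigma_g must be positive, got {self.sigma_g}")

    def interval_sd(self, delta_t: float) -> float:
        """Standard deviation accumulated over delta_t generations."""
        return self.sigma_g * np.sqrt(delta_t)


def _gaussian_rows(
    sigma_dt: float, grid: FrequencyGrid
) -> np.ndarray:
    """All-source Gaussian rows for one interval sd, vectorized."""
    q = grid.points
    G = grid.n_points
    h = grid.resolution

    R = np.zeros((G, G))
    interior = (q > 0.0) & (q < 1.0)
    src = q[interior][:, None]  # column of interior source frequencies

    diff = q[None, :] - src
    window = np.abs(diff) < 3.0 * sigma_dt
    dest_interior = (q > 0.0) & (q < 1.0)
    dens = norm.pdf(diff, scale=sigma_dt) * h
    dens = np.where(window & dest_interior[None, :], dens, 0.0)

    # absorbed mass: normal CDF below 0 (down to the -3 sigma window edge)
    # and above 1 (up to the +3 sigma edge)
    lo_edge = src - 3.0 * sigma_dt
    hi_edge = src + 3.0 * sigma_dt
    pi0 = np.where(
        lo_edge < 0.0,
        norm.cdf(0.0, loc=src, scale=sigma_dt) - norm.cdf(lo_edge, loc=src, scale=sigma_dt),
        0.0,
    ).ravel()
    pi1 = np.where(
        hi_edge > 1.0,
        norm.cdf(hi_edge, loc=src, scale=sigma_dt) - norm.cdf(1.0, loc=src, scale=sigma_dt),
        0.0,
    ).ravel()

    rows = dens
    rows[:, 0] += pi0
    rows[:, -1] += pi1
    rows /= rows.sum(axis=1, keepdims=True)

    R[interior] = rows
    R[0, 0] = 1.0
    R[-1, -1] = 1.0
    return R


def gaussian_row(
    q_from: float, sigma_g: float, delta_t: float, grid: FrequencyGrid
) -> np.ndarray:
    """One propagator row: distribution over destinations from ``q_from``.

    Boundary sources are exactly absorbing; interior sources receive the
    discretized truncated normal plus the Pi_0/Pi_1 boundary masses.
    """
    if sigma_g <= 0:
        raise ValueError(f"sigma_g must be positive, got {sigma_g}")
    if not 0.0 <= q_from <= 1.0:
        raise ValueError(f"q_from {q_from} outside [0, 1]")

    idx = grid.nearest_index(q_from)
    if q_from in (0.0, 1.0):
        row = np.zeros(grid.n_points)
        row[idx] = 1.0
        return row
    # evaluate on a source grid point; off-grid q_from snaps to nearest point
    sigma_dt = sigma_g * np.sqrt(delta_t)
    return _gaussian_rows(sigma_dt, grid)[idx]


def gaussian_propagator(
    sigma_g: float, delta_t: float, grid: FrequencyGrid
) -> TransitionMatrix:
    """Assemble the full row-stochastic Gaussian propagator for one interval.

    One analytic step covers the whole inter-sample interval; no
    per-generation chaining is needed.
    """
    if sigma_g <= 0:
        raise ValueError(f"sigma_g must be positive, got {sigma_g}")
    if delta_t < 1:
        raise ValueError(f"delta_t must be >= 1, got {delta_t}")
    sigma_dt = sigma_g * np.sqrt(delta_t)
    R = _gaussian_rows(sigma_dt, grid)
    return TransitionMatrix(grid, int(delta_t), R, model_tag="Gaussian", theta=float(sigma_g))
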