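"""Discrete frequency state space shared by the propagators and the HMM.

All distributions over allele frequency live on an evenly spaced grid on
[0, 1] (default 401 points, i.e. resolution 1/400) and are stored as
probability *masses* per grid point, not densities, so integrals over
frequency reduce to plain sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrequencyGrid", "GridDistribution", "make_grid", "delta_distribution"]

DEFAULT_N_POINTS = 401

MASS_TOL = 1e-9


@dataclass(frozen=True)
class FrequencyGrid:
    """Evenly spaced frequencies on [0, 1], endpoints included."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size < 3:
            raise ValueError("a frequency grid needs at least 3 points")
        if pts[0] != 0.0 or pts[-1] != 1.0:
            raise ValueError("grid must span [0, 1] exactly")
        spacing = np.diff(pts)
        if np.any(np.abs(spacing - spacing[0]) > 1e-12):
            raise ValueError("grid spacing must be uniform")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.size

    @property
    def resolution(self) -> float:
        """Spacing between adjacent grid points, 1/(n_points - 1)."""
        return 1.0 / (self.n_points - 1)

    def nearest_index(self, q: float) -> int:
        """Index of the grid point nearest to ``q``; ties go to the lower index."""
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"frequency {q} outside [0, 1]")
        d = np.abs(self.points - q)
        return int(np.argmin(d))  # argmin takes the first (lower) index on ties

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_points

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FrequencyGrid) and self.n_points == other.n_points

    def __hash__(self) -> int:
        return hash(("FrequencyGrid", self.n_points))


@dataclass
class GridDistribution:
    """Probability masses over the points of a :class:`FrequencyGrid`."""

    grid: FrequencyGrid
    mass: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.mass, dtype=float)
        if m.shape != (self.grid.n_points,):
            raise ValueError("mass vector does not match grid size")
        if np.any(m < 0):
            raise ValueError("negative probability mass")
        if abs(m.sum() - 1.0) > MASS_TOL:
            raise ValueError(f"mass sums to {m.sum()!r}, not 1")
        self.mass = m

    def mean(self) -> float:
        return float(self.mass @ self.grid.points)

    def variance(self) -> float:
        mu = self.mean()
        return float(self.mass @ (self.grid.points - mu) ** 2)

    def renormalized(self) -> "GridDistribution":
        total = self.mass.sum()
        if total <= 0:
            raise ValueError("cannot renormalize a zero distribution")
        return GridDistribution(self.grid, self.mass / total)


def make_grid(n_points: int = DEFAULT_N_POINTS) -> FrequencyGrid:
    """Build an evenly spaced frequency grid on [0, 1] with ``n_points`` points.

    The default 401-point grid has resolution 1/400; tests may use tiny grids.
    """
    if int(n_points) != n_points or n_points < 3:
        raise ValueError(f"n_points must be an integer >= 3, got {n_points}")
    n_points = int(n_points)
    pts = np.linspace(0.0, 1.0, n_points)
    pts[0], pts[-1] = 0.0, 1.0
    return FrequencyGrid(pts)


def uniform_distribution(grid: FrequencyGrid) -> GridDistribution:
    """Uniform density on [0, 1] discretized on the grid.

    Masses are proportional to the cell width each point represents, so the
    endpoints carry half weight (trapezoid rule); sums of point masses then
    approximate integrals of smooth functions to second order in the
    spacing.
    """
    w = np.full(grid.n_points, grid.resolution)
    w[0] = w[-1] = grid.resolution / 2.0
    return GridDistribution(grid, w / w.sum())


def delta_distribution(grid: FrequencyGrid, q: float) -> GridDistribution:
    """All mass on the grid point nearest ``q`` (ties toward the lower index)."""
    idx = grid.nearest_index(q)
    m = np.zeros(grid.n_points)
    m[idx] = 1.0
    return GridDistribution(grid, m)
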