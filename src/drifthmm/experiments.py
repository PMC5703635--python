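"""Model comparison and identifiability analyses.

The headline analysis asks which drift model better explains a panel of
allele-frequency trajectories: both families are fitted by maximum
likelihood and compared through the likelihood difference per locus per
sampling instant,

    delta_l = (logL_WF - logL_Gaussian) / (L * K),

positive values favouring Wright-Fisher.  An identifiability sweep maps
delta_l over (population size, experiment duration) cells and extracts
threshold contours; a locus bootstrap quantifies estimate uncertainty for
experimental-scale panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import FrequencyGrid, make_grid
from .hmm import (
    DEFAULT_GAUSSIAN_BOUNDS,
    DEFAULT_WF_BOUNDS,
    EmissionMode,
    TrajectorySet,
    infer_drift_parameter,
)
from .simulate import SimulationConfig, simulate_batch

__all__ = [
    "ModelComparisonResult",
    "IdentifiabilitySurface",
    "compare_models",
    "identifiability_sweep",
    "bootstrap_estimates",
    "extract_contour",
    "ema_smooth",
]


@dataclass
class ModelComparisonResult:
    """Both model fits on one dataset and their per-locus-per-instant gap."""

    n_hat: float
    sigma_hat: float
    logL_wf: float
    logL_gauss: float
    n_loci: int
    n_instants: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def delta_l(self) -> float:
        """(logL_WF - logL_Gaussian) / (n_loci * n_instants); > 0 favours WF."""
        return (self.logL_wf - self.logL_gauss) / (self.n_loci * self.n_instants)


@dataclass
class IdentifiabilitySurface:
    """Mean delta_l over an (N, T) sweep plus extracted threshold contours."""

    n_values: np.ndarray
    t_values: np.ndarray
    delta_l_grid: np.ndarray  # shape (len(n_values), len(t_values))
    contours: dict[float, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.n_values = np.asarray(self.n_values, dtype=float)
        self.t_values = np.asarray(self.t_values, dtype=float)
        self.delta_l_grid = np.asarray(self.delta_l_grid, dtype=float)
        if self.delta_l_grid.shape != (self.n_values.size, self.t_values.size):
            raise ValueError("delta_l_grid shape does not match the sweep axes")


def compare_models(
    data: TrajectorySet,
    grid: FrequencyGrid | None = None,
    bounds_wf: tuple[float, float] = DEFAULT_WF_BOUNDS,
    bounds_gauss: tuple[float, float] = DEFAULT_GAUSSIAN_BOUNDS,
    emission_mode: EmissionMode = "simple",
    exclude_fixed: bool = False,
    rel_tol: float = 1e-3,
) -> ModelComparisonResult:
    """Fit WF and Gaussian drift independently and report delta_l.

    ``exclude_fixed`` drops loci observed at 0 or full depth at every
    sampling instant before fitting (sensitivity analysis; fixation events
    are themselves informative about the drift model).
    """
    if exclude_fixed:
        data = data.without_fixed()
    grid = grid or make_grid()
    n_hat, ll_wf, diag_wf = infer_drift_parameter(
        data, "WF", bounds_wf, grid, emission_mode, rel_tol=rel_tol
    )
    sigma_hat, ll_g, diag_g = infer_drift_parameter(
        data, "Gaussian", bounds_gauss, grid, emission_mode, rel_tol=rel_tol
    )
    return ModelComparisonResult(
        n_hat=n_hat,
        sigma_hat=sigma_hat,
        logL_wf=ll_wf,
        logL_gauss=ll_g,
        n_loci=data.n_loci,
        n_instants=data.n_sampling_instants(),
        diagnostics={"WF": diag_wf, "Gaussian": diag_g},
    )


def ema_smooth(values: np.ndarray, span: int = 3) -> np.ndarray:
    """Exponential-moving-average smoothing along the last axis."""
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    smoothed = pd.DataFrame(arr.T).ewm(span=span, adjust=True).mean().to_numpy().T
    return smoothed.reshape(np.shape(values))


def extract_contour(
    x_values: np.ndarray,
    y_values: np.ndarray,
    surface: np.ndarray,
    level: float,
) -> np.ndarray:
    """Level-set points of ``surface`` (rows indexed by x, columns by y).

    For each x row, every sign change of (surface - level) along y is
    located by linear interpolation; returns an array of (x, y) crossing
    points (possibly empty).
    """
    x_values = np.asarray(x_values, dtype=float)
    y_values = np.asarray(y_values, dtype=float)
    pts = []
    for i, x in enumerate(x_values):
        row = surface[i] - level
        for j in range(row.size - 1):
            a, b = row[j], row[j + 1]
            if a == 0.0:
                pts.append((x, y_values[j]))
            elif a * b < 0:
                frac = a / (a - b)
                pts.append((x, y_values[j] + frac * (y_values[j + 1] - y_values[j])))
        if row[-1] == 0.0:
            pts.append((x, y_values[-1]))
    return np.array(pts).reshape(-1, 2)


def identifiability_sweep(
    n_values,
    t_values,
    replicates_per_cell: int = 1,
    base_config: SimulationConfig | None = None,
    threshold_levels=(0.01, 0.05),
    grid: FrequencyGrid | None = None,
    ema_span: int = 3,
    rel_tol: float = 1e-3,
    seed: int = 0,
) -> IdentifiabilitySurface:
    """Map mean delta_l over (N, T) cells of WF-simulated data.

    Each cell simulates ``replicates_per_cell`` WF datasets from
    ``base_config`` (with N and T overridden), runs :func:`compare_models`
    and averages delta_l.  The surface is smoothed with an exponential
    moving average along the T axis before threshold contours are extracted
    on (log10 N, T) by linear interpolation.  Cells where optimization
    fails are recorded as NaN.
    """
    from dataclasses import replace

    n_values = np.asarray(list(n_values), dtype=float)
    t_values = np.asarray(list(t_values), dtype=float)
    if n_values.size == 0 or t_values.size == 0 or replicates_per_cell < 1:
        raise ValueError("sweep axes must be non-empty with replicates >= 1")
    base_config = base_config or SimulationConfig()
    grid = grid or make_grid()
    rng = np.random.default_rng(seed)

    surface = np.full((n_values.size, t_values.size), np.nan)
    for i, N in enumerate(n_values):
        for j, T in enumerate(t_values):
            vals = []
            for _ in range(replicates_per_cell):
                cfg = replace(
                    base_config,
                    N=int(N),
                    T=int(T),
                    seed=int(rng.integers(2**31 - 1)),
                )
                try:
                    batch = simulate_batch(cfg, family="WF")
                    res = compare_models(batch.data, grid, rel_tol=rel_tol)
                    vals.append(res.delta_l)
                except (RuntimeError, ValueError):  # record failed cells as missing
                    continue
            if vals:
                surface[i, j] = float(np.mean(vals))

    smoothed = ema_smooth(surface, span=ema_span)
    contours = {
        float(level): extract_contour(np.log10(n_values), t_values, smoothed, level)
        for level in threshold_levels
    }
    return IdentifiabilitySurface(n_values, t_values, surface, contours)


@dataclass
class BootstrapResult:
    """Bootstrap distributions of delta_l and the WF size estimate."""

    delta_l: np.ndarray
    n_hat: np.ndarray
    sigma_hat: np.ndarray

    def boxplot_summary(self) -> dict[str, dict[str, float]]:
        """Median, quartiles and Tukey whiskers for each statistic."""
        out = {}
        for name, vals in (("delta_l", self.delta_l), ("n_hat", self.n_hat), ("sigma_hat", self.sigma_hat)):
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            lo = vals[vals >= q1 - 1.5 * iqr].min()
            hi = vals[vals <= q3 + 1.5 * iqr].max()
            out[name] = {
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "whisker_low": float(lo),
                "whisker_high": float(hi),
            }
        return out


def bootstrap_estimates(
    data: TrajectorySet,
    fraction: float = 0.1,
    n_boot: int = 100,
    seed: int = 0,
    grid: FrequencyGrid | None = None,
    bounds_wf: tuple[float, float] = DEFAULT_WF_BOUNDS,
    bounds_gauss: tuple[float, float] = DEFAULT_GAUSSIAN_BOUNDS,
    with_replacement: bool = True,
    emission_mode: EmissionMode = "simple",
    rel_tol: float = 1e-3,
) -> BootstrapResult:
    """Locus bootstrap of the model comparison.

    Draws ``n_boot`` sets of round(fraction * L) loci (with replacement by
    default; ``with_replacement=False`` with fraction=1 reproduces the point
    estimate exactly) and re-runs :func:`compare_models` on each.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    L = data.n_loci
    m = int(round(fraction * L))
    if m < 1:
        raise ValueError(f"fraction {fraction} of {L} loci leaves no loci to resample")
    grid = grid or make_grid()
    rng = np.random.default_rng(seed)

    dl, nh, sh = [], [], []
    for _ in range(n_boot):
        if with_replacement:
            idx = rng.integers(0, L, size=m)
        else:
            idx = rng.permutation(L)[:m] if m < L else np.arange(L)
        res = compare_models(
            data.subset(idx), grid, bounds_wf, bounds_gauss, emission_mode, rel_tol=rel_tol
        )
        dl.append(res.delta_l)
        nh.append(res.n_hat)
        sh.append(res.sigma_hat)
    return BootstrapResult(np.array(dl), np.array(nh), np.array(sh))
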