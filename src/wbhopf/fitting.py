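"""Grid-search fitting of the whole-brain model to a target FCD.

Two stages mirror the study design:

* **Baseline fit** — constant bifurcation parameter ``a`` and global coupling
  ``G`` swept on a grid (study grid: a from -0.1 to 0.1 step 0.01, G from 0 to
  2 step 0.1), scored against the pre-injection FCD block.
* **Temporal fit** — with (a0, G) fixed, the gamma-schedule parameters
  (lambda, beta) swept on a grid (study grid: lambda 0..200 step 5, beta
  20..900 step 20), scored against the full-session FCD.  The whole sweep is
  repeated with fresh noise realizations, yielding a distribution of
  per-repeat optima whose means and 95% CIs summarize a condition.

Scoring per cell: ``runs_per_cell`` stochastic sessions are simulated, their
FCD matrices averaged, and the normalized Frobenius distance to the target is
computed (average-then-distance, not distance-then-average).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .dynamics import (
    BifurcationSchedule,
    BOLDLikeSeries,
    Connectome,
    ConstantPostSchedule,
    FrequencyTable,
    IntegrationDivergenceError,
    ParameterError,
    SimConfig,
    simulate,
)
from .fcd import FCDMatrix, WindowSpec, compute_fcd, fcd_distance

__all__ = [
    "GridResult",
    "ConditionComparison",
    "grid_axis",
    "fit_baseline",
    "fit_temporal",
    "fit_constant_null",
    "compare_conditions",
]


def grid_axis(lo: float, hi: float, step: float) -> np.ndarray:
    """Inclusive arithmetic grid lo, lo+step, ..., hi."""
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


@dataclass(frozen=True)
class GridResult:
    """Outcome of an exhaustive grid search.

    ``surface`` holds mean distances with shape (len(axis1), len(axis2)) —
    axis order matches ``param_names`` — averaged over runs (and over repeats
    for the temporal fit).  ``optima`` lists the per-repeat argmin parameter
    pairs; ``optimum`` is the argmin of the mean surface.  Ties are broken
    toward the smallest first parameter, then the smallest second.
    """

    param_names: tuple[str, ...]
    axes: tuple[np.ndarray, ...]
    surface: np.ndarray
    optima: tuple[tuple[float, ...], ...]
    n_runs: int

    @property
    def optimum(self) -> tuple[float, ...]:
        return _argmin_params(self.surface, self.axes)


def _argmin_params(surface: np.ndarray, axes: tuple[np.ndarray, ...]) -> tuple[float, ...]:
    """Argmin with NaN cells excluded; ties break to the lowest flat index,
    i.e. smallest first axis value then smallest second."""
    flat = surface.ravel()
    if np.all(np.isnan(flat)):
        raise ParameterError("all grid cells diverged; no optimum")
    idx = np.nanargmin(flat)
    unraveled = np.unravel_index(idx, surface.shape)
    return tuple(float(ax[i]) for ax, i in zip(axes, unraveled))


def _cell_seed(master: int, repeat: int, cell: int, run: int) -> np.random.SeedSequence:
    # counter-based substream: reproducible and order-independent
    return np.random.SeedSequence(entropy=master, spawn_key=(repeat, cell, run))


def _mean_fcd_distance(
    net: Connectome,
    freqs: FrequencyTable,
    sched,
    cfg: SimConfig,
    target: FCDMatrix,
    runs: int,
    seeds: list[int],
) -> float:
    """Average `runs` simulated FCDs, return normalized distance to target.

    Returns NaN if any run diverges (cell flagged, excluded from argmin)."""
    acc = None
    for k in range(runs):
        try:
            series = simulate(net, freqs, sched, replace(cfg, seed=seeds[k]))
        except IntegrationDivergenceError as exc:
            warnings.warn(f"cell excluded, simulation diverged: {exc}")
            return float("nan")
        f = compute_fcd(series, target.spec)
        acc = f.values if acc is None else acc + f.values
    mean_fcd = acc / runs
    if mean_fcd.shape != target.values.shape:
        raise ParameterError(
            f"simulated FCD shape {mean_fcd.shape} does not match target {target.values.shape}; "
            "check duration/window settings"
        )
    return fcd_distance(mean_fcd, target.values, normalized=True)


def _derive_seeds(master: int, repeat: int, cell: int, runs: int) -> list[int]:
    return [int(_cell_seed(master, repeat, cell, k).generate_state(1)[0]) for k in range(runs)]


def fit_baseline(
    target_fcd: FCDMatrix,
    net: Connectome,
    freqs: FrequencyTable,
    a_grid: np.ndarray,
    g_grid: np.ndarray,
    runs_per_cell: int = 3,
    seed: int = 0,
    cfg: SimConfig | None = None,
) -> GridResult:
    """Sweep constant (a, G) against a baseline-block FCD target.

    ``cfg.duration`` must correspond to the baseline-block length so the
    simulated FCD has the target's window count.
    """
    a_grid = np.asarray(a_grid, dtype=float)
    g_grid = np.asarray(g_grid, dtype=float)
    if a_grid.size == 0 or g_grid.size == 0:
        raise ParameterError("empty parameter grid")
    cfg = cfg or SimConfig(duration=480.0)
    surface = np.empty((a_grid.size, g_grid.size))
    for i, a in enumerate(a_grid):
        for j, g in enumerate(g_grid):
            cell = i * g_grid.size + j
            seeds = _derive_seeds(seed, 0, cell, runs_per_cell)
            sched = ConstantPostSchedule(a0=a, t_inject=cfg.duration, a_post=a)
            surface[i, j] = _mean_fcd_distance(
                net, freqs, sched, replace(cfg, coupling=g), target_fcd, runs_per_cell, seeds
            )
    opt = _argmin_params(surface, (a_grid, g_grid))
    return GridResult(("a", "G"), (a_grid, g_grid), surface, (opt,), runs_per_cell)


def fit_temporal(
    target_fcd: FCDMatrix,
    net: Connectome,
    freqs: FrequencyTable,
    lam_grid: np.ndarray,
    beta_grid: np.ndarray,
    a0: float = 0.07,
    G: float = 0.5,
    runs_per_cell: int = 3,
    repeats: int = 5,
    seed: int = 0,
    cfg: SimConfig | None = None,
    t_inject: float = 480.0,
    norm_mode: str = "peak",
    lam_scale: float = 1.0e-3,
) -> GridResult:
    """Sweep the gamma-schedule parameters (lambda, beta) against a
    full-session FCD target; the sweep is repeated ``repeats`` times with
    independent noise, each repeat contributing one optimum."""
    lam_grid = np.asarray(lam_grid, dtype=float)
    beta_grid = np.asarray(beta_grid, dtype=float)
    if lam_grid.size == 0 or beta_grid.size == 0:
        raise ParameterError("empty parameter grid")
    cfg = cfg or SimConfig()
    cfg = replace(cfg, coupling=G)
    surfaces = np.empty((repeats, lam_grid.size, beta_grid.size))
    optima = []
    for r in range(repeats):
        for i, lam in enumerate(lam_grid):
            for j, beta in enumerate(beta_grid):
                cell = i * beta_grid.size + j
                seeds = _derive_seeds(seed, r, cell, runs_per_cell)
                sched = BifurcationSchedule(
                    a0=a0, t_inject=t_inject, lam=lam, beta=beta,
                    norm_mode=norm_mode, lam_scale=lam_scale,
                )
                surfaces[r, i, j] = _mean_fcd_distance(
                    net, freqs, sched, cfg, target_fcd, runs_per_cell, seeds
                )
        optima.append(_argmin_params(surfaces[r], (lam_grid, beta_grid)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_surface = np.nanmean(surfaces, axis=0)
    return GridResult(("lam", "beta"), (lam_grid, beta_grid), mean_surface, tuple(optima), runs_per_cell)


def fit_constant_null(
    target_fcd: FCDMatrix,
    net: Connectome,
    freqs: FrequencyTable,
    a_post_grid: np.ndarray,
    a0: float = 0.07,
    G: float = 0.5,
    runs_per_cell: int = 3,
    seed: int = 0,
    cfg: SimConfig | None = None,
    t_inject: float = 480.0,
) -> GridResult:
    """Null model: ``a`` constant at ``a0`` pre-injection, constant ``a_post``
    after, swept over ``a_post_grid`` with the same distance machinery."""
    a_post_grid = np.asarray(a_post_grid, dtype=float)
    if a_post_grid.size == 0:
        raise ParameterError("empty parameter grid")
    cfg = cfg or SimConfig()
    cfg = replace(cfg, coupling=G)
    surface = np.empty((a_post_grid.size, 1))
    for i, a_post in enumerate(a_post_grid):
        seeds = _derive_seeds(seed, 0, i, runs_per_cell)
        sched = ConstantPostSchedule(a0=a0, t_inject=t_inject, a_post=a_post)
        surface[i, 0] = _mean_fcd_distance(net, freqs, sched, cfg, target_fcd, runs_per_cell, seeds)
    opt = _argmin_params(surface, (a_post_grid, np.zeros(1)))[:1]
    return GridResult(("a_post",), (a_post_grid,), surface[:, 0], (opt,), runs_per_cell)


@dataclass(frozen=True)
class ConditionComparison:
    """Per-parameter Welch comparison of two sets of fitted optima.

    95% confidence intervals are mean +/- 1.96 * SEM.
    """

    param_names: tuple[str, ...]
    mean_a: tuple[float, ...]
    ci_a: tuple[float, ...]
    mean_b: tuple[float, ...]
    ci_b: tuple[float, ...]
    t_stat: tuple[float, ...]
    p_value: tuple[float, ...]


def _sem(v: np.ndarray) -> float:
    return float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0


def compare_conditions(
    optima_a,
    optima_b,
    param_names: tuple[str, ...] = ("lam", "beta"),
) -> ConditionComparison:
    """Welch two-sided t-test per parameter between two lists of optima.

    Degenerate case: zero variance in both samples with equal means yields
    t = 0, p = 1 by convention.
    """
    A = np.asarray(optima_a, dtype=float)
    B = np.asarray(optima_b, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    if B.ndim == 1:
        B = B[:, None]
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ParameterError("need at least 2 optima per condition")
    means_a, cis_a, means_b, cis_b, ts, ps = [], [], [], [], [], []
    for k in range(A.shape[1]):
        a, b = A[:, k], B[:, k]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(a, b, equal_var=False)
        if np.isnan(t):
            t, p = 0.0, 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
        means_a.append(float(a.mean()))
        cis_a.append(1.96 * _sem(a))
        means_b.append(float(b.mean()))
        cis_b.append(1.96 * _sem(b))
        ts.append(float(t))
        ps.append(float(p))
    return ConditionComparison(
        tuple(param_names),
        tuple(means_a), tuple(cis_a), tuple(means_b), tuple(cis_b),
        tuple(ts), tuple(ps),
    )
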