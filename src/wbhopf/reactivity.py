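"""Perturbational reactivity near the bifurcation.

The fitted schedule a(t) is sampled at equally spaced post-injection times
(the ``a_p`` values, default 42).  For each a_p and each forcing amplitude
F_ext, a session is simulated with a = a0 over the 8-minute baseline and a
held constant at a_p afterwards, while a resonant periodic forcing of
amplitude F_ext is applied to the nodes of one resting-state network (RSN)
from the end of the baseline.  The normalized Frobenius distance M between the
resulting FCD and the reference FCD is recorded, giving a surface
M(a_p, F_ext).

The reactivity is the susceptibility-like derivative

    chi(t_p) = dM/dF_ext,

evaluated with a second-order finite-difference scheme (central differences in
the interior, one-sided three-point stencils at the ends of the F_ext grid),
normalized by the number of nodes in the stimulated RSN, and referenced to the
injection-time sample by subtracting chi at the first post-injection time.
chi is largest when the held a_p is close to the bifurcation at a = 0 — the
system is maximally sensitive to forcing near criticality.

Downstream, peak reactivity chi_max is summarized by bootstrap over
simulation runs, condition differences Delta-chi(t) are formed pointwise, and
the per-RSN peak Delta-chi_max is correlated (Pearson, with a bootstrap over
networks) with the per-RSN mean receptor density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .dynamics import (
    BOLDLikeSeries,
    Connectome,
    ConstantPostSchedule,
    FrequencyTable,
    IntegrationDivergenceError,
    ParameterError,
    PerturbationSpec,
    SimConfig,
    simulate,
)
from .fcd import FCDMatrix, compute_fcd, fcd_distance

__all__ = [
    "RSNPartition",
    "APSampling",
    "ReactivitySurface",
    "ReactivityCurve",
    "ReceptorMap",
    "CorrelationResult",
    "default_fext_grid",
    "sample_ap",
    "perturbation_surface",
    "susceptibility_curve",
    "reactivity",
    "peak_reactivity",
    "delta_chi",
    "correlate_receptors",
    "rho_vs_intensity",
]

#: Default RSN labels, in the order of the study's six networks:
#: primary visual, extrastriate, auditory, sensorimotor, default mode,
#: executive control.
RSN_LABELS = ("Vis", "ES", "Aud", "SM", "DM", "EC")


def default_fext_grid() -> np.ndarray:
    """Forcing amplitudes 0 to 0.015 in steps of 0.00125 (13 points)."""
    return 0.00125 * np.arange(13)


@dataclass(frozen=True)
class RSNPartition:
    """Assignment of region indices to named resting-state networks."""

    assignment: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        clean = {k: tuple(int(i) for i in v) for k, v in self.assignment.items()}
        object.__setattr__(self, "assignment", clean)
        seen: set[int] = set()
        for name, idx in clean.items():
            if len(idx) < 1:
                raise ParameterError(f"network {name!r} is empty")
            if seen & set(idx):
                raise ParameterError("networks must be disjoint")
            seen |= set(idx)

    @property
    def networks(self) -> tuple[str, ...]:
        return tuple(self.assignment)

    def nodes(self, network: str) -> tuple[int, ...]:
        return self.assignment[network]

    def size(self, network: str) -> int:
        return len(self.assignment[network])


@dataclass(frozen=True)
class APSampling:
    """Equally spaced post-injection time samples of a schedule and the
    corresponding held bifurcation values a_p."""

    times: np.ndarray
    a_values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.a_values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "a_values", a)
        if t.size != a.size or t.size < 2:
            raise ParameterError("need >= 2 matched (time, a_p) samples")
        d = np.diff(t)
        if not np.allclose(d, d[0]):
            raise ParameterError("a_p sample times must be equally spaced")

    @property
    def n(self) -> int:
        return self.times.size


def sample_ap(sched, n: int = 42, span: float = 1200.0, t_inject: float | None = None) -> APSampling:
    """Sample ``n`` equally spaced times over (t_inject, t_inject + span].

    ``span`` defaults to the 20 post-injection minutes of the session; the
    first sample sits one spacing after the injection and the last at the
    span end.  ``t_inject`` is read off the schedule when it carries one.
    """
    if n < 2:
        raise ParameterError("need at least 2 a_p samples")
    if span <= 0:
        raise ParameterError("span must be positive")
    if t_inject is None:
        t_inject = getattr(sched, "t_inject", 0.0)
    times = t_inject + (span / n) * np.arange(1, n + 1)
    return APSampling(times, np.asarray(sched(times), dtype=float))


@dataclass(frozen=True)
class ReactivitySurface:
    """Per-run FCD distances M over (a_p time sample, forcing amplitude).

    ``values`` has shape (n_runs, n_times, n_fext); diverged cells are NaN.
    """

    values: np.ndarray
    times: np.ndarray
    fext: np.ndarray
    rsn: str
    rsn_size: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "fext", np.asarray(self.fext, dtype=float))
        if v.ndim != 3:
            raise ParameterError("surface values must be (runs, times, fext)")
        if v.shape[1] != self.times.size or v.shape[2] != self.fext.size:
            raise ParameterError("surface shape does not match axes")
        if np.any(np.diff(self.fext) <= 0) or (self.times.size > 1 and np.any(np.diff(self.times) <= 0)):
            raise ParameterError("surface axes must be strictly increasing")

    @property
    def mean(self) -> np.ndarray:
        """(n_times, n_fext) surface averaged over runs."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=0)


def perturbation_surface(
    net: Connectome,
    freqs: FrequencyTable,
    target_fcd: FCDMatrix,
    ap: APSampling,
    fext_grid: np.ndarray,
    rsn: str,
    partition: RSNPartition,
    cfg: SimConfig | None = None,
    n_runs: int = 1,
    seed: int = 0,
    t_inject: float = 480.0,
    a0: float = 0.07,
    simulate_fn=None,
) -> ReactivitySurface:
    """Simulate the perturbation protocol over the (a_p, F_ext) grid.

    For each cell: a = a0 during the baseline, a = a_p afterwards; forcing of
    amplitude F_ext on the RSN's nodes from the end of the baseline; M is the
    normalized FCD distance to ``target_fcd``.  ``simulate_fn`` (same
    signature as :func:`wbhopf.dynamics.simulate`) can replace the integrator,
    e.g. with a stub in tests.
    """
    fext_grid = np.asarray(fext_grid, dtype=float)
    if fext_grid.size < 3:
        raise ParameterError("F_ext grid needs >= 3 points for differencing")
    steps = np.diff(fext_grid)
    if not np.allclose(steps, steps[0]):
        raise ParameterError("F_ext grid must be uniform")
    if fext_grid[0] != 0.0:
        raise ParameterError("F_ext grid must include 0")
    cfg = cfg or SimConfig()
    sim = simulate_fn or simulate
    nodes = partition.nodes(rsn)
    values = np.empty((n_runs, ap.n, fext_grid.size))
    for r in range(n_runs):
        for i, a_p in enumerate(ap.a_values):
            sched = ConstantPostSchedule(a0=a0, t_inject=t_inject, a_post=float(a_p))
            for j, f in enumerate(fext_grid):
                ss = np.random.SeedSequence(entropy=seed, spawn_key=(r, i, j))
                run_seed = int(ss.generate_state(1)[0])
                pert = PerturbationSpec(amplitude=float(f), target_nodes=nodes, onset=t_inject)
                try:
                    series = sim(net, freqs, sched, replace(cfg, seed=run_seed), pert)
                except IntegrationDivergenceError as exc:
                    warnings.warn(f"surface cell flagged (diverged): {exc}")
                    values[r, i, j] = np.nan
                    continue
                fcd = compute_fcd(series, target_fcd.spec)
                values[r, i, j] = fcd_distance(fcd, target_fcd, normalized=True)
    return ReactivitySurface(values, ap.times, fext_grid, rsn, partition.size(rsn))


def susceptibility_curve(
    net: Connectome,
    freqs: FrequencyTable,
    a_values: np.ndarray,
    target_nodes,
    fext_grid: np.ndarray,
    cfg: SimConfig | None = None,
    t_inject: float = 240.0,
    a0: float = 0.07,
    n_runs: int = 4,
    seed: int = 0,
    spec=None,
) -> np.ndarray:
    """Forcing susceptibility of the FCD as a function of a constant held ``a``.

    For each ``a`` the post-injection bifurcation parameter is held at ``a``
    and the response to resonant forcing on ``target_nodes`` is measured as
    the normalized FCD distance between forced and unforced sessions sharing
    the same noise realization (paired seeds), so the distance isolates the
    forcing effect.  chi(a) is the second-order derivative of that distance
    with respect to F_ext at the grid midpoint, averaged over ``n_runs``
    paired runs.

    Near the bifurcation at a = 0 the oscillators are maximally entrainable,
    so chi(a) peaks in the grid cell containing a = 0; deep in either regime
    (robust limit cycle or strongly damped spiral) the response collapses.
    """
    from .fcd import WindowSpec, compute_fcd, fcd_distance  # local: avoid cycle at import

    a_values = np.asarray(a_values, dtype=float)
    fext_grid = np.asarray(fext_grid, dtype=float)
    if fext_grid.size < 3 or fext_grid[0] != 0.0:
        raise ParameterError("need a uniform F_ext grid of >= 3 points starting at 0")
    cfg = cfg or SimConfig(duration=480.0, noise_sd=0.02)
    spec = spec or WindowSpec()
    nodes = tuple(int(i) for i in target_nodes)
    mid = fext_grid.size // 2
    chi = np.empty(a_values.size)
    for ia, a in enumerate(a_values):
        sched = ConstantPostSchedule(a0=a0, t_inject=t_inject, a_post=float(a))
        slopes = []
        for r in range(n_runs):
            s = int(np.random.SeedSequence(entropy=seed, spawn_key=(r,)).generate_state(1)[0])
            run_cfg = replace(cfg, seed=s)
            unforced = compute_fcd(simulate(net, freqs, sched, run_cfg), spec)
            m = [0.0]
            for f in fext_grid[1:]:
                pert = PerturbationSpec(amplitude=float(f), target_nodes=nodes, onset=t_inject)
                forced = compute_fcd(simulate(net, freqs, sched, run_cfg, pert), spec)
                m.append(fcd_distance(forced, unforced, normalized=True))
            slopes.append(np.gradient(np.asarray(m), fext_grid, edge_order=2)[mid])
        chi[ia] = float(np.mean(slopes))
    return chi


@dataclass(frozen=True)
class ReactivityCurve:
    """chi(t) at a chosen forcing amplitude.

    ``per_run`` has shape (n_runs, n_times); ``values`` is the run mean.  Both
    are normalized by the RSN node count and referenced to the first
    (injection-time) sample, which is therefore 0 in ``values``.
    """

    values: np.ndarray
    per_run: np.ndarray
    times: np.ndarray
    rsn: str
    rsn_size: int
    at_fext: float
    baseline_subtracted: bool = True


def _dM_dF(M: np.ndarray, fext: np.ndarray, at_index: int) -> np.ndarray:
    """Second-order dM/dF_ext along the last axis, evaluated at one grid
    point: central differences inside, one-sided 3-point stencils at edges."""
    grad = np.gradient(M, fext, axis=-1, edge_order=2)
    return grad[..., at_index]


def reactivity(
    surface: ReactivitySurface,
    at_fext: float,
    partition: RSNPartition | None = None,
    rsn: str | None = None,
    baseline_subtract: bool = True,
) -> ReactivityCurve:
    """chi(t_p) = dM/dF_ext at ``at_fext``, per run then averaged.

    The derivative uses the second-order scheme (exact for quadratic M),
    divided by the stimulated RSN's node count; with ``baseline_subtract``
    the value at the first time sample is subtracted from the whole curve.
    """
    fext = surface.fext
    if fext.size < 3:
        raise ParameterError("need >= 3 F_ext grid points to difference")
    matches = np.where(np.isclose(fext, at_fext))[0]
    if matches.size == 0:
        raise ParameterError(f"at_fext={at_fext} not on the F_ext grid")
    j = int(matches[0])
    n_rsn = partition.size(rsn) if (partition is not None and rsn is not None) else surface.rsn_size
    per_run = _dM_dF(surface.values, fext, j) / n_rsn  # (runs, times)
    if baseline_subtract:
        per_run = per_run - per_run[:, :1]
    return ReactivityCurve(
        values=np.nanmean(per_run, axis=0) if per_run.shape[0] > 1 else per_run[0].copy(),
        per_run=per_run,
        times=surface.times,
        rsn=surface.rsn,
        rsn_size=n_rsn,
        at_fext=float(at_fext),
        baseline_subtracted=baseline_subtract,
    )


def peak_reactivity(
    curve: ReactivityCurve, n_boot: int = 200, seed: int = 0
) -> tuple[float, tuple[float, float], np.ndarray]:
    """Bootstrap distribution of the peak chi_max over time.

    Runs are resampled with replacement (resample size = number of runs), the
    resampled curves averaged, and the maximum over time taken; returns
    (bootstrap mean, 95% CI, bootstrap distribution).  The SD of the bootstrap
    distribution estimates the standard error of the peak statistic, so the
    CI is mean +/- 1.96 * SD(bootstrap).
    """
    runs = curve.per_run
    if runs.size == 0:
        raise ParameterError("empty reactivity curve")
    n_runs = runs.shape[0]
    if n_runs < 2:
        warnings.warn("single run: bootstrap CI is degenerate")
    rng = np.random.default_rng(seed)
    dist = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, n_runs, size=n_runs)
        dist[b] = np.nanmax(runs[pick].mean(axis=0))
    mean = float(dist.mean())
    half = 1.96 * float(dist.std(ddof=1)) if n_boot > 1 else 0.0
    return mean, (mean - half, mean + half), dist


def delta_chi(curve_a: ReactivityCurve, curve_b: ReactivityCurve) -> ReactivityCurve:
    """Pointwise difference of two reactivity curves (e.g. drug - placebo)."""
    if curve_a.times.shape != curve_b.times.shape or not np.allclose(curve_a.times, curve_b.times):
        raise ParameterError("time axes do not match")
    n = min(curve_a.per_run.shape[0], curve_b.per_run.shape[0])
    return ReactivityCurve(
        values=curve_a.values - curve_b.values,
        per_run=curve_a.per_run[:n] - curve_b.per_run[:n],
        times=curve_a.times.copy(),
        rsn=curve_a.rsn,
        rsn_size=curve_a.rsn_size,
        at_fext=curve_a.at_fext,
        baseline_subtracted=curve_a.baseline_subtracted and curve_b.baseline_subtracted,
    )


@dataclass(frozen=True)
class ReceptorMap:
    """Per-region receptor density (arbitrary PET-derived units)."""

    density: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "density", d)
        if np.any(d < 0):
            raise ParameterError("densities must be nonnegative")

    def network_means(self, partition: RSNPartition) -> np.ndarray:
        return np.array([self.density[list(partition.nodes(n))].mean() for n in partition.networks])


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with least-squares line and bootstrap summary."""

    rho: float
    slope: float
    intercept: float
    boot_rho: np.ndarray
    boot_mean: float
    ci: tuple[float, float]


def correlate_receptors(
    delta_peaks: np.ndarray,
    rmap: ReceptorMap,
    partition: RSNPartition,
    n_boot: int = 1000,
    seed: int = 0,
) -> CorrelationResult:
    """Correlate per-RSN peak differential reactivity with receptor density.

    ``delta_peaks`` is ordered as ``partition.networks``.  Pearson rho and the
    least-squares line are computed across networks; the bootstrap resamples
    networks with replacement (degenerate zero-variance resamples are
    redrawn), returning the rho distribution and a mean +/- 1.96*SEM CI.
    """
    x = rmap.network_means(partition)
    y = np.asarray(delta_peaks, dtype=float)
    if x.size < 3:
        raise ParameterError("need at least 3 networks")
    if x.size != y.size:
        raise ParameterError("delta_peaks length does not match network count")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ParameterError("zero variance: correlation undefined")
    rho = float(np.corrcoef(x, y)[0, 1])
    slope, intercept = np.polyfit(x, y, 1)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            pick = rng.integers(0, x.size, size=x.size)
            if np.std(x[pick]) > 0 and np.std(y[pick]) > 0:
                break
        boot[b] = np.corrcoef(x[pick], y[pick])[0, 1]
    bm = float(boot.mean())
    half = 1.96 * float(boot.std(ddof=1) / np.sqrt(n_boot))
    return CorrelationResult(rho, float(slope), float(intercept), boot, bm, (bm - half, bm + half))


def rho_vs_intensity(
    surfaces_a: dict[str, ReactivitySurface],
    surfaces_b: dict[str, ReactivitySurface],
    rmap: ReceptorMap,
    partition: RSNPartition,
    fext_grid: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Correlation of Delta-chi_max with receptor density per forcing level.

    ``surfaces_a``/``surfaces_b`` map RSN name -> surface for the two
    conditions (e.g. drug and placebo) on identical grids.  At each F_ext the
    per-RSN Delta-chi_max is correlated with the per-RSN densities; returns
    (fext axis, mean bootstrap rho, bootstrap SD).  Forcing levels where the
    planted response has no variance across networks yield NaN (flagged).
    """
    first = next(iter(surfaces_a.values()))
    grid = np.asarray(fext_grid, dtype=float) if fext_grid is not None else first.fext
    means = np.full(grid.size, np.nan)
    sds = np.full(grid.size, np.nan)
    for j, f in enumerate(grid):
        peaks = []
        for name in partition.networks:
            ca = reactivity(surfaces_a[name], f)
            cb = reactivity(surfaces_b[name], f)
            peaks.append(float(np.nanmax(delta_chi(ca, cb).values)))
        try:
            res = correlate_receptors(np.asarray(peaks), rmap, partition, n_boot=n_boot, seed=seed + j)
        except ParameterError:
            warnings.warn(f"rho undefined at F_ext={f:g} (degenerate response)")
            continue
        means[j] = res.boot_rho.mean()
        sds[j] = res.boot_rho.std(ddof=1)
    return grid, means, sds
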