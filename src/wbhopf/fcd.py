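"""Functional connectivity dynamics (FCD) and related summaries.

The FCD matrix captures how windowed functional connectivity evolves over a
session: the series is split into overlapping sliding windows (default 60 s
length, 20 s step, i.e. 40 s overlap), the Pearson FC matrix is computed per
window, and entry (i, j) of the M x M FCD matrix is the Pearson correlation
between the strictly-upper-triangular parts of FC(t_i) and FC(t_j).  A 28-min
session sampled at tr = 2 s yields M = 82 windows, the first 22 of which lie
wholly in the first 8 minutes.

Two matrices are compared with the Euclidean (Frobenius) distance, optionally
normalized by the norm of the reference ("empirical") matrix.  Alternative
summaries based on instantaneous analytic phases — phase-coherence FCD, and
Kuramoto synchrony/metastability — are also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .dynamics import BOLDLikeSeries, ParameterError

__all__ = [
    "WindowSpec",
    "FCMatrix",
    "FCDMatrix",
    "enumerate_windows",
    "compute_fc",
    "compute_fcd",
    "fcd_distance",
    "compute_phase_coherence",
    "phase_fcd",
    "synchrony_metastability",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window layout: windows start at t0, t0+step, ... and must be
    fully contained in the series."""

    length: float = 60.0
    step: float = 20.0

    def __post_init__(self) -> None:
        if not (self.length > self.step > 0):
            raise ParameterError("need window length > step > 0")

    def n_windows(self, total: float) -> int:
        """M = floor((total - length)/step) + 1 for total >= length."""
        if total < self.length:
            raise ParameterError(
                f"series of {total:g} s too short for {self.length:g} s windows"
            )
        return int(np.floor((total - self.length) / self.step + 1e-9)) + 1


@dataclass(frozen=True)
class FCMatrix:
    """Windowed functional connectivity (Pearson) with its window start."""

    values: np.ndarray
    start: float


@dataclass(frozen=True)
class FCDMatrix:
    """Window-by-window FC similarity matrix with its window layout."""

    values: np.ndarray
    spec: WindowSpec
    starts: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "starts", np.asarray(self.starts, dtype=float))
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ParameterError("FCD matrix must be square")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def baseline_block(self, t_inject: float) -> "FCDMatrix":
        """Submatrix over windows wholly contained before ``t_inject``
        (start + length <= t_inject, with starts relative to series t0)."""
        rel = self.starts - self.starts[0]
        mask = rel + self.spec.length <= t_inject + 1e-9
        idx = np.where(mask)[0]
        if idx.size == 0:
            raise ParameterError("no windows lie wholly before t_inject")
        return FCDMatrix(self.values[np.ix_(idx, idx)], self.spec, self.starts[idx])


def enumerate_windows(total: float, spec: WindowSpec) -> np.ndarray:
    """Start offsets (seconds, relative to series start) of all full windows."""
    m = spec.n_windows(total)
    return spec.step * np.arange(m)


def _window_slice(series: BOLDLikeSeries, start: float, spec: WindowSpec) -> np.ndarray:
    i0 = int(round(start / series.tr))
    n = int(round(spec.length / series.tr))
    if i0 < 0 or i0 + n > series.n_samples:
        raise ParameterError("window extends outside the series")
    return series.values[:, i0 : i0 + n]


def _safe_corrcoef(data: np.ndarray) -> np.ndarray:
    """Pearson correlation across rows; zero-variance rows yield 0 (warned)."""
    sd = data.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("zero-variance row in correlation window; entries set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(data)
    c = np.nan_to_num(c, nan=0.0)
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def compute_fc(series: BOLDLikeSeries, start: float, spec: WindowSpec) -> FCMatrix:
    """Pearson FC over one window starting ``start`` seconds into the series."""
    return FCMatrix(_safe_corrcoef(_window_slice(series, start, spec)), start)


def _fcd_from_fc_stack(fcs: np.ndarray, spec: WindowSpec, starts: np.ndarray) -> FCDMatrix:
    n = fcs.shape[1]
    if n < 3:
        raise ParameterError("FCD needs at least 3 regions (non-trivial upper triangle)")
    iu = np.triu_indices(n, k=1)
    vecs = fcs[:, iu[0], iu[1]]
    fcd = _safe_corrcoef(vecs)
    return FCDMatrix(fcd, spec, starts)


def compute_fcd(series: BOLDLikeSeries, spec: WindowSpec | None = None) -> FCDMatrix:
    """FCD matrix of a series: correlations between windowed FC patterns."""
    spec = spec or WindowSpec()
    offsets = enumerate_windows(series.duration, spec)
    if offsets.size < 2:
        raise ParameterError("series too short for at least 2 windows")
    fcs = np.stack([_safe_corrcoef(_window_slice(series, s, spec)) for s in offsets])
    return _fcd_from_fc_stack(fcs, spec, series.t0 + offsets)


def fcd_distance(a: FCDMatrix | np.ndarray, b: FCDMatrix | np.ndarray, normalized: bool = True) -> float:
    """Frobenius distance ||A - B||_F, optionally divided by ||B||_F.

    ``b`` plays the role of the reference (empirical) matrix for the
    normalization.
    """
    av = a.values if isinstance(a, FCDMatrix) else np.asarray(a, dtype=float)
    bv = b.values if isinstance(b, FCDMatrix) else np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ParameterError(f"shape mismatch: {av.shape} vs {bv.shape}")
    d = float(np.linalg.norm(av - bv))
    if normalized:
        d /= float(np.linalg.norm(bv))
    return d


def _analytic_phases(series: BOLDLikeSeries) -> np.ndarray:
    v = series.values
    if np.any(v.std(axis=1) == 0):
        raise ParameterError("constant signal: analytic phase undefined")
    analytic = hilbert(v - v.mean(axis=1, keepdims=True), axis=1)
    return np.angle(analytic)


def compute_phase_coherence(theta: np.ndarray) -> np.ndarray:
    """Pairwise phase coherence of a phase window: mean_t cos(theta_i - theta_j).

    1 for identical phases, -1 for antiphase pairs.
    """
    ph = np.exp(1j * theta)
    coh = np.real(ph @ ph.conj().T) / theta.shape[1]
    np.fill_diagonal(coh, 1.0)
    return np.clip(coh, -1.0, 1.0)


def phase_fcd(series: BOLDLikeSeries, spec: WindowSpec | None = None) -> FCDMatrix:
    """FCD built from windowed pairwise phase coherence.

    The analytic phase is extracted on the full (demeaned) series before
    windowing; one window length is trimmed at each end to limit Hilbert edge
    effects.  Per window, coherence(i, j) is the time average of
    cos(theta_i - theta_j); the window-by-window similarity matrix is then
    assembled exactly as in :func:`compute_fcd`.
    """
    spec = spec or WindowSpec()
    theta = _analytic_phases(series)
    trim = int(round(spec.length / series.tr))
    if theta.shape[1] <= 2 * trim:
        raise ParameterError("series too short to trim phase edge effects")
    theta = theta[:, trim:-trim]
    total = theta.shape[1] * series.tr
    offsets = enumerate_windows(total, spec)
    if offsets.size < 2:
        raise ParameterError("series too short for at least 2 phase windows")
    nwin = int(round(spec.length / series.tr))
    mats = []
    for s in offsets:
        i0 = int(round(s / series.tr))
        mats.append(compute_phase_coherence(theta[:, i0 : i0 + nwin]))
    starts = series.t0 + trim * series.tr + offsets
    return _fcd_from_fc_stack(np.stack(mats), spec, starts)


def synchrony_metastability(series: BOLDLikeSeries) -> tuple[float, float]:
    """Kuramoto order parameter statistics of the analytic phases.

    R(t) = |mean_n exp(i theta_n(t))|; returns (time-mean of R, time-SD of R),
    i.e. (synchrony, metastability).
    """
    if series.n_regions < 2:
        raise ParameterError("synchrony needs at least 2 nodes")
    theta = _analytic_phases(series)
    r = np.abs(np.exp(1j * theta).mean(axis=0))
    return float(r.mean()), float(r.std())
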