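"""Synthetic study fixtures: connectomes, frequencies, partitions, receptor
maps, and ground-truth-driven "empirical" FCD targets.

Every generator is a pure function of its parameters and seed, so fixtures
can be regenerated bit for bit from a recorded manifest.  The connectome is a
modular weighted random graph — only symmetry, nonnegativity and normalized
strength matter to the coupled-oscillator model, not detailed tractography
statistics.  The FCD target emulates a group-mean empirical FCD by averaging
the FCDs of independent simulated "subjects" driven by a known ground-truth
schedule, which makes parameter-recovery tests possible without any real
data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .dynamics import (
    BifurcationSchedule,
    Connectome,
    FrequencyTable,
    ParameterError,
    SimConfig,
    simulate,
)
from .fcd import FCDMatrix, WindowSpec, compute_fcd
from .reactivity import RSN_LABELS, ReceptorMap, RSNPartition

__all__ = [
    "FixtureManifest",
    "DEFAULT_RSN_SIZES",
    "make_connectome",
    "make_frequencies",
    "make_partition",
    "make_receptor_map",
    "make_fcd_target",
]

#: Node counts of the six resting-state networks (Vis, ES, Aud, SM, DM, EC).
DEFAULT_RSN_SIZES = (7, 9, 26, 13, 12, 24)


@dataclass(frozen=True)
class FixtureManifest:
    """Everything needed to regenerate a fixture set bit for bit."""

    seed: int
    n_regions: int
    a0: float
    G: float
    lam: float
    beta: float
    t_inject: float
    duration: float
    n_subjects: int
    window_length: float
    window_step: float
    version: str = "wbhopf-fixtures-1"

    def to_dict(self) -> dict:
        return asdict(self)


def make_connectome(n: int, density: float = 0.3, seed: int = 0, n_modules: int = 4) -> Connectome:
    """Modular weighted random connectome.

    Edges are drawn with probability ``density`` (tripled within modules),
    weighted uniformly, symmetrized, then rescaled by a symmetric
    Sinkhorn-style iteration so every node strength is 1 while the matrix
    stays exactly symmetric with a zero diagonal.
    """
    if n < 2:
        raise ParameterError("need at least 2 regions")
    if not (0 < density <= 1):
        raise ParameterError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    module = rng.integers(0, n_modules, size=n)
    same = module[:, None] == module[None, :]
    p = np.where(same, min(3 * density, 1.0), density)
    mask = rng.random((n, n)) < p
    w = rng.uniform(0.1, 1.0, (n, n)) * mask
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    # guarantee connectivity of the strength normalization: ring backbone
    for i in range(n):
        j = (i + 1) % n
        if w[i, j] == 0:
            w[i, j] = w[j, i] = 0.05
    for _ in range(50):
        s = w.sum(axis=1)
        d = 1.0 / np.sqrt(s)
        w = w * d[:, None] * d[None, :]
    w = (w + w.T) / 2.0
    labels = tuple(f"R{i:03d}" for i in range(n))
    return Connectome(weights=w, labels=labels)


def make_frequencies(n: int, seed: int = 0, band: tuple[float, float] = (0.01, 0.08)) -> FrequencyTable:
    """Node peak frequencies drawn uniformly in the BOLD band (Hz)."""
    if n < 1:
        raise ParameterError("need at least 1 node")
    rng = np.random.default_rng(seed)
    return FrequencyTable(rng.uniform(band[0], band[1], n))


def make_partition(n: int, sizes: tuple[int, ...] | None = None, seed: int = 0) -> RSNPartition:
    """Random disjoint assignment of nodes to the six RSNs.

    Default sizes are the study's network counts; they sum to 91, so for
    n < 91 the largest networks are trimmed (with a warning) until they fit.
    """
    sizes = list(sizes if sizes is not None else DEFAULT_RSN_SIZES)
    labels = RSN_LABELS[: len(sizes)]
    if len(sizes) != len(labels):
        raise ParameterError(f"at most {len(RSN_LABELS)} networks are supported")
    if any(s < 1 for s in sizes):
        raise ParameterError("every network needs at least 1 node")
    total = sum(sizes)
    if total > n:
        if tuple(sizes) != DEFAULT_RSN_SIZES:
            raise ParameterError(f"requested sizes sum to {total} > n = {n}")
        warnings.warn(f"default RSN sizes sum to {total} > n = {n}; capping largest networks")
        while sum(sizes) > n:
            sizes[int(np.argmax(sizes))] -= 1
        if any(s < 1 for s in sizes):
            raise ParameterError(f"n = {n} too small for 6 non-empty networks")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = {}
    k = 0
    for name, s in zip(labels, sizes):
        assignment[name] = tuple(sorted(int(i) for i in perm[k : k + s]))
        k += s
    return RSNPartition(assignment)


def make_receptor_map(
    partition: RSNPartition,
    target_rho: float,
    reference: np.ndarray,
    seed: int = 0,
    within_sd: float = 0.05,
) -> ReceptorMap:
    """Per-region densities whose network means correlate with ``reference``
    at exactly ``target_rho`` (sample Pearson).

    The network means are built as rho * r_hat + sqrt(1-rho^2) * n_hat with
    r_hat the z-scored reference and n_hat a z-scored residual orthogonal to
    it, then shifted/scaled to be positive; per-region densities scatter
    tightly (``within_sd``) around their network mean so the network means are
    recovered almost exactly.
    """
    nets = partition.networks
    m = len(nets)
    if m < 3:
        raise ParameterError("need at least 3 networks")
    if abs(target_rho) > 1:
        raise ParameterError("|target_rho| must be <= 1")
    ref = np.asarray(reference, dtype=float)
    if ref.size != m:
        raise ParameterError("reference length must equal number of networks")
    if np.std(ref) == 0:
        raise ParameterError("reference must have variance")
    rng = np.random.default_rng(seed)
    r_hat = (ref - ref.mean()) / ref.std()
    noise = rng.standard_normal(m)
    noise = noise - noise.mean()
    noise = noise - (noise @ r_hat) / (r_hat @ r_hat) * r_hat
    if np.std(noise) == 0:  # pathological draw
        noise = np.roll(r_hat, 1) - r_hat
        noise = noise - (noise @ r_hat) / (r_hat @ r_hat) * r_hat
    n_hat = noise / noise.std()
    mix = target_rho * r_hat + np.sqrt(max(0.0, 1 - target_rho**2)) * n_hat
    # map to positive densities, mean 1, spread 0.25
    means = 1.0 + 0.25 * mix
    means = np.maximum(means, 0.05)
    n_total = 1 + max(max(idx) for idx in partition.assignment.values())
    density = np.zeros(n_total)
    for mu, name in zip(means, nets):
        idx = list(partition.nodes(name))
        jitter = within_sd * rng.standard_normal(len(idx))
        jitter -= jitter.mean()  # zero-sum, so the network mean stays exact
        lo = jitter.min()
        if mu + lo < 0:  # shrink spread instead of clipping, keeping the mean
            jitter *= (0.9 * mu) / (-lo)
        density[idx] = mu + jitter
    return ReceptorMap(density)


def make_fcd_target(
    net: Connectome,
    freqs: FrequencyTable,
    truth_sched: BifurcationSchedule,
    cfg: SimConfig | None = None,
    n_subjects: int = 5,
    spec: WindowSpec | None = None,
    seed: int = 0,
) -> tuple[FCDMatrix, FixtureManifest]:
    """Group-mean "empirical" FCD target from a known ground-truth schedule.

    Simulates ``n_subjects`` independent sessions, averages their FCDs, and
    records the ground truth in a manifest so recovery tests can compare the
    fitted optimum against it.
    """
    cfg = cfg or SimConfig()
    spec = spec or WindowSpec()
    acc = None
    starts = None
    for s in range(n_subjects):
        sub_seed = int(np.random.SeedSequence(entropy=seed, spawn_key=(7, s)).generate_state(1)[0])
        series = simulate(net, freqs, truth_sched, replace(cfg, seed=sub_seed))
        f = compute_fcd(series, spec)
        acc = f.values if acc is None else acc + f.values
        starts = f.starts
    target = FCDMatrix(acc / n_subjects, spec, starts)
    manifest = FixtureManifest(
        seed=seed,
        n_regions=net.n_regions,
        a0=getattr(truth_sched, "a0", float("nan")),
        G=cfg.coupling,
        lam=getattr(truth_sched, "lam", 0.0),
        beta=getattr(truth_sched, "beta", float("nan")),
        t_inject=getattr(truth_sched, "t_inject", 0.0),
        duration=cfg.duration,
        n_subjects=n_subjects,
        window_length=spec.length,
        window_step=spec.step,
    )
    return target, manifest
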