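"""Staged pipeline tying the stages into the study workflow.

``run_pipeline`` executes an ordered subset of stages into a run directory:

    synth        generate fixtures (connectome, frequencies, partition,
                 receptor map, and ground-truth FCD targets for two
                 conditions, "drug" and "placebo")
    fit-baseline grid-search (a, G) against the baseline FCD block
    fit-temporal grid-search (lambda, beta) per condition + Welch comparison
    fit-null     constant-post-dose null model sweep
    perturb      reactivity surfaces and chi(t) curves per RSN and condition
    correlate    peak Delta-chi vs receptor density across RSNs

Every output carries the run-config digest; a stage refuses inputs written
under a different digest.  Rerunning with the same config reproduces outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np

from .dynamics import BifurcationSchedule, SimConfig, simulate
from .fcd import WindowSpec, compute_fcd
from .fitting import compare_conditions, fit_baseline, fit_constant_null, fit_temporal, grid_axis
from .io import (
    RunConfig,
    read_connectome,
    read_fcd,
    read_frequencies,
    read_partition,
    read_receptor_map,
    write_connectome,
    write_fcd,
    write_frequencies,
    write_partition,
    write_receptor_map,
)
from .reactivity import (
    correlate_receptors,
    delta_chi,
    peak_reactivity,
    perturbation_surface,
    reactivity,
    sample_ap,
)
from .synthetic import make_connectome, make_fcd_target, make_frequencies, make_partition, make_receptor_map

__all__ = ["STAGES", "PipelineError", "run_pipeline"]

log = logging.getLogger("wbhopf")

STAGES = ("synth", "fit-baseline", "fit-temporal", "fit-null", "perturb", "correlate")

#: desk-scale pipeline knobs (kept out of RunConfig, which mirrors the study
#: acquisition layout); override via the ``scale`` argument of run_pipeline
DESK_SCALE = {
    "n_regions": 20,
    "density": 0.3,
    "n_subjects": 3,
    "runs_per_cell": 2,
    "repeats": 3,
    "n_lam": 4,
    "n_beta": 4,
    "truth": {"drug": (120.0, 280.0), "placebo": (20.0, 500.0)},
    "n_ap": 4,
    "n_fext": 5,
    "n_runs_perturb": 2,
    "receptor_rho": 0.9,
    "n_baseline_a": 3,
    "n_baseline_g": 3,
}


class PipelineError(RuntimeError):
    """Missing stage dependency or inconsistent inputs."""


def _sim_config(cfg: RunConfig, duration: float | None = None) -> SimConfig:
    return SimConfig(
        dt=cfg.dt,
        tr=cfg.tr,
        duration=duration if duration is not None else cfg.duration,
        noise_sd=cfg.noise_sd,
        coupling=cfg.G,
        seed=cfg.seed,
        burn_in=cfg.burn_in,
    )


def _write_json(path: Path, payload: dict, cfg: RunConfig) -> None:
    payload = {"config_digest": cfg.digest, **payload}
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _load_json(path: Path, cfg: RunConfig, stage: str) -> dict:
    if not path.exists():
        raise PipelineError(f"stage {stage!r} needs {path.name}; run its producer stage first")
    payload = json.loads(path.read_text())
    digest = payload.get("config_digest")
    if digest is not None and digest != cfg.digest:
        raise PipelineError(
            f"{path.name} was produced under config digest {digest}, current is {cfg.digest}"
        )
    return payload


def _require(path: Path, stage: str, producer: str) -> Path:
    if not path.exists():
        raise PipelineError(f"stage {stage!r} needs {path.name}; run {producer!r} first")
    return path


def _check_digest(path: Path, cfg: RunConfig) -> Path:
    """Reject TSV inputs whose sidecar was written under another config."""
    from .io import _read_sidecar

    digest = _read_sidecar(path).get("config_digest")
    if digest is not None and digest != cfg.digest:
        raise PipelineError(
            f"{path.name} was produced under config digest {digest}, current is {cfg.digest}"
        )
    return path


def _truth_schedule(cfg: RunConfig, lam: float, beta: float) -> BifurcationSchedule:
    return BifurcationSchedule(
        a0=cfg.a0, t_inject=cfg.t_inject, lam=lam, beta=beta,
        norm_mode=cfg.norm_mode, lam_scale=cfg.lam_scale,
    )


def _stage_synth(out: Path, cfg: RunConfig, scale: dict) -> None:
    net = make_connectome(scale["n_regions"], scale["density"], seed=cfg.seed)
    freqs = make_frequencies(scale["n_regions"], seed=cfg.seed + 1)
    partition = make_partition(scale["n_regions"], seed=cfg.seed + 2)
    reference = np.arange(1.0, len(partition.networks) + 1)
    rmap = make_receptor_map(partition, scale["receptor_rho"], reference, seed=cfg.seed + 3)
    write_connectome(out / "sc.tsv", net, {"config_digest": cfg.digest})
    write_frequencies(out / "freqs.tsv", freqs)
    write_partition(out / "partition.tsv", partition)
    write_receptor_map(out / "receptors.tsv", rmap)
    spec = WindowSpec(cfg.window_length, cfg.window_step)
    manifests = {}
    for cond, (lam, beta) in scale["truth"].items():
        target, manifest = make_fcd_target(
            net, freqs, _truth_schedule(cfg, lam, beta),
            cfg=_sim_config(cfg), n_subjects=scale["n_subjects"], spec=spec, seed=cfg.seed,
        )
        write_fcd(out / f"target_{cond}.tsv", target, {"config_digest": cfg.digest})
        manifests[cond] = manifest.to_dict()
    _write_json(out / "manifest.json", {"truth": manifests}, cfg)


def _grids(cfg: RunConfig, scale: dict) -> tuple[np.ndarray, np.ndarray]:
    lam_grid = np.linspace(0.0, 200.0, scale["n_lam"])
    beta_grid = np.linspace(100.0, 600.0, scale["n_beta"])
    return lam_grid, beta_grid


def _stage_fit_baseline(out: Path, cfg: RunConfig, scale: dict) -> None:
    net = read_connectome(_check_digest(_require(out / "sc.tsv", "fit-baseline", "synth"), cfg))
    freqs = read_frequencies(out / "freqs.tsv")
    target = read_fcd(out / "target_placebo.tsv").baseline_block(cfg.t_inject)
    a_grid = np.linspace(0.0, 0.1, scale["n_baseline_a"])
    g_grid = np.linspace(0.0, 1.0, scale["n_baseline_g"])
    res = fit_baseline(
        target, net, freqs, a_grid, g_grid,
        runs_per_cell=scale["runs_per_cell"], seed=cfg.seed,
        cfg=_sim_config(cfg, duration=cfg.t_inject),
    )
    _write_json(out / "fit_baseline.json", {
        "a_grid": a_grid, "g_grid": g_grid, "surface": res.surface, "optimum": res.optimum,
    }, cfg)


def _stage_fit_temporal(out: Path, cfg: RunConfig, scale: dict) -> None:
    net = read_connectome(_check_digest(_require(out / "sc.tsv", "fit-temporal", "synth"), cfg))
    freqs = read_frequencies(out / "freqs.tsv")
    lam_grid, beta_grid = _grids(cfg, scale)
    results = {}
    for cond in scale["truth"]:
        target = read_fcd(_check_digest(out / f"target_{cond}.tsv", cfg))
        t0 = time.time()
        res = fit_temporal(
            target, net, freqs, lam_grid, beta_grid,
            a0=cfg.a0, G=cfg.G,
            runs_per_cell=scale["runs_per_cell"], repeats=scale["repeats"],
            seed=cfg.seed, cfg=_sim_config(cfg), t_inject=cfg.t_inject,
            norm_mode=cfg.norm_mode, lam_scale=cfg.lam_scale,
        )
        log.info("fit-temporal[%s]: %d cells in %.1f s, optimum %s",
                 cond, lam_grid.size * beta_grid.size, time.time() - t0, res.optimum)
        results[cond] = res
    conds = list(results)
    comparison = compare_conditions(results[conds[0]].optima, results[conds[1]].optima)
    _write_json(out / "fit_temporal.json", {
        "lam_grid": lam_grid, "beta_grid": beta_grid,
        "conditions": {c: {"surface": r.surface, "optima": r.optima, "optimum": r.optimum}
                       for c, r in results.items()},
        "comparison": {
            "params": comparison.param_names,
            "mean_a": comparison.mean_a, "ci_a": comparison.ci_a,
            "mean_b": comparison.mean_b, "ci_b": comparison.ci_b,
            "t": comparison.t_stat, "p": comparison.p_value,
        },
    }, cfg)


def _stage_fit_null(out: Path, cfg: RunConfig, scale: dict) -> None:
    net = read_connectome(_check_digest(_require(out / "sc.tsv", "fit-null", "synth"), cfg))
    freqs = read_frequencies(out / "freqs.tsv")
    target = read_fcd(out / "target_drug.tsv")
    a_post_grid = np.linspace(-0.05, cfg.a0, 5)
    res = fit_constant_null(
        target, net, freqs, a_post_grid, a0=cfg.a0, G=cfg.G,
        runs_per_cell=scale["runs_per_cell"], seed=cfg.seed,
        cfg=_sim_config(cfg), t_inject=cfg.t_inject,
    )
    _write_json(out / "fit_null.json", {
        "a_post_grid": a_post_grid, "surface": res.surface, "optimum": res.optimum,
    }, cfg)


def _stage_perturb(out: Path, cfg: RunConfig, scale: dict) -> None:
    net = read_connectome(_check_digest(_require(out / "sc.tsv", "perturb", "synth"), cfg))
    freqs = read_frequencies(out / "freqs.tsv")
    partition = read_partition(out / "partition.tsv")
    fit = _load_json(_require(out / "fit_temporal.json", "perturb", "fit-temporal"), cfg, "perturb")
    fext_grid = np.linspace(0.0, cfg.fext_max, scale["n_fext"])
    mid_fext = float(fext_grid[len(fext_grid) // 2])
    rows = ["time\tfext\trsn\tcondition\tchi"]
    curves: dict[str, dict[str, list]] = {}
    for cond, entry in fit["conditions"].items():
        lam, beta = entry["optimum"]
        sched = _truth_schedule(cfg, lam, beta)
        ap = sample_ap(sched, n=scale["n_ap"], span=cfg.ap_span)
        target = read_fcd(out / f"target_{cond}.tsv")
        curves[cond] = {}
        for rsn in partition.networks:
            surf = perturbation_surface(
                net, freqs, target, ap, fext_grid, rsn, partition,
                cfg=_sim_config(cfg), n_runs=scale["n_runs_perturb"], seed=cfg.seed,
                t_inject=cfg.t_inject, a0=cfg.a0,
            )
            curve = reactivity(surf, mid_fext)
            curves[cond][rsn] = curve
            for t, chi in zip(curve.times, curve.values):
                rows.append(f"{t:g}\t{mid_fext:g}\t{rsn}\t{cond}\t{chi:.8g}")
            log.info("perturb[%s/%s]: %d cells", cond, rsn, ap.n * fext_grid.size)
    (out / "reactivity.tsv").write_text("\n".join(rows) + "\n")
    conds = list(curves)
    summary = {}
    for rsn in partition.networks:
        dc = delta_chi(curves[conds[0]][rsn], curves[conds[1]][rsn])
        peak_mean, ci, _ = peak_reactivity(dc, n_boot=cfg.n_boot_peaks, seed=cfg.seed)
        summary[rsn] = {"delta_chi_max": float(np.nanmax(dc.values)),
                        "bootstrap_mean": peak_mean, "ci": ci}
    _write_json(out / "reactivity_summary.json", {
        "fext": mid_fext, "conditions": conds, "per_rsn": summary,
    }, cfg)


def _stage_correlate(out: Path, cfg: RunConfig, scale: dict) -> None:
    partition = read_partition(_require(out / "partition.tsv", "correlate", "synth"))
    rmap = read_receptor_map(out / "receptors.tsv")
    summary = _load_json(_require(out / "reactivity_summary.json", "correlate", "perturb"),
                         cfg, "correlate")
    peaks = np.array([summary["per_rsn"][n]["delta_chi_max"] for n in partition.networks])
    res = correlate_receptors(peaks, rmap, partition, n_boot=cfg.n_boot_corr, seed=cfg.seed)
    _write_json(out / "correlation.json", {
        "rho": res.rho, "slope": res.slope, "intercept": res.intercept,
        "bootstrap_mean": res.boot_mean, "ci": res.ci,
    }, cfg)


_STAGE_FN = {
    "synth": _stage_synth,
    "fit-baseline": _stage_fit_baseline,
    "fit-temporal": _stage_fit_temporal,
    "fit-null": _stage_fit_null,
    "perturb": _stage_perturb,
    "correlate": _stage_correlate,
}


def run_pipeline(config: RunConfig, stages, out_dir, scale: dict | None = None) -> Path:
    """Execute ``stages`` in order into ``out_dir``; returns the directory.

    ``scale`` overrides entries of the desk-scale defaults (grid sizes, run
    counts, fixture dimensions)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    eff_scale = {**DESK_SCALE, **(scale or {})}
    for stage in stages:
        if stage not in _STAGE_FN:
            raise PipelineError(f"unknown stage {stage!r}; valid stages: {', '.join(STAGES)}")
    (out / "config.json").write_text(
        json.dumps({"config_digest": config.digest, **config.to_dict()}, indent=1, sort_keys=True) + "\n"
    )
    for stage in stages:
        t0 = time.time()
        log.info("stage %s: start", stage)
        _STAGE_FN[stage](out, config, eff_scale)
        log.info("stage %s: done in %.1f s", stage, time.time() - t0)
    return out
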