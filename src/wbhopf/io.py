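"""Plain-text I/O and run configuration.

All artifacts are TSV matrices (labels in the first row/column) with JSON
sidecars carrying provenance: the run configuration digest, seeds, window and
schedule parameters.  Parcellated matrices rather than imaging volumes are
the unit of exchange, so no neuroimaging container formats are involved.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import BOLDLikeSeries, Connectome, FrequencyTable, ParameterError
from .fcd import FCDMatrix, WindowSpec
from .reactivity import ReceptorMap, RSNPartition

__all__ = [
    "RunConfig",
    "read_matrix",
    "write_connectome",
    "read_connectome",
    "write_frequencies",
    "read_frequencies",
    "write_series",
    "read_series",
    "write_fcd",
    "read_fcd",
    "write_partition",
    "read_partition",
    "write_receptor_map",
    "read_receptor_map",
]


@dataclass(frozen=True)
class RunConfig:
    """Study-default configuration for the full pipeline.

    Defaults follow the study layout: 28-min sessions at tr = 2 s with the
    injection at the end of minute 8, 60 s / 20 s sliding windows, baseline
    a0 = 0.07 and G = 0.5, noise gamma = 0.05, 42 post-injection a_p samples,
    forcing amplitudes 0–0.015, and 200/1000 bootstrap draws for peaks /
    correlations.
    """

    tr: float = 2.0
    dt: float = 0.1
    duration: float = 1680.0
    burn_in: float = 60.0
    t_inject: float = 480.0
    a0: float = 0.07
    G: float = 0.5
    noise_sd: float = 0.05
    window_length: float = 60.0
    window_step: float = 20.0
    lam_scale: float = 1.0e-3
    norm_mode: str = "peak"
    n_ap: int = 42
    ap_span: float = 1200.0
    fext_max: float = 0.015
    fext_step: float = 0.00125
    n_boot_peaks: int = 200
    n_boot_corr: int = 1000
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in names})


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(path: Path, meta: dict) -> None:
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def _read_sidecar(path: Path) -> dict:
    p = _sidecar_path(path)
    return json.loads(p.read_text()) if p.exists() else {}


def _read_labelled_matrix(path: Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        raise ParameterError(f"{path}: matrix contains non-finite entries")
    return values, [str(c) for c in df.index]


def read_matrix(path, kind: str, tol: float = 1e-8):
    """Read a TSV matrix as a typed object.

    ``kind`` is one of ``sc`` (-> :class:`Connectome`), ``fcd``
    (-> :class:`FCDMatrix`, window spec from the sidecar) or ``series``
    (-> :class:`BOLDLikeSeries`).  Symmetry is enforced for sc/fcd up to
    ``tol``; the error names the worst offending entry.
    """
    path = Path(path)
    values, labels = _read_labelled_matrix(path)
    if kind in ("sc", "fcd"):
        if values.shape[0] != values.shape[1]:
            raise ParameterError(f"{path}: {kind} matrix must be square")
        asym = np.abs(values - values.T)
        if asym.max() > tol:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ParameterError(
                f"{path}: asymmetric at ({labels[i]}, {labels[j]}): "
                f"{values[i, j]:g} vs {values[j, i]:g}"
            )
        values = (values + values.T) / 2
    if kind == "sc":
        return Connectome(weights=values, labels=tuple(labels))
    if kind == "fcd":
        meta = _read_sidecar(path)
        spec = WindowSpec(meta.get("window_length", 60.0), meta.get("window_step", 20.0))
        starts = np.asarray(meta.get("starts", spec.step * np.arange(values.shape[0])))
        return FCDMatrix(values, spec, starts)
    if kind == "series":
        meta = _read_sidecar(path)
        return BOLDLikeSeries(values, tr=float(meta.get("tr", 2.0)), t0=float(meta.get("t0", 0.0)))
    raise ParameterError(f"unknown matrix kind {kind!r}")


def _write_labelled_matrix(path: Path, values: np.ndarray, labels) -> None:
    df = pd.DataFrame(values, index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_connectome(path, net: Connectome, meta: dict | None = None) -> None:
    path = Path(path)
    _write_labelled_matrix(path, net.weights, net.labels)
    _write_sidecar(path, {"kind": "sc", **(meta or {})})


def read_connectome(path, tol: float = 1e-8) -> Connectome:
    return read_matrix(path, "sc", tol=tol)


def write_frequencies(path, freqs: FrequencyTable, labels=None) -> None:
    path = Path(path)
    labels = labels or [f"R{i:03d}" for i in range(freqs.freq_hz.size)]
    pd.DataFrame({"region": labels, "freq_hz": freqs.freq_hz}).to_csv(path, sep="\t", index=False)


def read_frequencies(path) -> FrequencyTable:
    df = pd.read_csv(path, sep="\t")
    return FrequencyTable(df["freq_hz"].to_numpy(dtype=float))


def write_series(path, series: BOLDLikeSeries, labels=None, meta: dict | None = None) -> None:
    path = Path(path)
    labels = labels or [f"R{i:03d}" for i in range(series.n_regions)]
    df = pd.DataFrame(series.values, index=labels, columns=[f"{t:g}" for t in series.times])
    df.to_csv(path, sep="\t", float_format="%.10g")
    _write_sidecar(path, {"kind": "series", "tr": series.tr, "t0": series.t0, **(meta or {})})


def read_series(path) -> BOLDLikeSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = _read_sidecar(path)
    return BOLDLikeSeries(df.to_numpy(dtype=float), tr=float(meta.get("tr", 2.0)), t0=float(meta.get("t0", 0.0)))


def write_fcd(path, fcd: FCDMatrix, meta: dict | None = None) -> None:
    path = Path(path)
    labels = [f"w{i:03d}" for i in range(fcd.n_windows)]
    _write_labelled_matrix(path, fcd.values, labels)
    _write_sidecar(
        path,
        {
            "kind": "fcd",
            "window_length": fcd.spec.length,
            "window_step": fcd.spec.step,
            "starts": [float(s) for s in fcd.starts],
            **(meta or {}),
        },
    )


def read_fcd(path) -> FCDMatrix:
    return read_matrix(path, "fcd")


def write_partition(path, partition: RSNPartition, labels=None) -> None:
    rows = []
    for name in partition.networks:
        for i in partition.nodes(name):
            rows.append((labels[i] if labels else f"R{i:03d}", i, name))
    pd.DataFrame(rows, columns=["region", "index", "network"]).to_csv(path, sep="\t", index=False)


def read_partition(path) -> RSNPartition:
    df = pd.read_csv(path, sep="\t")
    assignment: dict[str, list[int]] = {}
    for _, row in df.iterrows():
        assignment.setdefault(str(row["network"]), []).append(int(row["index"]))
    return RSNPartition({k: tuple(v) for k, v in assignment.items()})


def write_receptor_map(path, rmap: ReceptorMap, labels=None) -> None:
    labels = labels or [f"R{i:03d}" for i in range(rmap.density.size)]
    pd.DataFrame({"region": labels, "density": rmap.density}).to_csv(path, sep="\t", index=False)


def read_receptor_map(path) -> ReceptorMap:
    df = pd.read_csv(path, sep="\t")
    return ReceptorMap(df["density"].to_numpy(dtype=float))
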