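"""Config parsing, result serialization, and run provenance.

Network specifications are stored as YAML with three sections::

    units:                      # optional; defaults are seconds and Hz
      time: s | ms
      rate: Hz | kHz
    neurons:
      defaults: {h: 1.0, a: 0.1, tau: 0.01}
      count: 4                  # homogeneous, or an explicit list:
      list: [{h: 1.0, a: 0.1, tau: 0.01}, ...]
    weights:
      dense: [[...], ...]       # K x K, or sparse triplets (i <- j):
      sparse: [[i, j, w], ...]
    background: 1500.0          # scalar or per-neuron list (rate units)

Times (tau) are converted to seconds and rates (h, background) to Hz on
ingestion.  Reports are written as TSV or JSON with a manifest recording
the command, parameters, seeds and package version, so any run can be
reproduced exactly.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .network import NetworkSpec, NeuronParams
from .simulate import SpikeRecord, StateTrace

__all__ = [
    "load_config",
    "save_config",
    "write_report",
    "write_spikes",
    "write_trace",
    "RunManifest",
]

_TIME_UNITS = {"s": 1.0, "ms": 1e-3}
_RATE_UNITS = {"hz": 1.0, "khz": 1e3}

_DEFAULTS = {"h": 1.0, "a": 0.1, "tau": 0.01}


class ConfigError(ValueError):
    """Schema or validation failure in a network config file."""


def load_config(path) -> NetworkSpec:
    """Load and validate a NetworkSpec from a YAML config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {"units", "neurons", "weights", "background"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown top-level keys {sorted(unknown)}; "
                          f"expected {sorted(known)}")
    units = raw.get("units") or {}
    t_scale = _TIME_UNITS.get(str(units.get("time", "s")).lower())
    r_scale = _RATE_UNITS.get(str(units.get("rate", "Hz")).lower())
    if t_scale is None or r_scale is None:
        raise ConfigError(f"{path}: units.time must be s|ms and units.rate Hz|kHz")

    nsec = raw.get("neurons") or {}
    defaults = dict(_DEFAULTS)
    defaults.update(nsec.get("defaults") or {})
    if "list" in nsec:
        entries = nsec["list"]
    else:
        entries = [{} for _ in range(int(nsec.get("count", 1)))]
    params = []
    for k, entry in enumerate(entries):
        d = dict(defaults)
        d.update(entry or {})
        extra = set(d) - {"h", "a", "tau"}
        if extra:
            raise ConfigError(f"{path}: neuron {k}: unknown fields {sorted(extra)}")
        try:
            params.append(NeuronParams(h=float(d["h"]) * r_scale,
                                       a=float(d["a"]),
                                       tau=float(d["tau"]) * t_scale))
        except ValueError as e:
            raise ConfigError(f"{path}: neuron {k}: {e}") from e
    K = len(params)

    wsec = raw.get("weights") or {}
    W = np.zeros((K, K))
    if "dense" in wsec:
        W = np.asarray(wsec["dense"], dtype=float)
        if W.shape != (K, K):
            raise ConfigError(f"{path}: weights.dense must be {K}x{K}, "
                              f"got {W.shape}")
    elif "sparse" in wsec:
        for row in wsec["sparse"]:
            if len(row) != 3:
                raise ConfigError(f"{path}: sparse weight entries are [i, j, w]")
            i, j, w = int(row[0]), int(row[1]), float(row[2])
            if not (0 <= i < K and 0 <= j < K):
                raise ConfigError(f"{path}: weight index ({i},{j}) out of range")
            W[i, j] = w
    elif wsec:
        raise ConfigError(f"{path}: weights section needs 'dense' or 'sparse'")

    bg = raw.get("background", 0.0)
    bg_arr = (np.full(K, float(bg)) if np.isscalar(bg)
              else np.asarray(bg, dtype=float))
    try:
        return NetworkSpec(params=params, weights=W, background=bg_arr * r_scale)
    except ValueError as e:
        raise ConfigError(f"{path}: {e}") from e


def save_config(spec: NetworkSpec, path) -> None:
    """Serialize a NetworkSpec to YAML (SI units)."""
    W = spec.weights
    nz = np.nonzero(W)
    sparse = len(nz[0]) < 0.25 * W.size
    doc = {
        "neurons": {"list": [{"h": p.h, "a": p.a, "tau": p.tau}
                             for p in spec.params]},
        "weights": (
            {"sparse": [[int(i), int(j), float(W[i, j])]
                        for i, j in zip(*nz)]}
            if sparse else {"dense": W.tolist()}),
        "background": spec.background.tolist(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# results and provenance
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Provenance of one command invocation."""

    command: str
    parameters: dict
    seed: int | None
    version: str
    timestamp: str = field(default_factory=lambda: datetime.datetime.now(
        datetime.timezone.utc).isoformat())
    outputs: list = field(default_factory=list)

    @classmethod
    def create(cls, command: str, parameters: dict, seed: int | None):
        from . import __version__

        clean = {}
        for k, v in parameters.items():
            if isinstance(v, np.ndarray):
                clean[k] = v.tolist()
            elif isinstance(v, (str, int, float, bool, list, tuple, dict,
                                type(None))):
                clean[k] = v
            # non-serializable plumbing (e.g. dispatch callables) is dropped
        return cls(command=command, parameters=clean, seed=seed,
                   version=__version__)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def write_report(results: dict, path, fmt: str = "json",
                 manifest: RunManifest | None = None) -> None:
    """Write a flat result mapping as JSON or TSV with deterministic order.

    Values may be scalars or 1-d arrays (TSV expands arrays into columns
    of a table; JSON keeps them as lists).  A manifest, when given, is
    written next to the report with suffix ``.manifest.json``.
    """
    path = Path(path)
    ordered = {k: (np.asarray(v).tolist() if isinstance(v, (np.ndarray, list))
                   else v)
               for k, v in sorted(results.items())}
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(ordered, fh, indent=2, sort_keys=True,
                      default=float)
            fh.write("\n")
    elif fmt == "tsv":
        arrays = {k: v for k, v in ordered.items() if isinstance(v, list)}
        scalars = {k: v for k, v in ordered.items() if not isinstance(v, list)}
        with open(path, "w") as fh:
            if arrays:
                df = pd.DataFrame(arrays)
                df.to_csv(fh, sep="\t", index=False, float_format="%.17g")
            for k, v in scalars.items():
                fh.write(f"# {k}\t{v!r}\n")
    else:
        raise ValueError(f"unknown report format: {fmt}")
    if manifest is not None:
        manifest.outputs.append(str(path))
        manifest.write(path.with_suffix(path.suffix + ".manifest.json"))


def write_spikes(rec: SpikeRecord, path) -> None:
    """Spike train as TSV with columns replica, neuron, time_s."""
    rep = (rec.replicas if rec.replicas is not None
           else np.zeros(rec.n_events, dtype=int))
    df = pd.DataFrame({"replica": rep, "neuron": rec.neurons,
                       "time_s": rec.times})
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_trace(trace: StateTrace, path, sidecar: dict | None = None) -> None:
    """State trace as TSV (columns time_s, x0..x{K-1}) plus a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(trace.x.T, columns=[f"x{i}" for i in range(trace.x.shape[0])])
    df.insert(0, "time_s", trace.times)
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
    meta = {"dt": trace.dt, "t0": trace.t0, "seed": trace.seed}
    meta.update(sidecar or {})
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_trace(path) -> StateTrace:
    """Load a trace written by :func:`write_trace`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        meta = json.load(fh)
    x = df[[c for c in df.columns if c.startswith("x")]].to_numpy().T
    return StateTrace(t0=meta["t0"], dt=meta["dt"], x=x, seed=meta.get("seed", 0))
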