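"""Serialisation of traces, spike trains and fits.

Runtime containers are NumPy ``.npz`` archives with a JSON metadata entry;
text interchange uses gzipped CSV for stimulus traces, plain spike-time
lists (one time in seconds per line) for spike trains, and delimited tables
for filters and analysis results.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np

from .hh import SpikeTrain
from .stimulus import DT_STIM, EnvelopeSpec, StimulusTrace

__all__ = [
    "save_trace",
    "load_trace",
    "save_spikes_text",
    "load_spikes_text",
    "save_trace_text",
    "save_fit",
    "load_fit_arrays",
]


def _sd_spec_meta(sd_spec):
    if isinstance(sd_spec, EnvelopeSpec):
        return {"kind": sd_spec.kind, "period_p": sd_spec.period_p,
                "sigma": sd_spec.sigma}
    return float(sd_spec)


def _sd_spec_from_meta(meta):
    if isinstance(meta, dict):
        return EnvelopeSpec(kind=meta["kind"], period_p=meta["period_p"],
                            sigma=meta["sigma"])
    return float(meta)


def save_trace(path, trace: StimulusTrace) -> None:
    """Binary container: values + JSON metadata (mu, sd_spec, seed, dt)."""
    meta = {"mean_mu": trace.mean_mu, "sd_spec": _sd_spec_meta(trace.sd_spec),
            "seed": trace.seed, "dt_sample": trace.dt_sample}
    np.savez_compressed(path, values=trace.values,
                        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))


def load_trace(path) -> StimulusTrace:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        return StimulusTrace(
            values=z["values"], mean_mu=meta["mean_mu"],
            sd_spec=_sd_spec_from_meta(meta["sd_spec"]), seed=meta["seed"],
            dt_sample=meta["dt_sample"],
        )


def save_trace_text(path, trace: StimulusTrace) -> None:
    """Gzipped CSV interchange format: header comment + one value per line."""
    meta = {"mean_mu": trace.mean_mu, "sd_spec": _sd_spec_meta(trace.sd_spec),
            "seed": trace.seed, "dt_sample": trace.dt_sample}
    with gzip.open(path, "wt") as f:
        f.write(f"# {json.dumps(meta)}\n")
        f.write("current\n")
        for v in trace.values:
            f.write(f"{v:.9g}\n")


def save_spikes_text(path, spikes: SpikeTrain) -> None:
    """Plain-text spike-time list, one time in seconds per line."""
    with open(path, "w") as f:
        f.write(f"# duration_s={spikes.duration}\n")
        for t in spikes.spike_times:
            f.write(f"{t:.6f}\n")


def load_spikes_text(path) -> SpikeTrain:
    duration = None
    times = []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if line.startswith("#"):
                if "duration_s=" in line:
                    duration = float(line.split("duration_s=")[1])
                continue
            if line:
                times.append(float(line))
    if duration is None:
        raise ValueError("missing duration header")
    return SpikeTrain(spike_times=np.asarray(times), duration=duration)


def save_voltage_decimated(path, trace, stride: int = 100) -> None:
    """Save a voltage trace decimated for inspection (default every 1 ms).

    Writes CSV columns (time_s, V_mV); the full 0.01 ms trace is rarely
    needed outside debugging and is large.
    """
    t = trace.times()[::stride]
    v = trace.V[::stride]
    with open(path, "w") as f:
        f.write("time_s,V_mV\n")
        for ti, vi in zip(t, v):
            f.write(f"{ti:.6f},{vi:.4f}\n")


def save_fit(path, fit, extra_meta: dict | None = None) -> None:
    """Serialise a GLMResults with weights, link and optimiser diagnostics."""
    m = fit.model
    meta = {
        "link": m.link.name,
        "n_stim": m.n_stim,
        "n_hist": m.n_hist,
        "llf": fit.llf,
        "converged": bool(fit.converged),
        "grad_norm": fit.grad_norm,
        "n_iter": fit.n_iter,
        "t_hist_ms": fit.t_hist_ms,
    }
    if extra_meta:
        meta.update(extra_meta)
    arrays = {"params": fit.params}
    sb = getattr(m, "stim_basis", None)
    hb = getattr(m, "hist_basis", None)
    if sb is not None:
        arrays["stim_basis"] = sb.functions
        arrays["stim_lags_ms"] = sb.lags_ms
    if hb is not None:
        arrays["hist_basis"] = hb.functions
        arrays["hist_lags_ms"] = hb.lags_ms
    np.savez_compressed(
        path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **arrays,
    )


def load_fit_arrays(path) -> dict:
    """Load a serialised fit as a plain dict of metadata and arrays."""
    out = {}
    with np.load(path) as z:
        out["meta"] = json.loads(bytes(z["meta"]).decode())
        for k in z.files:
            if k != "meta":
                out[k] = z[k]
    return out


def export_filter_text(path, lags_ms, values) -> None:
    """Delimited (lag_ms, filter_value) export for plotting."""
    with open(path, "w") as f:
        f.write("lag_ms,filter_value\n")
        for lag, v in zip(lags_ms, values):
            f.write(f"{lag:.3f},{v:.9g}\n")
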