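"""Plain-text readers and writers.

Spike files are two whitespace-separated columns (source_id, time in ms),
sorted by time, one file per ensemble — compatible with common spike-raster
text dialects.  Voltage traces are CSV with columns time_ms, v_mV; sweep
results and STA tables are CSV.
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .spike_inputs import SpikeTrain, SpikeTrainEnsemble
from .lif_neuron import VmTrace
from .correlation_analysis import STAResult

__all__ = [
    "write_spike_trains", "read_spike_trains",
    "write_vm_trace", "read_vm_trace",
    "write_results", "write_sta", "load_config",
]


def write_spike_trains(path, trains) -> None:
    """Write a SpikeTrainEnsemble (or list of SpikeTrain) as id/time text rows."""
    if isinstance(trains, SpikeTrainEnsemble):
        trains = trains.trains
    ids = np.concatenate([np.full(t.n_spikes, t.source_id, dtype=np.int64)
                          for t in trains]) if trains else np.empty(0, dtype=np.int64)
    times = np.concatenate([t.times for t in trains]) if trains else np.empty(0)
    order = np.argsort(times, kind="stable")
    with open(path, "w") as fh:
        for i, t in zip(ids[order], times[order]):
            fh.write(f"{i} {t:.6f}\n")


def read_spike_trains(path, duration: float,
                      n_sources: Optional[int] = None) -> list:
    """Read a spike text file back into per-source SpikeTrains.

    ``n_sources`` forces empty trains for sources without spikes (ids are then
    taken to be 0..n_sources-1).
    """
    data = np.loadtxt(path, ndmin=2) if Path(path).stat().st_size else np.empty((0, 2))
    ids = data[:, 0].astype(np.int64) if data.size else np.empty(0, dtype=np.int64)
    times = data[:, 1] if data.size else np.empty(0)
    source_ids = (np.arange(n_sources) if n_sources is not None
                  else np.unique(ids))
    return [SpikeTrain(int(s), np.sort(times[ids == s]), duration)
            for s in source_ids]


def write_vm_trace(path, trace: VmTrace, spikes_path=None) -> None:
    """Write a voltage trace as CSV (time_ms, v_mV); optionally its spikes too."""
    df = pd.DataFrame({"time_ms": trace.t, "v_mV": trace.values})
    df.to_csv(path, index=False, float_format="%.6f")
    if spikes_path is not None:
        write_spike_trains(spikes_path,
                           [SpikeTrain(0, trace.spike_times,
                                       trace.duration + trace.dt)])


def read_vm_trace(path, spikes_path=None) -> VmTrace:
    """Read a voltage-trace CSV (and optional spike file) back into a VmTrace."""
    df = pd.read_csv(path)
    t = df["time_ms"].to_numpy()
    if t.size < 2:
        raise ValueError("trace file must contain at least two samples")
    dt = float(t[1] - t[0])
    duration = float(t[-1])
    if spikes_path is not None:
        trains = read_spike_trains(spikes_path, duration + dt)
        spikes = trains[0].times if trains else np.empty(0)
    else:
        spikes = np.empty(0)
    return VmTrace(dt=dt, values=df["v_mV"].to_numpy(), spike_times=spikes,
                   duration=duration)


def write_results(df: pd.DataFrame, path) -> None:
    """Write a long-format sweep result table as CSV."""
    df.to_csv(path, index=False)


def write_sta(sta: STAResult, path) -> None:
    """Write an STA pair as CSV (lag_ms, trigger_avg_mV, partner_avg_mV, n_triggers)."""
    pd.DataFrame({"lag_ms": sta.lags,
                  "trigger_avg_mV": sta.trigger_avg,
                  "partner_avg_mV": sta.partner_avg,
                  "n_triggers": sta.n_triggers}).to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a JSON or YAML configuration mapping."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(p) as fh:
        cfg = yaml.safe_load(fh)   # YAML is a JSON superset
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg
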