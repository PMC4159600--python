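"""Correlation and spike-triggered-average measurements.

Three operators act on simulated output:

* output *spike* correlation — each spike train is low-pass filtered with a
  unit-area triangular kernel (base 5 ms by default) sampled on the recording
  grid, and the Pearson coefficient of the two filtered signals is taken;
* *membrane-potential* correlation — before correlating two voltage traces,
  50 ms of both signals is removed after every threshold crossing of either
  neuron ("spike cleaning"), mimicking the spike-removal step applied to
  intracellular recordings;
* spike-triggered averages — voltage segments of the spiking (trigger) neuron
  and the simultaneous trace of its partner, aligned on the trigger's spikes.

Undefined coefficients (constant signals, too few valid samples) are reported
as missing (NaN) rather than silently as zero.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .lif_neuron import VmTrace
from .spike_inputs import SpikeTrain

__all__ = [
    "CorrelationResult", "STAResult",
    "filter_spike_train", "spike_correlation",
    "clean_vm_pair", "vm_correlation", "spike_triggered_average",
    "combine_trials", "combine_stas", "pooled_correlation",
]


@dataclass(frozen=True)
class CorrelationResult:
    """A Pearson coefficient with its trial statistics.

    ``coefficient`` is the single-trial value (or the trial mean after
    aggregation); NaN flags an undefined ("missing") coefficient.
    """

    coefficient: float
    n_valid_samples: int
    per_trial: tuple = ()
    mean: float = math.nan
    sem: float = math.nan

    @property
    def missing(self) -> bool:
        return math.isnan(self.coefficient)

    @staticmethod
    def single(r: float, n: int) -> "CorrelationResult":
        return CorrelationResult(coefficient=r, n_valid_samples=n,
                                 per_trial=(r,), mean=r, sem=math.nan)


def combine_trials(results: Sequence[CorrelationResult]) -> CorrelationResult:
    """Average per-trial coefficients; missing trials are dropped (and leave
    the aggregate missing only if no trial was valid)."""
    per = tuple(r.coefficient for r in results)
    valid = np.array([c for c in per if not math.isnan(c)], dtype=float)
    n = int(sum(r.n_valid_samples for r in results))
    if valid.size == 0:
        return CorrelationResult(math.nan, n, per, math.nan, math.nan)
    mean = float(valid.mean())
    sem = float(valid.std(ddof=1) / math.sqrt(valid.size)) if valid.size > 1 else math.nan
    return CorrelationResult(mean, n, per, mean, sem)


def pooled_correlation(xs: Sequence[np.ndarray],
                       ys: Sequence[np.ndarray]) -> CorrelationResult:
    """Pearson coefficient over trial samples pooled into one long record —
    the alternative to computing per trial and averaging (:func:`combine_trials`)."""
    x = np.concatenate([np.asarray(v, float) for v in xs])
    y = np.concatenate([np.asarray(v, float) for v in ys])
    if x.size != y.size:
        raise ValueError("pooled signals must have equal length")
    return CorrelationResult.single(_pearson(x, y), x.size)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2:
        return math.nan
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        return math.nan
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def filter_spike_train(train: SpikeTrain, kernel_support: float = 5.0,
                       dt: float = 0.1) -> np.ndarray:
    """Low-pass filter a spike train with a triangular kernel.

    Each spike contributes a symmetric triangular bump of base
    ``kernel_support`` ms centred on the spike, sampled on the dt grid.  The
    kernel is normalised to unit area on the grid, so the signal integrates
    (sum times dt) to the spike count.
    """
    if kernel_support <= 0 or dt <= 0:
        raise ValueError("kernel_support and dt must be positive")
    n = int(round(train.duration / dt))
    sig = np.zeros(n + 1)
    if train.times.size == 0:
        return sig
    counts = np.bincount(
        np.clip(np.rint(train.times / dt).astype(np.int64), 0, n),
        minlength=n + 1).astype(np.float64)
    half = kernel_support / 2.0
    k = int(math.ceil(half / dt)) - 1       # offsets with strictly positive weight
    offs = np.arange(-k, k + 1) * dt
    kernel = 1.0 - np.abs(offs) / half
    kernel /= kernel.sum() * dt             # unit area on the grid
    return np.convolve(counts, kernel, mode="same")


def spike_correlation(a: SpikeTrain, b: SpikeTrain, kernel_support: float = 5.0,
                      dt: float = 0.1) -> CorrelationResult:
    """Pearson correlation of two triangularly filtered spike trains."""
    if a.duration != b.duration:
        raise ValueError("spike trains must share one duration")
    fa = filter_spike_train(a, kernel_support, dt)
    fb = filter_spike_train(b, kernel_support, dt)
    return CorrelationResult.single(_pearson(fa, fb), fa.size)


def clean_vm_pair(a: VmTrace, b: VmTrace, removal: float = 50.0) -> np.ndarray:
    """Validity mask after spike cleaning of a simultaneously recorded pair.

    For every spike time s of *either* neuron the samples in [s, s + removal)
    are marked invalid; overlapping removal windows merge.  The mask applies
    identically to both traces.
    """
    if a.dt != b.dt or a.values.size != b.values.size:
        raise ValueError("traces must share dt and duration")
    n = a.values.size
    mask = np.ones(n, dtype=bool)
    width = int(round(removal / a.dt))
    for s in np.concatenate([a.spike_times, b.spike_times]):
        start = int(round(s / a.dt))
        mask[start:start + width] = False
    return mask


def vm_correlation(a: VmTrace, b: VmTrace,
                   mask: Optional[np.ndarray] = None) -> CorrelationResult:
    """Pearson correlation of two voltage traces over the masked-in samples."""
    if a.dt != b.dt or a.values.size != b.values.size:
        raise ValueError("traces must share dt and duration")
    if mask is None:
        x, y = a.values, b.values
    else:
        x, y = a.values[mask], b.values[mask]
    return CorrelationResult.single(_pearson(x, y), x.size)


@dataclass(frozen=True)
class STAResult:
    """Spike-triggered voltage averages around the trigger neuron's spikes."""

    window: tuple            # (t_pre, t_post) in ms, t_pre <= 0 <= t_post
    lags: np.ndarray         # ms relative to the trigger spike
    trigger_avg: np.ndarray  # mV
    partner_avg: np.ndarray  # mV
    n_triggers: int
    n_skipped: int = 0

    @property
    def missing(self) -> bool:
        return self.n_triggers == 0

    def at_lag(self, lag: float, which: str = "trigger") -> float:
        arr = self.trigger_avg if which == "trigger" else self.partner_avg
        i = int(np.argmin(np.abs(self.lags - lag)))
        return float(arr[i])


def spike_triggered_average(trigger: VmTrace, partner: VmTrace,
                            window: tuple = (-100.0, 20.0),
                            exclude_overlapping: bool = False) -> STAResult:
    """Average raw voltage segments of both neurons around the trigger spikes.

    Triggers whose window exceeds the recording are skipped and counted in
    ``n_skipped``.  Segments containing an earlier trigger spike within the
    window are kept by default (every spike is averaged);
    ``exclude_overlapping`` drops them.
    """
    if trigger.dt != partner.dt or trigger.values.size != partner.values.size:
        raise ValueError("traces must share dt and duration")
    t_pre, t_post = window
    if not (t_pre <= 0 <= t_post):
        raise ValueError("window must bracket lag 0")
    dt = trigger.dt
    npre = int(round(-t_pre / dt))
    npost = int(round(t_post / dt))
    lags = np.arange(-npre, npost + 1) * dt
    acc_t = np.zeros(npre + npost + 1)
    acc_p = np.zeros(npre + npost + 1)
    spk_idx = np.rint(trigger.spike_times / dt).astype(np.int64)
    n_used = 0
    n_skipped = 0
    nsamp = trigger.values.size
    for m, i in enumerate(spk_idx):
        lo, hi = i - npre, i + npost
        if lo < 0 or hi >= nsamp:
            n_skipped += 1
            continue
        if exclude_overlapping and m > 0 and i - spk_idx[m - 1] <= npre:
            n_skipped += 1
            continue
        acc_t += trigger.values[lo:hi + 1]
        acc_p += partner.values[lo:hi + 1]
        n_used += 1
    if n_used == 0:
        nanarr = np.full(lags.size, np.nan)
        return STAResult(window, lags, nanarr, nanarr.copy(), 0, n_skipped)
    return STAResult(window, lags, acc_t / n_used, acc_p / n_used,
                     n_used, n_skipped)


def combine_stas(stas: Sequence[STAResult]) -> STAResult:
    """Trigger-count-weighted average of per-trial STAs over a common window."""
    valid = [s for s in stas if not s.missing]
    if not valid:
        s0 = stas[0]
        return STAResult(s0.window, s0.lags, np.full(s0.lags.size, np.nan),
                         np.full(s0.lags.size, np.nan), 0,
                         sum(s.n_skipped for s in stas))
    w = np.array([s.n_triggers for s in valid], dtype=float)
    trig = np.sum([s.trigger_avg * s.n_triggers for s in valid], axis=0) / w.sum()
    part = np.sum([s.partner_avg * s.n_triggers for s in valid], axis=0) / w.sum()
    return STAResult(valid[0].window, valid[0].lags, trig, part,
                     int(w.sum()), sum(s.n_skipped for s in stas))
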