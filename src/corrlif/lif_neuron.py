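"""Conductance-based leaky integrate-and-fire neuron.

Subthreshold dynamics

    C dV/dt = -G_L (V - V_r) - G_E(t) (V - V_E) - G_I(t) (V - V_I) + I_ext,

where the total excitatory and inhibitory conductances are linear
superpositions of alpha-function transients g(t) = J (t/tau) exp(1 - t/tau)
over all input spikes.  When V crosses the threshold V_th a spike is emitted,
V is reset to V_r and clamped there for the refractory period t_ref while the
synaptic conductances keep evolving (a "freeze" alternative is available).

Numerics: the alpha transient solves a two-variable linear system which is
propagated *exactly* over each half step via its matrix exponential; spike
arrivals increment the auxiliary state.  The membrane equation is advanced by
classical fixed-step RK4 (default dt = 0.1 ms) using the conductances at the
step endpoints and midpoint.  Runs are bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.signal import lfilter

from .spike_inputs import SpikeTrainEnsemble

__all__ = [
    "NeuronParams", "SynapseParams", "VmTrace",
    "alpha_conductance", "summed_conductance",
    "simulate", "simulate_pair", "measure_rate", "mean_rate",
]


@dataclass(frozen=True)
class NeuronParams:
    """Passive membrane, threshold and reversal-potential parameters.

    Defaults are standard cortical regular-spiking values: a 20-ms membrane
    time constant (C/G_L), 15 mV from rest to threshold, and reversal
    potentials placing inhibition 5 mV below rest (shunting-dominated).
    """

    C: float = 500.0       # pF
    G_L: float = 25.0      # nS
    V_r: float = -65.0     # mV, resting = reset potential
    V_th: float = -50.0    # mV
    t_ref: float = 2.0     # ms
    V_E: float = 0.0       # mV
    V_I: float = -70.0     # mV

    def __post_init__(self):
        if self.C <= 0 or self.G_L <= 0:
            raise ValueError("C and G_L must be positive")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")
        if not (self.V_I <= self.V_r < self.V_th < self.V_E):
            raise ValueError("require V_I <= V_r < V_th < V_E")

    @property
    def tau_m(self) -> float:
        """Passive membrane time constant C/G_L in ms."""
        return self.C / self.G_L


@dataclass(frozen=True)
class SynapseParams:
    """Alpha-synapse peak conductances (nS) and rise times (ms)."""

    J_E: float = 15.0
    J_I: float = 15.0
    tau_E: float = 0.3
    tau_I: float = 2.0

    def __post_init__(self):
        if min(self.J_E, self.J_I, self.tau_E, self.tau_I) <= 0:
            raise ValueError("synapse parameters must be strictly positive")


@dataclass(frozen=True)
class VmTrace:
    """Recorded membrane potential on the grid {0, dt, 2dt, ...} plus spikes.

    At a threshold-crossing sample the recorded value is V_th (the crossing
    level); refractory samples are recorded at V_r.
    """

    dt: float
    values: np.ndarray
    spike_times: np.ndarray
    duration: float

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt

    def spike_count_rate(self) -> float:
        """Output rate in Hz."""
        return 1000.0 * self.spike_times.size / self.duration


def alpha_conductance(t_since_spike, peak: float, tau: float):
    """Closed-form alpha transient J (t/tau) e^{1 - t/tau}; zero for t < 0.

    Peaks at exactly ``peak`` when t = tau.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(t_since_spike, dtype=float)
    g = np.where(t >= 0, peak * (t / tau) * np.exp(1.0 - t / tau), 0.0)
    return g if g.shape else float(g)


def summed_conductance(spike_times: np.ndarray, peak: float, tau: float,
                       duration: float, dt: float) -> np.ndarray:
    """Total conductance G(t) on the dt grid for one synapse type.

    Linear superposition of alpha transients over all spikes (spike times are
    quantised to the grid), computed with the same discrete two-state filter
    the simulator uses, so the superposition is exact sample-for-sample.
    """
    n = int(round(duration / dt))
    idx = np.clip(np.rint(np.asarray(spike_times) / dt).astype(np.int64), 0, n)
    u = np.bincount(idx, minlength=n + 1).astype(np.float64) * peak
    beta = np.exp(-dt / tau)
    b = [0.0, np.e * dt / tau * beta]
    a = [1.0, -2.0 * beta, beta * beta]
    return lfilter(b, a, u)


@njit(cache=False)
def _integrate(wE, wI, n_steps, dt, C, G_L, V_r, V_th, n_ref,
               V_E, V_I, i_ext, tau_E, tau_I, freeze_ref):
    """RK4 membrane update with exact half-step alpha-synapse propagation.

    wE/wI are per-half-step conductance increments (nS) on the dt/2 grid
    (length 2*n_steps + 1).  Returns the voltage samples, spike times and the
    total conductances at the full-grid samples.
    """
    dt2 = 0.5 * dt
    aE = np.exp(-dt2 / tau_E)
    aI = np.exp(-dt2 / tau_I)
    rE = dt2 / tau_E
    rI = dt2 / tau_I

    gE = 0.0
    zE = wE[0]
    gI = 0.0
    zI = wI[0]
    V = V_r
    values = np.empty(n_steps + 1)
    values[0] = V
    GEout = np.empty(n_steps + 1)
    GIout = np.empty(n_steps + 1)
    GEout[0] = gE
    GIout[0] = gI
    max_spikes = n_steps // (n_ref + 1) + 1
    spike_buf = np.empty(max_spikes)
    n_spk = 0
    ref = 0
    for n in range(n_steps):
        ge0 = gE
        gi0 = gI
        if ref > 0 and freeze_ref:
            geh = ge0
            gih = gi0
            ge1 = ge0
            gi1 = gi0
        else:
            gE = aE * (gE + zE * rE)
            zE = aE * zE + wE[2 * n + 1]
            gI = aI * (gI + zI * rI)
            zI = aI * zI + wI[2 * n + 1]
            geh = gE
            gih = gI
            gE = aE * (gE + zE * rE)
            zE = aE * zE + wE[2 * n + 2]
            gI = aI * (gI + zI * rI)
            zI = aI * zI + wI[2 * n + 2]
            ge1 = gE
            gi1 = gI
        GEout[n + 1] = ge1
        GIout[n + 1] = gi1
        if ref > 0:
            V = V_r
            values[n + 1] = V_r
            ref -= 1
            continue
        a0 = -(G_L + ge0 + gi0) / C
        b0 = (G_L * V_r + ge0 * V_E + gi0 * V_I + i_ext) / C
        ah = -(G_L + geh + gih) / C
        bh = (G_L * V_r + geh * V_E + gih * V_I + i_ext) / C
        a1 = -(G_L + ge1 + gi1) / C
        b1 = (G_L * V_r + ge1 * V_E + gi1 * V_I + i_ext) / C
        k1 = a0 * V + b0
        k2 = ah * (V + dt2 * k1) + bh
        k3 = ah * (V + dt2 * k2) + bh
        k4 = a1 * (V + dt * k3) + b1
        V = V + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if V >= V_th:
            spike_buf[n_spk] = (n + 1) * dt
            n_spk += 1
            values[n + 1] = V_th
            V = V_r
            ref = n_ref
        else:
            values[n + 1] = V
    return values, spike_buf[:n_spk], GEout, GIout


def _bin_increments(ensemble: SpikeTrainEnsemble, peak: float, n_half: int,
                    dt2: float) -> np.ndarray:
    times = ensemble.all_times()
    # first-order timing interpolation: each spike impulse is split between the
    # two neighbouring half-grid points by proximity, so the effective input
    # (and hence the trace) is nearly independent of the integration step
    pos = times / dt2
    i0 = np.floor(pos).astype(np.int64)
    frac = pos - i0
    i0 = np.clip(i0, 0, n_half)
    i1 = np.clip(i0 + 1, 0, n_half)
    w = (np.bincount(i0, weights=1.0 - frac, minlength=n_half + 1)
         + np.bincount(i1, weights=frac, minlength=n_half + 1))
    # z-state increment J*e makes the transient peak at exactly J when t = tau
    return w * (np.e * peak)


def simulate(neuron: NeuronParams, syn: SynapseParams,
             exc: SpikeTrainEnsemble, inh: SpikeTrainEnsemble,
             i_ext: float = 0.0, dt: float = 0.1,
             duration: float | None = None,
             refractory_conductance: str = "evolve",
             record_conductance: bool = False):
    """Simulate one neuron driven by excitatory and inhibitory spike pools.

    Parameters
    ----------
    i_ext : constant injected current in pA (the current-injection protocol
        uses holding currents; step protocols are concatenated runs).
    refractory_conductance : "evolve" (default) lets synaptic conductances
        integrate incoming spikes during the refractory pause; "freeze" holds
        them fixed and ignores spikes arriving within the pause.
    record_conductance : if True, return ``(trace, G_E, G_I)`` with the total
        conductances sampled on the recording grid.

    Returns the :class:`VmTrace` (deterministic given the inputs).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if refractory_conductance not in ("evolve", "freeze"):
        raise ValueError("refractory_conductance must be 'evolve' or 'freeze'")
    if exc.duration != inh.duration:
        raise ValueError("excitatory and inhibitory pools must share one duration")
    if duration is None:
        duration = exc.duration
    elif duration > exc.duration:
        raise ValueError("requested duration exceeds the input window")
    n_steps = int(round(duration / dt))
    n_half = 2 * n_steps
    dt2 = dt / 2.0
    wE = _bin_increments(exc, syn.J_E, n_half, dt2)
    wI = _bin_increments(inh, syn.J_I, n_half, dt2)
    n_ref = int(round(neuron.t_ref / dt))
    values, spikes, GE, GI = _integrate(
        wE, wI, n_steps, dt, neuron.C, neuron.G_L, neuron.V_r, neuron.V_th,
        n_ref, neuron.V_E, neuron.V_I, i_ext, syn.tau_E, syn.tau_I,
        refractory_conductance == "freeze")
    if np.isnan(values).any():
        raise RuntimeError(
            "NaN in membrane-potential state; check parameters and inputs "
            f"(first NaN at sample {int(np.isnan(values).argmax())})")
    trace = VmTrace(dt=dt, values=values, spike_times=spikes, duration=duration)
    if record_conductance:
        return trace, GE, GI
    return trace


def simulate_pair(neuron: NeuronParams, syn: SynapseParams,
                  inputs_a, inputs_b, i_ext: float = 0.0, dt: float = 0.1,
                  duration: float | None = None):
    """Two uncoupled, identical neurons driven by their respective input sets."""
    if inputs_a.duration != inputs_b.duration:
        raise ValueError("both input sets must share one duration")
    ta = simulate(neuron, syn, inputs_a.exc, inputs_a.inh, i_ext=i_ext, dt=dt,
                  duration=duration)
    tb = simulate(neuron, syn, inputs_b.exc, inputs_b.inh, i_ext=i_ext, dt=dt,
                  duration=duration)
    return ta, tb


def measure_rate(trace: VmTrace) -> float:
    """Output firing rate in Hz (spike count / duration)."""
    return trace.spike_count_rate()


def mean_rate(traces) -> tuple[float, float]:
    """Mean rate and standard error over a list of trial traces."""
    rates = np.array([measure_rate(t) for t in traces], dtype=float)
    sem = rates.std(ddof=1) / np.sqrt(rates.size) if rates.size > 1 else float("nan")
    return float(rates.mean()), float(sem)
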