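"""Structured synaptic input ensembles.

Generators for homogeneous Poisson spike trains, pairs of Poisson processes with
a prescribed count correlation (shared-component construction), multiple
interaction process (MIP) ensembles, and the temporal manipulations used
throughout the package: uniform spike-time jitter and a fixed excitation/
inhibition lag.  The :func:`build_scenario` entry point assembles these pieces
into the named input configurations (correlated E/I, fluctuation-driven,
non-spike-driving background, spike-driving clusters) for one neuron or for a
pair of neurons sharing part of their input.

All generators take a :class:`numpy.random.Generator`; identical seeds yield
identical ensembles.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

EXCITATORY = "excitatory"
INHIBITORY = "inhibitory"

#: Default pool size N of a MIP ensemble.
DEFAULT_N_TRAINS = 1000
#: Excitatory Poisson rate (Hz) of the fluctuation-driven configuration.
FLUCTUATION_RATE_EXC = 2000.0
#: Excitatory Poisson rate (Hz) of the non-spike-driving background.
NSD_RATE_EXC = 1400.0
#: Inhibitory Poisson rate (Hz) shared by both configurations.
RATE_INH = 1647.0
#: Copy probability of the spike-driving MIP.
SD_COPY_PROB = 0.05


@dataclass(frozen=True)
class SpikeTrain:
    """A single point process: sorted spike times (ms) on a window [0, duration)."""

    source_id: int
    times: np.ndarray
    duration: float

    def __post_init__(self):
        times = np.ascontiguousarray(self.times, dtype=np.float64)
        if times.ndim != 1:
            raise ValueError("spike times must be a 1-d sequence")
        if not self.duration > 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if times.size:
            if np.any(np.diff(times) < 0):
                raise ValueError("spike times must be sorted non-decreasingly")
            if times[0] < 0 or times[-1] >= self.duration:
                raise ValueError("spike times must lie in [0, duration)")
        object.__setattr__(self, "times", times)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Empirical rate in Hz."""
        return 1000.0 * self.times.size / self.duration


@dataclass(frozen=True)
class SpikeTrainEnsemble:
    """A pool of spike trains sharing one window, targeting one synapse type."""

    trains: tuple
    pool_label: str

    def __post_init__(self):
        trains = tuple(self.trains)
        if not trains:
            raise ValueError("ensemble must contain at least one train")
        if self.pool_label not in (EXCITATORY, INHIBITORY):
            raise ValueError(f"unknown pool_label {self.pool_label!r}")
        d0 = trains[0].duration
        if any(t.duration != d0 for t in trains):
            raise ValueError("all trains in an ensemble must share one duration")
        object.__setattr__(self, "trains", trains)

    @property
    def duration(self) -> float:
        return self.trains[0].duration

    @property
    def n_trains(self) -> int:
        return len(self.trains)

    def all_times(self) -> np.ndarray:
        """Concatenated (unsorted) spike times of the whole pool."""
        return np.concatenate([t.times for t in self.trains]) if self.trains else np.empty(0)

    @property
    def total_rate(self) -> float:
        """Summed empirical rate of the pool in Hz."""
        return 1000.0 * sum(t.n_spikes for t in self.trains) / self.duration


@dataclass(frozen=True)
class MIPConfig:
    """Parameters of a multiple-interaction-process input pool.

    The user fixes the daughter rate r and the copy probability c; the mother
    process then runs at r/c so that the total synaptic drive N*r is invariant
    under changes of c.
    """

    n_trains: int = DEFAULT_N_TRAINS
    daughter_rate: float = 2.0      # Hz per daughter train
    copy_prob: float = SD_COPY_PROB
    mother_coupling: float = 0.0    # c_EI between the E and I mother processes
    jitter_width: float = 0.0       # w, ms; 0 disables jitter
    lag: float = 0.0                # ms; >0 delays inhibition (excitation leads)

    def __post_init__(self):
        if not 0.0 <= self.copy_prob <= 1.0:
            raise ValueError(f"copy_prob must lie in [0, 1], got {self.copy_prob}")
        if not 0.0 <= self.mother_coupling <= 1.0:
            raise ValueError(f"mother_coupling must lie in [0, 1], got {self.mother_coupling}")
        if self.jitter_width < 0:
            raise ValueError("jitter_width must be non-negative")
        if self.n_trains < 1:
            raise ValueError("n_trains must be >= 1")
        if self.daughter_rate < 0:
            raise ValueError("daughter_rate must be non-negative")

    @property
    def mother_rate(self) -> float:
        """Rate of the mother process in Hz (diverges as c -> 0)."""
        if self.copy_prob == 0:
            raise ValueError("mother rate undefined for copy_prob = 0 (Poisson limit)")
        return self.daughter_rate / self.copy_prob


SCENARIOS = ("correlated_EI", "fluctuation_driven", "sd", "nsd")


@dataclass(frozen=True)
class ScenarioConfig:
    """Fully specifies one named input configuration.

    ``rate_exc`` may be left as None, in which case it resolves to the
    configuration's canonical value (2000 Hz fluctuation-driven, 1400 Hz for
    the non-spike-driving background used alone or under SD clusters).
    """

    scenario: str
    rate_exc: Optional[float] = None
    rate_inh: float = RATE_INH
    mip: Optional[MIPConfig] = None
    n_neurons: int = 1
    nsd_shared: bool = True
    sd_correlation: float = 0.0
    shared_jitter: bool = True

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.n_neurons not in (1, 2):
            raise ValueError("n_neurons must be 1 or 2")
        if not 0.0 <= self.sd_correlation <= 1.0:
            raise ValueError("sd_correlation must lie in [0, 1]")
        if self.scenario in ("correlated_EI", "sd") and self.mip is None:
            raise ValueError(f"scenario {self.scenario!r} requires a MIPConfig")
        if self.scenario == "correlated_EI" and self.n_neurons != 1:
            raise ValueError("correlated_EI drives a single neuron")

    @property
    def resolved_rate_exc(self) -> float:
        if self.rate_exc is not None:
            return self.rate_exc
        return FLUCTUATION_RATE_EXC if self.scenario == "fluctuation_driven" else NSD_RATE_EXC


@dataclass(frozen=True)
class NeuronInputs:
    """The complete input to one neuron: an excitatory and an inhibitory pool."""

    exc: SpikeTrainEnsemble
    inh: SpikeTrainEnsemble

    def __post_init__(self):
        if self.exc.duration != self.inh.duration:
            raise ValueError("excitatory and inhibitory pools must share one duration")
        if self.exc.pool_label != EXCITATORY or self.inh.pool_label != INHIBITORY:
            raise ValueError("pools must be labelled excitatory/inhibitory respectively")

    @property
    def duration(self) -> float:
        return self.exc.duration


# ---------------------------------------------------------------------------
# elementary generators
# ---------------------------------------------------------------------------

def _poisson_times(rate: float, duration: float, rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate * duration / 1000.0)
    return np.sort(rng.uniform(0.0, duration, n))


def generate_poisson_train(rate: float, duration: float, rng: np.random.Generator,
                           source_id: int = 0) -> SpikeTrain:
    """Homogeneous Poisson process of the given rate (Hz) on [0, duration) ms."""
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    if not duration > 0:
        raise ValueError(f"duration must be positive, got {duration}")
    return SpikeTrain(source_id, _poisson_times(rate, duration, rng), duration)


def generate_correlated_pair(rate: float, rho: float, duration: float,
                             rng: np.random.Generator,
                             source_ids: Sequence[int] = (0, 1)):
    """Two Poisson processes of equal rate with binned-count correlation rho.

    Shared-component construction: a common Poisson process of rate rho*rate is
    superposed with two independent processes of rate (1-rho)*rate each.  The
    marginal rates are exactly equal and the spike-count correlation equals rho
    at every bin width.  Coincident-time collisions are not deduplicated (their
    probability is zero in continuous time).
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    shared = _poisson_times(rho * rate, duration, rng)
    if rho == 1.0:
        return (SpikeTrain(source_ids[0], shared, duration),
                SpikeTrain(source_ids[1], shared.copy(), duration))
    own_a = _poisson_times((1.0 - rho) * rate, duration, rng)
    own_b = _poisson_times((1.0 - rho) * rate, duration, rng)
    a = np.sort(np.concatenate([shared, own_a]))
    b = np.sort(np.concatenate([shared, own_b]))
    return (SpikeTrain(source_ids[0], a, duration),
            SpikeTrain(source_ids[1], b, duration))


def generate_mip_ensemble(mother: SpikeTrain, n_trains: int, copy_prob: float,
                          rng: np.random.Generator, pool_label: str = EXCITATORY,
                          id_offset: int = 0) -> SpikeTrainEnsemble:
    """MIP: each daughter keeps each mother spike independently with probability c.

    Daughter rate converges to c * mother rate and the pairwise binned-count
    correlation between daughters converges to c.  The degenerate c = 0 limit
    (independent Poisson daughters) is handled by the scenario builder, not
    here.
    """
    if not 0.0 < copy_prob <= 1.0:
        raise ValueError(
            f"copy_prob must lie in (0, 1], got {copy_prob}; the c = 0 limit is "
            "N independent Poisson trains and is assembled by the caller")
    if n_trains < 1:
        raise ValueError("n_trains must be >= 1")
    mt = mother.times
    trains = []
    for j in range(n_trains):
        keep = rng.random(mt.size) < copy_prob
        trains.append(SpikeTrain(id_offset + j, mt[keep], mother.duration))
    return SpikeTrainEnsemble(tuple(trains), pool_label)


def apply_jitter(ensemble: SpikeTrainEnsemble, width: float,
                 rng: np.random.Generator) -> SpikeTrainEnsemble:
    """Displace every spike by an independent Uniform(-w/2, +w/2) draw.

    Spikes jittered out of [0, duration) are discarded; w = 0 is the identity.
    """
    if width < 0:
        raise ValueError("jitter width must be non-negative")
    if width == 0:
        return ensemble
    T = ensemble.duration
    out = []
    for tr in ensemble.trains:
        t = tr.times + rng.uniform(-width / 2.0, width / 2.0, tr.times.size)
        t = np.sort(t[(t >= 0) & (t < T)])
        out.append(SpikeTrain(tr.source_id, t, T))
    return SpikeTrainEnsemble(tuple(out), ensemble.pool_label)


def apply_lag(ensemble: SpikeTrainEnsemble, lag: float) -> SpikeTrainEnsemble:
    """Shift every spike time by +lag ms, discarding out-of-window spikes."""
    if lag == 0:
        return ensemble
    T = ensemble.duration
    out = []
    for tr in ensemble.trains:
        t = tr.times + lag
        t = t[(t >= 0) & (t < T)]
        out.append(SpikeTrain(tr.source_id, t, T))
    return SpikeTrainEnsemble(tuple(out), ensemble.pool_label)


# ---------------------------------------------------------------------------
# scenario assembly
# ---------------------------------------------------------------------------

def _independent_poisson_pool(rate_per_train: float, n_trains: int, duration: float,
                              rng: np.random.Generator, pool_label: str,
                              id_offset: int = 0) -> SpikeTrainEnsemble:
    trains = tuple(
        generate_poisson_train(rate_per_train, duration, rng, source_id=id_offset + j)
        for j in range(n_trains))
    return SpikeTrainEnsemble(trains, pool_label)


def _build_correlated_ei(cfg: ScenarioConfig, duration: float,
                         rng: np.random.Generator) -> NeuronInputs:
    m = cfg.mip
    if m.copy_prob == 0.0:
        # Analytic c -> 0 limit: the mother rate diverges while each daughter
        # becomes an independent Poisson process at the daughter rate.
        exc = _independent_poisson_pool(m.daughter_rate, m.n_trains, duration, rng,
                                        EXCITATORY)
        inh = _independent_poisson_pool(m.daughter_rate, m.n_trains, duration, rng,
                                        INHIBITORY, id_offset=m.n_trains)
    else:
        mother_e, mother_i = generate_correlated_pair(
            m.mother_rate, m.mother_coupling, duration, rng)
        exc = generate_mip_ensemble(mother_e, m.n_trains, m.copy_prob, rng,
                                    EXCITATORY)
        inh = generate_mip_ensemble(mother_i, m.n_trains, m.copy_prob, rng,
                                    INHIBITORY, id_offset=m.n_trains)
    if m.lag != 0:
        inh = apply_lag(inh, m.lag)     # positive lag delays inhibition
    if m.jitter_width > 0:
        exc = apply_jitter(exc, m.jitter_width, rng)
        inh = apply_jitter(inh, m.jitter_width, rng)
    return NeuronInputs(exc, inh)


def _sd_trains_single(cfg: ScenarioConfig, duration: float,
                      rng: np.random.Generator, id_offset: int):
    """One jittered spike-driving MIP (list of SpikeTrain) for a single neuron."""
    m = cfg.mip
    mother = generate_poisson_train(m.mother_rate, duration, rng)
    ens = generate_mip_ensemble(mother, m.n_trains, m.copy_prob, rng, EXCITATORY,
                                id_offset=id_offset)
    if m.jitter_width > 0:
        ens = apply_jitter(ens, m.jitter_width, rng)
    return list(ens.trains)


def _sd_trains_pair(cfg: ScenarioConfig, duration: float, rng: np.random.Generator,
                    id_offset: int):
    """Two spike-driving MIPs whose summed inputs are correlated at sd_correlation.

    Matched thinning: the j-th daughters of the two pools keep spikes of the
    shared mother component with the *same* Bernoulli draws and receive the
    same jitter for those spikes, so at sd_correlation = 1 the two inputs are
    identical; spikes from the private mother components are thinned and
    jittered independently.
    """
    m = cfg.mip
    rho = cfg.sd_correlation
    w = m.jitter_width
    r_m = m.mother_rate
    shared = _poisson_times(rho * r_m, duration, rng)
    own_a = _poisson_times((1.0 - rho) * r_m, duration, rng)
    own_b = _poisson_times((1.0 - rho) * r_m, duration, rng)
    half = w / 2.0
    trains_a, trains_b = [], []
    for j in range(m.n_trains):
        ts = shared[rng.random(shared.size) < m.copy_prob]
        ta = own_a[rng.random(own_a.size) < m.copy_prob]
        tb = own_b[rng.random(own_b.size) < m.copy_prob]
        if w > 0:
            if cfg.shared_jitter:
                ts_a = ts_b = ts + rng.uniform(-half, half, ts.size)
            else:
                ts_a = ts + rng.uniform(-half, half, ts.size)
                ts_b = ts + rng.uniform(-half, half, ts.size)
            ta = ta + rng.uniform(-half, half, ta.size)
            tb = tb + rng.uniform(-half, half, tb.size)
        else:
            ts_a = ts_b = ts
        a = np.concatenate([ts_a, ta])
        b = np.concatenate([ts_b, tb])
        a = np.sort(a[(a >= 0) & (a < duration)])
        b = np.sort(b[(b >= 0) & (b < duration)])
        trains_a.append(SpikeTrain(id_offset + j, a, duration))
        trains_b.append(SpikeTrain(id_offset + j, b, duration))
    return trains_a, trains_b


def _build_sd(cfg: ScenarioConfig, duration: float, rng: np.random.Generator):
    """Non-spike-driving background plus spike-driving MIP clusters."""
    m = cfg.mip
    w = m.jitter_width
    r_e, r_i = cfg.resolved_rate_exc, cfg.rate_inh

    def jitter_train(tr: SpikeTrain, gen: np.random.Generator) -> SpikeTrain:
        if w == 0:
            return tr
        t = tr.times + gen.uniform(-w / 2.0, w / 2.0, tr.times.size)
        t = np.sort(t[(t >= 0) & (t < duration)])
        return SpikeTrain(tr.source_id, t, duration)

    if cfg.n_neurons == 1:
        nsd_e = jitter_train(generate_poisson_train(r_e, duration, rng, source_id=0), rng)
        nsd_i = jitter_train(generate_poisson_train(r_i, duration, rng, source_id=1), rng)
        sd = _sd_trains_single(cfg, duration, rng, id_offset=2)
        exc = SpikeTrainEnsemble(tuple([nsd_e] + sd), EXCITATORY)
        inh = SpikeTrainEnsemble((nsd_i,), INHIBITORY)
        return [NeuronInputs(exc, inh)]

    # neuron pair
    if cfg.nsd_shared:
        nsd_e = generate_poisson_train(r_e, duration, rng, source_id=0)
        nsd_i = generate_poisson_train(r_i, duration, rng, source_id=1)
        if cfg.shared_jitter:
            # one jitter draw per background spike, reused by both neurons
            nsd_e = jitter_train(nsd_e, rng)
            nsd_i = jitter_train(nsd_i, rng)
            nsd_e_a = nsd_e_b = nsd_e
            nsd_i_a = nsd_i_b = nsd_i
        else:
            nsd_e_a, nsd_e_b = jitter_train(nsd_e, rng), jitter_train(nsd_e, rng)
            nsd_i_a, nsd_i_b = jitter_train(nsd_i, rng), jitter_train(nsd_i, rng)
    else:
        nsd_e_a = jitter_train(generate_poisson_train(r_e, duration, rng, source_id=0), rng)
        nsd_i_a = jitter_train(generate_poisson_train(r_i, duration, rng, source_id=1), rng)
        nsd_e_b = jitter_train(generate_poisson_train(r_e, duration, rng, source_id=0), rng)
        nsd_i_b = jitter_train(generate_poisson_train(r_i, duration, rng, source_id=1), rng)

    sd_a, sd_b = _sd_trains_pair(cfg, duration, rng, id_offset=2)
    inputs_a = NeuronInputs(SpikeTrainEnsemble(tuple([nsd_e_a] + sd_a), EXCITATORY),
                            SpikeTrainEnsemble((nsd_i_a,), INHIBITORY))
    inputs_b = NeuronInputs(SpikeTrainEnsemble(tuple([nsd_e_b] + sd_b), EXCITATORY),
                            SpikeTrainEnsemble((nsd_i_b,), INHIBITORY))
    return [inputs_a, inputs_b]


def build_scenario(cfg: ScenarioConfig, duration: float,
                   rng: np.random.Generator):
    """Assemble the per-neuron input pools of a named configuration.

    Returns a list of :class:`NeuronInputs`, one entry per neuron.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    if cfg.scenario == "correlated_EI":
        return [_build_correlated_ei(cfg, duration, rng)]
    if cfg.scenario in ("fluctuation_driven", "nsd"):
        out = []
        for k in range(cfg.n_neurons):
            exc = SpikeTrainEnsemble(
                (generate_poisson_train(cfg.resolved_rate_exc, duration, rng, 0),),
                EXCITATORY)
            inh = SpikeTrainEnsemble(
                (generate_poisson_train(cfg.rate_inh, duration, rng, 1),),
                INHIBITORY)
            out.append(NeuronInputs(exc, inh))
        return out
    return _build_sd(cfg, duration, rng)
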