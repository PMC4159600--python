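"""Point-process generators: Poisson, correlated pairs, MIP, jitter, lag,
scenario assembly.  Count-correlation checks use an independent brute-force
binning oracle implemented here."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import corrlif as cl
from corrlif.spike_inputs import _poisson_times


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def binned_counts(times, duration, bin_ms=1.0):
    n = int(round(duration / bin_ms))
    idx = np.minimum((np.asarray(times) / bin_ms).astype(np.int64), n - 1)
    return np.bincount(idx, minlength=n)


def pearson(x, y):
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float) - np.mean(y)
    return float((x * y).sum() / np.sqrt((x * x).sum() * (y * y).sum()))


def count_correlation(a: cl.SpikeTrain, b: cl.SpikeTrain, bin_ms=1.0):
    return pearson(binned_counts(a.times, a.duration, bin_ms),
                   binned_counts(b.times, b.duration, bin_ms))


# ---------------------------------------------------------------------------
# Poisson trains
# ---------------------------------------------------------------------------

def test_poisson_zero_rate_gives_empty_train():
    rng = np.random.default_rng(0)
    assert cl.generate_poisson_train(0.0, 5000.0, rng).n_spikes == 0


@pytest.mark.parametrize("rate,duration", [(-1.0, 100.0), (10.0, 0.0), (10.0, -5.0)])
def test_poisson_rejects_bad_parameters(rate, duration):
    with pytest.raises(ValueError):
        cl.generate_poisson_train(rate, duration, np.random.default_rng(0))


def test_poisson_count_matches_expectation():
    rng = np.random.default_rng(1)
    train = cl.generate_poisson_train(2000.0, 20000.0, rng)
    expected = 40000
    assert abs(train.n_spikes - expected) < 3 * np.sqrt(expected)
    assert np.all(np.diff(train.times) >= 0)


def test_poisson_isi_distribution_is_exponential():
    rng = np.random.default_rng(2)
    train = cl.generate_poisson_train(100.0, 200000.0, rng)
    isi = np.diff(train.times)
    p = stats.kstest(isi, "expon", args=(0, 1000.0 / 100.0)).pvalue
    assert p > 0.01


# ---------------------------------------------------------------------------
# correlated Poisson pairs
# ---------------------------------------------------------------------------

def test_correlated_pair_full_coupling_is_identical():
    rng = np.random.default_rng(3)
    a, b = cl.generate_correlated_pair(500.0, 1.0, 10000.0, rng)
    assert np.array_equal(a.times, b.times)


def test_correlated_pair_rejects_rho_outside_unit_interval():
    rng = np.random.default_rng(3)
    for rho in (-0.1, 1.1):
        with pytest.raises(ValueError):
            cl.generate_correlated_pair(100.0, rho, 1000.0, rng)


@pytest.mark.parametrize("rate,rho,tol", [(2000.0, 0.0, 0.02), (1000.0, 0.5, 0.02)])
def test_correlated_pair_count_correlation(rate, rho, tol):
    # shared-component construction: count correlation equals the shared
    # fraction, verified by brute-force 1-ms binning over 100 s
    rng = np.random.default_rng(4)
    a, b = cl.generate_correlated_pair(rate, rho, 100000.0, rng)
    assert count_correlation(a, b) == pytest.approx(rho, abs=tol)


# ---------------------------------------------------------------------------
# MIP
# ---------------------------------------------------------------------------

def test_mip_copy_prob_one_copies_everything():
    rng = np.random.default_rng(5)
    mother = cl.generate_poisson_train(20.0, 10000.0, rng)
    ens = cl.generate_mip_ensemble(mother, 5, 1.0, rng)
    for d in ens.trains:
        assert np.array_equal(d.times, mother.times)


def test_mip_rejects_degenerate_copy_prob():
    rng = np.random.default_rng(5)
    mother = cl.generate_poisson_train(20.0, 1000.0, rng)
    for c in (0.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            cl.generate_mip_ensemble(mother, 10, c, rng)


def test_mip_daughter_rate_and_pairwise_correlation():
    # thinning: daughter rate = c * mother rate; pairwise count correlation = c
    rng = np.random.default_rng(6)
    mother = cl.generate_poisson_train(20.0, 100000.0, rng)
    ens = cl.generate_mip_ensemble(mother, 1000, 0.05, rng)
    rates = [d.rate for d in ens.trains]
    assert np.mean(rates) == pytest.approx(1.0, abs=0.1)

    pairs = rng.choice(1000, size=(50, 2), replace=False)
    cc = [count_correlation(ens.trains[i], ens.trains[j]) for i, j in pairs]
    assert np.mean(cc) == pytest.approx(0.05, abs=0.01)


def test_between_pool_correlation_is_c_times_cei():
    # daughters of two mothers coupled at c_EI correlate at c * c_EI
    rng = np.random.default_rng(7)
    c, c_ei = 0.2, 0.5
    me, mi = cl.generate_correlated_pair(20.0, c_ei, 200000.0, rng)
    exc = cl.generate_mip_ensemble(me, 20, c, rng)
    inh = cl.generate_mip_ensemble(mi, 20, c, rng, pool_label=cl.INHIBITORY)
    cc = [count_correlation(exc.trains[i], inh.trains[j])
          for i, j in rng.choice(20, size=(20, 2))]
    assert np.mean(cc) == pytest.approx(c * c_ei, abs=0.02)


# ---------------------------------------------------------------------------
# jitter and lag
# ---------------------------------------------------------------------------

def _cluster_ensemble(t0, n, duration):
    train = cl.SpikeTrain(0, np.full(n, float(t0)), duration)
    return cl.SpikeTrainEnsemble((train,), cl.EXCITATORY)


def test_jitter_zero_width_is_identity():
    rng = np.random.default_rng(8)
    ens = _cluster_ensemble(500.0, 100, 1000.0)
    assert cl.apply_jitter(ens, 0.0, rng) is ens


def test_jitter_rejects_negative_width():
    with pytest.raises(ValueError):
        cl.apply_jitter(_cluster_ensemble(500.0, 10, 1000.0), -1.0,
                        np.random.default_rng(0))


def test_jitter_spreads_cluster_uniformly():
    rng = np.random.default_rng(9)
    ens = cl.apply_jitter(_cluster_ensemble(500.0, 3000, 1000.0), 30.0, rng)
    t = ens.trains[0].times
    assert t.size == 3000                      # interior cluster: no boundary loss
    assert t.min() >= 485.0 and t.max() <= 515.0
    assert stats.kstest(t, "uniform", args=(485.0, 30.0)).pvalue > 0.01


def test_jitter_boundary_losses_are_bounded():
    rng = np.random.default_rng(10)
    train = cl.generate_poisson_train(1000.0, 2000.0, rng)
    ens = cl.SpikeTrainEnsemble((train,), cl.EXCITATORY)
    out = cl.apply_jitter(ens, 20.0, rng)
    lost = train.n_spikes - out.trains[0].n_spikes
    at_risk = np.sum((train.times < 10.0) | (train.times >= 1990.0))
    assert 0 <= lost <= at_risk


def test_lag_shifts_and_inverts():
    ens = _cluster_ensemble(500.0, 10, 1000.0)
    lagged = cl.apply_lag(ens, 2.0)
    assert np.allclose(lagged.trains[0].times, 502.0)
    back = cl.apply_lag(lagged, -2.0)
    assert np.allclose(back.trains[0].times, 500.0)
    assert cl.apply_lag(ens, 0.0) is ens


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), w=st.floats(0.1, 50.0),
       lag=st.floats(-20.0, 20.0))
def test_jitter_and_lag_preserve_train_invariants(seed, w, lag):
    rng = np.random.default_rng(seed)
    train = cl.generate_poisson_train(200.0, 500.0, rng)
    ens = cl.SpikeTrainEnsemble((train,), cl.EXCITATORY)
    for out in (cl.apply_jitter(ens, w, rng), cl.apply_lag(ens, lag)):
        t = out.trains[0].times
        assert np.all(np.diff(t) >= 0)
        assert t.size <= train.n_spikes
        if t.size:
            assert t[0] >= 0 and t[-1] < 500.0


# ---------------------------------------------------------------------------
# scenario assembly
# ---------------------------------------------------------------------------

def test_fluctuation_driven_rates():
    rng = np.random.default_rng(11)
    (inp,) = cl.build_scenario(cl.ScenarioConfig("fluctuation_driven"), 20000.0, rng)
    assert inp.exc.n_trains == 1 and inp.inh.n_trains == 1
    assert inp.exc.total_rate == pytest.approx(2000.0, abs=4 * np.sqrt(2000 / 20))
    assert inp.inh.total_rate == pytest.approx(1647.0, abs=4 * np.sqrt(1647 / 20))


def test_nsd_uses_reduced_excitatory_drive():
    rng = np.random.default_rng(12)
    (inp,) = cl.build_scenario(cl.ScenarioConfig("nsd"), 20000.0, rng)
    assert inp.exc.total_rate == pytest.approx(1400.0, abs=4 * np.sqrt(1400 / 20))


def test_scenario_requires_mip_where_needed():
    with pytest.raises(ValueError):
        cl.ScenarioConfig("sd")
    with pytest.raises(ValueError):
        cl.ScenarioConfig("correlated_EI")
    with pytest.raises(ValueError):
        cl.ScenarioConfig("bogus")


def _sd_pair_cfg(sd_corr, w, shared_jitter=True, nsd_shared=True):
    mip = cl.MIPConfig(n_trains=50, daughter_rate=0.1, copy_prob=0.05,
                       jitter_width=w)
    return cl.ScenarioConfig("sd", mip=mip, n_neurons=2, nsd_shared=nsd_shared,
                             sd_correlation=sd_corr, shared_jitter=shared_jitter)


def test_common_nsd_pair_shares_background_spikes():
    rng = np.random.default_rng(13)
    a, b = cl.build_scenario(_sd_pair_cfg(0.0, 0.0), 5000.0, rng)
    # background (first) trains bitwise identical, SD daughters independent
    assert np.array_equal(a.exc.trains[0].times, b.exc.trains[0].times)
    assert np.array_equal(a.inh.trains[0].times, b.inh.trains[0].times)


@pytest.mark.parametrize("w", [0.0, 30.0])
def test_fully_correlated_sd_pair_receives_identical_input(w):
    # at SD correlation 1 with shared jitter the two total inputs coincide
    rng = np.random.default_rng(14)
    a, b = cl.build_scenario(_sd_pair_cfg(1.0, w), 5000.0, rng)
    assert np.array_equal(np.sort(a.exc.all_times()), np.sort(b.exc.all_times()))
    assert np.array_equal(a.inh.trains[0].times, b.inh.trains[0].times)


def test_independent_nsd_pair_differs():
    rng = np.random.default_rng(15)
    a, b = cl.build_scenario(_sd_pair_cfg(0.0, 0.0, nsd_shared=False), 5000.0, rng)
    assert not np.array_equal(a.exc.trains[0].times, b.exc.trains[0].times)


def test_correlated_ei_copy_prob_zero_is_poisson_limit():
    rng = np.random.default_rng(16)
    mip = cl.MIPConfig(n_trains=100, daughter_rate=5.0, copy_prob=0.0)
    (inp,) = cl.build_scenario(cl.ScenarioConfig("correlated_EI", mip=mip),
                               20000.0, rng)
    assert inp.exc.n_trains == 100
    assert inp.exc.total_rate == pytest.approx(500.0, rel=0.1)


def test_generators_are_seed_reproducible():
    cfg = _sd_pair_cfg(0.5, 30.0)
    outs = []
    for _ in range(2):
        rng = np.random.default_rng(17)
        outs.append(cl.build_scenario(cfg, 5000.0, rng))
    for xa, xb in zip(outs[0], outs[1]):
        for ta, tb in zip(xa.exc.trains + xa.inh.trains,
                          xb.exc.trains + xb.inh.trains):
            assert np.array_equal(ta.times, tb.times)


def test_spike_train_validation():
    with pytest.raises(ValueError):
        cl.SpikeTrain(0, np.array([3.0, 1.0]), 10.0)       # unsorted
    with pytest.raises(ValueError):
        cl.SpikeTrain(0, np.array([5.0]), 5.0)             # at the boundary
    with pytest.raises(ValueError):
        cl.SpikeTrain(0, np.array([-1.0]), 5.0)            # negative time
    with pytest.raises(ValueError):
        cl.SpikeTrain(0, np.array([1.0]), 0.0)             # empty window
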