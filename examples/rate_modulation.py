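"""Firing-rate modulation by the temporal structure of the input.

One neuron receives two MIP pools (N = 1000 excitatory, N = 1000 inhibitory
trains) built from a pair of fully coupled mother processes.  Three effects
are shown at fixed total drive:

* sweeping the within-pool correlation c produces a non-monotone rate curve
  (small clusters are subthreshold, huge clusters waste spikes);
* at small c, inhibition leading excitation by 2 ms suppresses firing
  relative to excitation leading;
* jitter spreads the compound PSPs and, with coupled E/I, lets inhibition
  cancel excitation, collapsing the rate.
"""
import corrlif as cl

TRIALS, DUR = 2, 10000.0

spec = cl.default_spec("rate_modulation", base_seed=42, n_trials=TRIALS,
                       trial_duration=DUR)
rate_c = cl.run_rate_modulation(spec).groupby("c").value.mean()
print("rate (Hz) vs within-pool correlation c  (c_EI = 1, no lag):")
for c, r in rate_c.items():
    print(f"  c = {c:<6g} -> {r:6.2f} Hz")
print(f"-> interior maximum near c = {rate_c.idxmax():g}\n")

lag_spec = cl.default_spec("rate_modulation", base_seed=42, n_trials=TRIALS,
                           trial_duration=DUR,
                           grid={"c": [0.01], "lag": [-2.0, 2.0], "c_EI": [1.0]})
by_lag = cl.run_rate_modulation(lag_spec).groupby("lag").value.mean()
print(f"c = 0.01: inhibition leads by 2 ms -> {by_lag[-2.0]:.2f} Hz, "
      f"excitation leads -> {by_lag[2.0]:.2f} Hz")
print("-> leading inhibition vetoes the excitatory clusters\n")

jit_spec = cl.default_spec("rate_modulation", base_seed=42, n_trials=TRIALS,
                           trial_duration=DUR,
                           grid={"c": [0.02], "w": [0.0, 30.0], "c_EI": [0.0, 1.0]})
by_jit = cl.run_rate_modulation(jit_spec).groupby(["c_EI", "w"]).value.mean()
print("c = 0.02, 30-ms jitter: "
      f"uncoupled E/I {by_jit[(0.0, 0.0)]:.1f} -> {by_jit[(0.0, 30.0)]:.1f} Hz, "
      f"coupled E/I {by_jit[(1.0, 0.0)]:.1f} -> {by_jit[(1.0, 30.0)]:.1f} Hz")
print("-> jitter hurts far more when inhibition is coupled to excitation.")
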