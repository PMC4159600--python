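"""Independent control of Vm and spike correlations by input decomposition.

A neuron pair receives (i) a *common* non-spike-driving Poisson background
(E 1400 Hz, I 1647 Hz) that shapes subthreshold fluctuations without firing
the cell, and (ii) *spike-driving* MIP cluster inputs (c = 0.05, N = 1000,
rate tuned for ~1 Hz output) whose between-pool correlation is varied.

Without jitter, the Vm correlation stays pinned near 1 (set by the common
background) while the spike correlation tracks the SD input correlation.
With every input spike jittered over 30 ms (shared spikes get identical
jitter), failed clusters leak independent fluctuations into the subthreshold
voltage and the cleaned Vm correlation at SD correlation 0 drops to ~0.72 —
correlated membranes, uncorrelated spikes.
"""
import numpy as np

import corrlif as cl
from corrlif.experiments import _pair_correlations, sd_pair_inputs

neuron, syn = cl.NeuronParams(), cl.SynapseParams()
TRIALS, DUR = 2, 10000.0

for w in (0.0, 30.0):
    mother_rate = cl.tune_sd_mother_rate(jitter_width=w, n_trials=TRIALS,
                                         duration=DUR, base_seed=42)
    print(f"\njitter w = {w:.0f} ms (SD mother rate tuned to "
          f"{mother_rate:.2f} Hz for ~1 Hz output)")
    print("  SD corr   Vm corr   spike corr   rate (Hz)")
    for rho in (0.0, 0.5, 1.0):
        vms, sps, rts = [], [], []
        for trial in range(TRIALS):
            rng = np.random.default_rng([42, trial])
            ia, ib = sd_pair_inputs(rho, w, DUR, rng, mother_rate)
            ta, tb = cl.simulate_pair(neuron, syn, ia, ib)
            vm, sp = _pair_correlations(ta, tb)
            vms.append(vm.coefficient)
            sps.append(sp.coefficient)
            rts.append(0.5 * (cl.measure_rate(ta) + cl.measure_rate(tb)))
        print(f"   {rho:4.1f}    {np.mean(vms):+7.3f}   {np.nanmean(sps):+8.3f}"
              f"     {np.mean(rts):5.2f}")
print("\n-> the background sets the Vm correlation, the spike-driving input")
print("   sets the spike correlation; jitter uncovers the independent SD")
print("   fluctuations and lowers the Vm correlation toward 0.72.")
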