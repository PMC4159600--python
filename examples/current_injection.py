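"""EPSP/IPSP isolation by holding currents.

The neuron receives tightly coupled excitatory and inhibitory input clusters
(c_EI = 1).  Holding the membrane near or below the inhibitory reversal
potential makes compound events deflect the voltage upward (EPSP-dominated);
holding it depolarized but subthreshold lets the slower, larger-area
inhibitory conductance dominate, so the same events deflect it downward
(IPSP-dominated) — the classic protocol for separating excitation and
inhibition in intracellular recordings.
"""
import corrlif as cl

res = cl.run_current_injection(hold_targets=(-75.0, -55.0), base_seed=42)
for hold, r in res.items():
    kind = "EPSP-dominated (upward)" if r["deflection"] > 0 else \
        "IPSP-dominated (downward)"
    print(f"hold {hold:+.0f} mV  (i_ext {r['i_ext']:+7.1f} pA): "
          f"event deflection {r['deflection']:+.2f} mV over {r['n_events']} "
          f"events -> {kind}")
print("-> the same synaptic events reverse sign with the holding potential,")
print("   because the inhibitory driving force vanishes near -70 mV.")
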