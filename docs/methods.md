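# Methods

## Neuron model and numerics

The membrane follows `C dV/dt = −G_L(V−V_r) − G_E(t)(V−V_E) − G_I(t)(V−V_I)
+ I_ext` with a hard threshold: the first sample at which V ≥ V_th emits a
spike (no sub-step interpolation; downstream correlation kernels are ≥ 5 ms,
so sub-sample spike timing is irrelevant), the recorded value at that sample
is V_th, and V is clamped at V_r for t_ref.  By default the synaptic
conductance states keep evolving during the pause — conductances are
physical quantities independent of the spike mechanism — and a
`refractory_conductance="freeze"` switch holds them fixed and ignores spikes
arriving within the pause instead.

Each alpha transient `g(t) = J (t/τ) e^{1−t/τ}` solves the linear two-state
system g' = (z−g)/τ, z' = −z/τ with per-spike increment z ← z + J·e.  The
solver propagates (g, z) *exactly* over each half step via the closed-form
matrix exponential and advances V by classical RK4 (dt = 0.1 ms) using the
conductances at the step endpoints and midpoint.  Input spikes are binned on
the dt/2 grid with first-order (fractional) weight splitting between the two
neighbouring grid points, which keeps the effective input — and hence the
trace — nearly independent of dt.  This removes any adaptive-solver
dependence and makes runs bit-reproducible; accuracy is enforced by tests
(single-PSP amplitude within 1% of an adaptive fine-tolerance reference
integrator; halving dt changes the subthreshold trace by < 0.1 mV RMS and
the 20-s spike count by ≤ 1).

Parameter defaults (C = 500 pF, G_L = 25 nS, V_r = −65 mV, V_th = −50 mV,
t_ref = 2 ms, V_E = 0, V_I = −70 mV, J = 15 nS, τ_E = 0.3 ms, τ_I = 2 ms)
are standard cortical regular-spiking values; every one is overridable.

## Input generators

* **Poisson trains** are sampled by drawing the count and placing spikes
  uniformly in the window.
* **Correlated Poisson pairs** use the shared-component construction: a
  common process of rate ρ·r superposed with private processes of rate
  (1−ρ)·r.  Marginal rates are exactly equal and the count correlation is ρ
  at every bin width; coincident-time collisions are kept (probability zero
  in continuous time).  This is the only construction consistent with ρ → 1
  giving identical trains.
* **MIP ensembles**: each of N daughters keeps each mother spike with
  probability c, so the daughter rate is c·r_mother and the pairwise count
  correlation is c.  The user fixes the daughter rate; the mother runs at
  r/c so total drive N·r is invariant under changes of c ("fixed total input
  strength").  c = 0 is the analytic limit of N independent Poisson
  daughters and is assembled directly (the mother rate would diverge).
* **Jitter** displaces every spike by an independent Uniform(−w/2, +w/2)
  draw; **lag** shifts a whole pool by a signed offset (positive = inhibition
  delayed, i.e. excitation leads).  Both discard spikes leaving the window
  rather than wrapping them — with 20-s windows the boundary loss is
  negligible, and wrapping would create artificial correlations.

For a neuron *pair*, sharing is explicit: common NSD background trains are
the same objects for both neurons; the two SD MIPs are built from mothers
coupled at the SD correlation with *matched thinning* (same-index daughters
reuse the Bernoulli draws for shared mother spikes) so that SD correlation 1
delivers literally identical input.  Jitter is drawn once per source spike
and reused wherever that spike is shared; an `shared_jitter=False` override
draws independently per neuron.

## Calibration of the spike-driving input

The SD mother rate is bisected until the mean output rate over the
calibration run (5 × 20 s, fixed seeds, so the search is deterministic)
falls in [0.9, 1.1] Hz.  Calibration uses the same jitter width as the
target configuration: jittered clusters spread over 30 ms drive spikes far
less reliably, so each jitter condition needs its own rate to fire at ~1 Hz
(without jitter the tuned mother rate is ≈ 1 Hz; with 30-ms jitter ≈ 2 Hz).
Tuning in the unjittered condition and reusing that rate would leave the
jittered pair firing at ≈ 0.45 Hz and its cleaned Vm correlation near 0.88
instead of ≈ 0.72 — the headline decorrelation requires the ~1 Hz operating
point.

## Measurement operators

Spike correlation: trains are convolved with a symmetric triangular kernel
(base 5 ms, unit area on the grid) sampled at the recording step (0.1 ms;
the result is insensitive to the step, property-tested), then Pearson
correlated over the whole window.  Vm correlation: 50 ms of both traces is
removed after every spike of *either* neuron before correlating; overlapping
removal windows merge.  Undefined coefficients (constant signal, < 2 valid
samples) are reported as missing (NaN), never silently as 0.  Correlations
are computed per 20-s trial and averaged over 5 trials (mean ± SEM); pooled
samples are available via the aggregation helpers.

Spike-triggered averages use the raw (uncleaned) traces over a default
window of (−100, +20) ms — wide enough to show the pre-spike rise and a flat
pre-trigger baseline; no canonical window exists, so it is configurable.
Triggers whose window leaves the recording are skipped and counted; segments
containing an earlier trigger spike are kept by default (every spike is
averaged) with an exclusion switch.

## Experiment presets and reproducibility

Sweeps run 5 trials of 20 s per grid point with N = 1000 input trains — the
standard study conditions throughout, which the desk-scale examples shrink
explicitly.  Trial t of grid point g derives its generator from
SeedSequence(base_seed, crc32(preset|g|t)), so grid points are independent,
individually re-runnable, and byte-identical across runs and platforms.

Default grids are choices, not pinned values: the within-pool correlation
sweep uses log-spaced c ∈ {0.002 … 0.3} (the canonical sweep values are not
published), the correlated-E/I scenario uses one daughter rate (2 Hz, i.e.
2000 Hz per pool) for both pools because the shared-component mother
construction requires equal marginal rates as c_EI → 1, and the SD
correlation grid covers {0, 0.1, …, 1}.  The current-injection preset holds
the cell at −75 mV and −55 mV under sparse coupled E/I clusters
(c = 0.003, 5 Hz cluster rate) and reports the event-triggered deflection,
excluding events contaminated by an output spike.

## What the generators do and do not emulate

The synthetic inputs reproduce the second-order temporal statistics that the
study manipulates — pairwise and between-pool count correlations, E/I
timing, cluster jitter — under stationary, homogeneous-coupling assumptions.
They do not model rate nonstationarity, refractory or bursting point
processes, higher-order correlation structure beyond MIP, synaptic
depression/facilitation, dendritic filtering, or recurrent connectivity.
Passing tests therefore show that the *mechanisms* (rate modulation by
input structure; independent control of spike and Vm correlations by SD/NSD
decomposition) operate as described, not that real cortical inputs are MIP
processes.

## Known limitations

* Spike times are reported on the recording grid; analyses needing sub-0.1-ms
  spike precision would require threshold interpolation.
* The fluctuation-driven baseline rate is exquisitely sensitive to the
  E/I balance (a ~2% change in either rate moves it by tens of percent), so
  "around 1 Hz" is reproduced as 0.7–0.8 Hz rather than exactly 1.0.
* Bisection calibration assumes the rate is monotone in the mother rate over
  the bracket, which holds in all configurations used here.
* The pair simulator is strictly feedforward; there is no way to express
  coupling between the two neurons.
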