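# cochsyn

Release-site modelling and spike-train analysis of cochlear inner-hair-cell
(IHC) ribbon synapses.

Sound encoding in the auditory nerve is set by the kinetics of a small pool
of vesicular release sites ("slots") at the IHC active zone: the readily
releasable pool (RRP). `cochsyn` implements a mean-field kinetic model of
this pool, couples it to spiral-ganglion-neuron (SGN) spike generation
through a refractoriness description, and provides the analysis toolchain
used to confront the model with extracellular spike recordings,
patch-clamp/imaging waveforms and electron-microscopy morphometry — plus a
stochastic generator that produces all of these inputs synthetically with
known ground truth.

## The model

Each of `N_slots` release sites is empty or occupied. Occupied sites fuse
their vesicle at rate `k_fus(t)`, empty sites refill at `k_refill(t)`; both
rates interpolate linearly between spontaneous and stimulated values as the
acoustic drive `s(t)` rises from 0 to 1:

    dN/dt = k_refill(t) · (N_slots − N) − k_fus(t) · N            (occupancy)
    R(t)  = k_fus(t) · f · N(t)                                   (EPSC rate)

with `f` the fraction of fusion events large enough to trigger an action
potential. The postsynaptic neuron is *available*, *absolutely refractory*
(dead time `t_abs`) or *relatively refractory* (exponential recovery
`τ_rel`); its state fractions follow a delayed differential equation driven
by `R(t)`, and the observable firing rate is `AP(t) = f_avail(t) · R(t)`.
In the steady state

    N_ss  = k_refill / (k_fus + k_refill) · N_slots
    R_ss  = k_fus · f · N_ss
    AP_ss = R_ss / (1 + R_ss · (t_abs + τ_rel)).

Stimulus protocols (tone bursts at 10/5/0.5 Hz, forward masking with
4/16/64/256 ms masker–probe gaps) are integrated with cyclic boundary
conditions to the periodic steady state, and model PSTHs are fitted to
measured (or synthetic) PSTHs by seeded global optimization — jointly
across all gaps or all inter-stimulus intervals with one parameter vector.

## Worked example

```python
from cochsyn import (KineticParams, RefractoryParams, steady_state_ap_rate,
                     forward_masking_protocol, GeneratorConfig,
                     simulate_spike_trains, forward_masking_ratio,
                     fit_recovery)

params = KineticParams(n_slots=8.0, k_refill_spont=13.3, k_refill_stim=29.5,
                       k_fus_spont=0.6, k_fus_stim=32.2, f=1.0)
refrac = RefractoryParams(t_abs=0.6e-3, tau_rel=0.6e-3)

print(f"spontaneous AP rate: {steady_state_ap_rate(params, refrac, 'spont'):.2f} Hz")
print(f"stimulated AP rate:  {steady_state_ap_rate(params, refrac, 'stim'):.2f} Hz")

ratios = {}
for gap in (4e-3, 16e-3, 64e-3, 256e-3):
    proto = forward_masking_protocol(gap)
    spikes = simulate_spike_trains(GeneratorConfig(
        params=params, refrac=refrac, protocol=proto, n_trials=200, seed=1))
    ratios[gap] = forward_masking_ratio(spikes, 0.0, 0.1 + gap)
    print(f"gap {gap*1e3:5.0f} ms: probe/masker ratio {ratios[gap]:.2f}")
tau, amp, ok = fit_recovery(list(ratios), list(ratios.values()))
print(f"recovery time constant: {tau:.1f} ms")
```

prints

```
spontaneous AP rate: 4.57 Hz
stimulated AP rate:  107.30 Hz
gap     4 ms: probe/masker ratio 0.69
gap    16 ms: probe/masker ratio 0.68
gap    64 ms: probe/masker ratio 0.83
gap   256 ms: probe/masker ratio 1.02
recovery time constant: 81.7 ms
```

The steady-state rates are the closed-form values for this parameter set;
the probe/masker ratios come from 200 stochastic trials per gap and climb
back toward 1 as the silent gap gives the pool time to refill, and the
single-exponential fit of that recovery summarizes the replenishment
kinetics. (The 4 and 16 ms ratios differ only within trial noise.)

A command-line interface mirrors the library:
`cochsyn synth | psth | align | simulate | fit | classify | report | run`;
`cochsyn run --config pipeline.yaml --out-dir out/` executes a
synthesize → bin → fit pipeline and writes a manifest with the
configuration hash and seeds.

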