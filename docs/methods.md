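# Methods

## Model

The release-site model treats the IHC active zone as `N_slots` independent
vesicle docking sites with first-order refilling and fusion. Both rate
constants are linear in the stimulus drive `s(t) ∈ [0, 1]` between their
spontaneous (`s=0`) and stimulated (`s=1`) values; `s` abstracts sound
pressure over the fiber's dynamic range (0 = silence, 1 = 30 dB above
threshold), so no explicit dB-to-drive calibration enters the model.
Occupancy is continuous (mean-field), consistent with the non-integer slot
capacities that fits produce. The supra-threshold EPSC rate is
`R = k_fus · f · N_filled`, where `f ∈ (0, 1]` absorbs fusion events whose
EPSCs are too small to trigger a spike.

Refractoriness uses three neuron states. Transitions out of *available*
occur at rate `R(t)`; the neuron is *absolutely refractory* for the dead
time `t_abs` and then *relatively refractory*, returning to available at
rate `1/τ_rel`. This yields a delay differential equation (DDE) in
`f_avail` and `f_relref`, with `f_absref` the outflux integrated over the
trailing `t_abs` window. In some statements of these equations the scaling
`f` appears a second time in front of `R`; since `R` already contains `f`,
the package applies `f` exactly once. A `double_f` switch in
`simulate_protocol` reproduces the literal double application for
comparison.

### Parameters

| parameter | units | default / typical | meaning |
|---|---|---|---|
| `n_slots` | – | 8–16 (fitted) | release-site capacity |
| `k_refill_spont/stim` | 1/s | 5–30 (fitted) | refilling of empty slots |
| `k_fus_spont/stim` | 1/s | 0.6–80 (fitted) | fusion of docked vesicles |
| `f` | – | 1.0 | supra-threshold fraction |
| `t_abs` | s | 0.6e-3 | absolute refractory period |
| `tau_rel` | s | 0.6e-3 | relative refractory recovery |

Rate constants are interpreted as s⁻¹ (the source tables print bare
numbers). The refractory defaults are order-of-magnitude values for
auditory-nerve fibers; they are not part of the published parameter tables,
so every round-trip analysis fixes them explicitly and uses the same values
for generation and fitting. `f` and `n_slots` are nearly degenerate
(`R ∝ f · n_slots`), so `f` is fixed by default during fitting.

## Numerics

Integration is fixed-step classical Runge–Kutta (RK4) at `dt = 0.05 ms`.
The delayed outflux term is read from the stored solution history with
linear interpolation (the step must satisfy `dt ≤ t_abs/4`). Envelopes are
piecewise-smooth by construction: tones carry a 4 ms quarter-sin² onset
ramp and, by default, a symmetric offset ramp — the latter is not specified
by the protocols themselves but avoids forcing discontinuities in the DDE;
it can be disabled. Halving `dt` changes trajectories by < 0.1%.

Two numerical details matter for the DDE:

* `f_absref` is a neutral mode (a pure integral), so the RK4 stage sums
  conserve `f_avail + f_relref + f_absref = 1` to machine precision, but
  tiny quadrature mismatch between the stage rule and the interpolated
  delayed term would otherwise accumulate (~6e-6 per 500 ms cycle).
* Protocol simulation therefore re-anchors `f_absref` at each cycle
  boundary to the trapezoidal integral of the stored outflux over the
  trailing `t_abs` window, restoring `f_avail` from conservation. With
  this anchoring the cyclic iteration (terminal state and delay history
  carried into the next cycle) converges to a fixed point; convergence is
  declared when the start-of-cycle state changes by < 1e-6 (relative),
  with a hard cap of 200 cycles. `τ_rel = 0` is handled as instantaneous
  return from relative refractoriness and `t_abs = 0` as an ordinary ODE.

## Fitting

Model PSTHs are the converged-cycle AP rate averaged over 2 ms bins
(trapezoidal within-bin integration, conserving spike count to < 0.5%).
The loss is the unweighted sum of squared per-bin rate residuals,
concatenated across all conditions of a paradigm (Poisson deviance is
available as an option); four masker–probe gaps share one parameter vector
in the forward-masking fit, and the three tone-burst protocols share one in
the global fit, where only the first 50 ms of the 500 ms response (plus the
silent inter-stimulus bins) contribute for the 2 s protocol — later, slower
adaptation processes are outside the model. The optimizer is seeded
differential evolution (Sobol initialization, population 12·n_params, up to
120 generations) inside fixed physiological bounds, followed by Nelder–Mead
polish; during optimization non-converged cyclic simulations return their
last cycle instead of raising. On noiseless self-generated data the
generating parameters are recovered to optimizer precision in about a
minute per paradigm on one CPU. The forward-masking capacity is fitted as
an independent `n_slots` (a genuinely reduced engaged capacity `N'_slots`),
and `capacity_ratio` reports `N_slots(tone) / N'_slots(masking)`; note that
the published capacity ratios were estimated from rate drops in the
recordings, not from this division, so the two need not coincide.

## Spike-train analysis

PSTHs use half-open 2 ms bins, rate = count/(trials · bin width). Onset
detection for unit alignment follows a change in spike statistics: the
99.5th percentile `P` (linear interpolation between order statistics) of
spontaneous per-bin counts is computed over all pre-stimulus bins; the
first bin reaching `2P` is safely inside the response, and walking backward
to the last bin below `P` gives the onset edge. Units that never reach
`2P` are excluded and logged. Peak rate is the largest bin 3–11 ms after
onset (ties to the earliest bin); adapted rate averages 35–45 ms (50 ms
bursts) or 405–415 ms (500 ms bursts). Adaptation is fitted with single or
double exponentials plus a free constant offset (the published table
reports none, so round-trip checks generate with offset 0); amplitudes are
constrained non-negative and components are reported fast-first.
Forward-masking recovery is the probe/masker ratio of 10 ms onset spike
counts, fitted as `1 − A·exp(−Δ/τ)`. Vector strength follows the standard
definition with Rayleigh statistic `2nSI²`; the conventional significance
direction (`> 13.8` ⇒ significant synchrony) is the default, with a
`literal_below` flag for the opposite reading, and validity additionally
requires ≥ 15 spikes. Rate-level functions use a logistic with baseline
(only "sigmoidal" is prescribed); its 10–90% dynamic range is `2s·ln 9`.

## Waveform and imaging fits

Fractional activation curves follow the Boltzmann driving-force form
`F(V) = F0 + fv·(Vr−V)/(1+exp((Vh−V)/k))` with `Vr = 65.6 mV` fixed. The
slope `fv` is first estimated by linear regression on 3–23 mV (where
activation is essentially complete) and then, by default, refined jointly
with `F0`, `Vh`, `k`: holding `fv` at the regression value leaves a ~3%
slope bias from the residual Boltzmann tail that shifts `Vh` by ~0.3 mV
(`refine_fv=False` restores the strict two-step procedure). Whole-cell IV
relationships are converted to normalized conductance `I/(V−Vr)` before
Boltzmann fitting. Current steps are summarized by the 5–10 ms window mean
and the trapezoidal charge integral; activation kinetics by
`y0 + A(1−exp(−t/τ))²` over the first 5 ms. ΔC_m is the 400 ms
after-minus-before window difference, skipping 60 ms (30 ms in paired
mode, where windows truncate to the inter-pulse interval and are flagged
below 50 ms). Hotspots are quantified on ΔF images (stimulated minus
resting frame means) via the best 3×3-pixel square; ΔF_max averages the
samples whose ramp voltage lies in −17..+8 mV, and inclusion requires the
response to exceed twice the resting standard deviation of the same 3×3
average. Spatial extents come from a rotated 2D Gaussian with offset,
initialized from image moments (an isotropic start stalls the rotation
angle at a saddle); FWHM = 2√(2 ln 2)·σ and the ellipse area is
π·(FWHM_long/2)·(FWHM_short/2).

## Morphometry

Pool criteria are distances from the vesicle membrane (center distance
minus mean radius) with inclusive thresholds: membrane-proximal ≤ 25 nm
from the AZ membrane and ≤ 80 nm from the presynaptic density;
ribbon-associated within 80 nm of the ribbon outline (not MP); PD-associated
within 80 nm of the PD (ribbonless, not MP); an extended 50/100 nm MP
criterion serves tomogram-style analyses. The "first layer" around the
ribbon is operationalized purely by the 80 nm rule, the 80 nm PD distance
for MP vesicles as Euclidean distance to the nearest PD point (a
lateral-along-membrane reading is conceivable but less well defined for
curved membranes). Geometry distances use shapely; an independent exact
point-to-segment oracle in the test suite must agree on hundreds of random
scenes. Ribbon height/width are extents along the principal axes of the
densely resampled outline; areas are shoelace polygon areas.

## Synthetic data

The spike-train generator realizes the mechanism, not the mean field: per
0.05 ms step each empty slot refills with probability `1−exp(−k_refill dt)`
and each occupied slot fuses with `1−exp(−k_fus dt)`; fusions are
supra-threshold with probability `f`; a supra-threshold event spikes iff
the neuron is available, after which the neuron is silenced for `t_abs`
plus an exponential(`τ_rel`) delay. Slot capacity is rounded to the
nearest integer here. Trials are independent realizations warmed up for
3 cycles (configurable) so recording starts in the stationary cyclic
regime; the deterministic model is the generator's large-sample oracle
(PSTHs of 2000 trials fall within 99% Poisson bands of the model
prediction). Generators for activation curves, PSTH decay curves, hotspot
stacks and vesicle scenes evaluate their closed forms plus Gaussian or
Poisson noise. All generators are bit-reproducible given a seed.

What the synthetic data do not emulate: long-term adaptation beyond the
RRP mechanism, EPSC-size variability and spike-waveform noise, off-CF
cochlear filtering, imaging PSF blur beyond a Gaussian blob, and
section-to-section EM variability. Passing round trips therefore
demonstrate correctness of the estimation machinery under the model's own
assumptions, not the model's adequacy for any particular recording.

## Problem sizes used in the checks

Round-trip fits use noiseless self-generated PSTHs at the published
wild-type operating points with five free parameters; stochastic
comparisons use 2000 trials (Poisson-band check), 600 trials (unit-level
check), 200 trials (ratio examples) and 40×2 s of constant drive (closed-
form rate check); the classification oracle runs 1000 random scenes of 10
vesicles. These sizes give comfortable statistical resolution for the
asserted tolerances while keeping the full suite around two minutes.

## Known limitations

* The refractory parameters and `f` used for the published fits are not
  reported; round trips are self-consistent but absolute comparisons of
  fitted rate constants to the published tables inherit this ambiguity.
* The mean-field model ignores slot-number fluctuations; for small
  `n_slots` the stochastic generator's PSTH matches it in the mean but the
  trial-to-trial variance is not Poisson at high rates (refractoriness
  thins the counts).
* The onset-alignment percentile rule needs a spontaneous window with
  enough bins; very short pre-stimulus baselines make `P` noisy.
* `fit_tone_bursts_global` assumes the three PSTHs share the 2 ms grid and
  begin at tone onset.
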