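"""Synthetic-data generation with known ground truth.

Every analysis stage of the package can be exercised without recordings:

* stochastic spiral-ganglion-neuron spike trains realizing the release-site
  model mechanistically (slot-level Markov birth-death process for the
  vesicle pool, plus absolute/relative refractoriness of the neuron) under
  any stimulus protocol — the deterministic mean-field model is the
  large-sample oracle for these trains;
* noisy fluorescence-voltage activation curves, exponential PSTH decay
  curves, 2D Gaussian fluorescence hotspots and vesicle-scene geometries.

All generators take an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .morphometry import AZGeometry, VesicleRecord
from .protocols import Protocol
from .release_model import (DT_DEFAULT, Envelope, KineticParams,
                            RefractoryParams, steady_state_occupancy)
from .spike_stats import PSTHData, SpikeTrainSet


@dataclass
class GeneratorConfig:
    """Settings for the stochastic spike-train generator.

    ``n_slots`` is rounded to the nearest integer for the slot-level
    simulation (fractional capacities are a mean-field abstraction).
    ``warmup_cycles`` protocol cycles are simulated before the recorded
    cycle so each trial starts from the stationary cyclic regime.
    """

    params: KineticParams
    refrac: RefractoryParams
    protocol: Protocol
    n_trials: int = 200
    warmup_cycles: int = 3
    dt: float = DT_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.warmup_cycles < 0:
            raise ValueError("warmup_cycles must be >= 0")


def simulate_spike_trains(config: GeneratorConfig) -> SpikeTrainSet:
    """Draw trial-wise spike trains from the stochastic release-site model.

    Per time step (``dt`` grid) and trial: each empty slot refills with
    probability ``1 - exp(-k_refill dt)`` and each occupied slot fuses with
    probability ``1 - exp(-k_fus dt)``; every fusion is supra-threshold
    with probability ``f``.  A supra-threshold event elicits a spike iff
    the neuron is available; after a spike the neuron is silenced for
    ``t_abs`` plus an exponential(``tau_rel``) relative-refractory delay.
    Trials are independent realizations, each warmed up over
    ``warmup_cycles`` cycles before one cycle is recorded.
    """
    p, refrac = config.params, config.refrac
    env = config.protocol.envelope(config.dt) \
        if hasattr(config.protocol, "envelope") else config.protocol
    s = env.s
    dt = env.dt
    n_slots = int(round(p.n_slots))
    if n_slots < 1:
        raise ValueError("n_slots rounds to zero")
    kr = p.k_refill_spont + s * (p.k_refill_stim - p.k_refill_spont)
    kf = p.k_fus_spont + s * (p.k_fus_stim - p.k_fus_spont)
    p_ref = -np.expm1(-kr * dt)
    p_fus = -np.expm1(-kf * dt)

    rng = np.random.default_rng(config.seed)
    nt = config.n_trials
    occ0 = steady_state_occupancy(kr[0], kf[0], n_slots) / n_slots \
        if kr[0] + kf[0] > 0 else 1.0
    n = rng.binomial(n_slots, occ0, size=nt)
    next_avail = np.zeros(nt)

    period = env.period
    m = len(s) - 1
    trials: List[List[float]] = [[] for _ in range(nt)]
    t_global = 0.0
    for cyc in range(config.warmup_cycles + 1):
        record = cyc == config.warmup_cycles
        for k in range(m):
            fus = rng.binomial(n, p_fus[k])
            ref = rng.binomial(n_slots - n, p_ref[k])
            n = n + ref - fus
            events = fus if p.f >= 1.0 else rng.binomial(fus, p.f)
            t_now = t_global + k * dt
            firing = (events > 0) & (t_now >= next_avail)
            if firing.any():
                idx = np.nonzero(firing)[0]
                if record:
                    t_rel = k * dt
                    for i in idx:
                        trials[i].append(t_rel)
                delays = rng.exponential(refrac.tau_rel, size=idx.size) \
                    if refrac.tau_rel > 0 else np.zeros(idx.size)
                next_avail[idx] = t_now + refrac.t_abs + delays
        t_global += period
    return SpikeTrainSet(trials=[np.array(tr) for tr in trials],
                         duration=period, protocol=config.protocol,
                         seed=config.seed)


# ---------------------------------------------------------------------------
# waveform generators
# ---------------------------------------------------------------------------

def generate_fv_curve(vh: float, k: float, fv: float, f0: float,
                      noise_sd: float = 0.0, seed: int = 0,
                      vr: float = 65.6,
                      v_grid: Optional[np.ndarray] = None,
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Fluorescence-voltage curve from the Boltzmann driving-force model.

    Evaluated on the voltage-ramp grid (-87..+63 mV in 1 mV steps by
    default) with additive Gaussian noise of ``noise_sd``.
    """
    if k <= 0:
        raise ValueError("slope factor must be positive")
    v = np.arange(-87.0, 63.0 + 0.5, 1.0) if v_grid is None \
        else np.asarray(v_grid, dtype=float)
    f = f0 + fv * (vr - v) / (1.0 + np.exp((vh - v) / k))
    if noise_sd > 0:
        f = f + np.random.default_rng(seed).normal(0.0, noise_sd, size=v.size)
    return v, f


def generate_psth_curve(tau_fast: float, tau_slow: float, amp_fast: float,
                        amp_slow: float, offset: float = 0.0,
                        bin_ms: float = 2.0, duration_ms: float = 50.0,
                        n_trials: Optional[int] = None, seed: int = 0,
                        ) -> PSTHData:
    """Double-exponential PSTH decay curve on the 2 ms grid (taus in ms).

    Noiseless by default; with ``n_trials`` the per-bin rates are Poisson
    spike counts over that many sweeps, as in a measured histogram.
    """
    if tau_fast <= 0 or tau_slow <= 0:
        raise ValueError("time constants must be positive")
    n_bins = int(round(duration_ms / bin_ms))
    edges = np.arange(n_bins + 1) * bin_ms * 1e-3
    t = (np.arange(n_bins) + 0.5) * bin_ms  # bin centers, ms
    rate = offset + amp_fast * np.exp(-t / tau_fast) \
        + amp_slow * np.exp(-t / tau_slow)
    nt = 1
    if n_trials is not None:
        nt = n_trials
        rng = np.random.default_rng(seed)
        lam = rate * nt * (bin_ms * 1e-3)
        rate = rng.poisson(np.clip(lam, 0, None)) / (nt * bin_ms * 1e-3)
    return PSTHData(bin_width=bin_ms * 1e-3, edges=edges, rate=rate,
                    n_trials=nt, onset=0.0)


# ---------------------------------------------------------------------------
# image and scene generators
# ---------------------------------------------------------------------------

def generate_hotspot_image(shape: Tuple[int, int] = (32, 32),
                           amplitude: float = 10.0,
                           sigma: Tuple[float, float] = (3.0, 2.0),
                           orientation: float = 0.0,
                           center: Optional[Tuple[float, float]] = None,
                           baseline: float = 100.0,
                           noise_sd: float = 1.0,
                           n_rest: int = 10, n_stim: int = 6,
                           seed: int = 0) -> Dict[str, object]:
    """Image stack with a single Gaussian fluorescence hotspot.

    Returns a dict with the ``stack`` (rest frames first), the frame index
    lists and the ground-truth blob parameters.  The hotspot appears only
    in the stimulated frames, on top of a constant baseline with additive
    Gaussian noise.
    """
    h, w = shape
    cy, cx = center if center is not None else ((h - 1) / 2, (w - 1) / 2)
    y, x = np.mgrid[0:h, 0:w]
    ct, st = np.cos(orientation), np.sin(orientation)
    xr = ct * (x - cx) + st * (y - cy)
    yr = -st * (x - cx) + ct * (y - cy)
    sl, ss = sigma
    blob = amplitude * np.exp(-0.5 * ((xr / sl) ** 2 + (yr / ss) ** 2))
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_rest):
        frames.append(baseline + rng.normal(0, noise_sd, size=shape))
    for _ in range(n_stim):
        frames.append(baseline + blob + rng.normal(0, noise_sd, size=shape))
    return dict(stack=np.array(frames),
                rest_frames=list(range(n_rest)),
                stim_frames=list(range(n_rest, n_rest + n_stim)),
                truth=dict(amplitude=amplitude, sigma_long=max(sl, ss),
                           sigma_short=min(sl, ss), center=(cx, cy),
                           baseline=baseline, orientation=orientation))


def generate_vesicle_scene(seed: int = 0, n_vesicles: int = 20,
                           ribbon: bool = True,
                           diameter_nm: float = 40.0,
                           ) -> Tuple[List[VesicleRecord], AZGeometry]:
    """Random active-zone scene: membrane, PD, optional ribbon, vesicles.

    The membrane is a gently undulating horizontal polyline (~1 um wide)
    with a presynaptic density segment at its center; with ``ribbon`` an
    elliptical ribbon outline sits above the PD.  Vesicle centers are
    scattered within ~300 nm of the active zone so that all pools are
    populated; diameters jitter around ``diameter_nm``.
    """
    rng = np.random.default_rng(seed)
    xs = np.linspace(0.0, 1000.0, 41)
    ys = rng.normal(0.0, 2.0, size=xs.size)
    membrane = np.column_stack([xs, ys])
    pd_lo, pd_hi = 430.0, 570.0
    pd_mask = (xs >= pd_lo) & (xs <= pd_hi)
    pd = membrane[pd_mask]
    rib = None
    if ribbon:
        theta = np.linspace(0, 2 * np.pi, 33)[:-1]
        rib = np.column_stack([500.0 + 90.0 * np.cos(theta),
                               150.0 + 110.0 * np.sin(theta)])
    vesicles = []
    for _ in range(n_vesicles):
        cx = rng.uniform(200.0, 800.0)
        cy = rng.uniform(5.0, 350.0)
        d_h = rng.normal(diameter_nm, 2.0)
        d_v = rng.normal(diameter_nm, 2.0)
        vesicles.append(VesicleRecord(center=(cx, cy),
                                      diameter_h=max(d_h, 10.0),
                                      diameter_v=max(d_v, 10.0)))
    geometry = AZGeometry(membrane=membrane, pd_segments=[pd], ribbon=rib)
    return vesicles, geometry
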