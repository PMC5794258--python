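"""Fitting the release-site model to averaged PSTHs.

Two global fits are provided: the forward-masking fit (a single parameter
vector across the four masker-probe gaps) and the tone-burst fit across the
100/200/2000 ms inter-stimulus-interval protocols, where only the first
50 ms of the 500 ms response contribute for the 2000 ms ISI (later, slower
adaptation processes are outside the model).  Optimization is a seeded
population-based global search (scipy differential evolution) within bounds,
followed by local polishing.  By default the supra-threshold scaling ``f``
and the refractory parameters are fixed and the slot capacity plus the four
rate constants are free; ``f`` and ``n_slots`` are nearly degenerate
(R ~ f * n_slots), so freeing both is not identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .protocols import Protocol, forward_masking_protocol, tone_burst_protocol
from .release_model import (DT_DEFAULT, KineticParams, RefractoryParams,
                            simulate_protocol)
from .spike_stats import PSTHData

PARAM_ORDER = ("n_slots", "k_refill_spont", "k_refill_stim",
               "k_fus_spont", "k_fus_stim", "f", "t_abs", "tau_rel")

DEFAULT_FREE = ("n_slots", "k_refill_spont", "k_refill_stim",
                "k_fus_spont", "k_fus_stim")

DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "n_slots": (1.0, 50.0),
    "k_refill_spont": (0.5, 100.0),
    "k_refill_stim": (1.0, 200.0),
    "k_fus_spont": (0.01, 10.0),
    "k_fus_stim": (1.0, 300.0),
    "f": (0.05, 1.0),
    "t_abs": (0.0, 5e-3),
    "tau_rel": (0.0, 5e-3),
}


@dataclass
class FitSpec:
    """Which parameters to fit, their bounds, and optimizer settings."""

    free: Sequence[str] = DEFAULT_FREE
    bounds: Optional[Dict[str, Tuple[float, float]]] = None
    fixed: Optional[Dict[str, float]] = None
    loss: str = "sse"  # or "poisson"
    seed: int = 0
    popsize: int = 12
    maxiter: int = 120
    tol: float = 1e-10
    polish: bool = True
    dt: float = DT_DEFAULT
    max_cycles: int = 60

    def __post_init__(self) -> None:
        self.fixed = dict(self.fixed or {})
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {overlap}")
        b = dict(DEFAULT_BOUNDS)
        b.update(self.bounds or {})
        self.bounds = b
        for name in self.free:
            lo, hi = self.bounds[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name}")


@dataclass
class FitResult:
    """Best-fit parameter set and goodness of fit."""

    params: KineticParams
    refrac: RefractoryParams
    loss: float
    residuals: Dict[str, np.ndarray]
    n_evals: int
    success: bool
    message: str = ""

    @property
    def n_slots_engaged(self) -> float:
        return self.params.n_slots


def model_psth(params: KineticParams, refrac: RefractoryParams,
               protocol: Protocol, bin_ms: float = 2.0,
               dt: float = DT_DEFAULT, **sim_kw) -> PSTHData:
    """Predicted PSTH: the converged-cycle AP rate averaged in 2 ms bins."""
    traj = simulate_protocol(params, refrac, protocol, dt=dt, **sim_kw)
    return bin_rate(traj.t, traj.ap_rate, bin_ms)


def bin_rate(t: np.ndarray, rate: np.ndarray, bin_ms: float = 2.0,
             ) -> PSTHData:
    """Average a continuous rate trace within half-open time bins."""
    bw = bin_ms * 1e-3
    dt = t[1] - t[0]
    per = int(round(bw / dt))
    n_bins = (len(t) - 1) // per
    # trapezoid average within each bin
    r = rate[: n_bins * per + 1]
    csum = np.concatenate([[0.0], np.cumsum(0.5 * (r[1:] + r[:-1]) * dt)])
    binned = (csum[per::per] - csum[:-per:per][:n_bins]) / bw
    edges = t[0] + np.arange(n_bins + 1) * bw
    return PSTHData(bin_width=bw, edges=edges, rate=binned, n_trials=1)


def _assemble(theta: np.ndarray, spec: FitSpec,
              base: Dict[str, float]) -> Tuple[KineticParams, RefractoryParams]:
    vals = dict(base)
    for name, v in zip(spec.free, theta):
        vals[name] = float(v)
    vals.update(spec.fixed)
    params = KineticParams(n_slots=vals["n_slots"],
                           k_refill_spont=vals["k_refill_spont"],
                           k_refill_stim=vals["k_refill_stim"],
                           k_fus_spont=vals["k_fus_spont"],
                           k_fus_stim=vals["k_fus_stim"], f=vals["f"])
    refrac = RefractoryParams(t_abs=vals["t_abs"], tau_rel=vals["tau_rel"])
    return params, refrac


def _default_base() -> Dict[str, float]:
    return dict(n_slots=10.0, k_refill_spont=10.0, k_refill_stim=25.0,
                k_fus_spont=0.5, k_fus_stim=40.0, f=1.0,
                t_abs=6e-4, tau_rel=6e-4)


def _fit_joint(conditions: List[Tuple[Protocol, np.ndarray, np.ndarray]],
               spec: FitSpec, bin_ms: float) -> FitResult:
    """Minimize the summed per-bin loss over all conditions jointly.

    ``conditions`` holds (protocol, target rate per bin, boolean mask of
    bins included in the loss).
    """
    base = _default_base()
    n_evals = 0
    envs = [proto.envelope(spec.dt) for proto, _, _ in conditions]

    def predict(params, refrac):
        preds = []
        for env in envs:
            traj = simulate_protocol(params, refrac, env, dt=spec.dt,
                                     max_cycles=spec.max_cycles, strict=False)
            preds.append(bin_rate(traj.t, traj.ap_rate, bin_ms).rate)
        return preds

    def loss_fn(theta):
        nonlocal n_evals
        n_evals += 1
        try:
            params, refrac = _assemble(theta, spec, base)
        except ValueError:
            return 1e12
        total = 0.0
        for (proto, target, mask), pred in zip(conditions,
                                               predict(params, refrac)):
            p = pred[: len(target)][mask]
            y = target[mask]
            if spec.loss == "poisson":
                lam = np.maximum(p, 1e-6)
                yy = np.maximum(y, 0.0)
                total += float(2 * np.sum(lam - yy + yy *
                                          np.log(np.maximum(yy, 1e-6) / lam)))
            else:
                d = p - y
                total += float(np.dot(d, d))
        return total

    bounds = [spec.bounds[name] for name in spec.free]
    result = optimize.differential_evolution(
        loss_fn, bounds, seed=spec.seed, popsize=spec.popsize,
        maxiter=spec.maxiter, tol=spec.tol, polish=False,
        init="sobol", updating="deferred", workers=1)
    theta = result.x
    if spec.polish:
        local = optimize.minimize(
            loss_fn, theta, method="Nelder-Mead",
            options=dict(xatol=1e-10, fatol=1e-14, maxiter=4000))
        if local.fun <= result.fun:
            theta = local.x
    params, refrac = _assemble(theta, spec, base)
    residuals = {}
    for (proto, target, mask), pred in zip(conditions,
                                           predict(params, refrac)):
        residuals[proto.name] = pred[: len(target)] - target
    return FitResult(params=params, refrac=refrac, loss=float(loss_fn(theta)),
                     residuals=residuals, n_evals=n_evals,
                     success=bool(result.success or spec.polish),
                     message=str(result.message))


def fit_forward_masking(psths: Dict[float, PSTHData], spec: FitSpec,
                        bin_ms: float = 2.0, offset_ramp: bool = True,
                        ) -> FitResult:
    """Fit one parameter set in parallel to the four-gap forward-masking PSTHs.

    ``psths`` maps the masker-probe gap (s) to the averaged PSTH of that
    condition; all four canonical gaps must be present.
    """
    missing = [g for g in (4e-3, 16e-3, 64e-3, 256e-3) if g not in psths]
    if missing:
        raise ValueError(f"missing forward-masking gaps: {missing}")
    conditions = []
    for gap, psth in sorted(psths.items()):
        proto = forward_masking_protocol(gap, offset_ramp=offset_ramp)
        target = np.asarray(psth.rate, dtype=float)
        conditions.append((proto, target, np.ones(len(target), dtype=bool)))
    return _fit_joint(conditions, spec, bin_ms)


def fit_tone_bursts_global(psths: Dict[float, PSTHData], spec: FitSpec,
                           bin_ms: float = 2.0, offset_ramp: bool = True,
                           fit_window: float = 50e-3) -> FitResult:
    """Joint fit of the 100/200/2000 ms inter-stimulus-interval PSTHs.

    ``psths`` maps the ISI in ms (100, 200 or 2000) to the averaged PSTH.
    For the 2000 ms ISI (500 ms bursts) only bins within ``fit_window``
    after tone onset plus the silent inter-stimulus bins enter the loss.
    """
    proto_map = {100.0: tone_burst_protocol(50, 10, offset_ramp=offset_ramp),
                 200.0: tone_burst_protocol(50, 5, offset_ramp=offset_ramp),
                 2000.0: tone_burst_protocol(500, 0.5,
                                             offset_ramp=offset_ramp)}
    missing = [k for k in proto_map if k not in psths]
    if missing:
        raise ValueError(f"missing tone-burst ISIs (ms): {missing}")
    conditions = []
    for isi, proto in proto_map.items():
        psth = psths[isi]
        target = np.asarray(psth.rate, dtype=float)
        centers = psth.centers
        burst = dict(proto.segments)["tone"]
        mask = np.ones(len(target), dtype=bool)
        if isi == 2000.0:
            in_burst = (centers >= 0) & (centers < burst)
            late = in_burst & (centers >= fit_window)
            mask[late] = False
        conditions.append((proto, target, mask))
    return _fit_joint(conditions, spec, bin_ms)


def capacity_ratio(fit_tone: FitResult, fit_fm: FitResult) -> float:
    """N_slots(tone bursts) / N'_slots(forward masking).

    Indexes how much of the total release-site capacity is engaged during
    the more depleting forward-masking paradigm.
    """
    if fit_fm.params.n_slots == 0:
        raise ZeroDivisionError("forward-masking capacity is zero")
    return fit_tone.params.n_slots / fit_fm.params.n_slots
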