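"""Spike-train analysis: PSTHs, onset alignment, adaptation and recovery
fits, forward-masking ratios, vector strength and rate-level metrics.

All operations work on trial-wise spike times (seconds, relative to trial
start).  PSTHs use half-open 2 ms bins by default and report rates in Hz
(count / (n_trials * bin_width)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

BIN_DEFAULT_MS = 2.0
#: conventional significance bound of the Rayleigh statistic 2 n SI^2
RAYLEIGH_CRIT = 13.8


@dataclass
class SpikeTrainSet:
    """Trial-wise spike times for one unit under one protocol."""

    trials: List[np.ndarray]
    duration: float
    protocol: Optional[object] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.trials) < 1:
            raise ValueError("at least one trial is required")
        clean = []
        for tr in self.trials:
            a = np.sort(np.asarray(tr, dtype=float))
            if a.size and (a[0] < 0 or a[-1] >= self.duration):
                raise ValueError("spike times must lie in [0, duration)")
            clean.append(a)
        self.trials = clean

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def pooled(self) -> np.ndarray:
        return np.sort(np.concatenate(self.trials)) if self.trials else \
            np.empty(0)


@dataclass
class PSTHData:
    """Peristimulus time histogram: rate (Hz) per half-open time bin."""

    bin_width: float
    edges: np.ndarray
    rate: np.ndarray
    n_trials: int
    onset: Optional[float] = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if len(self.edges) != len(self.rate) + 1:
            raise ValueError("edges must have one more element than rate")
        if np.any(self.rate < 0):
            raise ValueError("rates must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def counts(self) -> np.ndarray:
        """Total spike counts per bin (over all trials)."""
        return np.rint(self.rate * self.n_trials * self.bin_width)


@dataclass
class ExpFitResult:
    """Single- or double-exponential decay fit of a PSTH (times in ms)."""

    kind: str
    tau: Optional[float] = None
    amplitude: Optional[float] = None
    tau_fast: Optional[float] = None
    tau_slow: Optional[float] = None
    amp_fast: Optional[float] = None
    amp_slow: Optional[float] = None
    offset: float = 0.0
    r: float = np.nan


def build_psth(spikes: SpikeTrainSet, bin_ms: float = BIN_DEFAULT_MS,
               ) -> PSTHData:
    """Average firing rate across trials in half-open bins [t, t + bin)."""
    bw = bin_ms * 1e-3
    n_bins = int(np.ceil(spikes.duration / bw - 1e-9))
    edges = np.arange(n_bins + 1) * bw
    counts, _ = np.histogram(spikes.pooled(), bins=edges)
    rate = counts / (spikes.n_trials * bw)
    return PSTHData(bin_width=bw, edges=edges, rate=rate,
                    n_trials=spikes.n_trials)


def detect_onset(psth: PSTHData, spont_window: Tuple[float, float],
                 percentile: float = 99.5) -> Optional[int]:
    """Onset bin index from a change in spike statistics.

    The given percentile of the spontaneous per-bin counts defines a
    baseline level P.  The first bin whose count reaches 2 P marks a point
    safely inside the response; walking backwards from it, the bin edge
    after the last bin below P is taken as the onset.  Returns ``None``
    when no bin ever reaches 2 P (unalignable unit).
    """
    counts = psth.counts
    centers = psth.centers
    mask = (centers >= spont_window[0]) & (centers < spont_window[1])
    if not mask.any():
        raise ValueError("spontaneous window contains no bins")
    p = np.percentile(counts[mask], percentile)  # linear interpolation
    thresh = 2.0 * p
    above = np.nonzero((counts >= thresh) & (counts > 0))[0]
    if above.size == 0:
        return None
    idx = int(above[0])
    j = idx
    while j > 0 and counts[j - 1] >= p and counts[j - 1] > 0:
        j -= 1
    return j


def align_onsets(psths: Sequence[PSTHData],
                 spont_window: Tuple[float, float],
                 percentile: float = 99.5,
                 ) -> Tuple[PSTHData, List[Optional[float]]]:
    """Shift PSTHs so their detected onsets coincide, then average.

    Units whose onset cannot be detected are excluded (logged).  The
    average is formed on the common overlapping grid after shifting each
    PSTH by an integer number of bins; the returned PSTH carries the
    reference onset time.
    """
    onsets: List[Optional[float]] = []
    usable: List[Tuple[PSTHData, int]] = []
    for i, p in enumerate(psths):
        ob = detect_onset(p, spont_window, percentile)
        if ob is None:
            logger.warning("unit %d unalignable: response never reaches "
                           "twice the spontaneous percentile; excluded", i)
            onsets.append(None)
            continue
        onsets.append(float(p.edges[ob]))
        usable.append((p, ob))
    if not usable:
        raise ValueError("no alignable PSTH")
    ref = min(ob for _, ob in usable)
    shifted = []
    min_len = None
    for p, ob in usable:
        sh = ob - ref
        r = p.rate[sh:]
        shifted.append(r)
        min_len = len(r) if min_len is None else min(min_len, len(r))
    avg = np.mean([r[:min_len] for r in shifted], axis=0)
    bw = usable[0][0].bin_width
    edges = usable[0][0].edges[0] + np.arange(min_len + 1) * bw
    return PSTHData(bin_width=bw, edges=edges, rate=avg,
                    n_trials=sum(p.n_trials for p, _ in usable),
                    onset=float(edges[ref])), onsets


def peak_and_adapted(psth: PSTHData, onset: float,
                     adapted_window: Tuple[float, float] = (35e-3, 45e-3),
                     peak_window: Tuple[float, float] = (3e-3, 11e-3),
                     ) -> Tuple[float, float]:
    """Peak (largest bin 3-11 ms after onset) and adapted (window mean) rate.

    Windows are relative to ``onset``; ``adapted_window`` is 35-45 ms for
    50 ms tone bursts and 405-415 ms for 500 ms bursts.  Ties in the peak
    window go to the earliest bin.
    """
    c = psth.centers - onset
    pk = (c >= peak_window[0]) & (c < peak_window[1])
    ad = (c >= adapted_window[0]) & (c < adapted_window[1])
    if not pk.any() or not ad.any():
        raise ValueError("analysis window outside PSTH support")
    peak = float(np.max(psth.rate[pk]))
    adapted = float(np.mean(psth.rate[ad]))
    return peak, adapted


# ---------------------------------------------------------------------------
# exponential adaptation fits
# ---------------------------------------------------------------------------

def _single_exp(t, a, tau, y0):
    return y0 + a * np.exp(-t / tau)


def _double_exp(t, a1, tau1, a2, tau2, y0):
    return y0 + a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)


def fit_adaptation(psth: PSTHData, onset: float, kind: str = "single",
                   fit_offset: bool = True) -> ExpFitResult:
    """Least-squares exponential fit of post-onset rate decay.

    ``kind`` selects a single or a double exponential (plus an optional
    constant offset).  Times are handled in milliseconds relative to the
    onset; the reported ``r`` is the Pearson correlation between fit and
    data.  Raises on non-convergence, quoting the starting values.
    """
    t = (psth.centers - onset) * 1e3  # ms
    sel = t >= 0
    t, y = t[sel], psth.rate[sel]
    if len(t) < 10:
        raise ValueError("need at least 10 post-onset bins")
    y0_guess = float(np.min(y)) if fit_offset else 0.0
    a_guess = max(float(np.max(y) - y0_guess), 1e-6)
    span = max(float(t[-1]), 1.0)

    if kind == "single":
        starts = [(a_guess, tau) for tau in (span / 10, span / 3)]
        model = _single_exp if fit_offset else \
            (lambda tt, a, tau: _single_exp(tt, a, tau, 0.0))
        best = None
        for a0, tau0 in starts:
            p0 = [a0, tau0] + ([y0_guess] if fit_offset else [])
            lo = [-np.inf, 1e-3] + ([-np.inf] if fit_offset else [])
            hi = [np.inf, 1e5] + ([np.inf] if fit_offset else [])
            try:
                popt, _ = optimize.curve_fit(model, t, y, p0=p0,
                                             bounds=(lo, hi), maxfev=20000)
            except RuntimeError:
                continue
            res = float(np.sum((model(t, *popt) - y) ** 2))
            if best is None or res < best[0]:
                best = (res, popt)
        if best is None:
            raise RuntimeError(
                f"single-exponential fit did not converge (starts {starts})")
        popt = best[1]
        yhat = model(t, *popt)
        r = _pearson(yhat, y)
        return ExpFitResult(kind="single", amplitude=float(popt[0]),
                            tau=float(popt[1]),
                            offset=float(popt[2]) if fit_offset else 0.0,
                            r=r)

    if kind != "double":
        raise ValueError("kind must be 'single' or 'double'")

    model = _double_exp if fit_offset else \
        (lambda tt, a1, t1, a2, t2: _double_exp(tt, a1, t1, a2, t2, 0.0))
    best = None
    starts = []
    for tf in (span / 20, span / 8):
        for ts in (span / 2, span, 3 * span):
            starts.append((a_guess, tf, a_guess / 5, ts))
    for a1, t1, a2, t2 in starts:
        p0 = [a1, t1, a2, t2] + ([y0_guess] if fit_offset else [])
        lo = [0.0, 1e-3, 0.0, 1e-3] + ([-np.inf] if fit_offset else [])
        hi = [np.inf, 1e5, np.inf, 1e5] + ([np.inf] if fit_offset else [])
        try:
            popt, _ = optimize.curve_fit(model, t, y, p0=p0,
                                         bounds=(lo, hi), maxfev=20000)
        except RuntimeError:
            continue
        res = float(np.sum((model(t, *popt) - y) ** 2))
        if best is None or res < best[0]:
            best = (res, popt)
    if best is None:
        raise RuntimeError(
            f"double-exponential fit did not converge (starts {starts})")
    popt = best[1]
    a1, t1, a2, t2 = popt[:4]
    off = float(popt[4]) if fit_offset else 0.0
    if t1 > t2:  # report fast component first
        a1, t1, a2, t2 = a2, t2, a1, t1
    yhat = model(t, *popt)
    return ExpFitResult(kind="double", tau_fast=float(t1), tau_slow=float(t2),
                        amp_fast=float(a1), amp_slow=float(a2), offset=off,
                        r=_pearson(yhat, y))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# forward masking
# ---------------------------------------------------------------------------

def forward_masking_ratio(spikes: SpikeTrainSet, masker_onset: float,
                          probe_onset: float, window: float = 10e-3,
                          ) -> float:
    """Probe/masker onset-response ratio.

    Spike counts in ``window`` (10 ms) after each onset are summed over all
    trials; the ratio indexes the recovery of the readily releasable pool.
    A zero masker count makes the ratio undefined (ValueError).
    """
    if spikes.n_trials < 25:
        warnings.warn("fewer than 25 repetitions; ratio estimate is noisy",
                      stacklevel=2)
    pooled = spikes.pooled()
    m = int(np.sum((pooled >= masker_onset) &
                   (pooled < masker_onset + window)))
    p = int(np.sum((pooled >= probe_onset) &
                   (pooled < probe_onset + window)))
    if m == 0:
        raise ValueError("zero masker count: ratio undefined")
    return p / m


def fit_recovery(gaps: Sequence[float], ratios: Sequence[float],
                 ) -> Tuple[float, float, bool]:
    """Fit ratio(gap) = 1 - A exp(-gap/tau); gaps in seconds, tau in ms.

    Returns ``(tau_ms, amplitude, identifiable)``; ``identifiable`` is
    False when the amplitude is negligible (flat recovery curve, tau
    meaningless).
    """
    g = np.asarray(gaps, dtype=float) * 1e3
    r = np.asarray(ratios, dtype=float)
    if len(g) < 3:
        raise ValueError("need at least 3 (gap, ratio) points")
    spread = float(np.ptp(r))
    if spread < 1e-9:
        return np.nan, 0.0, False
    a0 = max(1.0 - float(r[np.argmin(g)]), 0.05)
    best = None
    for tau0 in (10.0, 50.0, 200.0):
        try:
            popt, _ = optimize.curve_fit(
                lambda x, a, tau: 1.0 - a * np.exp(-x / tau), g, r,
                p0=[a0, tau0], bounds=([0, 1e-2], [10, 1e5]), maxfev=20000)
        except RuntimeError:
            continue
        res = float(np.sum((1 - popt[0] * np.exp(-g / popt[1]) - r) ** 2))
        if best is None or res < best[0]:
            best = (res, popt)
    if best is None:
        raise RuntimeError("recovery fit did not converge")
    a, tau = best[1]
    return float(tau), float(a), a > 1e-3


# ---------------------------------------------------------------------------
# phase locking and rate-level functions
# ---------------------------------------------------------------------------

def synchronization_index(spike_times: Sequence[float],
                          modulation_period: float,
                          min_spikes: int = 15,
                          literal_below: bool = False,
                          ) -> Tuple[float, float, bool]:
    """Vector strength of phase locking plus its Rayleigh statistic.

    SI = |sum exp(2 pi i t_j / T)| / n and the Rayleigh statistic is
    2 n SI^2.  ``valid`` requires at least ``min_spikes`` spikes and, by
    default, a Rayleigh statistic above 13.8 (significant synchrony);
    ``literal_below=True`` inverts the criterion direction.
    """
    if modulation_period <= 0:
        raise ValueError("modulation period must be positive")
    t = np.asarray(spike_times, dtype=float)
    n = t.size
    if n == 0:
        return np.nan, np.nan, False
    phases = 2 * np.pi * t / modulation_period
    si = float(np.abs(np.exp(1j * phases).sum()) / n)
    rayleigh = 2.0 * n * si ** 2
    if literal_below:
        sig = rayleigh < RAYLEIGH_CRIT
    else:
        sig = rayleigh > RAYLEIGH_CRIT
    return si, rayleigh, bool(n >= min_spikes and sig)


def _logistic(L, r0, rmax, l50, s):
    return r0 + (rmax - r0) / (1.0 + np.exp(-(L - l50) / s))


def rate_level_metrics(levels_db: Sequence[float], rates: Sequence[float],
                       ) -> dict:
    """Sigmoidal rate-level fit, dynamic range and maximal steepness.

    The dynamic range is the sound-pressure span between 10% and 90% of
    the fitted rate increase (2 s ln 9 for a logistic with slope factor s);
    maximal steepness is the largest rate increase between two consecutive
    5 dB steps.  Flat or unfittable data return ``flagged=True``.
    """
    L = np.asarray(levels_db, dtype=float)
    r = np.asarray(rates, dtype=float)
    if len(L) < 5:
        raise ValueError("need at least 5 level steps")
    max_steep = float(np.max(np.diff(r))) if len(r) > 1 else np.nan
    if np.ptp(r) < 1e-9:
        return dict(params=None, dynamic_range_db=np.nan,
                    max_steepness=max_steep, flagged=True)
    p0 = [float(r.min()), float(r.max()), float(np.median(L)), 5.0]
    try:
        popt, _ = optimize.curve_fit(
            _logistic, L, r, p0=p0,
            bounds=([-np.inf, -np.inf, L.min() - 50, 1e-3],
                    [np.inf, np.inf, L.max() + 50, 1e3]), maxfev=20000)
    except RuntimeError:
        return dict(params=None, dynamic_range_db=np.nan,
                    max_steepness=max_steep, flagged=True)
    r0, rmax, l50, s = popt
    dyn = 2.0 * s * np.log(9.0)
    return dict(params=dict(r0=float(r0), rmax=float(rmax),
                            l50=float(l50), s=float(s)),
                dynamic_range_db=float(dyn), max_steepness=max_steep,
                flagged=False)
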