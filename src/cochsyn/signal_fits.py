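"""Waveform- and image-level analyses of hair-cell electrophysiology.

Covers the voltage dependence of Ca2+-channel activation (Boltzmann fit of
fluorescence-voltage or conductance curves), activation kinetics of the
Ca2+ current, current/charge metrics of IV protocols, exocytic membrane-
capacitance increments, Ca2+-indicator hotspot quantification and rotated
2D Gaussian fits with FWHM/ellipse-area outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

#: Ca2+ reversal potential used throughout (mV)
V_REVERSAL = 65.6
#: voltage range for the linear fluorescence-voltage slope estimate (mV)
FV_LINEAR_RANGE = (3.0, 23.0)

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


# ---------------------------------------------------------------------------
# Boltzmann fractional activation
# ---------------------------------------------------------------------------

@dataclass
class BoltzmannParams:
    """Parameters of F(V) = F0 + fv (Vr - V) / (1 + exp((Vh - V)/k))."""

    f0: float
    fv: float
    vh: float
    k: float
    vr: float = V_REVERSAL

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("slope factor k must be positive")
        if self.vr <= self.vh:
            raise ValueError("reversal potential must exceed Vh")

    def __call__(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        return self.f0 + self.fv * (self.vr - v) / (
            1.0 + np.exp((self.vh - v) / self.k))


def boltzmann_fv_fit(v: Sequence[float], f: Sequence[float],
                     vr: float = V_REVERSAL,
                     refine_fv: bool = True) -> BoltzmannParams:
    """Fit the Boltzmann driving-force model to a fluorescence-voltage curve.

    The fluorescence-voltage slope ``fv`` is first estimated by linear
    regression on the 3-23 mV range, where the channels are essentially
    fully activated and F is linear in the driving force (Vr - V).  The
    half-activation voltage Vh, slope factor k and baseline F0 are then
    fitted by least squares with the reversal potential fixed.

    By default ``fv`` is refined jointly in the final fit (the regression
    value serves as its initializer); ``refine_fv=False`` holds it at the
    regression estimate.  Refining removes the small bias the residual
    Boltzmann tail leaves in the linear estimate.
    """
    v = np.asarray(v, dtype=float)
    f = np.asarray(f, dtype=float)
    lo, hi = FV_LINEAR_RANGE
    lin = (v >= lo) & (v <= hi)
    if not lin.any():
        raise ValueError(f"no samples in the {lo}-{hi} mV range")
    slope, intercept, *_ = stats.linregress(v[lin], f[lin])
    fv0 = -float(slope)  # F ~ F0 + fv (Vr - V) on the linear range
    if fv0 <= 0:
        fv0 = max(float(np.ptp(f)) / float(np.ptp(v)), 1e-9)

    vh0 = float(v[np.argmin(np.abs(f - 0.5 * (f.min() + f.max())))])
    vh0 = min(vh0, vr - 1.0)
    p0_common = [float(f.min()), vh0, 7.0]

    if refine_fv:
        def model(vv, f0, vh, k, fv):
            return f0 + fv * (vr - vv) / (1.0 + np.exp((vh - vv) / k))
        p0 = p0_common + [fv0]
        bounds = ([-np.inf, -200.0, 1e-2, 0.0],
                  [np.inf, vr - 1e-6, 100.0, np.inf])
    else:
        def model(vv, f0, vh, k):
            return f0 + fv0 * (vr - vv) / (1.0 + np.exp((vh - vv) / k))
        p0 = p0_common
        bounds = ([-np.inf, -200.0, 1e-2], [np.inf, vr - 1e-6, 100.0])
    popt, _ = optimize.curve_fit(model, v, f, p0=p0, bounds=bounds,
                                 maxfev=20000)
    fv_fit = float(popt[3]) if refine_fv else fv0
    return BoltzmannParams(f0=float(popt[0]), fv=fv_fit, vh=float(popt[1]),
                           k=float(popt[2]), vr=vr)


def fractional_activation(i: np.ndarray, v: np.ndarray,
                          vr: float = V_REVERSAL) -> np.ndarray:
    """Normalized conductance G(V)/G_max derived from an IV relationship."""
    i = np.asarray(i, dtype=float)
    v = np.asarray(v, dtype=float)
    g = i / (v - vr)
    gmax = np.max(np.abs(g))
    if gmax == 0:
        raise ValueError("flat IV curve")
    return g / np.max(g)


# ---------------------------------------------------------------------------
# current-trace metrics
# ---------------------------------------------------------------------------

def iv_metrics(t: np.ndarray, i: np.ndarray, step: Tuple[float, float],
               window: Tuple[float, float] = (5e-3, 10e-3),
               leak: float = 0.0) -> Tuple[float, float]:
    """Mean leak-subtracted current and total charge of a depolarizing step.

    ``step`` gives (start, end) of the depolarization (s); the current is
    averaged in ``window`` relative to the step start (default 5-10 ms) and
    the charge is the trapezoidal integral of the leak-subtracted current
    over the whole step.
    """
    t = np.asarray(t, dtype=float)
    i = np.asarray(i, dtype=float)
    t0, t1 = step
    w0, w1 = t0 + window[0], t0 + window[1]
    if w1 > t1 + 1e-12:
        raise ValueError("averaging window extends beyond the step")
    win = (t >= w0) & (t < w1)
    if not win.any():
        raise ValueError("averaging window contains no samples")
    ii = i - leak
    mean_i = float(np.mean(ii[win]))
    instep = (t >= t0) & (t <= t1)
    charge = float(np.trapezoid(ii[instep], t[instep]))
    return mean_i, charge


@dataclass
class ActivationKinetics:
    """Power-exponential activation fit I(t) = y0 + A (1 - exp(-t/tau))^2."""

    y0: float
    amplitude: float
    tau: float  # ms

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def activation_tau_fit(t: np.ndarray, i: np.ndarray,
                       fit_span: float = 5e-3) -> ActivationKinetics:
    """Fit activation kinetics to the first 5 ms of a current trace.

    Times in seconds; the fitted time constant is reported in ms.
    """
    t = np.asarray(t, dtype=float)
    i = np.asarray(i, dtype=float)
    sel = (t >= 0) & (t <= fit_span)
    if sel.sum() < 20:
        raise ValueError("need at least 20 samples within the fit span")
    tt = t[sel] * 1e3  # ms
    yy = i[sel]

    def model(x, y0, a, tau):
        return y0 + a * (1.0 - np.exp(-x / tau)) ** 2

    a0 = float(yy[-1] - yy[0])
    best = None
    for tau0 in (0.2, 0.5, 1.5):
        try:
            popt, _ = optimize.curve_fit(
                model, tt, yy, p0=[float(yy[0]), a0, tau0],
                bounds=([-np.inf, -np.inf, 1e-3], [np.inf, np.inf, 100.0]),
                maxfev=20000)
        except RuntimeError:
            continue
        res = float(np.sum((model(tt, *popt) - yy) ** 2))
        if best is None or res < best[0]:
            best = (res, popt)
    if best is None:
        raise RuntimeError("activation fit did not converge")
    y0, a, tau = best[1]
    return ActivationKinetics(y0=float(y0), amplitude=float(a),
                              tau=float(tau))


# ---------------------------------------------------------------------------
# capacitance
# ---------------------------------------------------------------------------

def delta_cm(t: np.ndarray, cm: np.ndarray, depol: Tuple[float, float],
             mode: str = "standard", window: float = 0.4,
             min_window: float = 0.05) -> Tuple[float, bool]:
    """Exocytic capacitance increment around a depolarization.

    ΔC_m is the mean of C_m over ``window`` (400 ms) after the
    depolarization minus the mean over the same span before it.  The first
    60 ms after the step end are skipped (30 ms in ``mode="paired"``,
    where the windows are additionally truncated to the available
    inter-pulse interval).  Returns ``(delta_fF_like_units, flagged)``
    with ``flagged`` set when a window had to be truncated below
    ``min_window``.
    """
    t = np.asarray(t, dtype=float)
    cm = np.asarray(cm, dtype=float)
    d0, d1 = depol
    if mode == "standard":
        skip = 0.06
    elif mode == "paired":
        skip = 0.03
    else:
        raise ValueError("mode must be 'standard' or 'paired'")
    before = (t >= d0 - window) & (t < d0)
    after0 = d1 + skip
    after = (t >= after0) & (t < after0 + window)
    flagged = False
    for m, name in ((before, "before"), (after, "after")):
        if not m.any():
            raise ValueError(f"no samples in the {name} window")
    span_before = t[before][-1] - t[before][0]
    span_after = t[after][-1] - t[after][0]
    if min(span_before, span_after) < min_window:
        flagged = True
    return float(np.mean(cm[after]) - np.mean(cm[before])), flagged


# ---------------------------------------------------------------------------
# Ca2+-indicator hotspots
# ---------------------------------------------------------------------------

@dataclass
class HotspotMetrics:
    df_image: np.ndarray
    df: float                # best 3x3-average fluorescence increase
    df_over_f0: float
    dfmax_over_f0: Optional[float]
    center: Tuple[int, int]  # (row, col) of the 3x3 square center
    include: bool
    clipped: bool


def hotspot_metrics(stack: np.ndarray, rest_frames: Sequence[int],
                    stim_frames: Sequence[int],
                    voltages: Optional[Sequence[float]] = None,
                    vmax_range: Tuple[float, float] = (-17.0, 8.0),
                    ) -> HotspotMetrics:
    """Quantify a synaptic Ca2+-indicator hotspot in an image stack.

    ΔF image = mean(stim frames) - mean(rest frames); ΔF is the average of
    the 3x3-pixel square with the greatest increase.  When per-frame ramp
    ``voltages`` are given, ΔF_max averages the per-frame ΔF values whose
    voltage falls in ``vmax_range`` (around peak Ca2+ influx).  A hotspot
    is included when its peak response exceeds the resting mean by two
    resting standard deviations; squares clipped at the image border are
    flagged.
    """
    stack = np.asarray(stack, dtype=float)
    rest = stack[list(rest_frames)]
    stim = stack[list(stim_frames)]
    rest_mean = rest.mean(axis=0)
    df_img = stim.mean(axis=0) - rest_mean

    from scipy.ndimage import uniform_filter
    df_boxed = uniform_filter(df_img, size=3, mode="constant")
    h, w = df_img.shape
    interior = df_boxed[1:h - 1, 1:w - 1]
    r, c = np.unravel_index(np.argmax(interior), interior.shape)
    r, c = int(r) + 1, int(c) + 1
    clipped = False
    # argmax over the full (including border) boxed image for the flag
    rb, cb = np.unravel_index(np.argmax(df_boxed), df_boxed.shape)
    if df_boxed[rb, cb] > df_boxed[r, c] + 1e-12:
        r, c, clipped = int(rb), int(cb), True
    sl = (slice(max(r - 1, 0), r + 2), slice(max(c - 1, 0), c + 2))
    df = float(np.mean(df_img[sl]))
    f0 = float(np.mean(rest_mean[sl]))

    dfmax = None
    if voltages is not None:
        voltages = np.asarray(voltages, dtype=float)
        per_frame = np.array([np.mean(s[sl] - rest_mean[sl]) for s in stim])
        in_range = (voltages >= vmax_range[0]) & (voltages <= vmax_range[1])
        if in_range.any():
            dfmax = float(np.mean(per_frame[in_range]))
    peak_df = dfmax if dfmax is not None else df
    # resting variability of the same 3x3 average, across rest frames
    rest_sd = float(np.std(np.stack([fr[sl] for fr in rest]).mean(axis=(1, 2))))
    include = bool(peak_df > 2.0 * rest_sd and peak_df > 0)
    denom = f0 if f0 != 0 else np.nan
    return HotspotMetrics(df_image=df_img, df=df,
                          df_over_f0=df / denom,
                          dfmax_over_f0=None if dfmax is None else dfmax / denom,
                          center=(r, c), include=include, clipped=clipped)


# ---------------------------------------------------------------------------
# 2D Gaussian spatial-extent fits
# ---------------------------------------------------------------------------

@dataclass
class Gauss2DFit:
    """Rotated 2D Gaussian fit: FWHM = 2 sqrt(2 ln 2) sigma per axis."""

    center: Tuple[float, float]
    amplitude: float
    sigma_long: float
    sigma_short: float
    orientation: float  # rad, long axis vs x
    offset: float

    def __post_init__(self) -> None:
        if not (self.sigma_long >= self.sigma_short > 0):
            raise ValueError("need sigma_long >= sigma_short > 0")

    @property
    def fwhm_long(self) -> float:
        return FWHM_FACTOR * self.sigma_long

    @property
    def fwhm_short(self) -> float:
        return FWHM_FACTOR * self.sigma_short

    @property
    def ellipse_area(self) -> float:
        """pi * (FWHM_long/2) * (FWHM_short/2), in squared pixel units."""
        return np.pi * (self.fwhm_long / 2.0) * (self.fwhm_short / 2.0)


def _gauss2d(coords, amp, x0, y0, sx, sy, theta, off):
    x, y = coords
    ct, st = np.cos(theta), np.sin(theta)
    xr = ct * (x - x0) + st * (y - y0)
    yr = -st * (x - x0) + ct * (y - y0)
    return off + amp * np.exp(-0.5 * ((xr / sx) ** 2 + (yr / sy) ** 2))


def gauss2d_fwhm(image: np.ndarray, pixel_size: float = 1.0) -> Gauss2DFit:
    """Least-squares rotated 2D Gaussian fit of a single fluorescent blob.

    ``pixel_size`` scales the spatial outputs (e.g. nm per pixel).  Raises
    on degenerate (flat) input.
    """
    img = np.asarray(image, dtype=float)
    if np.ptp(img) <= 0:
        raise ValueError("flat image: no blob to fit")
    h, w = img.shape
    y, x = np.mgrid[0:h, 0:w]
    off0 = float(np.percentile(img, 10))
    amp0 = float(img.max() - off0)
    wgt = np.clip(img - off0, 0, None)
    total = wgt.sum()
    x0 = float((x * wgt).sum() / total)
    y0 = float((y * wgt).sum() / total)
    # image moments give the initial covariance: an anisotropic, rotated
    # start keeps the optimizer off the theta=0 saddle
    cxx = float(((x - x0) ** 2 * wgt).sum() / total)
    cyy = float(((y - y0) ** 2 * wgt).sum() / total)
    cxy = float(((x - x0) * (y - y0) * wgt).sum() / total)
    cov = np.array([[cxx, cxy], [cxy, cyy]])
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.25, None)
    theta0 = float(np.arctan2(evecs[1, 1], evecs[0, 1]))  # major axis
    sx0, sy0 = float(np.sqrt(evals[1])), float(np.sqrt(evals[0]))
    p0 = [amp0, x0, y0, sx0, sy0, theta0, off0]
    bounds = ([0, -w, -h, 1e-3, 1e-3, -np.pi, -np.inf],
              [np.inf, 2 * w, 2 * h, 10 * max(h, w), 10 * max(h, w),
               np.pi, np.inf])
    popt, _ = optimize.curve_fit(_gauss2d, (x.ravel(), y.ravel()),
                                 img.ravel(), p0=p0, bounds=bounds,
                                 maxfev=40000)
    amp, x0, y0, sx, sy, theta, off = popt
    if sx >= sy:
        s_long, s_short, ang = sx, sy, theta
    else:
        s_long, s_short, ang = sy, sx, theta + np.pi / 2
    ang = (ang + np.pi / 2) % np.pi - np.pi / 2
    return Gauss2DFit(center=(float(x0) * pixel_size, float(y0) * pixel_size),
                      amplitude=float(amp),
                      sigma_long=float(s_long) * pixel_size,
                      sigma_short=float(s_short) * pixel_size,
                      orientation=float(ang), offset=float(off))
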