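"""Double-Weibull diel pulse model for continuous volatile time series.

Each ion's multi-day trace is segmented into day windows (light-on to the
next light-on, extended 6 h so pulses decaying after midnight are not
truncated) and a single asymmetric pulse is fitted per window:

    y(t) = b(t) + A * g(t)

    g(t) = exp(-((t_peak - t) / s_r) ** k_r)   for t <= t_peak
           exp(-((t - t_peak) / s_f) ** k_f)   for t >  t_peak

with separate rise/fall scales (``s_r``, ``s_f``, hours) and shapes
(``k_r``, ``k_f`` >= 1), and a baseline ``b(t)`` blending logistically from
``b_pre`` to ``b_post`` across the pulse (centered at ``t_peak``, scale
``s_r + s_f``).  The form has exactly the degrees of freedom the analysis
needs: different slopes in the rising and falling periods and different
baseline levels before and after the peak.

Cardinal times delimit the pulse by area quantiles of the fitted
baseline-free pulse ``A * g``: start at 0.5% of cumulative area, maximum at
``t_peak``, end at 99.5% — i.e. the central 99% of the modelled peak area.

All times are in hours relative to the dark (light-to-dark) transition,
which is aligned with local sunset when comparing to field pollinator data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "CardinalTimes",
    "DayWindow",
    "PulseFitResults",
    "WeibullPulseModel",
    "cardinal_times",
    "classify_timing",
    "diel_ratio",
    "fit_weibull_pulse",
    "median_maxima",
    "pulse_shape",
    "segment_days",
]


def pulse_shape(t, t_peak, s_r, s_f, k_r, k_f):
    """Unit-amplitude asymmetric pulse g(t); vectorized over t."""
    t = np.asarray(t, dtype=float)
    g = np.empty_like(t)
    rise = t <= t_peak
    g[rise] = np.exp(-(((t_peak - t[rise]) / s_r) ** k_r))
    g[~rise] = np.exp(-(((t[~rise] - t_peak) / s_f) ** k_f))
    return g


def pulse_model(t, b_pre, b_post, A, t_peak, s_r, s_f, k_r, k_f):
    """Full model: logistic baseline blend plus scaled pulse."""
    t = np.asarray(t, dtype=float)
    w = s_r + s_f
    blend = 1.0 / (1.0 + np.exp(-np.clip((t - t_peak) / w, -500, 500)))
    baseline = b_pre + (b_post - b_pre) * blend
    return baseline + A * pulse_shape(t, t_peak, s_r, s_f, k_r, k_f)


@dataclass
class DayWindow:
    """One day's fitting window: light-on to next light-on plus a 6 h tail."""

    day: int
    t: np.ndarray  #: hours relative to the dark transition of this day
    y: np.ndarray


def segment_days(series: pd.DataFrame, schedule, tail_h: float = 6.0) -> list[DayWindow]:
    """Split a uniformly sampled multi-day trace into per-day windows.

    ``series`` has columns ``time_h`` (hours from recording start, uniform
    step) and ``signal``; ``schedule`` is a
    :class:`~scentdiel.simulate.LightSchedule`.  Each window runs from one
    light-on to the next light-on extended by ``tail_h`` hours; incomplete
    first/last windows are dropped.  Window times are returned relative to
    the dark transition within the window.
    """
    t = series["time_h"].to_numpy(dtype=float)
    y = series["signal"].to_numpy(dtype=float)
    cycle = schedule.cycle_h
    light_rel = schedule.light_on % cycle  # clock hour of light-on
    start_clock = getattr(schedule, "start_clock", light_rel)
    # hours from recording start to each light-on event
    first = (light_rel - start_clock) % cycle
    windows: list[DayWindow] = []
    day = 0
    t0 = first
    if t0 > t[0] + 1e-9 and t0 - cycle >= t[0] - 1e-9:
        t0 -= cycle
    while True:
        t_end = t0 + cycle + tail_h
        if t0 < t[0] - 1e-9:
            t0 += cycle
            continue
        if t_end > t[-1] + 1e-9:
            break
        mask = (t >= t0 - 1e-9) & (t <= t_end + 1e-9)
        dark_h = t0 + schedule.light_hours  # dark transition within window
        windows.append(DayWindow(day=day, t=t[mask] - dark_h, y=y[mask]))
        day += 1
        t0 += cycle
    if not windows:
        import warnings

        warnings.warn("series shorter than one full light cycle; no windows")
    return windows


class WeibullPulseModel:
    """Asymmetric diel pulse model for one day window.

    Parameters
    ----------
    t : array
        Times in hours (relative to the dark transition).
    y : array
        Nonnegative signal per flower.

    ``fit()`` estimates the eight parameters by bounded nonlinear least
    squares from a deterministic multi-start grid over peak location and
    shape exponents, and returns a :class:`PulseFitResults`.
    """

    #: shape-exponent starting values for the multi-start grid
    SHAPE_STARTS = (1.0, 2.0, 4.0)
    #: peak-location grid spacing (hours)
    PEAK_GRID_H = 2.0

    def __init__(self, t, y):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.size != y.size:
            raise ValueError("t and y must have equal length")
        if t.size < 30:
            raise ValueError("window must contain at least 30 points")
        self.t = t
        self.y = y

    def _is_flat(self) -> bool:
        mad = np.median(np.abs(np.diff(self.y) - np.median(np.diff(self.y))))
        return float(np.ptp(self.y)) < 3.0 * mad or np.ptp(self.y) == 0.0

    def _bounds(self):
        t, y = self.t, self.y
        ymax = float(y.max())
        lo = [0.0, 0.0, 0.0, t[0], 1e-2, 1e-2, 1.0, 1.0]
        hi = [ymax + 1e-12, ymax + 1e-12, 2 * ymax + 1e-9, t[-1], 24.0, 24.0, 8.0, 8.0]
        return np.array(lo), np.array(hi)

    def _starts(self):
        t, y = self.t, self.y
        step = float(np.median(np.diff(t)))
        argmax_t = float(t[int(np.argmax(y))])  # earliest index on ties
        peaks = [argmax_t] + list(
            np.arange(t[0] + 1.0, t[-1] - 0.5, self.PEAK_GRID_H)
        )
        b0 = max(float(np.percentile(y, 5)), 0.0)
        A0 = max(float(y.max()) - b0, 1e-9)
        # crude width from points above half maximum
        above = t[y > b0 + 0.5 * A0]
        width = max(float(above.max() - above.min()), 4 * step) if above.size else 2.0
        starts = []
        for tp in peaks:
            for k in self.SHAPE_STARTS:
                starts.append(
                    np.array([b0, b0, A0, tp, width / 2, width / 2, k, k])
                )
        return starts

    def fit(self, max_starts: int | None = None) -> "PulseFitResults":
        t, y = self.t, self.y
        if self._is_flat():
            b = float(np.median(y))
            params = dict(
                b_pre=b, b_post=b, A=0.0, t_peak=float(t[int(np.argmax(y))]),
                s_r=1.0, s_f=1.0, k_r=1.0, k_f=1.0,
            )
            resid_sd = float(np.std(y - b))
            return PulseFitResults(
                model=self, converged=False, degenerate=True,
                resid_sd=resid_sd, **params,
            )
        lo, hi = self._bounds()
        # inverse-signal weights (floored at 5% of the window maximum):
        # volatile noise is multiplicative, so relative residuals are the
        # efficient objective; fixed data-side weights keep the problem
        # an ordinary bounded least squares
        from scipy.ndimage import median_filter

        smooth = median_filter(y, size=5, mode="nearest")
        weights = 1.0 / np.maximum(smooth, 0.05 * y.max())

        def resid(p):
            return (pulse_model(t, *p) - y) * weights

        starts = self._starts()
        # cheap triage: sum of squares at the start point, keep best few
        sses = [float((resid(np.clip(p, lo, hi)) ** 2).sum()) for p in starts]
        order = np.argsort(sses, kind="stable")
        n_polish = max_starts if max_starts is not None else 6
        best = None
        for i in order[:n_polish]:
            p0 = np.clip(starts[i], lo, hi)
            try:
                sol = least_squares(resid, p0, bounds=(lo, hi), method="trf", xtol=1e-10)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        p = best.x
        resid_sd = float(np.std(pulse_model(t, *p) - y))  # in signal units
        amplitude = float(p[2])
        # hitting a structural bound (peak at a window edge, scale or shape
        # pinned at its limit, amplitude at the cap) marks a failed fit;
        # k = 1 and b = 0 are legitimate interior values of the model family
        at_bounds = bool(
            np.isclose(p[3], lo[3], atol=1e-6)
            or np.isclose(p[3], hi[3], atol=1e-6)
            or np.any(np.isclose(p[4:6], lo[4:6], atol=1e-6))
            or np.any(np.isclose(p[4:6], hi[4:6], rtol=1e-6))
            or np.any(np.isclose(p[6:8], hi[6:8], rtol=1e-6))
            or np.isclose(p[2], hi[2], rtol=1e-6)
        )
        converged = amplitude > 0 and resid_sd <= 0.5 * amplitude and not at_bounds
        return PulseFitResults(
            model=self,
            b_pre=float(p[0]), b_post=float(p[1]), A=amplitude,
            t_peak=float(p[3]), s_r=float(p[4]), s_f=float(p[5]),
            k_r=float(p[6]), k_f=float(p[7]),
            resid_sd=resid_sd, converged=converged, degenerate=False,
        )


@dataclass
class PulseFitResults:
    """Fitted diel pulse parameters for one ion-day window."""

    model: WeibullPulseModel
    b_pre: float
    b_post: float
    A: float
    t_peak: float
    s_r: float
    s_f: float
    k_r: float
    k_f: float
    resid_sd: float
    converged: bool
    degenerate: bool

    @property
    def params(self) -> dict[str, float]:
        return {
            k: getattr(self, k)
            for k in ("b_pre", "b_post", "A", "t_peak", "s_r", "s_f", "k_r", "k_f")
        }

    def predict(self, t) -> np.ndarray:
        return pulse_model(t, **self.params)

    def cardinal_times(self, q_lo: float = 0.005, q_hi: float = 0.995):
        return cardinal_times(self, q_lo=q_lo, q_hi=q_hi)

    def summary(self) -> str:
        status = (
            "degenerate (flat window)" if self.degenerate
            else ("converged" if self.converged else "not converged")
        )
        lines = [
            "Double-Weibull diel pulse fit",
            f"  status: {status}; residual SD {self.resid_sd:.4g}",
            f"  amplitude A:      {self.A:.4g}",
            f"  peak time t_peak: {self.t_peak:.3f} h after dark",
            f"  rise  s_r={self.s_r:.3f} h, k_r={self.k_r:.2f}",
            f"  fall  s_f={self.s_f:.3f} h, k_f={self.k_f:.2f}",
            f"  baselines pre/post: {self.b_pre:.4g} / {self.b_post:.4g}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.t, self.model.y, ".", ms=3, label="signal")
        tt = np.linspace(self.model.t[0], self.model.t[-1], 500)
        ax.plot(tt, self.predict(tt), label="fitted pulse")
        ax.set_xlabel("hours after dark transition")
        ax.set_ylabel("signal per flower")
        ax.legend()
        return ax


def fit_weibull_pulse(window: DayWindow | tuple) -> PulseFitResults:
    """Convenience wrapper: fit the pulse model to one day window."""
    if isinstance(window, DayWindow):
        t, y = window.t, window.y
    else:
        t, y = window
    return WeibullPulseModel(t, y).fit()


@dataclass
class CardinalTimes:
    """Start, maximum, and end of a fitted pulse (hours after dark)."""

    t_start: float
    t_max: float
    t_end: float
    area: float  #: total modelled pulse area (signal * h)


def cardinal_times(
    fit: PulseFitResults, q_lo: float = 0.005, q_hi: float = 0.995
) -> CardinalTimes | None:
    """Area-quantile cardinal times of the baseline-free fitted pulse.

    The pulse ``A * g(t)`` is integrated on a 1-min grid; ``t_start`` and
    ``t_end`` are where the normalized cumulative area crosses ``q_lo`` and
    ``q_hi``.  Degenerate or zero-amplitude fits yield ``None`` (missing,
    not zero).
    """
    if fit.degenerate or fit.A <= 0:
        return None
    # support wide enough that g < 1e-8 at the edges: (-ln 1e-8)^(1/k) scales
    span_r = fit.s_r * (18.5 ** (1.0 / fit.k_r))
    span_f = fit.s_f * (18.5 ** (1.0 / fit.k_f))
    step = 1.0 / 60.0
    tt = np.arange(fit.t_peak - span_r, fit.t_peak + span_f + step, step)
    g = fit.A * pulse_shape(tt, fit.t_peak, fit.s_r, fit.s_f, fit.k_r, fit.k_f)
    cum = np.concatenate([[0.0], np.cumsum((g[1:] + g[:-1]) / 2 * step)])
    area = float(cum[-1])
    frac = cum / area
    t_start = float(np.interp(q_lo, frac, tt))
    t_end = float(np.interp(q_hi, frac, tt))
    return CardinalTimes(t_start=t_start, t_max=float(fit.t_peak), t_end=t_end, area=area)


def median_maxima(fits: dict | pd.DataFrame) -> pd.Series:
    """Median peak time per ion across plants and days.

    ``fits`` is either a mapping ion -> iterable of :class:`PulseFitResults`
    or a DataFrame with columns ``ion`` and ``t_max``.  Only converged fits
    contribute.
    """
    if isinstance(fits, pd.DataFrame):
        return fits.groupby("ion")["t_max"].median()
    out = {}
    for ion, fit_list in fits.items():
        vals = [f.t_peak for f in fit_list if f.converged]
        if vals:
            out[ion] = float(np.median(vals))
    return pd.Series(out, name="median_t_max")


def classify_timing(cardinals: CardinalTimes, schedule, tol: float = 0.5) -> str:
    """Timing class from the pulse start time (hours after dark).

    - ``morning``: starts within ``tol`` of the light-on transition,
    - ``dark``: starts at or after the dark transition (within ``tol``),
    - ``afternoon``: starts in between,
    - ``unclassified`` otherwise (e.g. before light-on).
    """
    light_on_rel = -schedule.light_hours  # light-on, hours relative to dark
    t_start = cardinals.t_start
    if abs(t_start - light_on_rel) <= tol:
        return "morning"
    if t_start >= -tol:
        return "dark"
    if light_on_rel + tol < t_start < -tol:
        return "afternoon"
    return "unclassified"


def diel_ratio(
    window: DayWindow,
    evening_window: tuple[float, float] = (2.0, 3.0),
    day_window: tuple[float, float] = (-5.0, -4.0),
) -> float:
    """Evening/day mean-signal ratio for one plant-day.

    Windows are in hours relative to the dark transition; the defaults are
    the 2-3 h after dark evening window against the 5-4 h before dark day
    window.  A ratio above 1 means emissions are evening-elevated.  A zero
    day-window mean yields ``inf``.
    """
    t, y = window.t, window.y
    ev = y[(t >= evening_window[0]) & (t < evening_window[1])]
    dy = y[(t >= day_window[0]) & (t < day_window[1])]
    if ev.size == 0 or dy.size == 0:
        raise ValueError("series does not cover both ratio windows")
    day_mean = float(dy.mean())
    if day_mean == 0:
        return float(np.inf)
    return float(ev.mean()) / day_mean
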