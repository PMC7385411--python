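"""Pollinator-emission synchrony via the areal-overlap statistic.

Moth visit times and volatile emission time courses are compared on a
common circular 24 h axis anchored at sunset (field) / the dark transition
(growth chamber).  Both are turned into unit-area densities on a 4-min
grid using sliding 16-min windows, and synchrony is the areal overlap

    O(f, g) = sum_i min(f_i, g_i) * step,

the integral of the pointwise minimum of the two densities: 1 for
identical densities, 0 for disjoint ones.  The null expectation replaces
one density by a flat line at 1/24 h^-1 — a hypothetical volatile emitted
at a constant rate (or a uniform distribution of peak times).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from scentdiel.pulsefit import segment_days
from scentdiel.solar import SolarContext, terrain_sunset

__all__ = [
    "BinnedDensity",
    "areal_overlap",
    "binned_density",
    "maxima_overlap",
    "null_overlap",
    "per_ion_overlap",
    "visits_relative_to_sunset",
]

_HALF_CYCLE = 12.0
_CYCLE = 24.0


@dataclass
class BinnedDensity:
    """Unit-area density on a circular 24 h grid.

    ``centers`` are hours relative to sunset/dark in [-12, 12); ``heights``
    are in h^-1 and integrate to exactly 1 over the cycle.
    """

    centers: np.ndarray
    heights: np.ndarray
    step_min: float = 4.0
    window_min: float = 16.0

    def __post_init__(self) -> None:
        if (self.heights < 0).any():
            raise ValueError("density heights must be nonnegative")
        if abs(self.area - 1.0) > 1e-9:
            raise ValueError(f"density area {self.area} is not 1")

    @property
    def step_h(self) -> float:
        return self.step_min / 60.0

    @property
    def area(self) -> float:
        return float(self.heights.sum() * self.step_min / 60.0)

    def shifted(self, n_steps: int) -> "BinnedDensity":
        """Circularly shifted copy (whole grid steps)."""
        return BinnedDensity(
            self.centers, np.roll(self.heights, n_steps), self.step_min, self.window_min
        )


def _grid(step_min: float) -> np.ndarray:
    n = int(round(_CYCLE * 60.0 / step_min))
    if abs(n * step_min - _CYCLE * 60.0) > 1e-9:
        raise ValueError("grid step must divide 24 h")
    return -_HALF_CYCLE + np.arange(n) * step_min / 60.0


def _wrap(values: np.ndarray) -> np.ndarray:
    return (np.asarray(values, dtype=float) + _HALF_CYCLE) % _CYCLE - _HALF_CYCLE


def binned_density(
    values=None,
    series: tuple[np.ndarray, np.ndarray] | None = None,
    step_min: float = 4.0,
    window_min: float = 16.0,
) -> BinnedDensity:
    """Unit-area density from point events or a nonnegative signal trace.

    For point events (``values``: hours relative to sunset/dark, wrapped
    onto the circular cycle), each 4-min grid point receives the count of
    events inside a 16-min window centered on it (half-open,
    ``[c - w/2, c + w/2)``), then heights are scaled to unit area.  For a
    ``series`` (``(times_h, signal)``), the signal is averaged per grid
    point, smoothed with the same centered window, and normalized
    identically.
    """
    centers = _grid(step_min)
    n = centers.size
    w_steps = int(round(window_min / step_min))
    if values is not None:
        values = np.atleast_1d(np.asarray(values, dtype=float))
        if values.size == 0:
            raise ValueError("no events supplied")
        v = _wrap(values)
        # signed circular offset of each event from each center
        diff = _wrap(v[:, None] - centers[None, :])
        half_w = window_min / 60.0 / 2.0
        eps = 1e-9  # half-open boundary robust to wrap-around rounding
        counts = ((diff >= -half_w - eps) & (diff < half_w - eps)).sum(axis=0).astype(float)
        heights = counts
    elif series is not None:
        t, y = series
        y = np.asarray(y, dtype=float)
        if (y < 0).any():
            raise ValueError("series signal must be nonnegative")
        v = _wrap(np.asarray(t, dtype=float))
        idx = np.round((v + _HALF_CYCLE) / (step_min / 60.0)).astype(int) % n
        sums = np.bincount(idx, weights=y, minlength=n)
        cnts = np.bincount(idx, minlength=n)
        means = np.divide(sums, cnts, out=np.zeros(n), where=cnts > 0)
        # same half-open centered window as for events
        offsets = [k - w_steps // 2 for k in range(w_steps)]
        heights = sum(np.roll(means, -o) for o in offsets) / w_steps
    else:
        raise ValueError("supply either values or series")
    total = heights.sum() * step_min / 60.0
    if total <= 0:
        raise ValueError("input has no mass; density undefined")
    return BinnedDensity(centers, heights / total, step_min, window_min)


def areal_overlap(f: BinnedDensity, g: BinnedDensity) -> float:
    """Integral of the pointwise minimum of two unit-area densities."""
    if f.centers.shape != g.centers.shape or not np.allclose(f.centers, g.centers):
        raise ValueError("densities must share the same grid")
    return float(np.minimum(f.heights, g.heights).sum() * f.step_h)


def null_overlap(f: BinnedDensity) -> float:
    """Overlap of ``f`` with the flat line at 1/24 h^-1 (unit area)."""
    uniform = BinnedDensity(
        f.centers,
        np.full_like(f.heights, 1.0 / _CYCLE),
        f.step_min,
        f.window_min,
    )
    return areal_overlap(f, uniform)


def maxima_overlap(t_max_values, visit_density: BinnedDensity) -> float:
    """Synchrony of emission peak times with pollinator visits.

    Builds the unit-area density of the fitted peak times (aggregated
    across ions, days, and plants; hours after dark, aligned to sunset)
    and overlaps it with the visit density.
    """
    t_max_values = np.atleast_1d(np.asarray(t_max_values, dtype=float))
    if t_max_values.size == 0:
        raise ValueError("need at least one peak time")
    dens = binned_density(
        t_max_values,
        step_min=visit_density.step_min,
        window_min=visit_density.window_min,
    )
    return areal_overlap(dens, visit_density)


def per_ion_overlap(ion_set, visit_density: BinnedDensity) -> pd.DataFrame:
    """Overlap of each plant-day emission time course with the visits.

    Each plant-day window of every ion trace is converted to a unit-area
    density (times relative to that day's dark transition) and overlapped
    with the visit density; per-ion mean and SD across plant-days are
    attached.  All-zero traces get overlap 0 and a flag.
    """
    rows = []
    for (plant, mz), grp in ion_set.data.groupby(["plant_id", "mz"], sort=False):
        series = grp.rename(columns={"signal_per_flower": "signal"})[["time_h", "signal"]]
        for win in segment_days(series, ion_set.schedule):
            if win.y.sum() == 0:
                rows.append(
                    {"plant_id": plant, "mz": mz, "day": win.day,
                     "overlap": 0.0, "flagged_zero": True}
                )
                continue
            dens = binned_density(
                series=(win.t, win.y),
                step_min=visit_density.step_min,
                window_min=visit_density.window_min,
            )
            rows.append(
                {"plant_id": plant, "mz": mz, "day": win.day,
                 "overlap": areal_overlap(dens, visit_density), "flagged_zero": False}
            )
    table = pd.DataFrame(rows)
    summary = table.groupby("mz")["overlap"].agg(["mean", "std"])
    return table.merge(
        summary.rename(columns={"mean": "ion_mean", "std": "ion_sd"}),
        left_on="mz",
        right_index=True,
    )


def visits_relative_to_sunset(visits: pd.DataFrame, context: SolarContext) -> np.ndarray:
    """Offsets (hours) of each visit from its date's terrain-corrected sunset.

    ``visits`` has columns ``date`` (datetime.date) and ``time_local``
    (datetime.time).  Offsets are pooled across dates.
    """
    sunsets = {d: terrain_sunset(context, d) for d in visits["date"].unique()}
    offsets = []
    for _, row in visits.iterrows():
        visit_dt = pd.Timestamp.combine(pd.Timestamp(row["date"]), row["time_local"])
        offsets.append((visit_dt - sunsets[row["date"]]).total_seconds() / 3600.0)
    return np.asarray(offsets)
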