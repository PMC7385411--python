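"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the study's data streams:

- :func:`simulate_gcms_experiment`: dynamic-headspace GC-MS sample tables
  for two species whose blends follow the packaged two-species blend table
  (per-compound occurrence probabilities and mean emission rates), ambient
  controls carrying designated contaminants, and calibration fixtures (a
  C7-C30 alkane ladder and 7-standard response curves spanning four orders
  of magnitude in mass).
- :func:`simulate_ion_timeseries`: multi-day PTR-MS-style ion traces built
  from the same double-Weibull pulse model the fitting stage assumes, with
  one pulse per day in one of three timing classes keyed to the light
  transitions (morning: rise at light-on; afternoon: rise hours before
  dark; dark: rise at dark, peak 1-3 h after), multiplicative log-normal
  noise, and optional day-to-day amplitude decay.
- :func:`simulate_moth_visits`: evening pollinator visits as a truncated
  normal offset after sunset (default mean 1.1 h, SD 0.4 h, support
  0.2-1.6 h).

All randomness flows from explicit integer seeds; identical configuration
and seed reproduce identical outputs.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from scentdiel.datasets import load_blend_table
from scentdiel.gcms import CalibrationModel, EmissionTable
from scentdiel.pulsefit import pulse_shape

__all__ = [
    "IonTimeSeriesSet",
    "LightSchedule",
    "TruthRecord",
    "default_truth",
    "simulate_gcms_experiment",
    "simulate_ion_timeseries",
    "simulate_moth_visits",
]

#: The study's seven authentic calibration standards with their compound class.
STANDARDS = {
    "(Z)-hex-3-en-1-ol": "aliphatic",
    "alpha-pinene": "monoterpene",
    "indole": "benzenoid",
    "linalool": "monoterpene",
    "beta-caryophyllene": "other",
    "benzaldehyde dimethyl acetate": "benzenoid",
    "(E,E)-farnesol": "irregular terpene",
}

#: Chemically nearest standard for each compound class in the blend table.
DEFAULT_CLASS_MAP = {
    "aliphatic": "(Z)-hex-3-en-1-ol",
    "benzenoid": "benzaldehyde dimethyl acetate",
    "monoterpene": "linalool",
    "irregular terpene": "(E,E)-farnesol",
    "other": "beta-caryophyllene",
}


@dataclass(frozen=True)
class LightSchedule:
    """Growth-chamber light schedule on a fixed 24 h cycle.

    ``light_on`` and ``dark_on`` are clock hours (default 5:00 and 17:00,
    i.e. a 12 h photoperiod); ``start_clock`` is the clock hour at which a
    recording begins (defaults to light-on so day 1 is complete).
    """

    light_on: float = 5.0
    dark_on: float = 17.0
    n_days: int = 3
    utc_offset: float = -8.0
    cycle_h: float = 24.0
    start_clock: float | None = None

    def __post_init__(self) -> None:
        if self.light_on % self.cycle_h == self.dark_on % self.cycle_h:
            raise ValueError("light_on and dark_on must differ")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.start_clock is None:
            object.__setattr__(self, "start_clock", self.light_on)

    @property
    def light_hours(self) -> float:
        return (self.dark_on - self.light_on) % self.cycle_h

    def dark_times_h(self, total_h: float) -> np.ndarray:
        """Hours (from recording start) of each dark transition."""
        first = (self.dark_on - self.start_clock) % self.cycle_h
        return np.arange(first, total_h, self.cycle_h)


@dataclass
class IonPulseTruth:
    """Ground-truth pulse parameters for one simulated ion."""

    mz: float
    timing_class: str  # morning | afternoon | dark
    t_peak: float  # hours relative to dark transition
    s_r: float
    s_f: float
    k_r: float
    k_f: float
    amplitude: float
    b_pre: float
    b_post: float
    daily_decay: float = 1.0  # day-d amplitude = amplitude * decay**d


@dataclass
class TruthRecord:
    """Configured ground truth for all three generators."""

    blend: pd.DataFrame  #: per-compound class/occurrence/mean rates per species
    contaminants: pd.DataFrame  #: name, class, control_mean, floral_mean
    ions: list[IonPulseTruth]
    visit_mean_h: float = 1.1
    visit_sd_h: float = 0.4
    visit_bounds_h: tuple[float, float] = (0.2, 1.6)
    day_factor: float = 0.6  #: day-phase emission relative to evening
    #: between-day amplitude correlation within a plant (not reported for
    #: the study system; exposed rather than guessed)
    amplitude_day_correlation: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.visit_bounds_h
        if not lo < hi:
            raise ValueError("visit truncation bounds must be ordered")
        for ion in self.ions:
            if ion.amplitude < 0:
                raise ValueError(f"ion {ion.mz}: amplitude must be >= 0")
        for col in ("occ_kaalae", "occ_hookeri"):
            p = self.blend[col].fillna(0.0)
            if ((p < 0) | (p > 1)).any():
                raise ValueError("occurrence probabilities must lie in [0, 1]")


#: Per timing class: peak-time range (h rel. dark), onset (0.5%-area) range,
#: fall-scale range, and shape-exponent range.  Morning pulses are
#: plateau-shaped (large k: rise at light-on, near-flat maximum through the
#: day); afternoon/dark pulses keep k <= 2.2 so the modelled maximum is
#: locally quadratic and its time is statistically identifiable.
_CLASS_RANGES = {
    "morning": ((-1.0, -0.2), (-12.3, -11.7), (1.0, 2.5), (3.0, 5.0)),
    "afternoon": ((0.0, 2.5), (-6.0, -1.0), (1.5, 3.0), (1.3, 2.1)),
    "dark": ((1.0, 3.0), (-0.2, 0.4), (1.0, 2.5), (1.3, 2.1)),
}


def _solve_rise_scale(
    t_peak: float, target_onset: float, s_f: float, k_r: float, k_f: float,
    q_lo: float = 0.005,
) -> float:
    """Rise scale s_r such that the 0.5%-area onset of the unit pulse lands
    at ``target_onset`` (bisection; onset is monotone decreasing in s_r)."""
    from scentdiel.pulsefit import PulseFitResults, cardinal_times

    def onset(s_r: float) -> float:
        fit = PulseFitResults(
            model=None, b_pre=0.0, b_post=0.0, A=1.0, t_peak=t_peak,
            s_r=s_r, s_f=s_f, k_r=k_r, k_f=k_f,
            resid_sd=0.0, converged=True, degenerate=False,
        )
        return cardinal_times(fit, q_lo=q_lo).t_start

    lo, hi = 0.05, 14.0
    if onset(lo) < target_onset or onset(hi) > target_onset:
        return np.clip((t_peak - target_onset) / 1.5, lo, hi)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if onset(mid) > target_onset:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def default_truth(
    n_morning: int = 4,
    n_afternoon: int = 8,
    n_dark: int = 8,
    seed: int = 0,
    daily_decay: float = 1.0,
) -> TruthRecord:
    """Default ground truth: blends from the packaged table, ion pulses in
    the three timing classes with parameters drawn once from ``seed``."""
    blend = load_blend_table()
    rng = np.random.default_rng(seed)
    ions: list[IonPulseTruth] = []
    mz = 41.0
    for cls, n in (("morning", n_morning), ("afternoon", n_afternoon), ("dark", n_dark)):
        (tp_lo, tp_hi), (on_lo, on_hi), (sf_lo, sf_hi), (k_lo, k_hi) = _CLASS_RANGES[cls]
        for _ in range(n):
            mz += float(rng.integers(2, 9))
            amp = float(10 ** rng.uniform(-2.0, -0.5))  # counts s^-1 flower^-1
            t_peak = float(rng.uniform(tp_lo, tp_hi))
            onset = float(rng.uniform(on_lo, on_hi))
            s_f = float(rng.uniform(sf_lo, sf_hi))
            k_r = float(rng.uniform(k_lo, k_hi))
            k_f = float(rng.uniform(k_lo, k_hi))
            s_r = _solve_rise_scale(t_peak, onset, s_f, k_r, k_f)
            ions.append(
                IonPulseTruth(
                    mz=mz,
                    timing_class=cls,
                    t_peak=t_peak,
                    s_r=s_r,
                    s_f=s_f,
                    k_r=k_r,
                    k_f=k_f,
                    amplitude=amp,
                    b_pre=amp * 0.02,
                    b_post=amp * 0.02,
                    daily_decay=daily_decay,
                )
            )
    contaminants = pd.DataFrame(
        {
            "name": ["siloxane D5", "toluene"],
            "compound_class": ["other", "benzenoid"],
            "control_mean": [1.2, 0.6],
            "floral_mean": [1.0, 0.5],
        }
    )
    return TruthRecord(blend=blend, contaminants=contaminants, ions=ions)


def _alkane_ladder() -> pd.DataFrame:
    carbons = np.arange(7, 31)
    # near-linear programmed-temperature elution with mild curvature
    rt = 1.5 + 0.85 * (carbons - 7) + 0.004 * (carbons - 7) ** 2
    return pd.DataFrame({"carbon_number": carbons, "rt_min": np.round(rt, 4)})


def _standard_curves(rng: np.random.Generator, noise_cv: float) -> tuple[pd.DataFrame, CalibrationModel]:
    masses = np.array([1.0, 10.0, 100.0, 1000.0])  # ng, four decades
    rows = []
    curves = {}
    for i, (name, cls) in enumerate(STANDARDS.items()):
        slope = 1.0
        # counts per ng, large enough that major floral compounds clear the
        # 120,000-count abundance threshold while trace ones may not
        intercept = np.log10(1.0e5 * (1.0 + 0.15 * i))
        curves[name] = (slope, float(intercept))
        resp = 10 ** (intercept + slope * np.log10(masses))
        if noise_cv > 0:
            resp = resp * np.exp(rng.normal(0.0, noise_cv, size=resp.size))
        for m, r in zip(masses, resp):
            rows.append({"standard": name, "compound_class": cls, "mass_ng": m, "response": r})
    table = pd.DataFrame(rows)
    return table, CalibrationModel(curves, dict(DEFAULT_CLASS_MAP))


def simulate_gcms_experiment(
    plan: pd.DataFrame,
    truth: TruthRecord | None = None,
    seed: int = 0,
    noise_cv: float = 0.3,
    n_controls: int = 19,
    standards_noise_cv: float = 0.0,
):
    """Simulate a dynamic-headspace GC-MS sampling campaign.

    Parameters
    ----------
    plan : pandas.DataFrame
        One row per sample with ``plant_id``, ``species`` ("kaalae" or
        "hookeri"), ``phase`` ("day"/"evening"), ``time_rel_sunset_h``,
        ``flowers_open`` (>= 1) and optionally ``duration_h`` (default 0.5,
        the 30-min pump time).
    truth : TruthRecord, optional
        Ground truth; defaults to the packaged blend table.
    noise_cv : float
        Log-normal noise scale on per-sample emission rates (0 = noiseless).

    Returns
    -------
    samples, controls : pandas.DataFrame
        Long tables with sample metadata, per-compound instrument
        ``response`` (counts), raw ``abundance``, and the ``true_rate``
        (ng per flower per hour) the response was generated from.
    fixtures : dict
        ``ladder`` (alkane retention table), ``standards`` (calibration
        responses), ``calibration`` (the generating CalibrationModel),
        ``compound_classes``, ``match_scores`` and ``truth``.
    """
    if len(plan) == 0:
        raise ValueError("empty sample plan")
    if (plan["flowers_open"] < 1).any():
        raise ValueError("flower counts must be >= 1")
    truth = truth if truth is not None else default_truth()
    rng = np.random.default_rng(seed)
    plan = plan.copy().reset_index(drop=True)
    if "duration_h" not in plan:
        plan["duration_h"] = 0.5
    standards, calibration = _standard_curves(rng, standards_noise_cv)
    ladder = _alkane_ladder()

    blend = truth.blend
    compound_classes = dict(zip(blend["name"], blend["compound_class"]))
    match_scores = {
        n: (float(s) if np.isfinite(s) else 0.9)
        for n, s in zip(blend["name"], blend["match_score"])
    }
    for _, row in truth.contaminants.iterrows():
        compound_classes[row["name"]] = row["compound_class"]
        match_scores[row["name"]] = 0.95

    def response_from_rate(rate, compound_class, flowers, duration):
        mass = rate * flowers * duration
        std = calibration.standard_for_class(compound_class)
        return np.where(mass > 0, calibration.predict_response(std, np.maximum(mass, 1e-300)), 0.0)

    rows = []
    for i, s in plan.iterrows():
        sp = s["species"]
        occ = blend[f"occ_{sp}"].fillna(0.0).to_numpy()
        mean = blend[f"mean_nonzero_{sp}"].fillna(0.0).to_numpy()
        # compounds that do occur but whose mean rate rounds to 0.00 in the
        # reference table emit at half the table's printed resolution
        mean = np.where((occ > 0) & (mean <= 0), 0.005, mean)
        phase_factor = 1.0 if s["phase"] == "evening" else truth.day_factor
        present = rng.random(len(blend)) < occ
        noise = np.exp(rng.normal(0.0, noise_cv, len(blend))) if noise_cv > 0 else 1.0
        rates = np.where(present, mean * phase_factor * noise, 0.0)
        for name, cls, rate in zip(blend["name"], blend["compound_class"], rates):
            resp = float(
                response_from_rate(rate, cls, s["flowers_open"], s["duration_h"])
            )
            rows.append(
                {
                    "sample_id": f"S{i:03d}",
                    "plant_id": s["plant_id"],
                    "species": sp,
                    "population": s.get("population", "interpop"),
                    "phase": s["phase"],
                    "time_rel_sunset_h": s["time_rel_sunset_h"],
                    "flowers_open": s["flowers_open"],
                    "duration_h": s["duration_h"],
                    "compound": name,
                    "response": resp,
                    "abundance": resp,
                    "true_rate": rate,
                }
            )
        # contaminants appear in floral samples at (at most) control level
        for _, c in truth.contaminants.iterrows():
            cnoise = float(np.exp(rng.normal(0.0, noise_cv))) if noise_cv > 0 else 1.0
            rate = c["floral_mean"] * cnoise
            resp = float(
                response_from_rate(rate, c["compound_class"], s["flowers_open"], s["duration_h"])
            )
            rows.append(
                {
                    "sample_id": f"S{i:03d}",
                    "plant_id": s["plant_id"],
                    "species": sp,
                    "population": s.get("population", "interpop"),
                    "phase": s["phase"],
                    "time_rel_sunset_h": s["time_rel_sunset_h"],
                    "flowers_open": s["flowers_open"],
                    "duration_h": s["duration_h"],
                    "compound": c["name"],
                    "response": resp,
                    "abundance": resp,
                    "true_rate": rate,
                }
            )
    samples = pd.DataFrame(rows)

    crows = []
    for j in range(n_controls):
        for _, c in truth.contaminants.iterrows():
            cnoise = float(np.exp(rng.normal(0.0, noise_cv))) if noise_cv > 0 else 1.0
            rate = c["control_mean"] * cnoise
            resp = float(response_from_rate(rate, c["compound_class"], 1.0, 0.5))
            crows.append(
                {
                    "sample_id": f"C{j:03d}",
                    "flowers_open": 1,
                    "duration_h": 0.5,
                    "compound": c["name"],
                    "response": resp,
                    "abundance": resp,
                    "true_rate": rate,
                }
            )
    controls = pd.DataFrame(crows)
    fixtures = {
        "ladder": ladder,
        "standards": standards,
        "calibration": calibration,
        "compound_classes": compound_classes,
        "match_scores": match_scores,
        "truth": truth,
    }
    return samples, controls, fixtures


@dataclass
class IonTimeSeriesSet:
    """Simulated per-plant, per-ion multi-day traces with retained truth."""

    data: pd.DataFrame  #: time_h, plant_id, species, mz, signal_per_flower
    schedule: LightSchedule
    truth: pd.DataFrame  #: per plant x ion x day true pulse parameters
    step_min: float = 4.0

    def trace(self, plant_id: str, mz: float) -> pd.DataFrame:
        sub = self.data[(self.data["plant_id"] == plant_id) & (self.data["mz"] == mz)]
        return sub.rename(columns={"signal_per_flower": "signal"})[["time_h", "signal"]]


def simulate_ion_timeseries(
    truth: TruthRecord | None = None,
    schedule: LightSchedule | None = None,
    plants: dict[str, str] | None = None,
    step_min: float = 4.0,
    seed: int = 0,
    noise_cv: float = 0.05,
) -> IonTimeSeriesSet:
    """Simulate multi-day ion traces from the diel pulse model.

    Each ion's trace is baseline plus one pulse per day with the ion's
    ground-truth shape, peak offset keyed to the dark transition, optional
    per-day amplitude decay, multiplicative log-normal noise on the pulse
    and additive noise (truncated at zero) on the baseline.

    ``plants`` maps plant id -> species; default two kaalae, one hookeri.
    """
    truth = truth if truth is not None else default_truth()
    schedule = schedule if schedule is not None else LightSchedule()
    if schedule.n_days < 2:
        raise ValueError("need at least 2 days of recording")
    if noise_cv < 0:
        raise ValueError("noise scale must be nonnegative")
    step_h = step_min / 60.0
    if abs((schedule.cycle_h / step_h) - round(schedule.cycle_h / step_h)) > 1e-9:
        raise ValueError("step must divide the 24 h cycle")
    plants = plants or {"K1": "kaalae", "K2": "kaalae", "H1": "hookeri"}
    total_h = schedule.n_days * schedule.cycle_h
    t = np.arange(0.0, total_h, step_h)
    darks = schedule.dark_times_h(total_h)
    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    for plant_id, species in plants.items():
        for ion in truth.ions:
            signal = np.zeros_like(t)
            for day, dark_h in enumerate(darks):
                amp = ion.amplitude * ion.daily_decay**day
                signal += amp * pulse_shape(
                    t - dark_h, ion.t_peak, ion.s_r, ion.s_f, ion.k_r, ion.k_f
                )
                truth_rows.append(
                    {
                        "plant_id": plant_id,
                        "mz": ion.mz,
                        "day": day,
                        "timing_class": ion.timing_class,
                        "t_peak": ion.t_peak,
                        "t_peak_abs_h": dark_h + ion.t_peak,
                        "amplitude": amp,
                        "s_r": ion.s_r,
                        "s_f": ion.s_f,
                        "k_r": ion.k_r,
                        "k_f": ion.k_f,
                    }
                )
            if noise_cv > 0:
                signal = signal * np.exp(rng.normal(0.0, noise_cv, t.size))
                base_noise = rng.normal(0.0, noise_cv * ion.b_pre, t.size)
            else:
                base_noise = 0.0
            baseline = np.maximum(ion.b_pre + base_noise, 0.0)
            y = baseline + signal
            rows.append(
                pd.DataFrame(
                    {
                        "time_h": t,
                        "plant_id": plant_id,
                        "species": species,
                        "mz": ion.mz,
                        "signal_per_flower": y,
                    }
                )
            )
    data = pd.concat(rows, ignore_index=True)
    return IonTimeSeriesSet(
        data=data,
        schedule=schedule,
        truth=pd.DataFrame(truth_rows),
        step_min=step_min,
    )


def simulate_moth_visits(
    n: int,
    dates: list[dt.date],
    mean_offset: float = 1.1,
    sd: float = 0.4,
    bounds: tuple[float, float] = (0.2, 1.6),
    seed: int = 0,
    sunsets: dict[dt.date, dt.datetime] | None = None,
    site_id: str = "ekahanui",
) -> pd.DataFrame:
    """Simulate moth flower-visit times after sunset.

    Offsets are drawn from a normal(mean_offset, sd) truncated to
    ``bounds`` (hours after sunset) and assigned round-robin across
    ``dates``.  If per-date ``sunsets`` are given, absolute local clock
    times are derived; otherwise only offsets are returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd <= 0:
        raise ValueError("sd must be positive")
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("bounds must be ordered")
    if hi < mean_offset - 6 * sd or lo > mean_offset + 6 * sd:
        raise ValueError("truncation bounds exclude the mean by more than 6 SD")
    a, b = (lo - mean_offset) / sd, (hi - mean_offset) / sd
    rng = np.random.default_rng(seed)
    offsets = stats.truncnorm.rvs(a, b, loc=mean_offset, scale=sd, size=n, random_state=rng)
    assigned = [dates[i % len(dates)] for i in range(n)]
    out = pd.DataFrame({"date": assigned, "offset_h": offsets, "site_id": site_id})
    if sunsets is not None:
        out["time_local"] = [
            (sunsets[d] + dt.timedelta(hours=float(o))).time().replace(microsecond=0)
            for d, o in zip(out["date"], out["offset_h"])
        ]
    return out
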