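"""GC-MS quantification: calibration, emission rates, and compound filters.

Dynamic headspace samples are trapped on adsorbent, desorbed into a GC-MS,
and integrated into per-compound peak responses.  This module turns those
responses into per-flower emission rates and applies the study's filtering
rules:

- retention indices on an n-alkane ladder (van den Dool-Kratz),
- log-log calibration curves per authentic standard, with a compound-class
  to standard assignment map,
- standardization by open-flower count and sampling duration,
- inclusion filters (spectral match > 75%, maximum abundance > 120,000
  counts, present in more than one sample),
- contaminant removal against ambient controls (one-sided Welch t-tests,
  Benjamini-Hochberg FDR) plus an explicit wound-volatile exclusion list,
- blend composition (relative proportions, Shannon diversity) and the
  occurrence filter for reporting, and a Mann-Whitney comparison of totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CalibrationModel",
    "EmissionTable",
    "META_COLUMNS",
    "apply_inclusion_filters",
    "benjamini_hochberg",
    "blend_composition",
    "filter_contaminants",
    "fit_calibration",
    "mann_whitney",
    "occurrence_filter",
    "quantify_and_standardize",
    "retention_index",
]

#: Sample-metadata columns recognised in wide emission tables.
META_COLUMNS = (
    "sample_id",
    "plant_id",
    "species",
    "population",
    "phase",
    "time_rel_sunset_h",
    "flowers_open",
    "duration_h",
)


class EmissionTable:
    """Samples x compounds matrix of emission rates with sample metadata.

    Parameters
    ----------
    meta : pandas.DataFrame
        One row per sample; any subset of :data:`META_COLUMNS`.
    rates : pandas.DataFrame
        Emission rates (ng per flower per hour), same row order as ``meta``,
        one column per compound.  Values must be nonnegative.
    """

    def __init__(self, meta: pd.DataFrame, rates: pd.DataFrame):
        if len(meta) != len(rates):
            raise ValueError("meta and rates must have the same number of rows")
        if (rates.to_numpy(dtype=float) < 0).any():
            raise ValueError("emission rates must be nonnegative")
        if "flowers_open" in meta and (meta["flowers_open"] < 1).any():
            raise ValueError("flowers_open must be >= 1")
        if "duration_h" in meta and (meta["duration_h"] <= 0).any():
            raise ValueError("duration_h must be positive")
        self.meta = meta.reset_index(drop=True)
        self.rates = rates.reset_index(drop=True)

    @property
    def compounds(self) -> list[str]:
        return list(self.rates.columns)

    def __len__(self) -> int:
        return len(self.meta)

    def subset_compounds(self, names) -> "EmissionTable":
        return EmissionTable(self.meta, self.rates[list(names)])

    def to_long(self) -> pd.DataFrame:
        """Long-format view (one row per sample x compound)."""
        wide = pd.concat([self.meta, self.rates], axis=1)
        return wide.melt(
            id_vars=list(self.meta.columns),
            var_name="compound",
            value_name="emission_ng_per_flower_h",
        )

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "EmissionTable":
        meta_cols = [c for c in META_COLUMNS if c in long.columns]
        if "sample_id" not in meta_cols:
            raise ValueError("long table requires a sample_id column")
        rates = long.pivot_table(
            index="sample_id",
            columns="compound",
            values="emission_ng_per_flower_h",
            fill_value=0.0,
            sort=False,
        )
        meta = long[meta_cols].drop_duplicates("sample_id").set_index("sample_id")
        meta = meta.loc[rates.index].reset_index()
        return cls(meta, rates.reset_index(drop=True))


def retention_index(rt: float, ladder: pd.DataFrame) -> float:
    """Linear (van den Dool-Kratz) retention index of an analyte.

    ``ladder`` has columns ``carbon_number`` and ``rt_min`` with strictly
    increasing retention times.  For an analyte eluting between alkanes
    C_n and C_{n+1}: ``100 * (n + (rt - rt_n) / (rt_{n+1} - rt_n))``.
    """
    carbons = ladder["carbon_number"].to_numpy(dtype=float)
    rts = ladder["rt_min"].to_numpy(dtype=float)
    if np.any(np.diff(rts) <= 0):
        raise ValueError("alkane ladder retention times must be strictly increasing")
    if rt < rts[0] or rt > rts[-1]:
        raise ValueError(
            f"retention time {rt} min outside ladder range [{rts[0]}, {rts[-1]}]"
        )
    i = int(np.searchsorted(rts, rt, side="right")) - 1
    i = min(i, len(rts) - 2)
    frac = (rt - rts[i]) / (rts[i + 1] - rts[i])
    return 100.0 * (carbons[i] + frac * (carbons[i + 1] - carbons[i]))


@dataclass
class CalibrationModel:
    """Per-standard log10-log10 response curves with a class->standard map.

    ``curves`` maps standard name -> (slope, intercept) of the least-squares
    line log10(response) = intercept + slope * log10(mass_ng); ``class_map``
    maps compound class -> standard name.
    """

    curves: dict[str, tuple[float, float]]
    class_map: dict[str, str] = field(default_factory=dict)

    def predict_response(self, standard: str, mass_ng) -> np.ndarray:
        slope, intercept = self.curves[standard]
        mass_ng = np.asarray(mass_ng, dtype=float)
        return 10.0 ** (intercept + slope * np.log10(mass_ng))

    def mass_from_response(self, standard: str, response) -> np.ndarray:
        """Inverse prediction: mass (ng) for a positive response."""
        slope, intercept = self.curves[standard]
        response = np.asarray(response, dtype=float)
        out = np.zeros_like(response, dtype=float)
        pos = response > 0
        out[pos] = 10.0 ** ((np.log10(response[pos]) - intercept) / slope)
        return out

    def standard_for_class(self, compound_class: str) -> str:
        try:
            return self.class_map[compound_class]
        except KeyError:
            raise KeyError(
                f"no calibration standard assigned to compound class {compound_class!r}"
            ) from None


def fit_calibration(
    standards: pd.DataFrame, class_map: dict[str, str] | None = None
) -> CalibrationModel:
    """Fit per-standard calibration lines in log10-log10 space.

    ``standards`` has columns ``standard``, ``mass_ng``, ``response`` with
    at least three positive (mass, response) pairs per standard.
    """
    curves: dict[str, tuple[float, float]] = {}
    for name, grp in standards.groupby("standard", sort=False):
        mass = grp["mass_ng"].to_numpy(dtype=float)
        resp = grp["response"].to_numpy(dtype=float)
        if len(grp) < 3:
            raise ValueError(f"standard {name!r} has fewer than 3 calibration points")
        if (mass <= 0).any() or (resp <= 0).any():
            raise ValueError(f"standard {name!r} has non-positive mass or response")
        res = stats.linregress(np.log10(mass), np.log10(resp))
        if res.slope <= 0:
            raise ValueError(f"calibration slope for {name!r} is not positive")
        curves[name] = (float(res.slope), float(res.intercept))
    return CalibrationModel(curves, dict(class_map or {}))


def quantify_and_standardize(
    peak_areas: pd.DataFrame,
    calibration: CalibrationModel,
    compound_classes: dict[str, str],
    meta: pd.DataFrame,
) -> EmissionTable:
    """Convert peak responses to per-flower emission rates.

    Parameters
    ----------
    peak_areas : pandas.DataFrame
        Samples x compounds matrix of integrated responses (counts).
    calibration : CalibrationModel
        Fitted curves plus the class->standard assignment.
    compound_classes : dict
        Compound name -> compound class, for every column of ``peak_areas``.
    meta : pandas.DataFrame
        Sample metadata including ``flowers_open`` and ``duration_h``.

    Each compound's response is inverted through its class's standard curve
    to a trapped mass (ng); the emission rate is
    ``mass_ng / (duration_h * flowers_open)``.  Zero responses give rate 0.
    """
    missing = [c for c in peak_areas.columns if c not in compound_classes]
    if missing:
        raise KeyError(f"compounds with no class assignment: {missing}")
    flowers = meta["flowers_open"].to_numpy(dtype=float)
    duration = meta["duration_h"].to_numpy(dtype=float)
    rates = pd.DataFrame(index=peak_areas.index, columns=peak_areas.columns, dtype=float)
    for compound in peak_areas.columns:
        standard = calibration.standard_for_class(compound_classes[compound])
        mass = calibration.mass_from_response(standard, peak_areas[compound].to_numpy())
        rates[compound] = mass / (duration * flowers)
    return EmissionTable(meta, rates)


def apply_inclusion_filters(
    table: EmissionTable,
    abundances: pd.DataFrame,
    match_scores: dict[str, float],
    min_match: float = 0.75,
    min_max_abundance: float = 120_000.0,
    min_samples: int = 2,
) -> tuple[EmissionTable, list[dict]]:
    """Drop compounds failing the identification/abundance inclusion rules.

    A compound is retained only if its mass-spectral match score is strictly
    greater than ``min_match``, its maximum raw abundance across samples is
    strictly greater than ``min_max_abundance`` counts, and it occurs
    (abundance > 0) in strictly more than ``min_samples - 1`` samples.
    Returns the filtered table and a report listing each removal with the
    rule that failed.
    """
    report: list[dict] = []
    keep: list[str] = []
    for compound in table.compounds:
        reasons = []
        score = match_scores.get(compound)
        if score is not None and not score > min_match:
            reasons.append(f"match score {score:.2f} not > {min_match}")
        if compound in abundances:
            col = abundances[compound].to_numpy(dtype=float)
            if not col.max() > min_max_abundance:
                reasons.append(
                    f"max abundance {col.max():.0f} not > {min_max_abundance:.0f}"
                )
            if not (col > 0).sum() >= min_samples:
                reasons.append(f"occurs in fewer than {min_samples} samples")
        if reasons:
            report.append({"compound": compound, "rules": reasons})
        else:
            keep.append(compound)
    return table.subset_compounds(keep), report


def benjamini_hochberg(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns (reject flags, adjusted p-values) in the input order.
    """
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def filter_contaminants(
    floral: EmissionTable,
    controls: EmissionTable,
    alpha: float = 0.05,
    exclusions: list[str] | None = None,
) -> tuple[EmissionTable, list[dict]]:
    """Remove compounds not exceeding ambient-control levels, plus exclusions.

    Per compound a one-sided Welch t-test (floral > control) is computed;
    p-values are Benjamini-Hochberg adjusted across compounds and compounds
    with adjusted p >= ``alpha`` are removed as contaminants.  Compounds on
    ``exclusions`` (e.g. wound volatiles) are removed regardless.  A
    compound absent from the control table is treated as control level 0
    and noted in the report.
    """
    if len(controls) < 2:
        raise ValueError("need at least 2 control samples")
    exclusions = set(exclusions or [])
    report: list[dict] = []
    tested: list[str] = []
    pvals: list[float] = []
    for compound in floral.compounds:
        if compound in exclusions:
            report.append({"compound": compound, "rules": ["on exclusions list"]})
            continue
        x = floral.rates[compound].to_numpy(dtype=float)
        if compound in controls.rates:
            y = controls.rates[compound].to_numpy(dtype=float)
        else:
            y = np.zeros(len(controls))
            report.append(
                {"compound": compound, "rules": ["absent from controls; level 0 assumed"]}
            )
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            # degenerate: identical constants -> no evidence of exceedance
            p = 1.0 if x.mean() <= y.mean() else 0.0
        else:
            p = stats.ttest_ind(x, y, equal_var=False, alternative="greater").pvalue
        tested.append(compound)
        pvals.append(float(p))
    if tested:
        reject, p_adj = benjamini_hochberg(pvals, alpha=alpha)
    else:
        reject, p_adj = np.array([], bool), np.array([])
    keep = []
    for compound, rej, p in zip(tested, reject, p_adj):
        if rej:
            keep.append(compound)
        else:
            report.append(
                {
                    "compound": compound,
                    "rules": [f"adjusted p {p:.3g} >= {alpha} (not above controls)"],
                }
            )
    return floral.subset_compounds(keep), report


def blend_composition(
    table: EmissionTable, group: str = "species"
) -> tuple[pd.DataFrame, pd.Series]:
    """Relative blend proportions per group and Shannon diversity per sample.

    The proportion of compound *j* within a group is its mean emission rate
    divided by the summed mean rates of all included compounds.  Shannon
    ``H = -sum p ln p`` is computed per sample on that sample's own relative
    rates; all-zero samples yield NaN.
    """
    groups = table.meta[group] if group in table.meta else pd.Series(["all"] * len(table))
    props = {}
    for g, idx in table.rates.groupby(groups.values).groups.items():
        means = table.rates.loc[idx].mean(axis=0)
        total = means.sum()
        if total <= 0:
            raise ValueError(f"group {g!r} has no compound with positive mean")
        props[g] = means / total
    proportions = pd.DataFrame(props)
    totals = table.rates.sum(axis=1).to_numpy()
    shannon = np.full(len(table), np.nan)
    nz = totals > 0
    p = table.rates.to_numpy(dtype=float)[nz] / totals[nz, None]
    shannon[nz] = stats.entropy(p, axis=1)  # natural log
    return proportions, pd.Series(shannon, name="shannon_h")


def occurrence_filter(
    table: EmissionTable, threshold: float = 0.20, group: str = "species"
) -> list[str]:
    """Compounds present (rate > 0) in strictly more than ``threshold`` of
    the samples of at least one group."""
    groups = table.meta[group] if group in table.meta else pd.Series(["all"] * len(table))
    keep = []
    for compound in table.compounds:
        present = table.rates[compound].to_numpy(dtype=float) > 0
        frac = pd.Series(present).groupby(groups.values).mean()
        if (frac > threshold).any():
            keep.append(compound)
    return keep


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U comparison of two samples (two-sided).

    Uses the exact null distribution when both samples are free of ties and
    the arrangement count is manageable; otherwise the normal approximation
    with continuity and tie correction.  Returns (U of sample ``a``, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    from math import comb

    exact = not ties and comb(a.size + b.size, a.size) <= 100_000
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)
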