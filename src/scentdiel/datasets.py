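"""Bundled reference data.

The packaged blend table lists the 40 floral volatiles detected in more than
20% of evening samples of either *Schiedea kaalae* or *S. hookeri*, with
compound class, retention index, mass-spectral match score, per-species
occurrence proportion, and mean emission rates (ng per flower per hour).
It seeds the synthetic generator's default ground truth and serves as the
worked example for blend statistics.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

__all__ = ["load_blend_table"]


def load_blend_table() -> pd.DataFrame:
    """Load the two-species evening blend table.

    Returns
    -------
    pandas.DataFrame
        One row per compound with columns ``compound_class``, ``ri``,
        ``match_score``, ``cas``, ``name``, per-species occurrence
        proportions (``occ_kaalae``, ``occ_hookeri``), mean nonzero and
        overall mean emission rates, printed relative emission rates
        (percent), and an ``excluded`` flag marking wound volatiles left
        out of quantitative analyses.
    """
    ref = importlib.resources.files("scentdiel.data").joinpath("blend_table.csv")
    with importlib.resources.as_file(ref) as path:
        table = pd.read_csv(path)
    table["excluded"] = table["excluded"].astype(bool)
    return table
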