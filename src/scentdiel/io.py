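"""Schema-checked CSV readers/writers and configuration loading.

All tables are plain CSV (long format preferred), reports are JSON, and
timestamps are ISO-8601 with an explicit UTC offset — naive timestamps are
rejected so field (HAST) and chamber (PST) clocks cannot be silently mixed.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

__all__ = ["SCHEMAS", "read_table", "write_table", "read_config", "write_report"]

#: Required columns per table kind; extra columns are preserved.
SCHEMAS: dict[str, tuple[str, ...]] = {
    "samples": (
        "sample_id", "plant_id", "species", "phase",
        "time_rel_sunset_h", "flowers_open", "compound", "response",
    ),
    "controls": ("sample_id", "compound", "response"),
    "ladder": ("carbon_number", "rt_min"),
    "standards": ("standard", "compound_class", "mass_ng", "response"),
    "ions": ("time_h", "plant_id", "species", "mz", "signal_per_flower"),
    "visits": ("date", "time_local", "site_id"),
    "cardinal_times": ("plant_id", "mz", "day", "t_start", "t_max", "t_end"),
}

_TIMESTAMP_COLUMNS = ("timestamp_iso",)


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a CSV and validate it against a named schema.

    Raises ``ValueError`` naming any missing required column; timestamp
    columns must parse as ISO-8601 with an explicit offset.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    table = pd.read_csv(path)
    missing = [c for c in SCHEMAS[schema] if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing} for {schema!r}")
    for col in _TIMESTAMP_COLUMNS:
        if col in table.columns:
            parsed = pd.to_datetime(table[col], errors="coerce", utc=True, format="ISO8601")
            bad = parsed.isna() & table[col].notna()
            if bad.any():
                raise ValueError(
                    f"{path}: malformed timestamp at row(s) {list(table.index[bad][:5])}"
                )
            raw = table[col].astype(str)
            naive = ~(raw.str.contains(r"[+-]\d{2}:?\d{2}$") | raw.str.endswith("Z"))
            if naive.any():
                raise ValueError(
                    f"{path}: naive timestamp (no UTC offset) at row(s) "
                    f"{list(table.index[naive][:5])}"
                )
            table[col] = parsed
    if schema == "visits":
        table["date"] = pd.to_datetime(table["date"]).dt.date
        table["time_local"] = pd.to_datetime(
            table["time_local"], format="%H:%M:%S"
        ).dt.time
    return table


def write_table(table: pd.DataFrame, path, float_format: str = "%.10g") -> Path:
    """Write a CSV with canonical float formatting (stable across reruns)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format=float_format)
    return path


def read_config(path) -> dict:
    """Load a YAML/JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def write_report(report: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, default=str) + "\n")
    return path
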