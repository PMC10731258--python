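"""CSV interchange for droplet event tables, plaque counts and plate maps.

All tables move as plain CSV with documented headers.  The event-table
dialect matches what droplet cytometer exports look like after conversion:

    sample_id, condition, timepoint_h, fsc, fluorescence

with an optional leading ``droplet_id`` column when the table came from the
simulator (it carries the latent-truth join key).  Validation is strict and
row-aware: a missing column raises a :class:`SchemaError` naming it, and
malformed numeric cells raise with their 1-based file line numbers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "EVENT_COLUMNS",
    "CONDITIONS",
    "read_event_table",
    "write_event_table",
    "read_plaque_table",
    "read_plate_table",
    "load_yaml",
]

EVENT_COLUMNS = ("sample_id", "condition", "timepoint_h", "fsc", "fluorescence")
NUMERIC_EVENT_COLUMNS = ("timepoint_h", "fsc", "fluorescence")
CONDITIONS = ("phage", "no_phage")


class SchemaError(ValueError):
    """A table does not match its documented CSV schema."""


def _lines(index: pd.Index) -> list:
    # +2: one for the header line, one for 0- vs 1-based indexing
    return [int(i) + 2 for i in index[:10]]


def read_event_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate an event table CSV.

    Raises :class:`SchemaError` when a required column is absent, and
    ``ValueError`` (with file line numbers) for rows whose numeric fields
    do not parse, are missing, or carry a nonpositive/nonfinite forward
    scatter.  Valid input round-trips losslessly through
    :func:`write_event_table`.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) {missing}; "
            f"expected {list(EVENT_COLUMNS)}"
        )
    for col in NUMERIC_EVENT_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        if len(bad):
            raise ValueError(
                f"{path.name}: column {col!r} is not numeric at line(s) "
                f"{_lines(bad)}"
            )
        df[col] = coerced.astype(float)
    bad_fsc = df.index[~np.isfinite(df["fsc"]) | (df["fsc"] <= 0)]
    if len(bad_fsc):
        raise ValueError(
            f"{path.name}: forward scatter must be finite and positive; "
            f"offending line(s) {_lines(bad_fsc)}"
        )
    bad_cond = df.index[~df["condition"].isin(CONDITIONS)]
    if len(bad_cond):
        raise ValueError(
            f"{path.name}: condition must be one of {CONDITIONS}; "
            f"offending line(s) {_lines(bad_cond)}"
        )
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def write_event_table(events: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write an event table CSV (documented column order, no index)."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise SchemaError(f"event table to write is missing column(s) {missing}")
    lead = [c for c in ("droplet_id",) if c in events.columns]
    events[lead + list(EVENT_COLUMNS)].to_csv(path, index=False)


def read_plaque_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a plaque-count CSV: timepoint_h, dilution_factor,
    plated_volume_mL, count_rep1..repN (one selected dilution per row)."""
    path = Path(path)
    df = pd.read_csv(path)
    required = ("timepoint_h", "dilution_factor", "plated_volume_mL")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    if not any(c.startswith("count_rep") for c in df.columns):
        raise SchemaError(f"{path.name}: needs at least one count_rep<N> column")
    return df


def read_plate_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a 96-well digitization CSV: plate_id, well, gate_label, outcome."""
    path = Path(path)
    df = pd.read_csv(path)
    required = ("plate_id", "well", "gate_label", "outcome")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    # make well ids globally unique across plates pooled under one gate
    df = df.copy()
    df["well"] = df["plate_id"].astype(str) + ":" + df["well"].astype(str)
    return df


def load_yaml(path: Union[str, Path]) -> dict:
    """Load a structured config file (YAML mapping)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{Path(path).name}: config must be a mapping")
    return data
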