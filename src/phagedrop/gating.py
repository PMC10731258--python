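"""Event-level gating of droplet cytometry tables.

Two gates, applied in a fixed, documented order:

1. **Size filter** — within each (sample, timepoint) group, events whose
   forward-scatter intensity deviates from the group mean by *more than*
   ``fsc_sd_multiplier`` sample standard deviations are removed.  Grouping
   per timepoint absorbs drift in the FSC mean across a time course.
2. **Fluorescence threshold** — an event is *fluorescent* iff its
   fluorescence is *strictly greater* than the threshold.  The threshold is
   either fixed (the assay's canonical 130 a.u. cutoff) or derived from a
   no-phage control as the smallest observed intensity that leaves at most
   ``fp_rate`` (default 0.5%) of control events strictly above it.

Ties therefore survive the size filter and count as non-fluorescent at the
threshold.  The per-timepoint fluorescent fractions produced by
:func:`classify_and_summarize` are the raw material for time-course plots
and for negative-fraction λ estimation (:mod:`phagedrop.poisson`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "GatePolicy",
    "GateSummary",
    "size_filter",
    "derive_threshold",
    "classify_and_summarize",
]

_GROUP_KEYS = ["sample_id", "timepoint_h"]


@dataclass(frozen=True)
class GatePolicy:
    """Filtering and classification rules for one gating pass."""

    fsc_sd_multiplier: float = 1.0
    threshold_mode: str = "fixed"  # "fixed" | "from_negative_control"
    fixed_threshold: Optional[float] = 130.0
    fp_rate: float = 0.005
    apply_size_filter: bool = True

    def __post_init__(self) -> None:
        if not self.fsc_sd_multiplier > 0:
            raise ValueError("fsc_sd_multiplier must be positive")
        if self.threshold_mode not in ("fixed", "from_negative_control"):
            raise ValueError(
                "threshold_mode must be 'fixed' or 'from_negative_control', "
                f"got {self.threshold_mode!r}"
            )
        if not 0 < self.fp_rate < 1:
            raise ValueError("fp_rate must be in (0, 1)")


@dataclass(frozen=True)
class GateSummary:
    """Per-(sample, timepoint) outcome counts of one gating pass."""

    sample_id: str
    timepoint_h: float
    n_input: int
    n_after_size_filter: int
    n_fluorescent: int
    fluorescent_fraction: float
    threshold_used: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_fluorescent <= self.n_after_size_filter <= self.n_input:
            raise ValueError("gate counts must be nested: fluorescent <= filtered <= input")
        if not 0.0 <= self.fluorescent_fraction <= 1.0:
            raise ValueError("fluorescent_fraction must be in [0, 1]")


def _require_columns(events: pd.DataFrame, cols: Iterable[str]) -> None:
    missing = [c for c in cols if c not in events.columns]
    if missing:
        raise ValueError(f"event table is missing required column(s): {missing}")


def size_filter(events: pd.DataFrame, policy: GatePolicy) -> pd.DataFrame:
    """Remove abnormally sized droplets by forward scatter, per group.

    Within each (sample_id, timepoint_h) group, keeps rows with
    ``|fsc - mean| <= multiplier * SD`` (sample SD, ddof=1); only strictly
    larger deviations are removed, so a zero-SD group is fully retained.
    Row order is preserved.  A group with a single event has no defined SD
    and raises.
    """
    _require_columns(events, _GROUP_KEYS + ["fsc"])
    if events.empty:
        raise ValueError("cannot size-filter an empty event table")
    grouped = events.groupby(_GROUP_KEYS, sort=False)["fsc"]
    sizes = grouped.transform("size")
    if (sizes < 2).any():
        bad = (
            events.loc[sizes < 2, _GROUP_KEYS]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        raise ValueError(
            "size filter needs >= 2 events per (sample, timepoint) to define "
            f"an SD; offending group(s): {list(bad)}"
        )
    mean = grouped.transform("mean")
    sd = grouped.transform("std")  # ddof=1
    keep = (events["fsc"] - mean).abs() <= policy.fsc_sd_multiplier * sd
    return events.loc[keep]


def derive_threshold(
    negative_events: Union[pd.DataFrame, np.ndarray, Iterable[float]],
    fp_rate: float = 0.005,
) -> float:
    """Fluorescence cutoff from a no-phage control.

    Returns the smallest observed intensity ``T`` such that the fraction of
    control events *strictly above* ``T`` is at most ``fp_rate`` — i.e. the
    ``ceil(n·(1-fp_rate))``-th order statistic, with no interpolation, so
    the result is exact on small fixtures.
    """
    if isinstance(negative_events, pd.DataFrame):
        _require_columns(negative_events, ["fluorescence"])
        values = negative_events["fluorescence"].to_numpy(dtype=float)
    else:
        values = np.asarray(list(negative_events) if not isinstance(
            negative_events, np.ndarray) else negative_events, dtype=float)
    if values.size == 0:
        raise ValueError("cannot derive a threshold from an empty control")
    if not 0 < fp_rate < 1:
        raise ValueError("fp_rate must be in (0, 1)")
    ordered = np.sort(values)
    rank = max(math.ceil(values.size * (1.0 - fp_rate)), 1)  # 1-indexed
    return float(ordered[rank - 1])


def classify_and_summarize(
    events: pd.DataFrame,
    policy: GatePolicy,
    control_events: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Gate an event table and tabulate fluorescent fractions per group.

    Applies the size filter first (unless ``policy.apply_size_filter`` is
    False because the caller already filtered), resolves the threshold
    (fixed, or derived from ``control_events`` which are size-filtered the
    same way), and counts events strictly above it per
    (sample_id, timepoint_h).

    Returns a DataFrame with one row per group and the
    :class:`GateSummary` columns, sorted by sample then timepoint.
    """
    _require_columns(events, _GROUP_KEYS + ["fsc", "fluorescence"])
    if events.empty:
        raise ValueError("cannot summarize an empty event table")

    if policy.threshold_mode == "fixed":
        if policy.fixed_threshold is None:
            raise ValueError("threshold_mode='fixed' requires fixed_threshold")
        threshold = float(policy.fixed_threshold)
    else:
        if control_events is None:
            raise ValueError(
                "threshold_mode='from_negative_control' requires control_events"
            )
        control = (
            size_filter(control_events, policy)
            if policy.apply_size_filter
            else control_events
        )
        threshold = derive_threshold(control, policy.fp_rate)

    n_input = (
        events.groupby(_GROUP_KEYS, sort=False).size().rename("n_input")
    )
    filtered = size_filter(events, policy) if policy.apply_size_filter else events
    grouped = filtered.groupby(_GROUP_KEYS, sort=False)
    n_after = grouped.size().rename("n_after_size_filter")
    n_fluor = (
        filtered.assign(_fluor=filtered["fluorescence"] > threshold)
        .groupby(_GROUP_KEYS, sort=False)["_fluor"]
        .sum()
        .rename("n_fluorescent")
    )
    summary = (
        pd.concat([n_input, n_after, n_fluor], axis=1)
        .fillna(0)
        .astype({"n_after_size_filter": int, "n_fluorescent": int})
        .reset_index()
    )
    summary["fluorescent_fraction"] = np.where(
        summary["n_after_size_filter"] > 0,
        summary["n_fluorescent"] / summary["n_after_size_filter"],
        0.0,
    )
    summary["threshold_used"] = threshold
    summary = summary.sort_values(_GROUP_KEYS, kind="stable").reset_index(drop=True)
    # validate invariants row-wise through the dataclass
    for row in summary.itertuples(index=False):
        GateSummary(
            sample_id=row.sample_id,
            timepoint_h=float(row.timepoint_h),
            n_input=int(row.n_input),
            n_after_size_filter=int(row.n_after_size_filter),
            n_fluorescent=int(row.n_fluorescent),
            fluorescent_fraction=float(row.fluorescent_fraction),
            threshold_used=float(row.threshold_used),
        )
    return summary
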