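"""Plaque-assay arithmetic and titer time courses.

A plaque assay counts clearings (PFU) formed by serial dilutions of a
ruptured droplet emulsion on a host lawn.  The titer of the ruptured
sample is ``mean(replicate counts) × dilution_factor / plated_volume``.
Because only a fixed emulsion aliquot (typically 8 μL of droplets) is
ruptured per timepoint and its aqueous fraction is not exactly known, the
per-aliquot PFU is reported as "PFU per aliquot of emulsion" with any
rupture/recovery dilution left as an explicit user input rather than
silently assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountableRangeWarning",
    "BelowDetectionWarning",
    "TiterMeasurement",
    "titer_from_plaques",
    "aliquot_pfu",
    "fold_change",
    "titer_time_course",
]

#: conventional countable-plaque window per plate
COUNTABLE_RANGE = (3, 300)


class CountableRangeWarning(UserWarning):
    """A replicate plaque count falls outside the reliable 3–300 window."""


class BelowDetectionWarning(UserWarning):
    """No plaques on any replicate: the titer is below the detection limit."""


@dataclass(frozen=True)
class TiterMeasurement:
    """One timepoint's plaque-assay result and its derived quantities."""

    timepoint_h: float
    plaque_counts: Sequence[int]
    dilution_factor: float
    plated_volume_mL: float
    titer_pfu_per_mL: float
    pfu_estimate: Optional[float] = None
    aliquot_label: str = ""

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.plaque_counts):
            raise ValueError("plaque counts must be nonnegative")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.pfu_estimate is not None and self.pfu_estimate < 0:
            raise ValueError("pfu_estimate must be nonnegative")


def titer_from_plaques(
    counts: Sequence[int],
    dilution_factor: float,
    plated_volume_mL: float,
) -> float:
    """Titer (PFU/mL of ruptured sample) from replicate plaque counts.

    ``mean(counts) × dilution_factor / plated_volume_mL``.  Counts outside
    the countable window (3–300 per plate) trigger a warning but are never
    dropped; all-zero counts warn that the sample is below detection.
    """
    counts = list(counts)
    if len(counts) == 0:
        raise ValueError("at least one replicate plaque count is required")
    if not plated_volume_mL > 0:
        raise ValueError("plated_volume_mL must be positive")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    arr = np.asarray(counts, dtype=float)
    if np.any(arr < 0) or np.any(arr != np.round(arr)):
        raise ValueError("plaque counts must be nonnegative integers")
    lo, hi = COUNTABLE_RANGE
    outside = arr[(arr < lo) | (arr > hi)]
    if outside.size and arr.sum() > 0:
        warnings.warn(
            f"replicate count(s) {sorted(int(c) for c in outside)} outside the "
            f"countable range {lo}-{hi}; titer may be unreliable",
            CountableRangeWarning,
            stacklevel=2,
        )
    if arr.sum() == 0:
        warnings.warn(
            "no plaques on any replicate: titer is below the detection limit "
            f"({dilution_factor / plated_volume_mL:.3g} PFU/mL per plaque)",
            BelowDetectionWarning,
            stacklevel=2,
        )
    return float(arr.mean() * dilution_factor / plated_volume_mL)


def aliquot_pfu(
    titer_per_mL: float,
    aliquot_volume_uL: float,
    recovery_dilution: float = 1.0,
) -> float:
    """Total PFU contained in an emulsion aliquot.

    ``titer × (aliquot μL / 1000) × recovery_dilution`` — the recovery
    dilution is the fold by which rupturing diluted the aqueous phase
    before plating (explicit because it is assay-specific).
    """
    if titer_per_mL < 0:
        raise ValueError("titer must be nonnegative")
    if not aliquot_volume_uL > 0 or not recovery_dilution > 0:
        raise ValueError("aliquot volume and recovery dilution must be positive")
    return titer_per_mL * (aliquot_volume_uL / 1000.0) * recovery_dilution


def fold_change(pfu_t0: float, pfu_t1: float) -> float:
    """Ratio of a later PFU value to a baseline (e.g. the first-hour rise)."""
    if not pfu_t0 > 0:
        raise ValueError("baseline PFU must be strictly positive")
    return pfu_t1 / pfu_t0


def titer_time_course(
    plaques: pd.DataFrame,
    aliquot_volume_uL: float = 8.0,
    recovery_dilution: float = 1.0,
) -> pd.DataFrame:
    """Per-timepoint titers and aliquot PFU from a plaque-count table.

    ``plaques`` columns: ``timepoint_h``, ``dilution_factor``,
    ``plated_volume_mL`` and one or more replicate columns named
    ``count_rep1``, ``count_rep2``, ...  One row per timepoint (the
    dilution already selected for counting).  Output adds
    ``titer_pfu_per_mL``, ``pfu_per_aliquot`` and ``fold_change_vs_first``
    (NaN when the first timepoint has zero PFU).
    """
    required = ["timepoint_h", "dilution_factor", "plated_volume_mL"]
    missing = [c for c in required if c not in plaques.columns]
    if missing:
        raise ValueError(f"plaque table is missing column(s): {missing}")
    rep_cols = [c for c in plaques.columns if c.startswith("count_rep")]
    if not rep_cols:
        raise ValueError("plaque table needs at least one count_rep<N> column")

    rows = []
    for rec in plaques.sort_values("timepoint_h").itertuples(index=False):
        counts = [
            int(getattr(rec, c))
            for c in rep_cols
            if not pd.isna(getattr(rec, c))
        ]
        titer = titer_from_plaques(
            counts, float(rec.dilution_factor), float(rec.plated_volume_mL)
        )
        pfu = aliquot_pfu(titer, aliquot_volume_uL, recovery_dilution)
        rows.append(
            {
                "timepoint_h": float(rec.timepoint_h),
                "n_replicates": len(counts),
                "mean_count": float(np.mean(counts)),
                "dilution_factor": float(rec.dilution_factor),
                "plated_volume_mL": float(rec.plated_volume_mL),
                "titer_pfu_per_mL": titer,
                "pfu_per_aliquot": pfu,
                "aliquot_label": f"per {aliquot_volume_uL:g} uL emulsion",
            }
        )
    out = pd.DataFrame(rows)
    base = out["pfu_per_aliquot"].iloc[0]
    out["fold_change_vs_first"] = (
        out["pfu_per_aliquot"] / base if base > 0 else np.nan
    )
    return out
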