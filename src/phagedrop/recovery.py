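"""Recovery statistics for single-droplet isolation into 96-well plates.

After sorting, each isolated droplet is ruptured in its own well,
re-inoculated with host cells, and scored by spot assay as phage-positive
or phage-negative — a *digitization* of droplet content.  This module
turns those binary well outcomes into recovery rates with binomial
confidence intervals, and compares the high-fluorescence gate against the
low-fluorescence control gate (rate difference with a Newcombe score
interval and a Fisher exact test, chosen because the control gate often
has a zero cell).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "PlateDigitization",
    "GateComparison",
    "digitize_plate",
    "recovery_ci",
    "compare_gates",
]

VALID_OUTCOMES = ("positive", "negative", "excluded")


@dataclass(frozen=True)
class PlateDigitization:
    """Pooled binary well outcomes for one fluorescence gate."""

    gate_label: str
    n_positive: int
    n_total: int
    recovery_rate: float
    ci_low: float
    ci_high: float
    wells: Tuple[Tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.n_positive <= self.n_total:
            raise ValueError("need 0 <= n_positive <= n_total")
        if not 0.0 <= self.recovery_rate <= 1.0:
            raise ValueError("recovery_rate must be in [0, 1]")


@dataclass(frozen=True)
class GateComparison:
    """High-vs-low gate contrast: rate difference, interval, exact test."""

    rate_difference: float
    ci_low: float
    ci_high: float
    fisher_p: float
    high: PlateDigitization
    low: PlateDigitization


def _normalize_wells(
    well_outcomes: Union[Mapping[str, str], Sequence[str], pd.DataFrame],
    gate_label: str,
) -> Tuple[Tuple[str, str], ...]:
    if isinstance(well_outcomes, pd.DataFrame):
        missing = [c for c in ("well", "outcome") if c not in well_outcomes.columns]
        if missing:
            raise ValueError(f"plate table is missing column(s): {missing}")
        items = list(
            zip(well_outcomes["well"].astype(str), well_outcomes["outcome"].astype(str))
        )
    elif isinstance(well_outcomes, Mapping):
        items = [(str(k), str(v)) for k, v in well_outcomes.items()]
    else:
        items = [
            (f"{gate_label}:{i}", str(v)) for i, v in enumerate(well_outcomes)
        ]
    for well, outcome in items:
        if outcome not in VALID_OUTCOMES:
            raise ValueError(
                f"unknown outcome {outcome!r} for well {well!r}; "
                f"expected one of {VALID_OUTCOMES}"
            )
    return tuple(items)


def recovery_ci(
    n_positive: int, n_total: int, method: str = "wilson"
) -> Tuple[float, float]:
    """95% binomial interval for a recovery rate.

    Wilson score by default (``method="clopper-pearson"`` for the exact
    interval).  Boundary counts behave sensibly: 0 positives give a lower
    bound of exactly 0, all-positive gives an upper bound of exactly 1.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_positive <= n_total:
        raise ValueError("need 0 <= n_positive <= n_total")
    methods = {"wilson": "wilson", "clopper-pearson": "beta"}
    if method not in methods:
        raise ValueError(f"method must be one of {sorted(methods)}")
    low, high = proportion_confint(
        n_positive, n_total, alpha=0.05, method=methods[method]
    )
    # the Wilson closed form can overshoot [0, 1] by an ulp at the boundaries
    return float(min(max(low, 0.0), 1.0)), float(min(max(high, 0.0), 1.0))


def digitize_plate(
    well_outcomes: Union[Mapping[str, str], Sequence[str], pd.DataFrame],
    gate_label: str,
) -> PlateDigitization:
    """Pool binary well outcomes into a recovery rate for one gate.

    Accepts a well→outcome mapping, a plain sequence of outcome codes, or
    a DataFrame with ``well``/``outcome`` columns (rows from multiple
    plates under one gate label are simply concatenated).  Outcomes must
    be ``positive``, ``negative`` or ``excluded``; excluded wells are
    dropped from the denominator, and a plate with no scorable wells is an
    error.
    """
    wells = _normalize_wells(well_outcomes, gate_label)
    n_positive = sum(1 for _, o in wells if o == "positive")
    n_negative = sum(1 for _, o in wells if o == "negative")
    n_total = n_positive + n_negative
    if n_total == 0:
        raise ValueError(
            f"gate {gate_label!r}: every well is excluded, no denominator"
        )
    low, high = recovery_ci(n_positive, n_total)
    return PlateDigitization(
        gate_label=gate_label,
        n_positive=n_positive,
        n_total=n_total,
        recovery_rate=n_positive / n_total,
        ci_low=low,
        ci_high=high,
        wells=wells,
    )


def _newcombe_interval(
    k1: int, n1: int, k2: int, n2: int
) -> Tuple[float, float]:
    """Newcombe score interval for p1 - p2 (hybrid of two Wilson intervals)."""
    p1, p2 = k1 / n1, k2 / n2
    l1, u1 = recovery_ci(k1, n1)
    l2, u2 = recovery_ci(k2, n2)
    d = p1 - p2
    lower = d - math.sqrt((p1 - l1) ** 2 + (u2 - p2) ** 2)
    upper = d + math.sqrt((u1 - p1) ** 2 + (p2 - l2) ** 2)
    return lower, upper


def compare_gates(
    high: PlateDigitization, low: PlateDigitization
) -> GateComparison:
    """Contrast the high- and low-fluorescence gates.

    Reports the recovery-rate difference with a 95% Newcombe score
    interval and a two-sided Fisher exact p-value on the 2×2 table.  The
    two digitizations must come from disjoint wells.
    """
    high_ids = {w for w, _ in high.wells}
    low_ids = {w for w, _ in low.wells}
    overlap = high_ids & low_ids
    if overlap:
        raise ValueError(
            f"gates share well id(s) {sorted(overlap)[:5]}; comparisons "
            "require disjoint wells"
        )
    table = np.array(
        [
            [high.n_positive, high.n_total - high.n_positive],
            [low.n_positive, low.n_total - low.n_positive],
        ]
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    lower, upper = _newcombe_interval(
        high.n_positive, high.n_total, low.n_positive, low.n_total
    )
    return GateComparison(
        rate_difference=high.recovery_rate - low.recovery_rate,
        ci_low=lower,
        ci_high=upper,
        fisher_p=float(p),
        high=high,
        low=low,
    )
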