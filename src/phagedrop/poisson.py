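"""Poisson occupancy statistics for droplet digital assays.

When a phage suspension is partitioned into monodisperse water-in-oil
droplets, the number of particles per droplet is Poisson distributed with
mean ``lambda`` (written λ_phg for phage).  Everything quantitative about a
droplet experiment flows from that fact:

* the fraction of droplets expected to hold exactly ``k`` particles is the
  Poisson pmf;
* the purity of single-particle encapsulation is the conditional
  probability ``P(K = 1 | K >= 1)``;
* λ_phg can be estimated either *forward* from the titer of the suspension
  and the droplet volume, or *backward* from the observed fraction of
  negative (non-fluorescent) droplets via ``p0 = exp(-λ)``.

Both estimator routes are provided here, with binomial confidence
intervals on the negative fraction propagated through the log transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "DropletGeometry",
    "OccupancyEstimate",
    "occupancy_pmf",
    "prob_single_given_occupied",
    "lambda_from_negative_fraction",
    "lambda_from_concentration",
    "volume_from_diameter",
    "diameter_from_volume",
]

#: microlitre-scale conversion: 1 pL expressed in mL
_PL_PER_ML = 1e9


def volume_from_diameter(diameter_um: float) -> float:
    """Volume of a spherical droplet, in picolitres, from its diameter in μm.

    ``V = (π/6) d³``; 1000 μm³ = 1 pL.  A 30 μm droplet holds ≈14.1 pL,
    a 33 μm droplet ≈18.9 pL.
    """
    if not diameter_um > 0:
        raise ValueError(f"diameter must be positive, got {diameter_um}")
    return (math.pi / 6.0) * diameter_um**3 / 1000.0


def diameter_from_volume(volume_pL: float) -> float:
    """Inverse of :func:`volume_from_diameter` (μm from pL)."""
    if not volume_pL > 0:
        raise ValueError(f"volume must be positive, got {volume_pL}")
    return (6.0 * volume_pL * 1000.0 / math.pi) ** (1.0 / 3.0)


@dataclass(frozen=True)
class DropletGeometry:
    """Droplet size conventions used to convert titers to occupancies.

    Either field may be given alone; the other is filled in from the sphere
    formula.  Both may also be given explicitly and *inconsistently*: droplet
    assays commonly pair a nominal generator diameter with an independently
    measured mean volume, and neither silently overrides the other.
    """

    diameter_um: Optional[float] = None
    volume_pL: Optional[float] = None

    def __post_init__(self) -> None:
        if self.diameter_um is None and self.volume_pL is None:
            raise ValueError("supply diameter_um and/or volume_pL")
        if self.volume_pL is None:
            object.__setattr__(self, "volume_pL", volume_from_diameter(self.diameter_um))
        if self.diameter_um is None:
            object.__setattr__(self, "diameter_um", diameter_from_volume(self.volume_pL))
        if not self.volume_pL > 0 or not self.diameter_um > 0:
            raise ValueError("droplet geometry must be strictly positive")


@dataclass(frozen=True)
class OccupancyEstimate:
    """An estimate of λ_phg (mean phage particles per droplet) with provenance.

    ``method`` records which route produced it: ``"from_negative_fraction"``
    (digital counting on the non-fluorescent fraction) or
    ``"from_concentration"`` (titer × droplet volume).  Confidence bounds are
    95% unless noted; they are ``None`` when no uncertainty input exists
    (a bare titer with no standard error).
    """

    lambda_hat: float
    method: str
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    p0_hat: Optional[float] = None
    n_droplets: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lambda_hat < 0:
            raise ValueError("lambda_hat must be nonnegative")
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.lambda_hat <= self.ci_high):
                raise ValueError(
                    f"CI [{self.ci_low}, {self.ci_high}] does not bracket "
                    f"lambda_hat={self.lambda_hat}"
                )

    @property
    def implied_concentration_pfu_per_ml(self) -> Optional[float]:
        """λ̂ / V as PFU/mL, available once a geometry is attached."""
        return None  # filled by pipeline-level helpers that know the geometry


def occupancy_pmf(lam: float, k: int) -> float:
    """P(K = k) for K ~ Poisson(lam): the expected fraction of droplets
    holding exactly ``k`` particles.

    ``occupancy_pmf(0.08, 0)`` ≈ 0.923 — at a mean occupancy of 0.08,
    92.3% of droplets are expected to be empty.
    """
    if lam < 0:
        raise ValueError(f"lambda must be nonnegative, got {lam}")
    if k < 0 or int(k) != k:
        raise ValueError(f"k must be a nonnegative integer, got {k}")
    return float(stats.poisson.pmf(int(k), lam))


def prob_single_given_occupied(lam: float) -> float:
    """P(K = 1 | K >= 1) for K ~ Poisson(lam): single-encapsulation purity.

    Equals ``λ e^{-λ} / (1 - e^{-λ})``.  For λ = 0.08 this is ≈0.96: 96% of
    occupied droplets hold exactly one particle.  The limit as λ → 0⁺ is 1
    but λ = 0 itself is rejected (no droplet is occupied).
    """
    if lam <= 0:
        raise ValueError(
            f"lambda must be strictly positive (limit as lambda->0 is 1), got {lam}"
        )
    # -expm1(-lam) = 1 - exp(-lam), accurate for small lam
    return lam * math.exp(-lam) / (-math.expm1(-lam))


def lambda_from_negative_fraction(
    p0_hat: float,
    n_droplets: int,
    ci_method: str = "wilson",
) -> OccupancyEstimate:
    """Estimate λ_phg from the observed fraction of negative droplets.

    Digital-assay inversion: if a droplet is negative exactly when it
    received no particle, the negative fraction estimates ``e^{-λ}`` and so
    ``λ̂ = -ln(p0_hat)``.  The 95% CI is a binomial interval on p0
    (Wilson score by default, Clopper–Pearson exact via
    ``ci_method="clopper-pearson"``) mapped through ``-ln``.

    Parameters
    ----------
    p0_hat
        Observed negative fraction, in (0, 1].  A value of 0 means every
        droplet was occupied and λ is unidentifiable.
    n_droplets
        Number of droplets behind ``p0_hat``; sets the CI width.
    """
    if not 0 < p0_hat <= 1:
        if p0_hat == 0:
            raise ValueError(
                "p0_hat = 0: every droplet is occupied, lambda is unbounded; "
                "dilute the sample and repeat"
            )
        raise ValueError(f"p0_hat must be in (0, 1], got {p0_hat}")
    if n_droplets < 1:
        raise ValueError(f"n_droplets must be >= 1, got {n_droplets}")

    methods = {"wilson": "wilson", "clopper-pearson": "beta"}
    if ci_method not in methods:
        raise ValueError(f"ci_method must be one of {sorted(methods)}")

    lam = -math.log(p0_hat)
    count = int(round(p0_hat * n_droplets))
    count = min(max(count, 0), n_droplets)
    p_low, p_high = proportion_confint(
        count, n_droplets, alpha=0.05, method=methods[ci_method]
    )
    # -ln is decreasing: the upper p0 bound gives the lower lambda bound
    ci_low = -math.log(p_high) if p_high > 0 else math.inf
    ci_high = -math.log(p_low) if p_low > 0 else math.inf
    # rounding p0*n to an integer count can nudge the interval by O(1/n);
    # never let that break the bracketing invariant
    ci_low = min(ci_low, lam)
    ci_high = max(ci_high, lam)
    return OccupancyEstimate(
        lambda_hat=lam,
        method="from_negative_fraction",
        ci_low=ci_low,
        ci_high=ci_high,
        p0_hat=p0_hat,
        n_droplets=n_droplets,
    )


def lambda_from_concentration(
    conc_pfu_per_ml: float,
    geometry: DropletGeometry,
    titer_se_pfu_per_ml: Optional[float] = None,
) -> OccupancyEstimate:
    """Estimate λ_phg forward from a suspension titer and droplet volume.

    ``λ̂ = c × V`` with the titer ``c`` in PFU/mL and the droplet volume
    ``V`` in mL (1 pL = 1e-9 mL).  E.g. 5.32e7 PFU/mL in 18.8 pL droplets
    gives λ̂ = 1.0.  A normal-approximation 95% CI is attached only when a
    titer standard error is supplied.
    """
    if conc_pfu_per_ml < 0:
        raise ValueError(f"concentration must be nonnegative, got {conc_pfu_per_ml}")
    vol_ml = geometry.volume_pL / _PL_PER_ML
    if not vol_ml > 0:
        raise ValueError("droplet volume must be positive")
    lam = conc_pfu_per_ml * vol_ml
    ci_low = ci_high = None
    if titer_se_pfu_per_ml is not None:
        if titer_se_pfu_per_ml < 0:
            raise ValueError("titer standard error must be nonnegative")
        half = 1.959963984540054 * titer_se_pfu_per_ml * vol_ml
        ci_low = max(0.0, lam - half)
        ci_high = lam + half
    return OccupancyEstimate(
        lambda_hat=lam,
        method="from_concentration",
        ci_low=ci_low,
        ci_high=ci_high,
    )
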