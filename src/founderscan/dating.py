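"""Founder-cluster dating: the rho statistic under a linear molecular clock.

rho is the mean number of mutations separating a founder node from its
sampled sink descendants; multiplied by the clock calibration (years per
substitution) it estimates the age of the founder event. Its standard
error follows the Saillard branch-weighted estimator,

    sigma_rho^2 = sum over branches b of (n_b / n)^2 * m_b,

where the sum runs over the sink-restricted subtree of the cluster,
``n_b`` is the number of cluster leaves below branch ``b``, ``m_b`` its
mutation count and ``n`` the cluster size. For a star phylogeny this
reduces to sqrt(total mutations) / n.

The clock is strictly linear, defaulting to 1 substitution per 2565
years — the mitogenome rate near the present after correcting for
purifying selection. Mutations on the branch *into* the founder node are
excluded: rho dates the divergence of the sink subtree from the founder
haplotype, not the founder haplotype's own origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .founders import FounderCluster

#: Default clock calibration: years per substitution (whole mitogenome,
#: purifying-selection-corrected, near-present linearisation).
DEFAULT_YEARS_PER_MUTATION = 2565.0


@dataclass(frozen=True)
class ClockModel:
    years_per_mutation: float = DEFAULT_YEARS_PER_MUTATION

    def __post_init__(self):
        if not self.years_per_mutation > 0:
            raise ValueError(
                f"years_per_mutation must be positive, "
                f"got {self.years_per_mutation}"
            )


@dataclass(frozen=True)
class AgeEstimate:
    """rho, its Saillard standard error, and both converted to years."""

    rho: float
    sigma_rho: float
    age_years: float
    sigma_years: float

    def __post_init__(self):
        if self.rho < 0 or self.sigma_rho < 0:
            raise ValueError("rho and sigma_rho must be non-negative")


def rho(cluster: FounderCluster) -> float:
    """Mean mutation-count path from the founder node to its sink leaves."""
    return cluster.total_mutations / cluster.n


def saillard_se(cluster: FounderCluster) -> float:
    """Branch-weighted standard error of rho."""
    n = cluster.n
    var = sum((b.n_b / n) ** 2 * b.m_b for b in cluster.branches)
    return math.sqrt(var)


def to_age(rho_value: float, sigma_rho: float, clock: ClockModel) -> AgeEstimate:
    """Convert rho and its error to calendar years under the linear clock."""
    if rho_value < 0 or sigma_rho < 0:
        raise ValueError("rho and sigma_rho must be non-negative")
    return AgeEstimate(
        rho=rho_value,
        sigma_rho=sigma_rho,
        age_years=rho_value * clock.years_per_mutation,
        sigma_years=sigma_rho * clock.years_per_mutation,
    )


def date_cluster(cluster: FounderCluster, clock: ClockModel) -> AgeEstimate:
    return to_age(rho(cluster), saillard_se(cluster), clock)


def date_clusters(
    clusters: list[FounderCluster], clock: ClockModel | None = None
) -> dict[str, AgeEstimate]:
    """Age estimates keyed by founder_id."""
    clock = clock or ClockModel()
    return {c.founder_id: date_cluster(c, clock) for c in clusters}
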