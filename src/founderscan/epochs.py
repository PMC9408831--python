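"""Fixed-epoch allocation: partitioning founders between migration events.

Under a model with a small number of fixed migration times (the default
two-migration model places one event at 8 ka, the Holocene Climate
Optimum, and one at 0.5 ka, the onset of the Atlantic slave trade),
each founder is statistically allocated between the epochs: the
posterior weight of epoch ``j`` is proportional to the Gaussian density
of the founder's age estimate evaluated at the epoch time, with a
uniform prior over epochs and the same sigma floor as the migration
scan. If every density underflows, the epoch nearest in time takes all
the mass. Allocations are aggregated into per-epoch lineage proportions
weighted by cluster sink sample counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .dating import AgeEstimate

#: Default sigma floor in years — one step of the default scan grid.
DEFAULT_SIGMA_FLOOR = 200.0


@dataclass(frozen=True)
class EpochModel:
    """Ordered migration epochs (years before present) with labels."""

    times: tuple[float, ...] = (8000.0, 500.0)
    labels: tuple[str, ...] = ("prehistoric", "historical")

    def __post_init__(self):
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.times) < 2:
            raise ValueError("an epoch model needs at least two epochs")
        if len(set(self.times)) != len(self.times):
            raise ValueError("epoch times must be distinct")
        if any(t < 0 for t in self.times):
            raise ValueError("epoch times must be non-negative")
        if len(self.labels) != len(self.times):
            raise ValueError("labels and times must have the same length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("epoch labels must be unique")


@dataclass(frozen=True)
class EpochAllocation:
    """Per-founder epoch posteriors plus aggregated lineage proportions."""

    epochs: EpochModel
    posteriors: dict[str, np.ndarray]   # founder_id -> posterior over epochs
    proportions: np.ndarray             # sample-weighted, sums to 1
    effective_counts: np.ndarray = field(default=None)


def allocate(
    age: AgeEstimate,
    epochs: EpochModel,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
) -> np.ndarray:
    """Posterior over epochs for one founder (uniform prior)."""
    sd = max(age.sigma_years, sigma_floor)
    times = np.asarray(epochs.times)
    dens = norm.pdf(times, loc=age.age_years, scale=sd)
    total = dens.sum()
    if total <= 0.0 or not np.isfinite(total):
        post = np.zeros(len(times))
        post[int(np.argmin(np.abs(times - age.age_years)))] = 1.0
        return post
    return dens / total


def aggregate_allocation(
    weighted_posteriors: list[tuple[int, np.ndarray]],
) -> np.ndarray:
    """Sample-count-weighted mean of per-founder posteriors."""
    if not weighted_posteriors:
        raise ValueError("no allocations to aggregate")
    w = np.array([float(n) for n, _ in weighted_posteriors])
    mat = np.vstack([p for _, p in weighted_posteriors])
    return (w[:, None] * mat).sum(axis=0) / w.sum()


def allocate_clusters(
    clusters,
    ages: dict[str, AgeEstimate],
    epochs: EpochModel | None = None,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
) -> EpochAllocation:
    """Allocate every cluster and aggregate lineage proportions."""
    epochs = epochs or EpochModel()
    posteriors = {
        c.founder_id: allocate(ages[c.founder_id], epochs, sigma_floor)
        for c in clusters
    }
    weighted = [(c.n, posteriors[c.founder_id]) for c in clusters]
    proportions = aggregate_allocation(weighted)
    counts = sum(c.n * posteriors[c.founder_id] for c in clusters)
    return EpochAllocation(
        epochs=epochs,
        posteriors=posteriors,
        proportions=proportions,
        effective_counts=counts,
    )
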