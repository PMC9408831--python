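"""Migration-time scan: probability mass of founder arrivals over a grid.

Each dated founder contributes a Gaussian sampling distribution over
candidate migration times, centred on its age estimate with standard
deviation ``max(sigma_years, sigma_floor)``; the floor (one grid step by
default) keeps zero-diversity clusters from collapsing to delta spikes.
Per-founder densities are evaluated on the grid and renormalised over
its support (truncation, not reflection, at the grid edges), then
aggregated into a single mass function — by default weighting each
founder by its sink sample count, so the scan reads as the distribution
of *lineages* over migration times. Peaks of the aggregate mass are the
most probable migration periods.

The default grid mirrors the standard design: every 200 years from 0 to
25 ka.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .dating import AgeEstimate


@dataclass(frozen=True)
class ScanGrid:
    """Inclusive time grid for the migration scan (years before present)."""

    t_min: float = 0.0
    t_max: float = 25000.0
    step: float = 200.0

    def __post_init__(self):
        if not self.t_min < self.t_max:
            raise ValueError("t_min must be < t_max")
        if not self.step > 0:
            raise ValueError("step must be positive")
        n_steps = (self.t_max - self.t_min) / self.step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("(t_max - t_min) must be divisible by step")

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.t_max - self.t_min) / self.step))
        return self.t_min + self.step * np.arange(n + 1)

    def __len__(self) -> int:
        return int(round((self.t_max - self.t_min) / self.step)) + 1


@dataclass(frozen=True)
class ScanResult:
    grid: ScanGrid
    mass: np.ndarray
    founder_ids: tuple[str, ...] = ()
    weights: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if len(self.mass) != len(self.grid):
            raise ValueError("mass length must equal grid length")
        if abs(float(np.sum(self.mass)) - 1.0) > 1e-9:
            raise ValueError("scan mass must sum to 1")


def founder_density(
    age: AgeEstimate, grid: ScanGrid, sigma_floor: float | None = None
) -> np.ndarray:
    """Normalised Gaussian weight vector for one founder on the grid.

    ``sigma_floor`` defaults to one grid step. If the density underflows
    everywhere (age far outside the grid), the nearest grid point takes
    all the mass.
    """
    if sigma_floor is None:
        sigma_floor = grid.step
    sd = max(age.sigma_years, sigma_floor)
    t = grid.times
    w = norm.pdf(t, loc=age.age_years, scale=sd)
    total = w.sum()
    if total <= 0.0 or not np.isfinite(total):
        w = np.zeros(len(t))
        w[int(np.argmin(np.abs(t - age.age_years)))] = 1.0
        return w
    return w / total


def aggregate_scan(
    clusters_with_ages: list[tuple[int, AgeEstimate]] | dict,
    grid: ScanGrid | None = None,
    sigma_floor: float | None = None,
    weighting: str = "size",
    founder_ids: tuple[str, ...] = (),
    keep_weights: bool = False,
) -> ScanResult:
    """Aggregate per-founder weight vectors into a single scan mass.

    ``clusters_with_ages`` is a list of ``(n_sink, AgeEstimate)`` pairs
    (or a dict mapping founder_id to such a pair, in which case founder
    ids are taken from the keys). ``weighting`` is ``"size"`` (each
    founder counts its sink samples — lineage-proportional, the default)
    or ``"equal"``.
    """
    grid = grid or ScanGrid()
    if isinstance(clusters_with_ages, dict):
        founder_ids = tuple(clusters_with_ages)
        pairs = list(clusters_with_ages.values())
    else:
        pairs = list(clusters_with_ages)
    if not pairs:
        raise ValueError("migration scan requires at least one dated cluster")
    if weighting not in ("size", "equal"):
        raise ValueError(f"unknown weighting {weighting!r}")
    mat = np.vstack(
        [founder_density(age, grid, sigma_floor) for _, age in pairs]
    )
    w = np.array(
        [float(n) for n, _ in pairs] if weighting == "size"
        else [1.0] * len(pairs)
    )
    mass = (w[:, None] * mat).sum(axis=0) / w.sum()
    mass = mass / mass.sum()
    return ScanResult(
        grid=grid,
        mass=mass,
        founder_ids=founder_ids,
        weights=mat if keep_weights else None,
    )


def find_peaks(result: ScanResult) -> list[tuple[float, float]]:
    """Strict local maxima of the scan mass, sorted by mass descending.

    Interior points must exceed both neighbours; grid ends must exceed
    their single neighbour. A flat mass has no peaks.
    """
    t = result.grid.times
    m = result.mass
    peaks = []
    for i in range(len(m)):
        left_ok = i == 0 or m[i] > m[i - 1]
        right_ok = i == len(m) - 1 or m[i] > m[i + 1]
        if left_ok and right_ok:
            peaks.append((float(t[i]), float(m[i])))
    peaks.sort(key=lambda p: (-p[1], p[0]))
    return peaks
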