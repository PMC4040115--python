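"""Core domain types: spatial units, study regions and simulated datasets.

A study region is a tessellation of ``n`` spatial units (SUs), census-tract-like
areas each carrying a centroid and an at-risk population size (here, mean annual
live births — a real number, not forced to an integer).  Coordinates are planar:
every distance used downstream (distance to the region edge, scan radii) is
Euclidean, so geographic lon/lat must be projected before building a
:class:`Region`.

A :class:`Dataset` is one realisation of case counts on a region under a global
incidence ``lambda_``: the expected count in SU *i* is ``mu_i = lambda_ * pop_i``
and observed counts are non-negative integers.  Note the deliberate naming:
``total_cases`` and ``total_population`` are the region-wide totals (the scan
literature often writes these ``n`` and ``N``, clashing with ``n`` = number of
SUs used everywhere else).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry
from shapely.validation import explain_validity

__all__ = ["SpatialUnit", "Region", "Dataset", "validate_region", "expected_counts"]


@dataclass(frozen=True)
class SpatialUnit:
    """One spatial unit: an id, a planar centroid and an at-risk population.

    Parameters
    ----------
    id : str
        Unique label within the region.
    centroid : (float, float)
        Planar coordinates of the SU's reference point.  Whether this is the
        geometric polygon centroid or a population-weighted point is up to the
        data producer; it is used as given, never recomputed.
    population : float
        At-risk population size (e.g. mean annual live births), >= 0.
    polygon : shapely geometry, optional
        The SU's own boundary, kept only for export; not used in computation.
    """

    id: str
    centroid: tuple[float, float]
    population: float
    polygon: Optional[BaseGeometry] = None


@dataclass
class Region:
    """An ordered tessellation of spatial units inside a boundary polygon.

    The unit order is fixed at construction time and defines the vector index
    ``i`` used by every per-SU array downstream (expected counts, participation
    rates, edge coefficients).
    """

    units: list[SpatialUnit]
    boundary: BaseGeometry

    def __post_init__(self) -> None:
        self._centroids = np.asarray([u.centroid for u in self.units], dtype=float)
        self._populations = np.asarray([u.population for u in self.units], dtype=float)

    @property
    def n(self) -> int:
        """Number of spatial units."""
        return len(self.units)

    @property
    def ids(self) -> list[str]:
        return [u.id for u in self.units]

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) array of SU centroids, in unit order."""
        return self._centroids

    @property
    def populations(self) -> np.ndarray:
        """(n,) array of at-risk population sizes, in unit order."""
        return self._populations

    @property
    def total_population(self) -> float:
        return float(self._populations.sum())

    def index_of(self, unit_id: str) -> int:
        try:
            return self.ids.index(unit_id)
        except ValueError:
            raise KeyError(f"no spatial unit with id {unit_id!r}") from None


def validate_region(region: Region) -> list[str]:
    """Check every region invariant; return a list of human-readable violations.

    An empty list means the region is well formed.  This never raises: it is a
    reporting operation used both on load and in tests.
    """
    violations: list[str] = []
    if region.n < 2:
        violations.append(f"region has {region.n} spatial units; at least 2 required")
    ids = region.ids
    seen: set[str] = set()
    for uid in ids:
        if uid in seen:
            violations.append(f"duplicate spatial unit id {uid!r}")
        seen.add(uid)
    if region.boundary is None or region.boundary.is_empty:
        violations.append("boundary polygon is empty")
    elif not region.boundary.is_valid:
        violations.append(
            f"boundary polygon is invalid: {explain_validity(region.boundary)}"
        )
    for u in region.units:
        if u.population < 0:
            violations.append(
                f"unit {u.id!r}: population {u.population} is negative"
            )
        if not (np.isfinite(u.centroid[0]) and np.isfinite(u.centroid[1])):
            violations.append(f"unit {u.id!r}: centroid is not finite")
        elif (
            region.boundary is not None
            and not region.boundary.is_empty
            and region.boundary.is_valid
            and not region.boundary.covers(Point(u.centroid))
        ):
            violations.append(f"unit {u.id!r}: centroid outside boundary")
    if region.n >= 1 and not region.total_population > 0:
        violations.append(
            f"total population is {region.total_population}; must be > 0"
        )
    return violations


def expected_counts(region: Region, lambda_: float) -> np.ndarray:
    """Per-SU expected case counts ``mu_i = lambda_ * population_i``.

    ``lambda_`` is the global incidence (cases per at-risk individual); it must
    be non-negative.  The result sums to ``lambda_ * total_population`` exactly
    (up to floating point).
    """
    if lambda_ < 0:
        raise ValueError(f"incidence lambda_ must be >= 0, got {lambda_}")
    return lambda_ * region.populations


@dataclass
class Dataset:
    """One simulated (or observed) realisation of case counts on a region.

    ``expected`` is always ``lambda_ * population`` elementwise; the constructor
    computes it, so the invariant holds by construction.
    """

    region: Region
    lambda_: float
    observed: np.ndarray
    expected: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed)
        if obs.shape != (self.region.n,):
            raise ValueError(
                f"observed has shape {obs.shape}, expected ({self.region.n},)"
            )
        if np.any(obs < 0):
            raise ValueError("observed case counts must be non-negative")
        if not np.all(obs == np.floor(obs)):
            raise ValueError("observed case counts must be integers")
        self.observed = obs.astype(np.int64)
        self.expected = expected_counts(self.region, self.lambda_)

    @property
    def total_cases(self) -> int:
        return int(self.observed.sum())

    @property
    def total_population(self) -> float:
        return self.region.total_population
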