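"""Kulldorff's circular spatial scan statistic (Poisson model, Monte-Carlo inference).

Candidate zones are circles centred on SU centroids with radius growing from 0:
each zone is the set of SUs whose centroids fall inside the circle, capped so
that the zone's at-risk population never exceeds a fraction of the regional
total (50% in the usual setting).  For a zone *z* with ``n_z`` cases and
population ``N_z`` out of totals ``n`` and ``N``, the log-likelihood ratio is

    LLR(z) = n_z log(n_z / (lambda N_z)) + (n - n_z) log((n - n_z) / (lambda (N - N_z)))

when ``n_z`` exceeds its null expectation ``lambda N_z``, and 0 otherwise; the
zone maximising it is the most likely cluster (MLC).  Significance comes from
rank-based Monte-Carlo inference: replicate datasets are generated under risk
homogeneity, scanned identically, and

    p = (1 + #{replicate max-LLR >= observed max-LLR}) / (n_mc + 1).

Replicates are multinomial by default — the observed total case count is
redistributed over SUs proportionally to expected counts, i.e. inference
conditional on the total, as the standard R implementations do — with an
unconditional independent-Poisson option.

Everything is computed in log space: the product form of the likelihood ratio
overflows for realistic counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import log
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.special import xlogy

from .region import Dataset, Region

__all__ = ["Zone", "ZoneSet", "ScanResult", "enumerate_zones", "poisson_llr", "scan"]


@dataclass(frozen=True)
class Zone:
    """A candidate circular cluster.

    ``member_ids`` is ordered by distance from the centre; ``radius`` is the
    distance to the farthest included centroid.  ``cases_in`` is only filled
    on the zone returned as a scan's most likely cluster.
    """

    center_id: str
    member_ids: tuple[str, ...]
    pop_in: float
    radius: float
    cases_in: Optional[int] = None

    def __len__(self) -> int:
        return len(self.member_ids)


class ZoneSet(Sequence):
    """The deduplicated collection of candidate zones for one region.

    Behaves as a sequence of :class:`Zone` and caches the dense membership
    matrix used to score thousands of replicate datasets in one matrix product.
    """

    def __init__(self, region: Region, zones: list[Zone], member_index: list[np.ndarray]):
        self.region = region
        self._zones = zones
        self._member_index = member_index
        n = region.n
        m = np.zeros((n, len(zones)))
        for j, idx in enumerate(member_index):
            m[idx, j] = 1.0
        self.membership = m  # (n_SUs, n_zones)
        self.pop_in = np.array([z.pop_in for z in zones])

    def __len__(self) -> int:
        return len(self._zones)

    def __getitem__(self, j):
        return self._zones[j]

    def member_indices(self, j: int) -> np.ndarray:
        return self._member_index[j]


@dataclass(frozen=True)
class ScanResult:
    """The most likely cluster of one dataset with its Monte-Carlo p-value."""

    mlc: Zone
    llr: float
    p_value: float
    n_replicates: int
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


def enumerate_zones(region: Region, max_pop_fraction: float = 0.5) -> ZoneSet:
    """Enumerate all circular zones up to the population cap.

    For each centre SU, the other SUs are sorted by centroid distance and
    included cumulatively; a zone is emitted after each inclusion while its
    population stays within ``max_pop_fraction`` of the regional total.
    Centroids at exactly equal distance from the centre are included together
    (a circle covers both or neither).  Duplicate member sets reached from
    different centres are kept once, at their first (lowest centre index)
    occurrence.
    """
    if not 0 < max_pop_fraction <= 1:
        raise ValueError(
            f"max_pop_fraction must be in (0, 1], got {max_pop_fraction}"
        )
    cap = max_pop_fraction * region.total_population
    xy = region.centroids
    pops = region.populations
    ids = region.ids
    zones: list[Zone] = []
    member_index: list[np.ndarray] = []
    seen: set[frozenset[int]] = set()
    for c in range(region.n):
        dist = np.hypot(xy[:, 0] - xy[c, 0], xy[:, 1] - xy[c, 1])
        order = np.argsort(dist, kind="stable")
        radii = dist[order]
        members: list[int] = []
        pop = 0.0
        k = 0
        while k < region.n:
            # tie group: all centroids at exactly this distance enter together
            k2 = k
            while k2 < region.n and radii[k2] == radii[k]:
                k2 += 1
            group = order[k:k2]
            pop += float(pops[group].sum())
            if pop > cap:
                break
            members.extend(int(i) for i in group)
            key = frozenset(members)
            if key not in seen:
                seen.add(key)
                idx = np.array(members, dtype=np.intp)
                zones.append(
                    Zone(
                        center_id=ids[c],
                        member_ids=tuple(ids[i] for i in members),
                        pop_in=pop,
                        radius=float(radii[k2 - 1]),
                    )
                )
                member_index.append(idx)
            k = k2
    return ZoneSet(region, zones, member_index)


def poisson_llr(
    cases_in: float, expected_in: float, cases_out: float, expected_out: float
) -> float:
    """Poisson log-likelihood ratio of a single zone.

    Zero unless the in-zone count exceeds its null expectation; zero-count
    terms contribute 0 (the ``x log x -> 0`` limit).
    """
    if expected_in <= 0 or expected_out <= 0:
        raise ValueError(
            f"expected counts must be positive, got in={expected_in}, out={expected_out}"
        )
    if cases_in < 0 or cases_out < 0:
        raise ValueError("case counts must be non-negative")
    if not cases_in > expected_in:
        return 0.0
    llr = cases_in * log(cases_in / expected_in)
    if cases_out > 0:
        llr += cases_out * log(cases_out / expected_out)
    return llr


def _max_llr(
    counts: np.ndarray, zones: ZoneSet, lam: float | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Max LLR (and argmax) per row of a (R, n_SUs) count matrix.

    ``lam`` is a scalar (nominal incidence) or a per-row array (each row's
    estimated incidence, for conditional inference).
    """
    lam = np.atleast_1d(np.asarray(lam, dtype=float))[:, None]  # (R or 1, 1)
    lam = np.where(lam > 0, lam, np.finfo(float).tiny)
    e_in = lam * zones.pop_in  # (R or 1, n_zones)
    e_tot = lam * zones.region.total_population  # (R or 1, 1)
    n_in = counts @ zones.membership  # (R, n_zones)
    n_tot = counts.sum(axis=1, keepdims=True)
    n_out = n_tot - n_in
    with np.errstate(divide="ignore", invalid="ignore"):
        llr = xlogy(n_in, n_in / e_in) + xlogy(n_out, n_out / (e_tot - e_in))
    llr[n_in <= np.broadcast_to(e_in, llr.shape)] = 0.0
    best = np.argmax(llr, axis=1)
    return llr[np.arange(llr.shape[0]), best], best


def scan(
    dataset: Dataset,
    zones: ZoneSet,
    n_mc: int = 999,
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
    replicates: Literal["multinomial", "poisson"] = "multinomial",
    lambda_mode: Literal["estimated", "nominal"] = "estimated",
) -> ScanResult:
    """Scan one dataset: find the MLC and its Monte-Carlo p-value.

    ``replicates='multinomial'`` conditions on the observed total case count
    (the default, matching common practice); ``'poisson'`` draws unconditional
    independent Poisson counts.  ``lambda_mode`` selects the incidence used in
    the LLR.  The default ``'estimated'`` uses each count vector's own
    ``total_cases/total_population`` — the conditional scan statistic, a
    nonnegative KL-type quantity, which is what the standard R/SaTScan
    implementations compute.  ``'nominal'`` uses the dataset's stated
    incidence; note that the proportional form of the statistic then loses a
    factor depending only on the total, so whole-region deficits push every
    zone's value to zero and the Monte-Carlo test becomes conservative.
    Ties for the maximal LLR break to the earliest enumerated zone (lowest
    centre index, then fewest members).
    """
    if len(zones) == 0:
        raise ValueError("zone set is empty")
    if zones.region is not dataset.region and zones.region.ids != dataset.region.ids:
        raise ValueError("dataset and zones refer to different regions")
    if n_mc < 1:
        raise ValueError(f"n_mc must be >= 1, got {n_mc}")
    if lambda_mode not in ("estimated", "nominal"):
        raise ValueError(f"unknown lambda_mode {lambda_mode!r}")

    obs = dataset.observed.astype(float)[None, :]
    if lambda_mode == "nominal":
        lam_obs: float | np.ndarray = dataset.lambda_
    else:
        lam_obs = dataset.total_cases / dataset.total_population
    obs_llr, obs_best = _max_llr(obs, zones, lam_obs)
    obs_llr = float(obs_llr[0])
    j = int(obs_best[0])

    rng = np.random.default_rng(seed)
    mu = dataset.expected
    if replicates == "multinomial":
        total = dataset.total_cases
        if mu.sum() > 0:
            probs = mu / mu.sum()
        else:
            probs = np.full(dataset.region.n, 1.0 / dataset.region.n)
        counts = rng.multinomial(total, probs, size=n_mc).astype(float)
    elif replicates == "poisson":
        counts = rng.poisson(mu, size=(n_mc, dataset.region.n)).astype(float)
    else:
        raise ValueError(f"unknown replicates mode {replicates!r}")
    if lambda_mode == "nominal":
        lam_rep: float | np.ndarray = dataset.lambda_
    else:
        lam_rep = counts.sum(axis=1) / dataset.total_population
    rep_llr, _ = _max_llr(counts, zones, lam_rep)
    p = (1 + int(np.count_nonzero(rep_llr >= obs_llr))) / (n_mc + 1)

    mlc = replace(
        zones[j], cases_in=int(dataset.observed[zones.member_indices(j)].sum())
    )
    return ScanResult(mlc=mlc, llr=obs_llr, p_value=p, n_replicates=n_mc, alpha=alpha)
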