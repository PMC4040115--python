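"""Spatial description of type I error: participation rates and the E test.

When datasets simulated under risk homogeneity are scanned, every significant
most likely cluster is a wrongly detected cluster (WDC).  The overall type I
error rate is the fraction of datasets yielding a WDC.  Its spatial structure
is described per SU by the participation rate

    P_i = sum_j I_ij / (m * l_j),

where *m* is the number of WDCs, ``l_j`` the number of SUs in the *j*-th WDC
and ``I_ij`` indicates membership of SU *i*; by construction P_i >= 0 and the
P_i sum to 1, with expected value 1/n per SU under spatial homogeneity.

The edge-effect statistic contrasts participation with the edge coefficients
``eps_i`` (see :mod:`scanedge.geometry`):

    E = sum_i eps_i (P_i - 1/n),

positive under an ascending centre-to-edge gradient of participation, negative
under a descending one (WDCs preferentially central), zero in expectation under
spatial homogeneity.  Its null distribution is obtained by permutation: the
observed P values are redistributed uniformly at random among the SUs and E is
recomputed; the p-value ranks the observed statistic within the collection of
simulated and observed statistics, so the smallest attainable p with B
replicates is 1/(B+1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import spearmanr
from statsmodels.stats.proportion import proportion_confint

from .geometry import EdgeCoefficients
from .region import Region
from .scan import ScanResult

__all__ = [
    "WDCCollection",
    "ParticipationVector",
    "ETestResult",
    "collect_wdc",
    "participation_rates",
    "e_statistic",
    "e_permutation_test",
    "correlate_participation_population",
]


@dataclass(frozen=True)
class WDCCollection:
    """The wrongly detected clusters harvested from a batch of null scans.

    ``rate`` is the overall type I error estimate m'/n_datasets, where m' counts
    significant datasets, with its 95% Wilson score confidence interval.
    """

    clusters: tuple[frozenset[str], ...]
    n_datasets: int

    @property
    def m(self) -> int:
        return len(self.clusters)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(c) for c in self.clusters], dtype=np.intp)

    @property
    def rate(self) -> float:
        return self.m / self.n_datasets

    @property
    def rate_ci(self) -> tuple[float, float]:
        lo, hi = proportion_confint(self.m, self.n_datasets, alpha=0.05, method="wilson")
        return float(lo), float(hi)


@dataclass(frozen=True)
class ParticipationVector:
    """Per-SU participation rates in the overall type I error (sum to 1)."""

    p: np.ndarray


@dataclass(frozen=True)
class ETestResult:
    """Observed E, its permutation null and the Monte-Carlo p-value."""

    e_obs: float
    null_e: np.ndarray
    n_replicates: int
    p_value: float
    sidedness: str

    @property
    def gradient(self) -> str:
        """'ascending' (edge-ward) or 'descending' (centre-ward) participation."""
        if self.e_obs > 0:
            return "ascending"
        if self.e_obs < 0:
            return "descending"
        return "none"


def collect_wdc(
    scan_results: Sequence[ScanResult], alpha: float = 0.05
) -> WDCCollection:
    """Keep the most likely clusters significant at ``alpha`` as WDCs."""
    clusters = tuple(
        frozenset(r.mlc.member_ids) for r in scan_results if r.p_value <= alpha
    )
    return WDCCollection(clusters=clusters, n_datasets=len(scan_results))


def participation_rates(wdc: WDCCollection, region: Region) -> ParticipationVector:
    """Participation rate P_i of every SU, weighting each WDC by 1/(m l_j)."""
    if wdc.m == 0:
        raise ValueError(
            "no wrongly detected cluster: participation rates are undefined"
        )
    idx = {uid: i for i, uid in enumerate(region.ids)}
    p = np.zeros(region.n)
    m = wdc.m
    for cluster in wdc.clusters:
        w = 1.0 / (m * len(cluster))
        for uid in cluster:
            try:
                p[idx[uid]] += w
            except KeyError:
                raise ValueError(f"WDC member {uid!r} is not a unit of the region")
    return ParticipationVector(p=p)


def e_statistic(p: ParticipationVector, eps: EdgeCoefficients) -> float:
    """E = sum_i eps_i (P_i - 1/n); sign gives the gradient direction."""
    pv = np.asarray(p.p, dtype=float)
    ev = np.asarray(eps.epsilon, dtype=float)
    if pv.shape != ev.shape:
        raise ValueError(
            f"participation vector (n={pv.size}) and edge coefficients "
            f"(n={ev.size}) are indexed on different regions"
        )
    n = pv.size
    return float(ev @ (pv - 1.0 / n))


def e_permutation_test(
    p: ParticipationVector,
    eps: EdgeCoefficients,
    n_replicates: int = 99_999,
    seed: int | np.random.SeedSequence = 0,
    sidedness: Literal["two-sided", "upper", "lower"] = "two-sided",
) -> ETestResult:
    """Permutation test of spatial homogeneity of type I error (H0: E = 0).

    Each replicate redistributes the observed P values uniformly at random
    among the SUs and recomputes E.  The observed statistic is included in the
    ranking collection, so p >= 1/(B+1).  The default two-sided rule compares
    |E| (matching the alternative E != 0); 'upper' and 'lower' give the
    one-tailed rules.
    """
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    e_obs = e_statistic(p, eps)
    pv = np.asarray(p.p, dtype=float)
    ev = np.asarray(eps.epsilon, dtype=float)
    n = pv.size
    rng = np.random.default_rng(seed)
    # E for a permutation pi is  eps . P_pi - mean(eps) (sum P = const);
    # permute P across SUs for each replicate in one vectorised pass
    perm = np.tile(pv, (n_replicates, 1))
    rng.permuted(perm, axis=1, out=perm)
    null_e = perm @ ev - ev.sum() / n
    # |E| <= 2, so an absolute tolerance keeps exact permutation ties counted
    # as ties despite floating-point summation order
    tol = 1e-12
    if sidedness == "two-sided":
        k = int(np.count_nonzero(np.abs(null_e) >= abs(e_obs) - tol))
    elif sidedness == "upper":
        k = int(np.count_nonzero(null_e >= e_obs - tol))
    elif sidedness == "lower":
        k = int(np.count_nonzero(null_e <= e_obs + tol))
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    p_value = (1 + k) / (n_replicates + 1)
    return ETestResult(
        e_obs=e_obs,
        null_e=null_e,
        n_replicates=n_replicates,
        p_value=p_value,
        sidedness=sidedness,
    )


def correlate_participation_population(
    p: ParticipationVector, region: Region
) -> tuple[float, float]:
    """Spearman rank correlation of P_i against the at-risk population sizes.

    Returns ``(r, p_value)`` (two-sided).  Raises on constant input, where the
    rank correlation is undefined.
    """
    pv = np.asarray(p.p, dtype=float)
    pop = region.populations
    if pv.size < 3:
        raise ValueError("need at least 3 SUs for a rank correlation")
    if np.all(pv == pv[0]) or np.all(pop == pop[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    res = spearmanr(pv, pop)
    return float(res.statistic), float(res.pvalue)
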