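"""Null-hypothesis simulation: independent Poisson case counts per SU.

Under risk homogeneity every SU shares the global incidence ``lambda_``, so the
observed count in SU *i* is Poisson with mean ``lambda_ * population_i``,
independently across SUs.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .region import Dataset, Region, expected_counts

__all__ = ["simulate_null", "dataset_rng"]


def dataset_rng(seed: int, index: int) -> np.random.Generator:
    """RNG stream for one dataset, derived from (master seed, dataset index).

    Each dataset gets its own child stream, so any subset of datasets can be
    regenerated independently (and in parallel) with identical output.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    )


def simulate_null(
    region: Region, lambda_: float, n_datasets: int, seed: int
) -> Iterator[Dataset]:
    """Yield ``n_datasets`` datasets with independent Poisson(lambda * pop) counts.

    Deterministic: identical ``(region, lambda_, n_datasets, seed)`` reproduce
    identical datasets, dataset *k* depending only on ``(seed, k)``.
    """
    if lambda_ < 0:
        raise ValueError(f"incidence lambda_ must be >= 0, got {lambda_}")
    if n_datasets < 1:
        raise ValueError(f"n_datasets must be >= 1, got {n_datasets}")
    mu = expected_counts(region, lambda_)
    for k in range(n_datasets):
        counts = dataset_rng(seed, k).poisson(mu)
        yield Dataset(region=region, lambda_=lambda_, observed=counts)
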