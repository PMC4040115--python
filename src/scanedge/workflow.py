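"""End-to-end study: simulate under the null, scan, describe the type I error.

``run_study`` ties the stages together the way the full simulation experiment
is organised: generate (or load) a region, simulate ``n_datasets`` Poisson
datasets under risk homogeneity, scan each for its most likely cluster,
collect the significant ones as wrongly detected clusters, compute per-SU
participation rates and edge coefficients, and run the edge-effect permutation
test.  Everything is reproducible from the master seed: dataset *k* uses the
child stream ``(seed, k)`` for both its counts and its scan replicates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as sio
from .geometry import edge_coefficients
from .region import Region
from .scan import ScanResult, enumerate_zones, scan
from .simulate import simulate_null
from .type1 import (
    collect_wdc,
    correlate_participation_population,
    e_permutation_test,
    e_statistic,
    participation_rates,
)

__all__ = ["RunConfig", "run_study"]

log = logging.getLogger("scanedge")

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of a full null-simulation study.

    Defaults mirror the standard setting: alpha 0.05, 999 scan replicates,
    zones capped at 50% of the total population, 99 999 permutation replicates
    for the edge-effect test.
    """

    region_path: Optional[str] = None
    boundary_path: Optional[str] = None
    lambda_: float = 0.0226
    n_datasets: int = 100
    n_mc: int = 999
    alpha: float = 0.05
    max_pop_fraction: float = 0.5
    e_test_replicates: int = 99_999
    seed: int = 0
    out_dir: Optional[str] = None
    sidedness: str = "two-sided"
    replicates: str = "multinomial"
    write_datasets: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.max_pop_fraction <= 1:
            raise ValueError(
                f"max_pop_fraction must be in (0, 1], got {self.max_pop_fraction}"
            )
        for name in ("n_datasets", "n_mc", "e_test_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from JSON or TOML, keyed by field name."""
        path = Path(path)
        if path.suffix.lower() == ".toml":
            import tomllib

            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        else:
            with open(path) as fh:
                data = json.load(fh)
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the fields that determine results (output paths excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        payload.pop("write_datasets", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _mc_seed(seed: int, k: int) -> np.random.SeedSequence:
    # scan-replicate stream for dataset k, disjoint from the simulation streams
    return np.random.SeedSequence(entropy=seed, spawn_key=(1, k))


def run_study(config: RunConfig, region: Region | None = None) -> dict:
    """Run the whole pipeline; return the JSON-able study report.

    ``region`` may be passed directly (e.g. from :mod:`scanedge.synthetic`);
    otherwise it is read from ``config.region_path``.  When ``config.out_dir``
    is set, per-dataset scan results, the participation/edge-coefficient map
    and the report are written there as CSV/JSON.
    """
    if region is None:
        if config.region_path is None:
            raise ValueError("either a region or config.region_path is required")
        region = sio.read_region(config.region_path, config.boundary_path)
    log.info(
        "run_study: seed=%d config=%s n=%d SUs", config.seed, config.config_hash(), region.n
    )

    zones = enumerate_zones(region, config.max_pop_fraction)
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    results: list[ScanResult] = []
    for k, ds in enumerate(
        simulate_null(region, config.lambda_, config.n_datasets, config.seed)
    ):
        res = scan(
            ds,
            zones,
            n_mc=config.n_mc,
            alpha=config.alpha,
            seed=_mc_seed(config.seed, k),
            replicates=config.replicates,  # type: ignore[arg-type]
        )
        results.append(res)
        if out and config.write_datasets:
            sio.write_dataset_csv(ds, out / f"dataset_{k:05d}.csv")

    wdc = collect_wdc(results, config.alpha)
    eps = edge_coefficients(region)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_units": region.n,
        "lambda": config.lambda_,
        "n_datasets": config.n_datasets,
        "alpha": config.alpha,
        "n_zones": len(zones),
        "type_i_error": {
            "n_wdc": wdc.m,
            "rate": wdc.rate,
            "rate_ci95": list(wdc.rate_ci),
        },
        "expected_participation_rate": 1.0 / region.n,
    }
    if wdc.m >= 1:
        lengths = wdc.lengths
        report["wdc_size"] = {
            "mean": float(lengths.mean()),
            "min": int(lengths.min()),
            "median": float(np.median(lengths)),
            "max": int(lengths.max()),
        }
        p = participation_rates(wdc, region)
        et = e_permutation_test(
            p,
            eps,
            n_replicates=config.e_test_replicates,
            seed=np.random.SeedSequence(entropy=config.seed, spawn_key=(2,)),
            sidedness=config.sidedness,  # type: ignore[arg-type]
        )
        r, rp = correlate_participation_population(p, region)
        report["participation"] = {
            "mean": float(p.p.mean()),
            "sd": float(p.p.std(ddof=1)),
            "min": float(p.p.min()),
            "max": float(p.p.max()),
            "spearman_r_vs_population": r,
            "spearman_p": rp,
        }
        report["edge_effect"] = {
            "E": et.e_obs,
            "p_value": et.p_value,
            "gradient": et.gradient,
            "n_replicates": et.n_replicates,
            "sidedness": et.sidedness,
            "depth_D": float(eps.depth)
            if np.isscalar(eps.depth)
            else [float(v) for v in eps.depth],
        }
        if out:
            sio.write_participation_csv(p, eps, region, out / "participation.csv")
            sio.write_participation_geojson(
                p, eps, region, out / "participation.geojson"
            )
    else:
        report["edge_effect"] = None
        report["participation"] = None

    if out:
        sio.write_scan_results_csv(results, out / "scan_results.csv")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        log.info("run_study: report written to %s", out / "report.json")
    return report
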