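"""End-to-end pipeline: build -> simulate -> aggregate analysis -> CMC fit.

Every stage writes its intermediate to the output directory; the final
ResultRecord lists each artifact with a checksum, so a re-run with the
same config and seed reproduces identical files.  A CMC fit that cannot
cross 50% (non-aggregating system) is captured inside ``cmc.json`` rather
than aborting the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, replace
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

from .aggregates import free_fraction
from .builder import build_composition, build_topology
from .cmc import cmc_from_free_fraction, fit_free_fraction
from .config import RunConfig
from .engine import simulate_concentration_series
from .errors import NumericalError
from .gro import write_gro
from .study import _spawn_seeds
from .tables import FREE_FRACTION_SCHEMA, write_table

logger = logging.getLogger("micellekit")


def _package_version() -> str:
    try:
        return version("micellekit")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class ResultRecord:
    """Per-stage outputs with checksums plus run provenance."""

    tool_version: str
    config_digest: str
    seed: int
    outputs: dict  # stage -> {path, sha256}
    timings_s: dict
    cmc_failed: bool
    started_at: str
    finished_at: str

    def to_dict(self) -> dict:
        return self.__dict__.copy()

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def run_pipeline(config: RunConfig) -> ResultRecord:
    """Execute the full pipeline described by ``config``.

    Stages: composition build, one self-assembly run per concentration,
    free-fraction analysis, power-law CMC fit.  All randomness derives
    from ``config.seed``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = _time.strftime("%Y-%m-%dT%H:%M:%S")
    outputs: dict = {}
    timings: dict = {}

    def record(stage: str, path: Path) -> None:
        outputs[stage] = {"path": str(path), "sha256": _checksum(path)}

    t0 = _time.perf_counter()
    topology = build_topology(config.chain_id, config.fraction_deprotonated >= 0.5)
    compositions = {
        c: build_composition(
            config.chain_id, c, config.fraction_deprotonated,
            config.ionic_strength_mM, config.box, config.temperature_C,
        )
        for c in config.concentrations_mM
    }
    comp_path = outdir / "compositions.json"
    comp_path.write_text(
        json.dumps({str(c): comp.to_dict() for c, comp in compositions.items()}, indent=2) + "\n"
    )
    record("compositions", comp_path)
    timings["build"] = _time.perf_counter() - t0

    t0 = _time.perf_counter()
    seeds = _spawn_seeds(config.seed, len(config.concentrations_mM))
    logger.info("simulating %d concentrations, seeds %s", len(seeds), seeds)
    runs = simulate_concentration_series(
        config.chain_id,
        list(config.concentrations_mM),
        replace(config.engine, bond_length=topology.bond_length),
        seeds,
        config.box,
        fraction_deprotonated=config.fraction_deprotonated,
        ionic_strength_mM=config.ionic_strength_mM,
        temperature_C=config.temperature_C,
    )
    for conc, traj in runs:
        path = outdir / f"traj_{conc:g}mM.gro"
        write_gro(traj, path, name=f"{config.chain_id} {conc:g} mM seed={traj.metadata.get('seed')}")
        record(f"trajectory_{conc:g}mM", path)
    timings["simulate"] = _time.perf_counter() - t0

    t0 = _time.perf_counter()
    points = []
    for conc, traj in runs:
        pt = free_fraction(
            traj,
            cutoff=config.analysis.cutoff_nm,
            size_cutoff=config.analysis.size_cutoff,
            window_fraction=config.analysis.window_fraction,
            n_snapshots=config.analysis.n_snapshots,
        )
        logger.info("free fraction at %g mM: %.3f +- %.3f", conc, pt.mean_free_fraction, pt.sd)
        points.append(pt)
    ff_path = outdir / "free_fraction.csv"
    write_table(
        pd.DataFrame(
            {
                "concentration_mM": [p.concentration_mM for p in points],
                "free_fraction": [p.mean_free_fraction for p in points],
                "sd": [p.sd for p in points],
                "n_snapshots": [p.n_snapshots for p in points],
            }
        ),
        ff_path,
        FREE_FRACTION_SCHEMA,
    )
    record("free_fraction", ff_path)
    timings["aggregates"] = _time.perf_counter() - t0

    t0 = _time.perf_counter()
    cmc_failed = False
    try:
        fit = fit_free_fraction(points)
        estimate = cmc_from_free_fraction(fit)
        cmc_payload = estimate.to_dict()
    except (NumericalError, ValueError) as err:
        cmc_failed = True
        cmc_payload = {"error": f"{type(err).__name__}: {err}"}
        logger.warning("CMC stage failed: %s", err)
    cmc_path = outdir / "cmc.json"
    cmc_path.write_text(json.dumps(cmc_payload, indent=2) + "\n")
    record("cmc", cmc_path)
    timings["cmc"] = _time.perf_counter() - t0

    rec = ResultRecord(
        tool_version=_package_version(),
        config_digest=config.digest(),
        seed=config.seed,
        outputs=outputs,
        timings_s=timings,
        cmc_failed=cmc_failed,
        started_at=started,
        finished_at=_time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    rec.write(outdir / "record.json")
    return rec
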