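"""Reduced-scale self-assembly study protocols.

These helpers bundle the standard desk-scale study: a concentration
series of implicit-solvent Langevin runs in a 15 nm box, free-fraction
analysis over the final tenth of each run, and a power-law CMC estimate.
The box is far smaller and the runs far shorter than production
coarse-grained MD, so only qualitative trends (free fraction falling with
concentration, longer chains aggregating at lower concentration) are
meaningful — absolute concentration thresholds are not.

Default study conditions: fully deprotonated chains, 140 mM implicit
salt, 37 degC, concentrations 30-120 mM (about 60-240 molecules in the
15 nm box), three replicate seeds per concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .aggregates import FreeFractionPoint, free_fraction
from .builder import BoxSpec, build_composition, build_topology
from .cmc import CMCEstimate, cmc_from_free_fraction, fit_free_fraction
from .engine import EngineParams, run_selfassembly, simulate_concentration_series

DEFAULT_BOX = BoxSpec(15.0, 15.0, 15.0)
DEFAULT_CONCENTRATIONS_MM = (30.0, 60.0, 90.0, 120.0)


def default_engine_params(seed: int = 0, n_steps: int = 50000) -> EngineParams:
    """Engine parameters used by the standard reduced study."""
    return EngineParams(seed=seed, n_steps=n_steps)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


@dataclass
class ConcentrationStudy:
    """Free-fraction series (seed-averaged) and its CMC estimate."""

    chain_id: str
    concentrations_mM: tuple[float, ...]
    #: replicate-averaged free fraction per concentration
    points: list[FreeFractionPoint]
    #: per-replicate free fractions, shape (n_concentrations, n_seeds)
    replicate_fractions: np.ndarray
    cmc: Optional[CMCEstimate]
    cmc_error: Optional[str]


def free_fraction_series(
    chain_id: str,
    seed: int,
    concentrations_mM: Sequence[float] = DEFAULT_CONCENTRATIONS_MM,
    n_seeds: int = 3,
    box: BoxSpec = DEFAULT_BOX,
    params: Optional[EngineParams] = None,
    size_cutoff: int = 5,
    n_snapshots: int = 20,
    fraction_deprotonated: float = 1.0,
    ionic_strength_mM: float = 140.0,
) -> ConcentrationStudy:
    """Run the concentration series with replicate seeds and fit the CMC.

    Per concentration, ``n_seeds`` independent runs are performed and the
    late-window free fractions averaged; the seed-averaged series is then
    fitted with the power law and solved for the 50%-free point.  A fit
    that cannot cross 0.5 (non-decreasing series) is reported in
    ``cmc_error`` instead of raising.
    """
    if params is None:
        params = default_engine_params()
    all_seeds = _spawn_seeds(seed, n_seeds * len(concentrations_mM))
    fractions = np.empty((len(concentrations_mM), n_seeds))
    for rep in range(n_seeds):
        seeds = all_seeds[rep * len(concentrations_mM) : (rep + 1) * len(concentrations_mM)]
        runs = simulate_concentration_series(
            chain_id,
            list(concentrations_mM),
            params,
            seeds,
            box,
            fraction_deprotonated=fraction_deprotonated,
            ionic_strength_mM=ionic_strength_mM,
        )
        for ci, (_conc, traj) in enumerate(runs):
            point = free_fraction(
                traj, size_cutoff=size_cutoff, n_snapshots=n_snapshots
            )
            fractions[ci, rep] = point.mean_free_fraction

    points = [
        FreeFractionPoint(
            concentration_mM=float(c),
            mean_free_fraction=float(fractions[ci].mean()),
            sd=float(fractions[ci].std(ddof=1)) if n_seeds > 1 else 0.0,
            n_snapshots=n_snapshots * n_seeds,
        )
        for ci, c in enumerate(concentrations_mM)
    ]
    cmc = None
    cmc_error = None
    try:
        fit = fit_free_fraction(points)
        cmc = cmc_from_free_fraction(fit)
    except Exception as err:  # captured, not raised: study reports the failure
        cmc_error = f"{type(err).__name__}: {err}"
    return ConcentrationStudy(
        chain_id=chain_id,
        concentrations_mM=tuple(float(c) for c in concentrations_mM),
        points=points,
        replicate_fractions=fractions,
        cmc=cmc,
        cmc_error=cmc_error,
    )


def repulsive_control_free_fraction(
    seed: int,
    concentration_mM: float = 90.0,
    n_seeds: int = 3,
    chain_id: str = "C10",
    box: BoxSpec = DEFAULT_BOX,
    params: Optional[EngineParams] = None,
    size_cutoff: int = 5,
    n_snapshots: int = 20,
) -> float:
    """Mean late-window free fraction with every attractive well removed.

    The LJ term is truncated at its minimum (WCA form) so beads only
    repel; without hydrophobic attraction essentially all molecules should
    stay free.
    """
    if params is None:
        params = default_engine_params()
    params = replace(params, repulsive_only=True)
    topology = build_topology(chain_id, deprotonated=True)
    comp = build_composition(chain_id, concentration_mM, 1.0, 140.0, box)
    seeds = _spawn_seeds(seed + 1, n_seeds)
    vals = []
    for s in seeds:
        traj = run_selfassembly(comp, topology, replace(params, seed=s))
        vals.append(
            free_fraction(traj, size_cutoff=size_cutoff, n_snapshots=n_snapshots).mean_free_fraction
        )
    return float(np.mean(vals))
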