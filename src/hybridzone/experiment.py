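"""Replicate grids of hybrid-zone scenarios and their movement summaries.

The default grid crosses the three scenario knobs — one or two mating-trait
loci, heterospecific:homospecific acceptance ratio 0.5 or 0.75, dominance
coefficient 0.5 or 0.75 — into eight scenarios.  Each scenario is run as a
set of seeded replicates; at the final generation a mating-trait cline and
a pooled neutral cline are fitted per replicate, the mating center is
classified RH/S/DH, and movement is summarized across replicates:
per-class frequencies, the signed mating-neutral displacement, and a paired
one-sided Wilcoxon test on the replicates whose mating cline moved toward
the dominant homozygote (DH).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from . import clines
from .params import SimulationParams
from .simulator import Trajectory, run_simulation

__all__ = [
    "ScenarioResult",
    "GridSummary",
    "default_grid",
    "scenario_label",
    "run_scenario",
    "run_default_grid",
    "summarize_grid",
]

logger = logging.getLogger(__name__)

MIN_WILCOXON_N = 3
ALPHA = 0.05  # threshold for calling a displacement significant


def scenario_label(params: SimulationParams) -> str:
    return (f"L{params.n_mating_loci}"
            f"_r{params.pref_ratio:g}"
            f"_d{params.dominance:g}")


def default_grid(**overrides) -> List[SimulationParams]:
    """The eight-scenario grid: 2 loci counts x 2 ratios x 2 dominances."""
    grid = []
    for n_loci, ratio, dom in itertools.product((1, 2), (0.5, 0.75),
                                                (0.5, 0.75)):
        grid.append(SimulationParams(n_mating_loci=n_loci, pref_ratio=ratio,
                                     dominance=dom, **overrides))
    return grid


@dataclass
class ScenarioResult:
    """Per-replicate cline summaries for one scenario."""

    params: SimulationParams
    replicates: pd.DataFrame          # one row per replicate
    trajectories: Optional[pd.DataFrame] = None  # center per snapshot
    n_extinct: int = 0

    @property
    def label(self) -> str:
        return scenario_label(self.params)


@dataclass
class GridSummary:
    """Movement-class frequencies and displacement tests across scenarios."""

    per_scenario: pd.DataFrame
    pooled_dh_fraction: float
    pooled_dh_wilcoxon_p: float
    n_replicates_total: int
    n_dh_total: int


def _summarize_final(traj: Trajectory, cline_kwargs: dict) -> dict:
    snap = traj.final
    rows = {}
    for cls in ("mating", "neutral"):
        pts = clines.allele_frequency_points(snap, cls)
        fit = clines.fit_cline(pts, **cline_kwargs)
        rows[f"center_{cls}"] = fit.center_
        rows[f"width_{cls}"] = fit.width_
        rows[f"width_flagged_{cls}"] = fit.width_flagged_
    rows["movement_class"] = clines.classify_movement(rows["center_mating"])
    rows["displacement"] = clines.displacement(rows["center_mating"],
                                               rows["center_neutral"])
    return rows


def run_scenario(params: SimulationParams, n_replicates: int,
                 base_seed: int, fit_trajectory: bool = False,
                 **cline_kwargs) -> ScenarioResult:
    """Run seeded replicates of one scenario and fit final clines.

    Replicate seeds are ``base_seed + i`` (recorded per row).  Extinct
    replicates are logged and excluded from the summary rows.  With
    ``fit_trajectory=True``, mating and neutral centers are additionally
    extracted at every recorded snapshot (slower; used for center-over-time
    plots, not for the movement summaries).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows, traj_rows = [], []
    n_extinct = 0
    for i in range(n_replicates):
        seed = int((base_seed + i) % (2**31 - 1))
        rep_params = params.replace(seed=seed)
        traj = run_simulation(rep_params)
        if traj.extinct:
            n_extinct += 1
            logger.warning("replicate %d (seed %d) went extinct at "
                           "generation %d; excluded", i, seed,
                           traj.snapshots[-1].generation)
            continue
        row = {"replicate": i, "seed": seed,
               "generation": traj.final.generation,
               "params_hash": rep_params.params_hash()}
        row.update(_summarize_final(traj, cline_kwargs))
        rows.append(row)
        if fit_trajectory:
            for snap in traj.snapshots:
                for cls in ("mating", "neutral"):
                    pts = clines.allele_frequency_points(snap, cls)
                    fit = clines.fit_cline(pts, **cline_kwargs)
                    traj_rows.append({"replicate": i,
                                      "generation": snap.generation,
                                      "locus_class": cls,
                                      "center": fit.center_,
                                      "width": fit.width_})
    replicates = pd.DataFrame(rows)
    trajectories = pd.DataFrame(traj_rows) if fit_trajectory else None
    return ScenarioResult(params=params, replicates=replicates,
                          trajectories=trajectories, n_extinct=n_extinct)


def run_default_grid(n_replicates: int, base_seed: int,
                     fit_trajectory: bool = False,
                     **cline_kwargs) -> List[ScenarioResult]:
    """Run every scenario of the default grid with scenario-offset seeds.

    Scenario ``i`` uses replicate seeds ``base_seed + 1000 * i + j`` so no
    two replicates anywhere in the grid share a seed (for grids of up to
    1000 replicates per scenario).
    """
    results = []
    for i, params in enumerate(default_grid()):
        logger.info("scenario %s", scenario_label(params))
        results.append(run_scenario(params, n_replicates,
                                    base_seed + 1000 * i,
                                    fit_trajectory=fit_trajectory,
                                    **cline_kwargs))
    return results


def summarize_grid(results: List[ScenarioResult]) -> GridSummary:
    """Movement-class frequencies, displacements and Wilcoxon tests.

    Per scenario: RH/S/DH frequencies of final mating-cline centers, the
    mean and SD of |displacement|, and a paired one-sided Wilcoxon test
    (mating center > neutral center) restricted to DH replicates (reported
    as NaN when fewer than 3 replicates are DH).  Pooled across scenarios:
    the overall DH fraction and the same Wilcoxon test on all DH replicates.
    """
    if not results:
        raise ValueError("no scenario results")
    rows = []
    dh_mating, dh_neutral = [], []
    n_total = 0
    n_dh = 0
    for res in results:
        rep = res.replicates
        n = len(rep)
        n_total += n
        counts = rep["movement_class"].value_counts()
        dh = rep[rep["movement_class"] == "DH"]
        n_dh += len(dh)
        dh_mating.append(dh["center_mating"].to_numpy())
        dh_neutral.append(dh["center_neutral"].to_numpy())
        if len(dh) >= MIN_WILCOXON_N:
            p = clines.wilcoxon_displacement_test(dh["center_mating"],
                                                  dh["center_neutral"])
        else:
            p = np.nan
        rows.append({
            "scenario": res.label,
            "n_mating_loci": res.params.n_mating_loci,
            "pref_ratio": res.params.pref_ratio,
            "dominance": res.params.dominance,
            "n_replicates": n,
            "n_extinct": res.n_extinct,
            "freq_RH": counts.get("RH", 0) / n if n else np.nan,
            "freq_S": counts.get("S", 0) / n if n else np.nan,
            "freq_DH": counts.get("DH", 0) / n if n else np.nan,
            "mean_abs_displacement": rep["displacement"].abs().mean(),
            "sd_abs_displacement": rep["displacement"].abs().std(),
            "mean_dh_displacement": dh["displacement"].mean(),
            "wilcoxon_p_dh": p,
            "significant": bool(p < ALPHA) if np.isfinite(p) else False,
        })
    dh_m = np.concatenate(dh_mating)
    dh_n = np.concatenate(dh_neutral)
    pooled_p = (clines.wilcoxon_displacement_test(dh_m, dh_n)
                if dh_m.size >= MIN_WILCOXON_N else np.nan)
    return GridSummary(per_scenario=pd.DataFrame(rows),
                       pooled_dh_fraction=n_dh / n_total if n_total else np.nan,
                       pooled_dh_wilcoxon_p=pooled_p,
                       n_replicates_total=n_total,
                       n_dh_total=n_dh)


def write_scenario(result: ScenarioResult, outdir: str | Path) -> Path:
    """Write per-replicate rows (and trajectories if fitted) as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"scenario_{result.label}.tsv"
    result.replicates.to_csv(path, sep="\t", index=False)
    if result.trajectories is not None:
        result.trajectories.to_csv(
            outdir / f"scenario_{result.label}_trajectory.tsv",
            sep="\t", index=False)
    return path


def write_grid_summary(summary: GridSummary, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "grid_summary.tsv"
    summary.per_scenario.to_csv(path, sep="\t", index=False)
    return path
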