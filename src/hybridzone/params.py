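"""Scenario parameterization for the hybrid-zone simulator.

A scenario is fully described by :class:`SimulationParams`: the genetic
architecture of the mating trait (number of loci, dominance coefficient),
the strength of assortative mating (the heterospecific:homospecific
acceptance ratio), demography (per-species carrying capacity, low-density
growth rate, density-dependence kernel width), dispersal, the initial
ranges of the two parental populations on the unit transect, and run
length/bookkeeping settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import yaml

__all__ = ["SimulationParams", "load_params"]


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one hybrid-zone simulation scenario.

    Parameters
    ----------
    n_mating_loci : int
        Number of loci underlying the mating trait (1 or 2).
    n_neutral_loci : int
        Number of selectively neutral marker loci.
    pref_ratio : float
        Ratio of heterospecific to homospecific matings, in (0, 1].  A
        maximally different male (trait difference 1) is accepted at
        exactly this multiple of the rate of an identical male; 1 means
        random mating.
    dominance : float
        Dominance coefficient in [0, 1]: the proportion of the dominant
        homozygote's phenotype expressed by a heterozygote (0.5 is
        codominance, 1 is complete dominance).
    carrying_capacity_per_species : int
        K per parental species; total transect capacity is 2K.
    growth_rate : float
        Low-density per-generation growth multiplier R.
    density_sd : float
        SD of the Gaussian kernel used to measure local density, in
        transect-length units.
    dispersal_sd : float
        SD of natal dispersal and of the mate-encounter kernel, in
        transect-length units.
    range_a, range_b : (float, float)
        Initial range limits of the recessive-allele (A) and
        dominant-allele (B) species on the unit transect.
    n_generations : int
        Number of non-overlapping generations to simulate.
    snapshot_interval : int
        Record a population snapshot every this many generations.
    hybrid_fitness : float
        Multiplier on expected offspring number; 1 means no loss of
        hybrid fitness.
    max_mate_rejections : int
        A female stops searching after this many rejected candidates and
        leaves no offspring that generation.
    seed : int
        RNG seed for the replicate.
    """

    n_mating_loci: int = 1
    n_neutral_loci: int = 3
    pref_ratio: float = 0.5
    dominance: float = 0.75
    carrying_capacity_per_species: int = 800
    growth_rate: float = 1.05
    density_sd: float = 0.01
    dispersal_sd: float = 0.01
    range_a: Tuple[float, float] = (0.0, 0.48)
    range_b: Tuple[float, float] = (0.52, 1.0)
    n_generations: int = 500
    snapshot_interval: int = 5
    hybrid_fitness: float = 1.0
    max_mate_rejections: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.pref_ratio <= 1.0):
            raise ValueError("pref_ratio must be in (0, 1]")
        if not (0.0 <= self.dominance <= 1.0):
            raise ValueError("dominance must be in [0, 1]")
        for name in ("n_mating_loci", "n_neutral_loci",
                     "carrying_capacity_per_species", "snapshot_interval",
                     "max_mate_rejections"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.density_sd <= 0 or self.dispersal_sd < 0:
            raise ValueError("kernel SDs must be positive")
        if self.growth_rate <= 0 or self.hybrid_fitness < 0:
            raise ValueError("growth_rate and hybrid_fitness must be positive")
        a, b = self.range_a, self.range_b
        if not (0.0 <= a[0] < a[1] <= b[0] < b[1] <= 1.0):
            raise ValueError(
                "range_a and range_b must be disjoint ordered sub-intervals "
                "of [0, 1] with range_a to the left")

    def replace(self, **kwargs) -> "SimulationParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["range_a"] = list(d["range_a"])
        d["range_b"] = list(d["range_b"])
        return d

    def params_hash(self) -> str:
        """Stable short hash of the full parameterization (incl. seed)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_FIELD_NAMES = {f.name for f in dataclasses.fields(SimulationParams)}


def load_params(path: str | Path, **overrides) -> SimulationParams:
    """Load a scenario configuration from a YAML file.

    Keys must match :class:`SimulationParams` field names; unknown keys
    are rejected so that typos do not silently fall back to defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    unknown = set(raw) - _FIELD_NAMES
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    raw.update(overrides)
    for key in ("range_a", "range_b"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SimulationParams(**raw)
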