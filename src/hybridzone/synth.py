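"""Synthetic genotype, phenotype and transect generators.

Everything the analysis stages consume can be generated here:

* diagnostic-SNP genotypes for the standard cross classes (parentals, F1,
  F2, backcrosses) under a two-block architecture — 43 loci on chromosome
  1A and 49 in the chromosome-20 / ASIP block, fixed for alternative
  alleles in the parental populations, with a small within-block
  recombination probability per adjacent-locus interval and free
  recombination between blocks, plus independent missingness;
* continuous phenotypes from the region-class lookup mechanism (or a pure
  additive control), on an ordered white-plumage scale with Gaussian noise;
* transect genotype samples drawn from a logistic cline of known center
  and width, for exercising the cline-fitting stage;
* plumage-class labels drawn at the frequencies observed in the contact
  zone (33% alba, 29% personata, 20% alba-like, 4% intermediate, 14%
  personata-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import inheritance
from .clines import ClinePoints
from .inheritance import (DEFAULT_REGION_SIZES, DiagnosticGenotypes,
                          PLUMAGE_CLASSES, UNOBSERVED, classify_individuals)

__all__ = [
    "CrossSpec",
    "PhenotypeSpec",
    "CROSS_CLASSES",
    "HYBRID_ZONE_COMPOSITION",
    "simulate_cross_genotypes",
    "simulate_phenotypes",
    "simulate_inheritance_dataset",
    "simulate_transect_sample",
    "sample_hybrid_zone_composition",
]

CROSS_CLASSES = ("P_alba", "P_personata", "F1", "F2",
                 "BC_alba", "BC_personata")

# observed plumage-class frequencies in the contact zone (n = 104 birds)
HYBRID_ZONE_COMPOSITION = {
    "alba": 0.33,
    "personata": 0.29,
    "alba_like_hybrid": 0.20,
    "intermediate": 0.04,
    "personata_like_hybrid": 0.14,
}


@dataclass
class CrossSpec:
    """How many individuals of each cross class to simulate.

    ``recombination`` is the per-meiosis probability of switching source
    haplotype between adjacent loci within a block (default 0.005, so each
    block mostly segregates as a unit while occasionally producing
    recombinant genotypes); blocks assort independently.
    """

    counts: Dict[str, int]
    loci_per_region: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REGION_SIZES))
    recombination: float = 0.005
    missingness: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(CROSS_CLASSES)
        if unknown:
            raise ValueError(f"unknown cross classes: {sorted(unknown)}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be >= 0")
        if not (0.0 <= self.recombination <= 0.5):
            raise ValueError("recombination must be in [0, 0.5]")
        if not (0.0 <= self.missingness < 1.0):
            raise ValueError("missingness must be in [0, 1)")


@dataclass
class PhenotypeSpec:
    """Plumage-class means on a white-pixel-like scale, plus noise.

    The absolute numbers are an arbitrary ordered scale; more white plumage
    means a larger value, and the means must be strictly ordered
    alba > alba-like > intermediate > personata-like > personata.
    """

    class_means: Dict[str, float] = field(default_factory=lambda: {
        "alba": 100.0,
        "alba_like_hybrid": 75.0,
        "intermediate": 50.0,
        "personata_like_hybrid": 25.0,
        "personata": 0.0,
    })
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        means = [self.class_means[c] for c in PLUMAGE_CLASSES]
        if not all(a > b for a, b in zip(means, means[1:])):
            raise ValueError("class means must be strictly decreasing from "
                             "alba to personata")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def scale_range(self) -> float:
        return self.class_means["alba"] - self.class_means["personata"]


def _gametes(hap_a: np.ndarray, hap_b: np.ndarray, r: float,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete per row: copy from hap_a/hap_b with switch prob r."""
    n, loci = hap_a.shape
    start = rng.integers(0, 2, size=(n, 1))
    if loci > 1:
        switches = (rng.random((n, loci - 1)) < r).astype(np.int64)
        sel = (start + np.concatenate(
            [np.zeros((n, 1), np.int64), np.cumsum(switches, axis=1)],
            axis=1)) % 2
    else:
        sel = start
    return np.where(sel == 0, hap_a, hap_b)


def _class_region_dosages(cls: str, n: int, loci: int, r: float,
                          rng: np.random.Generator) -> np.ndarray:
    zeros = np.zeros((n, loci), np.int8)
    ones = np.ones((n, loci), np.int8)
    if cls == "P_alba":
        return zeros + zeros
    if cls == "P_personata":
        return ones + ones
    if cls == "F1":
        return zeros + ones
    # gametes from an F1 parent (haplotypes all-0 and all-1)
    g1 = _gametes(zeros, ones, r, rng)
    if cls == "F2":
        g2 = _gametes(zeros, ones, r, rng)
    elif cls == "BC_alba":
        g2 = zeros
    elif cls == "BC_personata":
        g2 = ones
    else:
        raise ValueError(f"unknown cross class {cls!r}")
    return (g1 + g2).astype(np.int8)


def simulate_cross_genotypes(spec: CrossSpec,
                             rng: Optional[np.random.Generator] = None,
                             ) -> DiagnosticGenotypes:
    """Diagnostic-SNP dosage matrix for the requested cross classes.

    Parental haplotypes are all-0 (alba) or all-1 (personata) across each
    block, so F1s are heterozygous at every locus; F2 and backcross
    genotypes recombine within blocks at rate ``spec.recombination`` per
    interval and assort blocks independently.  Missing entries (NaN) are
    assigned independently at ``spec.missingness``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    columns, region_labels = [], []
    for region in sorted(spec.loci_per_region):
        loci = spec.loci_per_region[region]
        columns += [f"{region}_{i + 1:03d}" for i in range(loci)]
        region_labels += [region] * loci
    blocks, classes = [], []
    for cls in CROSS_CLASSES:
        n = spec.counts.get(cls, 0)
        if n == 0:
            continue
        per_region = [
            _class_region_dosages(cls, n, spec.loci_per_region[region],
                                  spec.recombination, rng)
            for region in sorted(spec.loci_per_region)
        ]
        blocks.append(np.concatenate(per_region, axis=1).astype(float))
        classes += [cls] * n
    if not blocks:
        raise ValueError("no individuals requested")
    matrix = np.concatenate(blocks, axis=0)
    if spec.missingness > 0:
        matrix[rng.random(matrix.shape) < spec.missingness] = np.nan
    index = pd.RangeIndex(matrix.shape[0], name="individual")
    dosages = pd.DataFrame(matrix, index=index, columns=columns)
    return DiagnosticGenotypes(dosages=dosages,
                               regions=pd.Series(region_labels,
                                                 index=columns),
                               cross_class=pd.Series(classes, index=index))


def simulate_phenotypes(genotypes: DiagnosticGenotypes,
                        pspec: Optional[PhenotypeSpec] = None,
                        rng: Optional[np.random.Generator] = None,
                        mechanism: str = "lookup",
                        classes: Optional[pd.DataFrame] = None) -> pd.Series:
    """Continuous phenotypes from classified region genotypes.

    ``mechanism='lookup'`` applies the dominance/epistasis class lookup;
    ``'additive'`` is the control where the expectation interpolates
    linearly between the alba and personata means in the mean of the two
    regions' additive scores.  Individuals that are unclassifiable, or that
    fall in the never-observed (AA, PP) cell under the lookup, get NaN.
    """
    if pspec is None:
        pspec = PhenotypeSpec()
    if rng is None:
        rng = np.random.default_rng(pspec.seed)
    if classes is None:
        classes = classify_individuals(genotypes)
    means = np.full(len(classes), np.nan)
    if mechanism == "lookup":
        for i, plumage in enumerate(classes["plumage_class"]):
            if plumage is not None and plumage != UNOBSERVED:
                means[i] = pspec.class_means[plumage]
    elif mechanism == "additive":
        score = (classes["chr20_class"].map(inheritance._ADDITIVE_SCORE)
                 + classes["chr1A_class"].map(
                     inheritance._ADDITIVE_SCORE)).to_numpy(float) / 2.0
        top = pspec.class_means["alba"]
        means = top - pspec.scale_range * score
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    excluded = classes["excluded"].to_numpy(bool)
    means[excluded] = np.nan
    noise = rng.normal(0.0, 1.0, size=means.shape) * pspec.noise_sd
    values = np.where(np.isnan(means), np.nan, means + noise)
    return pd.Series(values, index=classes.index, name="phenotype")


def simulate_inheritance_dataset(n: int, cross: str = "F2",
                                 pspec: Optional[PhenotypeSpec] = None,
                                 recombination: float = 0.005,
                                 missingness: float = 0.03,
                                 mechanism: str = "lookup",
                                 rng: Optional[np.random.Generator] = None,
                                 ) -> tuple[pd.DataFrame, pd.Series]:
    """Classified individuals + phenotypes, resampled to ``n`` valid rows.

    Individuals that are unclassifiable or land in the never-observed
    genotype cell are discarded and redrawn, so the returned dataset has
    exactly ``n`` usable rows.
    """
    if pspec is None:
        pspec = PhenotypeSpec()
    if rng is None:
        rng = np.random.default_rng(pspec.seed)
    kept_classes, kept_pheno = [], []
    total = 0
    while total < n:
        batch = max(n - total, 32)
        spec = CrossSpec(counts={cross: int(batch * 1.5)},
                         recombination=recombination,
                         missingness=missingness)
        geno = simulate_cross_genotypes(spec, rng)
        classes = classify_individuals(geno)
        pheno = simulate_phenotypes(geno, pspec, rng, mechanism=mechanism,
                                    classes=classes)
        ok = pheno.notna()
        classes, pheno = classes.loc[ok], pheno.loc[ok]
        take = min(len(pheno), n - total)
        kept_classes.append(classes.iloc[:take])
        kept_pheno.append(pheno.iloc[:take])
        total += take
    classes = pd.concat(kept_classes, ignore_index=True)
    pheno = pd.concat(kept_pheno, ignore_index=True)
    return classes, pheno


def simulate_transect_sample(center: float, width: float, n: int,
                             rng: np.random.Generator,
                             locus_class: str = "mating") -> ClinePoints:
    """Genotype sample from a logistic cline of known center and width.

    Locations are uniform on [0, 1]; the per-individual dosage is
    Binomial(2, p(x)) with ``p(x) = 1 / (1 + exp(-4 (x - center) / width))``
    (slope parameterization whose 0.1-0.9 crossing span is
    ``width * ln(9) / 2``).
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    if n < 20:
        raise ValueError("need n >= 20")
    x = rng.uniform(0.0, 1.0, size=n)
    p = 1.0 / (1.0 + np.exp(-4.0 * (x - center) / width))
    freq = rng.binomial(2, p) / 2.0
    return ClinePoints(x, freq, locus_class)


def sample_hybrid_zone_composition(n: int, rng: np.random.Generator,
                                   ) -> np.ndarray:
    """Plumage-class labels at the observed contact-zone frequencies."""
    if n < 1:
        raise ValueError("n must be >= 1")
    labels = np.array(list(HYBRID_ZONE_COMPOSITION))
    probs = np.array(list(HYBRID_ZONE_COMPOSITION.values()))
    return labels[rng.choice(len(labels), size=n, p=probs)]
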