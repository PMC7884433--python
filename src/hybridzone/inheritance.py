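"""Two-region inheritance analysis of a continuous plumage phenotype.

Individuals carry dosages of personata-type alleles at diagnostic SNPs in
two genomic regions (a block on chromosome 1A and the ASIP block on
chromosome 20).  Per region we compute a hybrid index (mean dosage / 2)
and interclass heterozygosity (fraction of loci heterozygous), classify
the region as alba-type, heterozygous, or personata-type, and map the pair
of region classes to an expected plumage class through a deterministic
lookup (the dominance/epistasis mechanism):

=========  =====  ======================  ==============
chr20      chr1A  plumage                 note
=========  =====  ======================  ==============
AA or Ap   aa     alba                    alba allele dominant at ASIP
AA or Ap   aP     alba-like hybrid
Ap         PP     intermediate
AA         PP     (unobserved)            sentinel, never a phenotype
pp         aa     personata-like hybrid
pp         aP     personata               1A het masked by pp
pp         PP     personata
=========  =====  ======================  ==============

For a formal test, linear models encoding additive/codominant, completely
dominant, or partially dominant (free heterozygote level) inheritance at
each region, with or without a single epistatic product term, are fit by
OLS and ranked by the small-sample-corrected Akaike criterion (AICc).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

__all__ = [
    "DiagnosticGenotypes",
    "InheritanceModelReport",
    "InheritanceModelSelector",
    "hybrid_index",
    "interclass_heterozygosity",
    "classify_region_genotype",
    "classify_individuals",
    "phenotype_class_lookup",
    "build_model_designs",
    "fit_and_compare",
]

logger = logging.getLogger(__name__)

REGIONS = ("chr1A", "chr20")
DEFAULT_REGION_SIZES = {"chr1A": 43, "chr20": 49}

# region-class alphabets; capital letters mark the (partially) dominant allele
CHR20_CLASSES = {"alba": "AA", "het": "Ap", "personata": "pp"}
CHR1A_CLASSES = {"alba": "aa", "het": "aP", "personata": "PP"}

PLUMAGE_CLASSES = ("alba", "alba_like_hybrid", "intermediate",
                   "personata_like_hybrid", "personata")
UNOBSERVED = "unobserved"

# per-region numeric scores used by the model encodings
_ADDITIVE_SCORE = {"alba": 0.0, "het": 0.5, "personata": 1.0}
# alba allele dominant at chr20; personata allele dominant at chr1A
_COMPLETE_SCORE = {
    "chr20": {"alba": 0.0, "het": 0.0, "personata": 1.0},
    "chr1A": {"alba": 0.0, "het": 1.0, "personata": 1.0},
}

DEFAULT_ALBA_MAX = 0.25
DEFAULT_PERSONATA_MIN = 0.75
DEFAULT_MAX_MISSING = 0.5


@dataclass
class DiagnosticGenotypes:
    """Individuals x diagnostic-SNP dosage matrix with region labels.

    ``dosages`` holds counts of personata-type alleles (0/1/2, NaN for
    missing); ``regions`` labels every locus column as 'chr1A' or 'chr20'.
    """

    dosages: pd.DataFrame
    regions: pd.Series
    cross_class: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.regions = pd.Series(self.regions, index=self.dosages.columns)
        unknown = set(self.regions.unique()) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown region labels: {sorted(unknown)}")
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0/1/2 or missing")

    def region_dosages(self, region: str) -> pd.DataFrame:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        return self.dosages.loc[:, self.regions == region]

    def missing_fraction(self) -> pd.Series:
        return self.dosages.isna().mean(axis=1)


def _as_matrix(dosages) -> np.ndarray:
    a = np.asarray(dosages, dtype=float)
    return a.reshape(1, -1) if a.ndim == 1 else a


def hybrid_index(dosages) -> np.ndarray | float:
    """Composite genotype scaled 0 (alba) to 1 (personata).

    Mean personata-allele dosage over non-missing loci, divided by 2;
    NaN when every locus is missing.  Accepts one individual (1-D) or a
    matrix (rows = individuals).
    """
    a = _as_matrix(dosages)
    if a.shape[1] == 0:
        raise ValueError("no loci")
    with np.errstate(invalid="ignore"):
        hi = np.nanmean(a, axis=1) / 2.0
    return float(hi[0]) if np.asarray(dosages).ndim == 1 else hi


def interclass_heterozygosity(dosages) -> np.ndarray | float:
    """Fraction of non-missing diagnostic loci that are heterozygous."""
    a = _as_matrix(dosages)
    if a.shape[1] == 0:
        raise ValueError("no loci")
    non_missing = (~np.isnan(a)).sum(axis=1)
    het = np.nansum(a == 1.0, axis=1)
    with np.errstate(invalid="ignore"):
        out = np.where(non_missing > 0, het / non_missing, np.nan)
    return float(out[0]) if np.asarray(dosages).ndim == 1 else out


def classify_region_genotype(hi: float, het: Optional[float] = None,
                             alba_max: float = DEFAULT_ALBA_MAX,
                             personata_min: float = DEFAULT_PERSONATA_MIN,
                             ) -> Optional[str]:
    """Classify a region composite as 'alba', 'het' or 'personata'.

    Alba-type if HI <= ``alba_max``, personata-type if HI >= ``personata_min``,
    otherwise the heterozygote class.  ``het`` is carried for plotting and
    exclusion rules; the default classification uses HI alone.  Undefined
    (NaN) HI returns None.
    """
    if hi is None or np.isnan(hi):
        return None
    if not (0.0 <= hi <= 1.0):
        raise ValueError("hybrid index outside [0, 1]")
    if hi <= alba_max:
        return "alba"
    if hi >= personata_min:
        return "personata"
    return "het"


def phenotype_class_lookup(chr20_class: str, chr1A_class: str) -> str:
    """Expected plumage class for a pair of region genotype classes.

    Accepts either the generic labels ('alba', 'het', 'personata') or the
    allele-letter labels ('AA'/'Ap'/'pp' for chr20, 'aa'/'aP'/'PP' for
    chr1A).  The (AA, PP) combination was never observed and returns the
    explicit 'unobserved' sentinel rather than a phenotype.
    """
    rev20 = {v: k for k, v in CHR20_CLASSES.items()}
    rev1a = {v: k for k, v in CHR1A_CLASSES.items()}
    c20 = rev20.get(chr20_class, chr20_class)
    c1a = rev1a.get(chr1A_class, chr1A_class)
    if c20 not in _ADDITIVE_SCORE or c1a not in _ADDITIVE_SCORE:
        raise ValueError(f"invalid region classes ({chr20_class!r}, "
                         f"{chr1A_class!r})")
    if c20 in ("alba", "het"):
        if c1a == "alba":
            return "alba"
        if c1a == "het":
            return "alba_like_hybrid"
        return UNOBSERVED if c20 == "alba" else "intermediate"
    # personata-type ASIP masks the 1A heterozygote
    return "personata_like_hybrid" if c1a == "alba" else "personata"


def classify_individuals(genotypes: DiagnosticGenotypes,
                         alba_max: float = DEFAULT_ALBA_MAX,
                         personata_min: float = DEFAULT_PERSONATA_MIN,
                         max_missing: float = DEFAULT_MAX_MISSING,
                         ) -> pd.DataFrame:
    """Per-individual composites, region classes and predicted plumage.

    Individuals with more than ``max_missing`` missing genotypes or with an
    unclassifiable region are marked ``excluded`` (the generalization of
    dropping ambiguous recombinant individuals).
    """
    rows = {}
    rows["hybrid_index"] = hybrid_index(genotypes.dosages.to_numpy(float))
    rows["heterozygosity"] = interclass_heterozygosity(
        genotypes.dosages.to_numpy(float))
    for region in REGIONS:
        sub = genotypes.region_dosages(region).to_numpy(float)
        rows[f"hi_{region}"] = hybrid_index(sub)
        rows[f"het_{region}"] = interclass_heterozygosity(sub)
    df = pd.DataFrame(rows, index=genotypes.dosages.index)
    df["missing_fraction"] = genotypes.missing_fraction()

    for region, alphabet in (("chr20", CHR20_CLASSES),
                             ("chr1A", CHR1A_CLASSES)):
        generic = [classify_region_genotype(hi, alba_max=alba_max,
                                            personata_min=personata_min)
                   for hi in df[f"hi_{region}"]]
        df[f"{region}_class"] = [None if g is None else g for g in generic]
        df[f"{region}_label"] = [None if g is None else alphabet[g]
                                 for g in generic]
    df["plumage_class"] = [
        phenotype_class_lookup(c20, c1a)
        if c20 is not None and c1a is not None else None
        for c20, c1a in zip(df["chr20_class"], df["chr1A_class"])
    ]
    df["excluded"] = (
        df["chr20_class"].isna() | df["chr1A_class"].isna()
        | (df["missing_fraction"] > max_missing)
    )
    return df


# ---------------------------------------------------------------------------
# model comparison

MODES = ("additive", "complete", "partial")


def _region_columns(mode: str, region: str,
                    classes: pd.Series) -> Dict[str, np.ndarray]:
    if mode == "additive":
        return {f"{region}_additive":
                classes.map(_ADDITIVE_SCORE).to_numpy(float)}
    if mode == "complete":
        return {f"{region}_dominant":
                classes.map(_COMPLETE_SCORE[region]).to_numpy(float)}
    if mode == "partial":
        return {
            f"{region}_het": (classes == "het").to_numpy(float),
            f"{region}_hom": (classes == "personata").to_numpy(float),
        }
    raise ValueError(f"unknown inheritance mode {mode!r}")


def model_name(mode20: str, mode1A: str, epistasis: bool) -> str:
    return (f"chr20-{mode20}_chr1A-{mode1A}"
            f"{'_epistasis' if epistasis else ''}")


def build_model_designs(classes: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Numeric design matrices (without intercept) for every model.

    ``classes`` must carry generic region classes in columns
    ``chr20_class`` and ``chr1A_class``.  Eighteen models are enumerated
    (3 inheritance modes per region x with/without epistasis) plus an
    intercept-only null.  The epistasis term is always the product of the
    two regions' additive 0/0.5/1 scores — a single interaction degree of
    freedom, whichever main-effect encoding it accompanies.
    """
    for col in ("chr20_class", "chr1A_class"):
        if col not in classes:
            raise ValueError(f"missing column {col!r}")
    valid = classes[["chr20_class", "chr1A_class"]].notna().all(axis=1)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("excluding %d unclassified individuals", n_dropped)
    sub = classes.loc[valid]
    s20 = sub["chr20_class"].map(_ADDITIVE_SCORE).to_numpy(float)
    s1a = sub["chr1A_class"].map(_ADDITIVE_SCORE).to_numpy(float)
    designs: Dict[str, pd.DataFrame] = {
        "intercept_only": pd.DataFrame(index=sub.index)
    }
    for mode20, mode1a, epi in itertools.product(MODES, MODES,
                                                 (False, True)):
        cols: Dict[str, np.ndarray] = {}
        cols.update(_region_columns(mode20, "chr20", sub["chr20_class"]))
        cols.update(_region_columns(mode1a, "chr1A", sub["chr1A_class"]))
        if epi:
            cols["epistasis"] = s20 * s1a
        designs[model_name(mode20, mode1a, epi)] = pd.DataFrame(
            cols, index=sub.index)
    return designs


@dataclass
class InheritanceModelReport:
    """Ranked fit statistics plus the winning model's term effects."""

    table: pd.DataFrame                 # one row per model, sorted by AICc
    best_model: str
    coefficients: pd.Series             # winning model's term estimates
    skipped: Dict[str, str] = field(default_factory=dict)

    @property
    def winner_row(self) -> pd.Series:
        return self.table.loc[self.table["model"] == self.best_model].iloc[0]


def _aicc(result, n: int) -> float:
    # number of estimated parameters including the residual variance
    k = result.df_model + 1 + 1
    aic = -2.0 * result.llf + 2.0 * k
    return float(aic + 2.0 * k * (k + 1) / (n - k - 1))


class InheritanceModelSelector(BaseEstimator):
    """OLS comparison of two-locus inheritance models, ranked by AICc.

    fit(X, y) with ``X`` a DataFrame holding generic region classes
    (columns ``chr20_class`` and ``chr1A_class``) and ``y`` the continuous
    phenotype.  Rows with a missing class or phenotype are dropped.

    Fitted attributes: ``report_`` (:class:`InheritanceModelReport`),
    ``best_model_``, ``best_result_`` (statsmodels results),
    ``coefficients_``.
    """

    def fit(self, X: pd.DataFrame, y) -> "InheritanceModelSelector":
        y = pd.Series(np.asarray(y, dtype=float), index=X.index)
        keep = (X[["chr20_class", "chr1A_class"]].notna().all(axis=1)
                & y.notna())
        X, y = X.loc[keep], y.loc[keep]
        designs = build_model_designs(X)
        max_p = max(d.shape[1] for d in designs.values()) + 1
        if len(y) <= max_p + 2:
            raise ValueError(
                f"need more than {max_p + 2} classified individuals")
        rows, skipped, fits = [], {}, {}
        for name, design in designs.items():
            exog = sm.add_constant(design.to_numpy(float), has_constant="add")
            if np.linalg.matrix_rank(exog) < exog.shape[1]:
                skipped[name] = "rank-deficient design (empty class cell?)"
                continue
            res = sm.OLS(y.to_numpy(float), exog).fit()
            fits[name] = (res, ["const"] + list(design.columns))
            rows.append({
                "model": name,
                "n_terms": design.shape[1],
                "loglik": res.llf,
                "aicc": _aicc(res, len(y)),
                "r2_adj": res.rsquared_adj,
                "resid_var": res.mse_resid,
            })
        table = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
        table["delta_aicc"] = table["aicc"] - table["aicc"].iloc[0]
        table["winner"] = table["delta_aicc"] == 0.0
        best = table["model"].iloc[0]
        res, names = fits[best]
        self.report_ = InheritanceModelReport(
            table=table, best_model=best,
            coefficients=pd.Series(res.params, index=names),
            skipped=skipped)
        self.best_model_ = best
        self.best_result_ = res
        self.coefficients_ = self.report_.coefficients
        self.n_observations_ = len(y)
        return self


def fit_and_compare(classes: pd.DataFrame, phenotype) -> InheritanceModelReport:
    """Fit all inheritance models and rank them by AICc."""
    sel = InheritanceModelSelector().fit(classes, phenotype)
    return sel.report_
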