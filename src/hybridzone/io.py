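"""Plain-text input/output: trajectory tables, genotype matrices, VCF.

All tabular artifacts are TSV so runs can be inspected and re-analyzed
with standard tools.  Genotype matrices carry the region label in each
column name (``chr1A_001`` ...); missing dosages are written as ``NA``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .inheritance import DiagnosticGenotypes, REGIONS
from .simulator import Trajectory

__all__ = [
    "trajectory_frame",
    "write_trajectory",
    "read_trajectory",
    "write_genotypes",
    "read_genotypes",
    "read_vcf_dosages",
]


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """Long-format snapshot table for one replicate."""
    frames = []
    for snap in traj.snapshots:
        n = snap.locations.size
        frames.append(pd.DataFrame({
            "generation": np.full(n, snap.generation, dtype=int),
            "individual_id": np.arange(n),
            "location": snap.locations,
            "mating_freq": snap.mating_freq,
            "neutral_freq": snap.neutral_freq,
        }))
    return pd.concat(frames, ignore_index=True)


def write_trajectory(traj: Trajectory, outdir: str | Path,
                     stem: str = "trajectory") -> Path:
    """Write the snapshot table plus a replicate metadata record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{stem}.tsv"
    trajectory_frame(traj).to_csv(path, sep="\t", index=False)
    meta = {
        "seed": traj.params.seed,
        "params_hash": traj.params.params_hash(),
        "extinct": traj.extinct,
        "params": traj.params.to_dict(),
    }
    (outdir / f"{stem}.meta.json").write_text(json.dumps(meta, indent=2))
    return path


def read_trajectory(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_genotypes(genotypes: DiagnosticGenotypes, path: str | Path,
                    phenotype: Optional[pd.Series] = None) -> Path:
    """Write a dosage matrix (and optional phenotype column) as TSV."""
    path = Path(path)
    df = genotypes.dosages.copy()
    if genotypes.cross_class is not None:
        df.insert(0, "cross_class", genotypes.cross_class)
    if phenotype is not None:
        df.insert(0, "phenotype", phenotype)
    df.to_csv(path, sep="\t", index_label="individual", na_rep="NA")
    return path


def _region_of(column: str) -> Optional[str]:
    for region in REGIONS:
        if column.startswith(region + "_"):
            return region
    return None


def read_genotypes(path: str | Path) -> tuple[DiagnosticGenotypes,
                                              Optional[pd.Series]]:
    """Read a TSV dosage matrix written by :func:`write_genotypes`.

    Returns the genotypes and the phenotype column (None if absent).
    Region membership is recovered from the column-name prefixes.
    """
    df = pd.read_csv(path, sep="\t", index_col="individual",
                     na_values=["NA"])
    phenotype = df.pop("phenotype") if "phenotype" in df else None
    cross = df.pop("cross_class") if "cross_class" in df else None
    regions = {c: _region_of(c) for c in df.columns}
    bad = [c for c, r in regions.items() if r is None]
    if bad:
        raise ValueError(f"columns without a region prefix: {bad[:5]}")
    geno = DiagnosticGenotypes(dosages=df.astype(float),
                               regions=pd.Series(regions),
                               cross_class=cross)
    return geno, phenotype


def read_vcf_dosages(vcf_path: str | Path,
                     sites: pd.DataFrame) -> DiagnosticGenotypes:
    """Read diagnostic-site dosages from a VCF.

    ``sites`` must have columns ``chrom``, ``pos`` (1-based) and
    ``region`` (chr1A / chr20).  The ALT allele is counted as the
    personata-type allele, so supply sites whose ALT is the allele fixed
    in personata.  Unlisted sites are ignored; listed sites absent from
    the VCF raise.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    for col in ("chrom", "pos", "region"):
        if col not in sites:
            raise ValueError(f"sites table missing column {col!r}")
    wanted = {(str(r.chrom), int(r.pos)): str(r.region)
              for r in sites.itertuples()}
    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    columns, region_labels, dosage_cols = [], [], []
    seen = set()
    for variant in vcf:
        key = (str(variant.CHROM), int(variant.POS))
        if key not in wanted:
            continue
        seen.add(key)
        region = wanted[key]
        columns.append(f"{region}_{variant.CHROM}:{variant.POS}")
        region_labels.append(region)
        # gt_types: 0=hom ref, 1=het, 2=hom alt (cyvcf2 gt012), 3=missing
        gt = variant.gt_types.astype(float)
        gt[gt == 3] = np.nan
        dosage_cols.append(gt)
    missing = set(wanted) - seen
    if missing:
        raise ValueError(f"sites not found in VCF: {sorted(missing)[:5]}")
    dosages = pd.DataFrame(np.column_stack(dosage_cols), index=samples,
                           columns=columns)
    return DiagnosticGenotypes(dosages=dosages,
                               regions=pd.Series(region_labels,
                                                 index=columns))
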