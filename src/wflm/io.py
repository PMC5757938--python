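"""File formats: VCF / dosage-matrix genotypes, phenotype TSV, kinship, BED, results.

Conventions: region coordinates are BED-style 0-based half-open; VCF positions
(1-based) are converted internally. Genotypes are re-polarized so dosages
count the minor allele in the analyzed sample; missing dosages are
mean-imputed per variant. Samples across genotypes, phenotypes and the
relationship matrix are intersected by ID and reordered to the phenotype
order — misalignment is an error, never silent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .flm import AssociationResult, RegionGenotypes
from .mixedmodel import PhenotypeData, RelationshipMatrix

log = logging.getLogger("wflm")

__all__ = [
    "RegionDefinition",
    "RunConfig",
    "read_regions_bed",
    "read_genotypes_vcf",
    "read_genotype_matrix",
    "read_phenotypes",
    "read_kinship",
    "align_samples",
    "write_results",
    "write_genotype_matrix",
    "write_kinship",
]


@dataclass(frozen=True)
class RegionDefinition:
    """BED-style region: 0-based half-open [start, end) on chrom."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")


@dataclass
class RunConfig:
    """Validated analysis configuration, echoed into result headers."""

    basis: str = "bspline"
    K: int = 15
    order: int = 4
    genotype_smoothing: bool = False
    weights: str = "beta"
    a1: float = 1.0
    a2: float = 25.0
    maf_filter: float | None = None
    seed: int | None = None

    def header_lines(self) -> list[str]:
        return [f"# {k}={v}" for k, v in asdict(self).items()]


def read_regions_bed(path) -> list[RegionDefinition]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{parts[1]}-{parts[2]}"
            out.append(RegionDefinition(parts[0], int(parts[1]), int(parts[2]), name))
    if not out:
        raise ValueError(f"no regions found in {path}")
    return out


def read_genotypes_vcf(path, region: RegionDefinition, sample_ids=None) -> RegionGenotypes:
    """Extract biallelic SNVs in a region from a VCF as minor-allele dosages.

    Multi-allelic and non-SNV records are skipped with a warning; missing
    genotypes become NaN and are mean-imputed downstream.
    """
    from cyvcf2 import VCF

    kwargs = {}
    if sample_ids is not None:
        kwargs["samples"] = [str(s) for s in sample_ids]
    vcf = VCF(str(path), gts012=True, **kwargs)
    ids = np.asarray(vcf.samples)
    if ids.size == 0:
        raise ValueError("no samples overlap the requested IDs")
    positions, columns = [], []
    query = f"{region.chrom}:{region.start + 1}-{region.end}"
    # full scan with an in-Python window filter: plain-text VCFs carry no
    # index, and regional gene tests read small files
    for v in vcf:
        if v.CHROM != region.chrom or not (region.start < v.POS <= region.end):
            continue
        if len(v.ALT) != 1 or not v.is_snp:
            log.warning("skipping multi-allelic/non-SNV site %s:%d", v.CHROM, v.POS)
            continue
        g = np.asarray(v.gt_types, dtype=float)  # 0/1/2, 3 = missing
        g[g == 3] = np.nan
        positions.append(v.POS)
        columns.append(g)
    vcf.close()
    if not columns:
        raise ValueError(f"no biallelic SNVs in region {region.name or query}")
    G = np.column_stack(columns)
    return RegionGenotypes.from_dosages(ids, np.asarray(positions), G, region.name or query)


def read_genotype_matrix(matrix_path, positions_path, region_id="region") -> RegionGenotypes:
    """Plain-text dosage matrix (first column = sample ID) + position sidecar."""
    df = pd.read_csv(matrix_path, sep=r"\s+", header=None, dtype=str)
    ids = df.iloc[:, 0].to_numpy()
    G = df.iloc[:, 1:].replace({"NA": np.nan, ".": np.nan}).astype(float).to_numpy()
    positions = np.loadtxt(positions_path, dtype=int, ndmin=1)
    if positions.ndim > 1:
        positions = positions[:, -1]
    if positions.size != G.shape[1]:
        raise ValueError("position sidecar does not match the genotype matrix")
    kept_before = G.shape[1]
    region = RegionGenotypes.from_dosages(ids, positions, G, region_id)
    if region.m < kept_before:
        log.warning("dropped %d monomorphic variant(s) from %s", kept_before - region.m, region_id)
    return region


def read_phenotypes(path, trait_col, covar_cols=(), id_col=None) -> PhenotypeData:
    """Phenotype/covariate TSV -> trait vector and covariate matrix with intercept."""
    df = pd.read_csv(path, sep="\t")
    id_col = id_col or df.columns[0]
    for col in [id_col, trait_col, *covar_cols]:
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    if df[id_col].duplicated().any():
        raise ValueError("sample IDs are not unique")
    used = df[[id_col, trait_col, *covar_cols]]
    complete = used.dropna()
    dropped = len(used) - len(complete)
    if dropped:
        log.warning("dropped %d sample(s) with missing trait/covariates", dropped)
    if len(complete) < 2:
        raise ValueError("fewer than 2 complete phenotype rows")
    y = complete[trait_col].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(complete))] + [complete[c].to_numpy(dtype=float) for c in covar_cols]
    )
    return PhenotypeData(ids=complete[id_col].astype(str).to_numpy(), y=y, X=X)


def read_kinship(path) -> RelationshipMatrix:
    """Square whitespace-delimited relationship matrix with a one-line ID header."""
    with open(path) as fh:
        ids = np.asarray(fh.readline().split())
    R = np.loadtxt(path, skiprows=1)
    R = np.atleast_2d(R)
    if R.shape != (ids.size, ids.size):
        raise ValueError("kinship matrix is not square or does not match its ID header")
    return RelationshipMatrix(R=R, ids=ids)


def align_samples(
    region: RegionGenotypes,
    pheno: PhenotypeData,
    kinship: RelationshipMatrix | None = None,
):
    """Intersect samples by ID and reorder everything to the phenotype order."""
    pheno_ids = [str(s) for s in pheno.ids]
    geno_index = {str(s): i for i, s in enumerate(region.ids)}
    kin_index = {str(s): i for i, s in enumerate(kinship.ids)} if kinship is not None else None
    keep = [
        i for i, s in enumerate(pheno_ids)
        if s in geno_index and (kin_index is None or s in kin_index)
    ]
    if not keep:
        raise ValueError("no samples are shared between genotypes, phenotypes and kinship")
    ids = np.asarray([pheno_ids[i] for i in keep])
    g_rows = np.asarray([geno_index[s] for s in ids])
    region2 = RegionGenotypes.from_dosages(
        ids, region.positions, region.G[g_rows], region.region_id
    )
    pheno2 = PhenotypeData(ids=ids, y=pheno.y[keep], X=pheno.X[keep])
    kin2 = None
    if kinship is not None:
        k_rows = np.asarray([kin_index[s] for s in ids])
        kin2 = RelationshipMatrix(R=kinship.R[np.ix_(k_rows, k_rows)], ids=ids)
    return region2, pheno2, kin2


_RESULT_COLS = [
    "region_id", "n", "m_variants", "K_beta_used", "df1", "df2", "F_stat", "p_value", "notes",
]


def write_results(results: list[AssociationResult], path, config: RunConfig | None = None):
    """Results TSV with a stable column order and config echoed as # comments."""
    with open(path, "w") as fh:
        if config is not None:
            for line in config.header_lines():
                fh.write(line + "\n")
        fh.write("\t".join(_RESULT_COLS) + "\n")
        for r in results:
            row = [
                r.region_id, str(r.n), str(r.m_variants), str(r.K_beta_used),
                str(r.df1), str(r.df2), f"{r.F_stat:.17g}", f"{r.p_value:.17e}",
                ";".join(r.notes) if r.notes else ".",
            ]
            fh.write("\t".join(row) + "\n")


def write_genotype_matrix(region: RegionGenotypes, matrix_path, positions_path):
    with open(matrix_path, "w") as fh:
        for sid, row in zip(region.ids, region.G.astype(int)):
            fh.write(str(sid) + " " + " ".join(map(str, row)) + "\n")
    np.savetxt(positions_path, region.positions, fmt="%d")


def write_kinship(R: RelationshipMatrix, path):
    with open(path, "w") as fh:
        fh.write(" ".join(map(str, R.ids)) + "\n")
        np.savetxt(fh, R.R, fmt="%.10g")
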