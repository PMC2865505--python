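"""Core data containers and text-format readers/writers.

Expression, genotype and covariate data are exchanged as tab-separated
text with one header row of individual identifiers.  Genotypes carry
genomic coordinates (1-based bp) so downstream association results can
be classified as cis or trans.  All containers are thin wrappers around
numpy arrays with identifier bookkeeping and validation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("peerqtl")

__all__ = [
    "ExpressionMatrix",
    "GenotypeMatrix",
    "CovariateMatrix",
    "ProbeAnnotation",
    "Hyperparameters",
    "read_expression",
    "read_covariates",
    "read_genotypes",
    "read_genotypes_vcf",
    "read_probe_annotations",
    "write_expression",
    "write_covariates",
    "write_genotypes",
    "align_individuals",
    "load_config",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Gene-by-individual expression values with a missingness mask.

    ``values`` is a float matrix of shape (G, N); entries where
    ``missing_mask`` is False are unobserved and stored as NaN.
    """

    values: np.ndarray
    gene_ids: list[str]
    individual_ids: list[str]
    missing_mask: np.ndarray = field(default=None)  # True = observed

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        self.gene_ids = list(map(str, self.gene_ids))
        self.individual_ids = list(map(str, self.individual_ids))
        if self.missing_mask is None:
            self.missing_mask = np.isfinite(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        G, N = self.values.shape
        if len(self.gene_ids) != G:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {G} rows")
        if len(self.individual_ids) != N:
            raise ValueError(f"{len(self.individual_ids)} individual ids for {N} columns")
        if self.missing_mask.shape != (G, N):
            raise ValueError("missing_mask shape mismatch")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.individual_ids, "individual")
        if not np.all(np.isfinite(self.values[self.missing_mask])):
            raise ValueError("observed expression entries must be finite")
        self.values = self.values.copy()
        self.values[~self.missing_mask] = np.nan

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_individuals(self, ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.individual_ids.index(i) for i in ids]
        return ExpressionMatrix(
            self.values[:, idx], self.gene_ids, list(ids), self.missing_mask[:, idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.individual_ids)


@dataclass
class GenotypeMatrix:
    """SNP-by-individual genotype codes with genomic positions.

    Codes are 0/1 for a haploid or inbred cross (``ploidy=1``) and
    additive dosages 0/1/2 for diploids (``ploidy=2``); missing is -1.
    """

    values: np.ndarray
    snp_ids: list[str]
    chrom: list[str]
    pos_bp: np.ndarray
    individual_ids: list[str]
    ploidy: int = 2

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int16)
        self.snp_ids = list(map(str, self.snp_ids))
        self.chrom = list(map(str, self.chrom))
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.individual_ids = list(map(str, self.individual_ids))
        S, N = self.values.shape
        if not (len(self.snp_ids) == len(self.chrom) == len(self.pos_bp) == S):
            raise ValueError("SNP annotation lengths do not match genotype rows")
        if len(self.individual_ids) != N:
            raise ValueError("individual id count does not match genotype columns")
        _check_unique(self.snp_ids, "SNP")
        _check_unique(self.individual_ids, "individual")
        if np.any(self.pos_bp <= 0):
            raise ValueError("SNP positions must be positive 1-based integers")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        alphabet = set(range(self.ploidy + 1)) | {-1}
        bad = ~np.isin(self.values, sorted(alphabet))
        if bad.any():
            s = int(np.nonzero(bad.any(axis=1))[0][0])
            raise ValueError(
                f"genotype code outside ploidy-{self.ploidy} alphabet for SNP "
                f"{self.snp_ids[s]!r}"
            )

    @property
    def n_snps(self) -> int:
        return self.values.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.values.shape[1]

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.individual_ids.index(i) for i in ids]
        return GenotypeMatrix(
            self.values[:, idx], self.snp_ids, self.chrom, self.pos_bp,
            list(ids), self.ploidy,
        )

    def dosages(self) -> np.ndarray:
        """Float dosage matrix with missing (-1) as NaN."""
        x = self.values.astype(float)
        x[self.values < 0] = np.nan
        return x


@dataclass
class CovariateMatrix:
    """Known covariates (covariate-by-individual), e.g. gender or batch."""

    values: np.ndarray
    covariate_ids: list[str]
    individual_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.covariate_ids = list(map(str, self.covariate_ids))
        self.individual_ids = list(map(str, self.individual_ids))
        F, N = self.values.shape
        if len(self.covariate_ids) != F or len(self.individual_ids) != N:
            raise ValueError("covariate id lengths do not match matrix shape")
        _check_unique(self.covariate_ids, "covariate")
        _check_unique(self.individual_ids, "individual")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("covariate values must be finite")

    @property
    def n_covariates(self) -> int:
        return self.values.shape[0]

    def subset_individuals(self, ids: Sequence[str]) -> "CovariateMatrix":
        idx = [self.individual_ids.index(i) for i in ids]
        return CovariateMatrix(self.values[:, idx], self.covariate_ids, list(ids))


@dataclass
class ProbeAnnotation:
    """Probe/gene genomic anchors: chromosome and midpoint (1-based bp)."""

    gene_ids: list[str]
    chrom: list[str]
    midpoint_bp: np.ndarray

    def __post_init__(self):
        self.gene_ids = list(map(str, self.gene_ids))
        self.chrom = list(map(str, self.chrom))
        self.midpoint_bp = np.asarray(self.midpoint_bp, dtype=np.int64)
        if not (len(self.gene_ids) == len(self.chrom) == len(self.midpoint_bp)):
            raise ValueError("annotation column lengths differ")
        _check_unique(self.gene_ids, "gene")
        if np.any(self.midpoint_bp <= 0):
            raise ValueError("probe midpoints must be positive")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def lookup(self, gene_id: str) -> tuple[str, int]:
        try:
            i = self._index[gene_id]
        except KeyError:
            raise KeyError(f"no annotation for gene {gene_id!r}") from None
        return self.chrom[i], int(self.midpoint_bp[i])


@dataclass
class Hyperparameters:
    """Model hyperparameters and inference controls.

    ``ard_shape``/``ard_rate`` and ``noise_shape``/``noise_rate`` are the
    gamma priors on the per-factor relevance precisions and the per-gene
    noise precisions; broad defaults (1e-3, 1e-3) leave complexity control
    to the data.  ``prior_inclusion`` is the prior probability that a gene
    has a genetic association; it plays the role of a significance
    threshold on the Bayesian scale.
    """

    K_hidden: int = 10
    ard_shape: float = 1e-3
    ard_rate: float = 1e-3
    noise_shape: float = 1e-3
    noise_rate: float = 1e-3
    prior_inclusion: float = 0.01
    slab_var: float = 1.0
    max_iter: int = 1000
    tol: float = 1e-5
    schedule: str = "iVBQTL"
    center_genes: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.K_hidden < 0:
            raise ValueError("K_hidden must be >= 0")
        for name in ("ard_shape", "ard_rate", "noise_shape", "noise_rate", "slab_var"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.prior_inclusion < 1.0):
            raise ValueError("prior_inclusion must lie in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        sched = self.schedule.lower()
        if sched not in ("ivbqtl", "fvbqtl"):
            raise ValueError("schedule must be 'iVBQTL' or 'fVBQTL'")
        self.schedule = "iVBQTL" if sched == "ivbqtl" else "fVBQTL"

    def replace(self, **kw) -> "Hyperparameters":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_table(path) -> tuple[list[str], list[str], list[list[str]]]:
    """Parse a TSV with header of column ids and a leading row-id column."""
    lines = Path(path).read_text().splitlines()
    lines = [ln for ln in lines if ln.strip() != ""]
    if len(lines) < 2:
        raise ValueError(f"{path}: expected a header row and at least one data row")
    header = lines[0].rstrip("\n").split("\t")
    col_ids = header[1:]
    ncol = len(col_ids)
    row_ids, cells = [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != ncol + 1:
            raise ValueError(
                f"{path}: ragged row at line {lineno} "
                f"({len(parts) - 1} values, expected {ncol})"
            )
        row_ids.append(parts[0])
        cells.append(parts[1:])
    return col_ids, row_ids, cells


def _to_float(cell: str) -> float:
    try:
        return float(cell)
    except ValueError:
        return np.nan


def read_expression(path, dialect: str = "genes-in-rows") -> ExpressionMatrix:
    """Read an expression TSV; non-numeric or empty cells become missing.

    ``dialect='genes-in-cols'`` reads a transposed table (individuals in
    rows); output orientation is always genes x individuals.
    """
    if dialect not in ("genes-in-rows", "genes-in-cols"):
        raise ValueError(f"unknown dialect {dialect!r}")
    col_ids, row_ids, cells = _parse_table(path)
    values = np.array([[_to_float(c) for c in row] for row in cells], dtype=float)
    if dialect == "genes-in-cols":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return ExpressionMatrix(values, row_ids, col_ids)


def read_covariates(path) -> CovariateMatrix:
    col_ids, row_ids, cells = _parse_table(path)
    values = np.array([[_to_float(c) for c in row] for row in cells], dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: covariates must be fully observed and numeric")
    return CovariateMatrix(values, row_ids, col_ids)


def read_genotypes(path, ploidy: int = 2) -> GenotypeMatrix:
    """Read a genotype TSV with columns snp_id, chrom, pos, then individuals.

    Codes must lie in the ploidy alphabet (0/1 haploid, 0/1/2 diploid);
    empty, 'NA' or -1 cells are treated as missing.
    """
    lines = Path(path).read_text().splitlines()
    lines = [ln for ln in lines if ln.strip() != ""]
    if len(lines) < 2:
        raise ValueError(f"{path}: expected a header and at least one SNP row")
    header = lines[0].split("\t")
    if len(header) < 4 or [h.lower() for h in header[:3]] != ["snp_id", "chrom", "pos"]:
        raise ValueError(f"{path}: header must start with snp_id, chrom, pos")
    individual_ids = header[3:]
    snp_ids, chroms, pos, rows = [], [], [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise ValueError(f"{path}: ragged row at line {lineno}")
        snp_ids.append(parts[0])
        chroms.append(parts[1])
        if parts[2].strip() == "":
            raise ValueError(f"{path}: missing position for SNP {parts[0]!r}")
        try:
            pos.append(int(parts[2]))
        except ValueError:
            raise ValueError(f"{path}: bad position {parts[2]!r} for SNP {parts[0]!r}")
        row = []
        for c in parts[3:]:
            c = c.strip()
            if c in ("", "NA", "nan", "."):
                row.append(-1)
            else:
                try:
                    row.append(int(c))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-integer genotype {c!r} for SNP {parts[0]!r}"
                    )
        rows.append(row)
    return GenotypeMatrix(np.array(rows), snp_ids, chroms, pos, individual_ids, ploidy)


def read_genotypes_vcf(path, ploidy: int = 2) -> GenotypeMatrix:
    """Read a VCF into additive dosages (GT field; 0/1 -> 1, 1/1 -> 2)."""
    try:
        from cyvcf2 import VCF
    except ImportError as e:  # pragma: no cover - optional dependency
        raise ImportError("reading VCF requires the optional cyvcf2 dependency") from e
    vcf = VCF(str(path))
    individual_ids = list(vcf.samples)
    snp_ids, chroms, pos, rows = [], [], [], []
    for var in vcf:
        snp_ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        pos.append(int(var.POS))
        # gt_types: 0=hom ref, 1=het, 2=hom alt, 3=unknown
        gt = np.asarray(var.gt_types, dtype=np.int16)
        dos = np.where(gt == 3, -1, gt)
        if ploidy == 1:
            dos = np.where(dos == 2, 1, dos)
        rows.append(dos)
    return GenotypeMatrix(np.array(rows), snp_ids, chroms, pos, individual_ids, ploidy)


def read_probe_annotations(path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    for col in ("gene_id", "chrom", "midpoint_bp"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return ProbeAnnotation(
        list(df["gene_id"]), list(df["chrom"]), df["midpoint_bp"].to_numpy()
    )


def _write_table(path, values, row_ids, col_ids, row_label):
    with open(path, "w") as fh:
        fh.write(row_label + "\t" + "\t".join(col_ids) + "\n")
        for rid, row in zip(row_ids, values):
            cells = ["NA" if not np.isfinite(v) else repr(float(v)) for v in row]
            fh.write(rid + "\t" + "\t".join(cells) + "\n")


def write_expression(expr: ExpressionMatrix, path) -> None:
    _write_table(path, expr.values, expr.gene_ids, expr.individual_ids, "gene_id")


def write_covariates(covs: CovariateMatrix, path) -> None:
    _write_table(path, covs.values, covs.covariate_ids, covs.individual_ids, "covariate_id")


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\tchrom\tpos\t" + "\t".join(geno.individual_ids) + "\n")
        for i in range(geno.n_snps):
            codes = "\t".join(str(int(v)) for v in geno.values[i])
            fh.write(f"{geno.snp_ids[i]}\t{geno.chrom[i]}\t{int(geno.pos_bp[i])}\t{codes}\n")


def align_individuals(expr, geno=None, covs=None):
    """Restrict all inputs to shared individuals, in expression-file order.

    Returns (expr, geno, covs) with absent inputs passed through as None.
    Raises if fewer than two individuals are shared.
    """
    shared = set(expr.individual_ids)
    for other in (geno, covs):
        if other is not None:
            shared &= set(other.individual_ids)
    order = [i for i in expr.individual_ids if i in shared]
    if len(order) == 0:
        raise ValueError("no shared individuals between inputs")
    if len(order) < 2:
        raise ValueError("need at least two shared individuals")
    dropped = sorted(set(expr.individual_ids) - shared)
    if geno is not None:
        dropped += sorted(set(geno.individual_ids) - shared)
    if covs is not None:
        dropped += sorted(set(covs.individual_ids) - shared)
    if dropped:
        logger.info("align_individuals: dropped %d unmatched ids: %s",
                    len(dropped), ",".join(dropped[:10]))
    expr_a = expr.subset_individuals(order)
    geno_a = geno.subset_individuals(order) if geno is not None else None
    covs_a = covs.subset_individuals(order) if covs is not None else None
    return expr_a, geno_a, covs_a


def load_config(path) -> Hyperparameters:
    """Load hyperparameters from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fields = {f.name: f.type for f in dataclasses.fields(Hyperparameters)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    # YAML leaves scientific notation like "1e-6" as a string; coerce
    coerced = {}
    for key, val in raw.items():
        ftype = str(fields[key])
        if "float" in ftype:
            coerced[key] = float(val)
        elif "int" in ftype:
            coerced[key] = int(val)
        elif "bool" in ftype:
            coerced[key] = bool(val)
        else:
            coerced[key] = val
    return Hyperparameters(**coerced)
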