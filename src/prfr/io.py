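"""Genotype, variant, phenotype and gene-coordinate I/O.

Two genotype dialects are supported:

``tsv``
    Plain tab-separated matrix: first column ``sample_id``, remaining
    column headers are SNP ids, cells are minor-allele dosages 0/1/2 or
    ``NA`` for missing.

``plink_raw``
    PLINK ``--recode A`` style: space-separated, six leading columns
    (FID IID PAT MAT SEX PHENOTYPE), then one column per SNP headed
    ``<snpid>_<counted allele>``; the counted allele is stored as the
    minor allele.

Internal conventions: genotype dosages live in a float matrix with NaN
as the missing sentinel (0 is a valid dosage and never means missing);
genomic coordinates are 1-based closed intervals, with BED's half-open
0-based intervals converted on read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan

_TSV_TOKENS = {"0": 0.0, "1": 1.0, "2": 2.0, "NA": np.nan}

GENOTYPE_DIALECTS = ("tsv", "plink_raw")


class GenotypeParseError(ValueError):
    """Raised when a genotype file does not conform to its dialect."""


@dataclass
class GenotypeMatrix:
    """Additively coded genotypes: ``values[i, j]`` counts minor alleles.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_snps)
        Float matrix with entries in {0, 1, 2} or NaN for missing calls.
    sample_ids, snp_ids : list of str
        Unique row / column labels aligned with ``values``.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.snp_ids) != p:
            raise ValueError(f"{len(self.snp_ids)} snp ids for {p} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids are not unique")
        if len(set(self.snp_ids)) != p:
            raise ValueError("snp ids are not unique")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosage {bad!r} outside {{0, 1, 2, NA}}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.snp_ids)

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        """Column subset, preserving the order given in ``snp_ids``."""
        idx = {s: j for j, s in enumerate(self.snp_ids)}
        cols = [idx[s] for s in snp_ids]
        return GenotypeMatrix(self.values[:, cols], list(self.sample_ids), list(snp_ids))

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return GenotypeMatrix(self.values[rows], list(sample_ids), list(self.snp_ids))


def _empty_variant_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["snp_id", "chrom", "pos", "allele_minor", "allele_major"]
    )


def make_variant_table(snp_ids, chrom="1", pos=None, allele_minor="A", allele_major="G") -> pd.DataFrame:
    """Build a minimal variant table aligned with ``snp_ids``."""
    n = len(snp_ids)
    if pos is None:
        pos = np.arange(1, n + 1)
    return pd.DataFrame(
        {
            "snp_id": list(snp_ids),
            "chrom": np.broadcast_to(np.asarray(chrom, dtype=object), n).copy(),
            "pos": np.asarray(pos, dtype=int),
            "allele_minor": np.broadcast_to(np.asarray(allele_minor, dtype=object), n).copy(),
            "allele_major": np.broadcast_to(np.asarray(allele_major, dtype=object), n).copy(),
        }
    )


def _parse_token(tok: str, path, lineno: int) -> float:
    try:
        return _TSV_TOKENS[tok]
    except KeyError:
        raise ValueError(
            f"{path}:{lineno}: genotype token {tok!r} outside {{0,1,2,NA}}"
        ) from None


def read_genotypes(path, dialect: str = "tsv"):
    """Read a genotype file.

    Returns
    -------
    (GenotypeMatrix, DataFrame)
        The genotype matrix and a variant table with one row per SNP
        column, in column order. For the ``tsv`` dialect the variant
        table carries placeholder coordinates/alleles (the dialect does
        not encode them); for ``plink_raw`` the counted allele from the
        header suffix is stored as ``allele_minor``.
    """
    if dialect not in GENOTYPE_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {GENOTYPE_DIALECTS}")
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenotypeParseError(f"{path}:1: empty genotype file")
    if dialect == "tsv":
        return _read_tsv(path, lines)
    return _read_plink_raw(path, lines)


def _read_tsv(path, lines):
    header = lines[0].split("\t")
    if header[0] != "sample_id":
        raise GenotypeParseError(f"{path}:1: expected leading column 'sample_id'")
    snp_ids = header[1:]
    sample_ids, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise GenotypeParseError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        sample_ids.append(fields[0])
        rows.append([_parse_token(t, path, lineno) for t in fields[1:]])
    values = np.array(rows, dtype=float).reshape(len(sample_ids), len(snp_ids))
    g = GenotypeMatrix(values, sample_ids, snp_ids)
    return g, make_variant_table(snp_ids)


_RAW_LEADING = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _read_plink_raw(path, lines):
    header = lines[0].split()
    if header[: len(_RAW_LEADING)] != _RAW_LEADING:
        raise GenotypeParseError(
            f"{path}:1: expected leading columns {' '.join(_RAW_LEADING)}"
        )
    snp_ids, alleles = [], []
    for col in header[len(_RAW_LEADING):]:
        snp, _, allele = col.rpartition("_")
        if not snp or not allele:
            raise GenotypeParseError(
                f"{path}:1: column {col!r} lacks the '_<allele>' counted-allele suffix"
            )
        snp_ids.append(snp)
        alleles.append(allele)
    sample_ids, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        fields = line.split()
        if len(fields) != len(header):
            raise GenotypeParseError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        sample_ids.append(fields[1])  # IID
        rows.append([_parse_token(t, path, lineno) for t in fields[len(_RAW_LEADING):]])
    values = np.array(rows, dtype=float).reshape(len(sample_ids), len(snp_ids))
    g = GenotypeMatrix(values, sample_ids, snp_ids)
    v = make_variant_table(snp_ids, allele_minor="A")
    v["allele_minor"] = alleles
    return g, v


def _format_dosage(x: float) -> str:
    return "NA" if np.isnan(x) else str(int(x))


def write_genotypes(g: GenotypeMatrix, v: pd.DataFrame, path, dialect: str = "tsv"):
    """Write genotypes so that :func:`read_genotypes` round-trips them."""
    if dialect not in GENOTYPE_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {GENOTYPE_DIALECTS}")
    if list(v["snp_id"]) != list(g.snp_ids):
        raise ValueError("variant table is not aligned with genotype columns")
    with open(path, "w") as fh:
        if dialect == "tsv":
            fh.write("\t".join(["sample_id", *g.snp_ids]) + "\n")
            for sid, row in zip(g.sample_ids, g.values):
                fh.write("\t".join([sid, *(_format_dosage(x) for x in row)]) + "\n")
        else:
            cols = [f"{s}_{a}" for s, a in zip(g.snp_ids, v["allele_minor"])]
            fh.write(" ".join(_RAW_LEADING + cols) + "\n")
            for sid, row in zip(g.sample_ids, g.values):
                lead = [sid, sid, "0", "0", "0", "-9"]
                fh.write(" ".join(lead + [_format_dosage(x) for x in row]) + "\n")
    return path


def read_gene_bed(path) -> pd.DataFrame:
    """Read a BED4+ gene table, converting to 1-based closed intervals.

    BED line ``chr3 100 200 GENE1`` becomes gene GENE1 on chr3 spanning
    [101, 200] inclusive. Duplicate gene names are kept as separate
    intervals.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED4 needs >= 4 columns")
            chrom, start, end, gene = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if start > end:
                raise ValueError(f"{path}:{lineno}: start {start} > end {end}")
            records.append({"gene": gene, "chrom": chrom, "start": start + 1, "end": end})
    if not records:
        return pd.DataFrame(columns=["gene", "chrom", "start", "end"])
    return pd.DataFrame(records)


def read_phenotypes(path) -> pd.DataFrame:
    """Read a TSV phenotype table (sample_id, outcome, covariates...)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "outcome" not in df.columns:
        raise ValueError(f"{path}: phenotype table needs 'sample_id' and 'outcome'")
    if not df["outcome"].isin([0, 1]).all():
        raise ValueError(f"{path}: outcome must be binary 0/1")
    return df


def write_phenotypes(pheno: pd.DataFrame, path):
    pheno.to_csv(path, sep="\t", index=False)
    return path


def align_phenotypes(g: GenotypeMatrix, pheno: pd.DataFrame) -> pd.DataFrame:
    """Reorder phenotype rows to match the genotype matrix's samples."""
    indexed = pheno.set_index("sample_id")
    missing = [s for s in g.sample_ids if s not in indexed.index]
    if missing:
        raise ValueError(f"samples absent from phenotype table: {missing[:5]}")
    return indexed.loc[g.sample_ids].reset_index()


def sha256_of(path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def ensure_dir(path):
    os.makedirs(path, exist_ok=True)
    return path
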