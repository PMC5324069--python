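"""Top-importance SNP selection and SNP-to-gene mapping.

SNPs ranked by forest importance are cut at a top fraction (25/50/75/
100% in the standard workflow; the count is floor(fraction * n)), then
mapped to genes whose interval, widened by 10 kb on each side, contains
the SNP position. Both window boundaries are inclusive and strand is
ignored. The resulting gene lists are exported one symbol per line for
downstream enrichment tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class TopFractionSelection:
    fraction: float
    snp_ids: list[str]

    @property
    def count(self) -> int:
        return len(self.snp_ids)


def select_top_fraction(importance: pd.DataFrame, fraction: float) -> TopFractionSelection:
    """Top ``floor(fraction * n)`` SNPs by importance rank (1 = best)."""
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    n = len(importance)
    count = int(np.floor(fraction * n))
    if count == 0:
        raise ValueError(f"fraction {fraction} of {n} SNPs selects none")
    top = importance.sort_values("rank").head(count)
    return TopFractionSelection(fraction, list(top["snp_id"]))


def map_snps_to_genes(selection, variants: pd.DataFrame, genes: pd.DataFrame,
                      window_bp: int = 10_000) -> pd.DataFrame:
    """Map selected SNPs to genes within ±``window_bp`` (inclusive).

    A SNP hits a gene iff ``gene.start - window <= pos <= gene.end +
    window`` on the same chromosome. Returns one row per gene with the
    supporting SNP ids; chromosome names present in the variants but
    absent from the gene table trigger a warning (such SNPs can never
    map).
    """
    snp_ids = selection.snp_ids if isinstance(selection, TopFractionSelection) else list(selection)
    v = variants[variants["snp_id"].isin(snp_ids)]
    gene_chroms = set(genes["chrom"].astype(str)) if len(genes) else set()
    unmatched = sorted(set(v["chrom"].astype(str)) - gene_chroms)
    if unmatched and len(genes):
        warnings.warn(f"no genes on chromosome(s) {unmatched}; SNPs there cannot map")
    hits: dict[str, set] = {}
    for _, gene in genes.iterrows():
        sel = v[(v["chrom"].astype(str) == str(gene["chrom"]))
                & (v["pos"] >= gene["start"] - window_bp)
                & (v["pos"] <= gene["end"] + window_bp)]
        if len(sel):
            hits.setdefault(gene["gene"], set()).update(sel["snp_id"])
    rows = [{"gene": g, "snp_ids": sorted(s), "n_snps": len(s)}
            for g, s in sorted(hits.items())]
    out = pd.DataFrame(rows, columns=["gene", "snp_ids", "n_snps"])
    out.attrs["n_genes"] = len(out)
    return out


def intersect_gene_lists(a: pd.DataFrame, b: pd.DataFrame) -> list[str]:
    """Sorted genes common to two hit lists."""
    genes_a = set(a["gene"]) if len(a) else set()
    genes_b = set(b["gene"]) if len(b) else set()
    return sorted(genes_a & genes_b)


def export_gene_list(hits, path):
    """One gene symbol per line, UTF-8, newline-terminated."""
    genes = list(hits["gene"]) if isinstance(hits, pd.DataFrame) else list(hits)
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")
    return path
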