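"""Per-gene 10-dimensional feature construction from two summary-statistic layers.

Each gene is represented by the concatenation of

* a phenotype part ``[P_p1 .. P_p5]``: the five smallest GWAS p-values among
  the SNPs falling inside the gene body (plus an optional flank), sorted
  ascending, and
* a transcriptome part ``[P_T1 .. P_T5]``: the eQTL p-values of those same
  five SNPs, aligned index-wise.

Missing entries are padded with exactly 1 — a p-value of 1 encodes "no
evidence of association": genes with fewer than five mapped SNPs pad the
tail of the phenotype part, and a selected SNP with no eQTL record
contributes 1 to the transcriptome part.  Genes with zero mapped SNPs are
excluded from the feature matrix entirely (they carry no signal in either
layer and are reported as ineligible).

Ties between equal p-values are broken by (position, variant_id), so the
extraction is invariant to the row order of the input tables.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

DEFAULT_K = 5
#: fixed column order of the feature matrix (phenotype part then eQTL part)
FEATURE_COLUMNS = [f"P_p{i}" for i in range(1, DEFAULT_K + 1)] + \
                  [f"P_T{i}" for i in range(1, DEFAULT_K + 1)]

#: SnpGeneMap: gene_id -> list of (variant_id, pos, pvalue) for mapped SNPs
SnpGeneMap = dict


def map_snps_to_genes(gwas: pd.DataFrame, annotation: pd.DataFrame,
                      flank: int = 0) -> SnpGeneMap:
    """Assign GWAS SNPs to genes by coordinate containment.

    A SNP at position ``pos`` maps to every gene whose (flank-extended)
    interval ``[start - flank, end + flank)`` contains it on the same
    chromosome — overlapping genes each receive the SNP.  Genes with no
    SNPs are present in the result with an empty list.
    """
    if annotation.empty:
        raise ValueError("annotation is empty")
    trees: dict[str, IntervalTree] = {}
    for g in annotation.itertuples(index=False):
        lo = max(0, g.start - flank)
        trees.setdefault(g.chrom, IntervalTree()).addi(lo, g.end + flank,
                                                       g.gene_id)
    snp_map: SnpGeneMap = {gid: [] for gid in annotation["gene_id"]}
    unmatched_chroms: dict[str, int] = {}
    for r in gwas.itertuples(index=False):
        tree = trees.get(r.chrom)
        if tree is None:
            unmatched_chroms[r.chrom] = unmatched_chroms.get(r.chrom, 0) + 1
            continue
        for iv in tree.at(r.pos):
            snp_map[iv.data].append((r.variant_id, int(r.pos), float(r.pvalue)))
    if unmatched_chroms:
        logger.warning("GWAS chromosomes absent from the annotation "
                       "(SNPs skipped): %s", unmatched_chroms)
    return snp_map


def gwas_features(gene_id: str, snp_map: SnpGeneMap,
                  k: int = DEFAULT_K) -> tuple[np.ndarray, list[str]]:
    """Phenotype part: the gene's ``k`` smallest GWAS p-values, ascending.

    Returns the length-``k`` vector (tail padded with exactly 1.0 when the
    gene has fewer than ``k`` SNPs) and the selected variant IDs in the same
    order.  Ties are broken by (position, variant_id).
    """
    if gene_id not in snp_map:
        raise KeyError(f"gene {gene_id!r} is not present in the SNP map")
    snps = sorted(snp_map[gene_id], key=lambda t: (t[2], t[1], t[0]))[:k]
    part = np.ones(k, dtype=float)
    part[:len(snps)] = [p for _, _, p in snps]
    return part, [v for v, _, _ in snps]


def _eqtl_lookup(eqtl: pd.DataFrame, match_mode: str) -> Mapping:
    """Best (smallest) eQTL p-value per key; key depends on the match mode."""
    if match_mode == "pair":
        return eqtl.groupby(["variant_id", "gene_id"])["pvalue"].min().to_dict()
    if match_mode == "snp_any_gene":
        return eqtl.groupby("variant_id")["pvalue"].min().to_dict()
    raise ValueError(f"unknown match_mode {match_mode!r}; "
                     "use 'pair' or 'snp_any_gene'")


def eqtl_features(gene_id: str, selected_snps: Sequence[str],
                  eqtl: pd.DataFrame, match_mode: str = "pair",
                  k: int = DEFAULT_K, _lookup: Mapping | None = None) -> np.ndarray:
    """Transcriptome part, index-aligned with the phenotype part.

    Entry ``i`` is the eQTL p-value of ``selected_snps[i]`` — matched as a
    (variant, gene) pair by default, or by variant alone under
    ``match_mode='snp_any_gene'`` — and exactly 1.0 where no record matches
    (including the padded tail beyond ``len(selected_snps)``).
    """
    lookup = _lookup if _lookup is not None else _eqtl_lookup(eqtl, match_mode)
    part = np.ones(k, dtype=float)
    for i, v in enumerate(selected_snps[:k]):
        key = (v, gene_id) if match_mode == "pair" else v
        p = lookup.get(key)
        if p is not None:
            part[i] = p
    return part


def build_feature_matrix(annotation: pd.DataFrame, gwas: pd.DataFrame,
                         eqtl: pd.DataFrame, k: int = DEFAULT_K,
                         flank: int = 0, match_mode: str = "pair",
                         scale: str = "pvalue",
                         ) -> tuple[pd.DataFrame, list[str]]:
    """Assemble the per-gene feature matrix.

    Returns ``(features, excluded)`` where ``features`` is indexed by
    gene_id with columns ``P_p1..P_pk, P_T1..P_Tk`` plus the provenance
    columns ``n_mapped_snps`` and ``selected_snps`` (comma-joined variant
    IDs), and ``excluded`` lists genes with zero mapped SNPs, which are
    inadmissible for training or scoring.

    ``scale='neglog10'`` transforms every entry to -log10(p) (padding
    becomes exactly 0); the default keeps raw p-values (padding 1).
    """
    if scale not in ("pvalue", "neglog10"):
        raise ValueError(f"unknown scale {scale!r}")
    snp_map = map_snps_to_genes(gwas, annotation, flank=flank)
    lookup = _eqtl_lookup(eqtl, match_mode)
    cols = [f"P_p{i}" for i in range(1, k + 1)] + \
           [f"P_T{i}" for i in range(1, k + 1)]
    rows, index, excluded = [], [], []
    for gid in annotation["gene_id"]:
        mapped = snp_map[gid]
        if not mapped:
            excluded.append(gid)
            continue
        gpart, selected = gwas_features(gid, snp_map, k=k)
        tpart = eqtl_features(gid, selected, eqtl, match_mode=match_mode,
                              k=k, _lookup=lookup)
        rows.append(np.concatenate([gpart, tpart]).tolist()
                    + [len(mapped), ",".join(selected)])
        index.append(gid)
    if not rows:
        raise ValueError("no gene has any mapped SNP; feature matrix is empty")
    if excluded:
        logger.info("excluded %d gene(s) with zero mapped SNPs", len(excluded))
    feats = pd.DataFrame(rows, columns=cols + ["n_mapped_snps", "selected_snps"],
                         index=pd.Index(index, name="gene_id"))
    feats["n_mapped_snps"] = feats["n_mapped_snps"].astype(int)
    if scale == "neglog10":
        feats[cols] = -np.log10(feats[cols].astype(float))
    return feats, excluded


def write_feature_matrix(features: pd.DataFrame, path) -> None:
    features.to_csv(path, sep="\t", index=True)


def read_feature_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
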