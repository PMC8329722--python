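"""Readers, writers and validation for the pipeline's tabular inputs.

Five plain tab-delimited formats (optionally gzip-compressed) are supported;
in memory each is a :class:`pandas.DataFrame` with fixed column names:

* GWAS summary statistics — ``variant_id, chrom, pos, pvalue``
* eQTL variant–gene pairs — ``variant_id, gene_id, pvalue``
* gene annotation — ``gene_id, symbol, chrom, start, end`` (BED or GTF on disk)
* gene–disease associations — ``gene_id, score``
* gene–gene network edges — ``gene_a, gene_b, score``

Genomic coordinates are normalised to the BED convention internally:
0-based, half-open.  GTF input (1-based, fully closed) is converted on read
and converted back on write, so the two conversions are involutive.

Readers drop rows that violate the basic invariants (p-values outside
``(0, 1]``, negative positions, self-edges, negative scores) rather than
failing; the number of dropped rows is logged and recorded in
``df.attrs["n_dropped"]``.  A p-value of exactly 0 is clamped to the
smallest positive float with a warning instead of being dropped — it is
accepted by the downstream math but is suspicious in summary statistics.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GWAS_COLUMNS = ["variant_id", "chrom", "pos", "pvalue"]
EQTL_COLUMNS = ["variant_id", "gene_id", "pvalue"]
ANNOTATION_COLUMNS = ["gene_id", "symbol", "chrom", "start", "end"]
GENE_DISEASE_COLUMNS = ["gene_id", "score"]
NETWORK_COLUMNS = ["gene_a", "gene_b", "score"]

_P_FLOOR = np.nextafter(0.0, 1.0)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class AnnotationError(ValueError):
    """The gene annotation violates a structural invariant (e.g. duplicate IDs)."""


def _apply_column_map(df: pd.DataFrame, column_map: Mapping[str, str] | None,
                      required: Sequence[str], what: str) -> pd.DataFrame:
    """Rename file columns to internal names and check that all are present."""
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}; "
                          f"found {list(df.columns)}")
    return df[list(required)].copy()


def _clean_pvalues(df: pd.DataFrame, what: str) -> pd.DataFrame:
    """Coerce the pvalue column to float, clamp exact zeros, drop p not in (0, 1]."""
    n_in = len(df)
    p = pd.to_numeric(df["pvalue"], errors="coerce").astype(float)
    n_zero = int((p == 0).sum())
    if n_zero:
        logger.warning("%s: clamped %d p-value(s) of exactly 0 to %g",
                       what, n_zero, _P_FLOOR)
        p = p.mask(p == 0, _P_FLOOR)
    keep = (p > 0) & (p <= 1)
    df = df.loc[keep.to_numpy()].copy()
    df["pvalue"] = p[keep].astype(float).to_numpy()
    n_dropped = n_in - len(df)
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with unparseable or out-of-range "
                       "p-values", what, n_dropped)
    df.attrs["n_dropped"] = n_dropped
    return df


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def read_gwas(path: str | Path, column_map: Mapping[str, str] | None = None,
              one_based: bool = False) -> pd.DataFrame:
    """Read a GWAS summary-statistics table.

    Parameters
    ----------
    path
        Tab-delimited file with a header row; gzip input is detected from
        the extension.
    column_map
        Optional mapping from internal names (``variant_id``, ``chrom``,
        ``pos``, ``pvalue``) to the column names used in the file, so that
        GWAS-Catalog-style exports can be read without editing the file.
    one_based
        If True, positions in the file are 1-based and are shifted to the
        internal 0-based convention.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    df = _apply_column_map(raw, column_map, GWAS_COLUMNS, "GWAS table")
    if df.empty:
        logger.warning("GWAS table %s is empty", path)
        df.attrs["n_dropped"] = 0
        df["pos"] = df["pos"].astype(np.int64)
        df["pvalue"] = df["pvalue"].astype(float)
        return df
    n_in = len(df)
    pos = pd.to_numeric(df["pos"], errors="coerce")
    if one_based:
        pos = pos - 1
    keep = pos.notna() & (pos >= 0)
    df = df.loc[keep.to_numpy()].copy()
    df["pos"] = pos[keep].astype(np.int64).to_numpy()
    n_bad_pos = n_in - len(df)
    df = _clean_pvalues(df, "GWAS table")
    df.attrs["n_dropped"] += n_bad_pos
    return df.reset_index(drop=True)


def write_gwas(df: pd.DataFrame, path: str | Path) -> None:
    df[GWAS_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# eQTL variant–gene pairs
# ---------------------------------------------------------------------------

def read_eqtl(path: str | Path,
              column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read an eQTL association table (variant–gene pairs with nominal p-values)."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    df = _apply_column_map(raw, column_map, EQTL_COLUMNS, "eQTL table")
    if df.empty:
        df.attrs["n_dropped"] = 0
        df["pvalue"] = df["pvalue"].astype(float)
        return df
    return _clean_pvalues(df, "eQTL table").reset_index(drop=True)


def write_eqtl(df: pd.DataFrame, path: str | Path) -> None:
    df[EQTL_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene annotation (BED / GTF)
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_annotation(path: str | Path, fmt: str = "bed") -> pd.DataFrame:
    """Read a gene annotation as BED (0-based half-open) or GTF (1-based closed).

    GTF coordinates are converted to the internal 0-based half-open
    convention.  Duplicate gene identifiers are rejected.
    """
    fmt = fmt.lower()
    if fmt == "bed":
        raw = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if raw.shape[1] < 4:
            raise SchemaError("BED annotation needs >= 4 columns "
                              "(chrom, start, end, gene_id)")
        df = pd.DataFrame({
            "gene_id": raw[3],
            "symbol": raw[6] if raw.shape[1] > 6 else raw[3],
            "chrom": raw[0],
            "start": raw[1].astype(np.int64),
            "end": raw[2].astype(np.int64),
        })
    elif fmt == "gtf":
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(_GTF_ATTR.findall(f[8]))
                gid = attrs.get("gene_id")
                if gid is None:
                    raise SchemaError("GTF gene record without gene_id attribute")
                rows.append((gid, attrs.get("gene_name", gid), f[0],
                             int(f[3]) - 1, int(f[4])))
        df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}; use 'bed' or 'gtf'")

    bad = df[df["start"] >= df["end"]]
    if len(bad):
        raise AnnotationError(f"empty or inverted gene interval(s): "
                              f"{bad['gene_id'].tolist()}")
    dup = df["gene_id"][df["gene_id"].duplicated()].unique().tolist()
    if dup:
        raise AnnotationError(f"duplicate gene_id(s) in annotation: {dup}")
    return df[ANNOTATION_COLUMNS].reset_index(drop=True)


def write_annotation(df: pd.DataFrame, path: str | Path, fmt: str = "bed") -> None:
    """Write the annotation back to BED or GTF, inverting the coordinate
    conversion applied on read."""
    fmt = fmt.lower()
    if fmt == "bed":
        out = pd.DataFrame({
            0: df["chrom"], 1: df["start"], 2: df["end"], 3: df["gene_id"],
            4: 0, 5: "+", 6: df["symbol"],
        })
        out.to_csv(path, sep="\t", index=False, header=False)
    elif fmt == "gtf":
        with open(path, "w") as fh:
            for r in df.itertuples(index=False):
                attrs = f'gene_id "{r.gene_id}"; gene_name "{r.symbol}";'
                fh.write("\t".join([r.chrom, "priogene", "gene",
                                    str(r.start + 1), str(r.end),
                                    ".", "+", ".", attrs]) + "\n")
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")


# ---------------------------------------------------------------------------
# Gene–disease table and gene–gene network
# ---------------------------------------------------------------------------

def read_gene_disease(path: str | Path,
                      column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a gene–disease association table (gene identifier + evidence score)."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    df = _apply_column_map(raw, column_map, GENE_DISEASE_COLUMNS,
                           "gene-disease table")
    n_in = len(df)
    score = pd.to_numeric(df["score"], errors="coerce")
    keep = score.notna() & (score >= 0)
    df = df.loc[keep.to_numpy()].copy()
    df["score"] = score[keep].astype(float).to_numpy()
    df.attrs["n_dropped"] = n_in - len(df)
    if df.attrs["n_dropped"]:
        logger.warning("gene-disease table: dropped %d row(s) with invalid scores",
                       df.attrs["n_dropped"])
    return df.reset_index(drop=True)


def write_gene_disease(df: pd.DataFrame, path: str | Path) -> None:
    df[GENE_DISEASE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_network(path: str | Path,
                 column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a gene–gene network edge list with correlation scores.

    Self-edges are dropped with a warning.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    df = _apply_column_map(raw, column_map, NETWORK_COLUMNS, "network edge list")
    n_in = len(df)
    score = pd.to_numeric(df["score"], errors="coerce")
    keep = score.notna() & (df["gene_a"] != df["gene_b"])
    n_self = int((df["gene_a"] == df["gene_b"]).sum())
    if n_self:
        logger.warning("network: dropped %d self-edge(s)", n_self)
    df = df.loc[keep.to_numpy()].copy()
    df["score"] = score[keep].astype(float).to_numpy()
    df.attrs["n_dropped"] = n_in - len(df)
    return df.reset_index(drop=True)


def write_network(df: pd.DataFrame, path: str | Path) -> None:
    df[NETWORK_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Referential-integrity validation across tables
# ---------------------------------------------------------------------------

def validate_dataset(gwas: pd.DataFrame, eqtl: pd.DataFrame,
                     annotation: pd.DataFrame, gene_disease: pd.DataFrame,
                     network: pd.DataFrame) -> dict:
    """Cross-table referential-integrity report.

    eQTL rows referencing unknown genes or variants are *flagged*, not
    removed — the feature stage simply never matches them.
    """
    genes = set(annotation["gene_id"])
    gwas_variants = set(gwas["variant_id"])
    report = {
        "n_gwas": len(gwas),
        "n_eqtl": len(eqtl),
        "n_genes": len(annotation),
        "eqtl_variants_missing_from_gwas":
            sorted(set(eqtl["variant_id"]) - gwas_variants),
        "eqtl_genes_not_annotated":
            sorted(set(eqtl["gene_id"]) - genes),
        "disease_genes_not_annotated":
            sorted(set(gene_disease["gene_id"]) - genes),
        "network_genes_not_annotated":
            sorted((set(network["gene_a"]) | set(network["gene_b"])) - genes),
        "gwas_chromosomes_not_annotated": {
            c: int(n) for c, n in gwas["chrom"].value_counts().items()
            if c not in set(annotation["chrom"])
        },
    }
    report["ok"] = not (report["eqtl_variants_missing_from_gwas"]
                        or report["gwas_chromosomes_not_annotated"])
    return report
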