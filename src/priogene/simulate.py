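"""Synthetic GWAS + eQTL study generator with a planted truth.

Emulates the five inputs the prioritization pipeline consumes — GWAS summary
statistics, tissue eQTL pairs, a gene annotation, a gene–disease table and a
gene–gene network — on a small synthetic genome, with a known set of planted
causal genes so every downstream stage can be tested end to end.

Generative model
----------------
Genes are placed on a genome of ``n_chromosomes`` equal-length chromosomes,
non-overlapping by default.  Each gene receives a number of SNPs drawn
uniformly from ``snps_per_gene_range``, placed uniformly inside the gene
body.  SNP p-values follow the standard one-parameter p-value enrichment
model: Uniform(0, 1) under the null and Beta(a, 1) with ``a < 1`` inside
causal genes (mean ``a / (a + 1)``, so smaller ``a`` means stronger signal).

In the eQTL layer, each of a causal gene's top-``k`` GWAS SNPs carries an
enriched Beta(a, 1) association with its gene with probability
``eqtl_signal_prob``; every other SNP is emitted as a null Uniform(0, 1)
pair with its host gene with probability ``eqtl_null_pair_prob``.  Every
eQTL variant therefore also exists in the GWAS table.

A fraction ``frac_causal_labeled`` of causal genes is written to the
gene–disease table (the "known disease genes"); the held-out causal genes
are wired into the network as candidates, so ranking them above null
candidates is the recoverable planted signal.  Each non-causal gene gets a
weak (< 1) network edge to a random listed gene with probability
``negative_link_fraction`` (making it a negative under the downstream
threshold rule) and a strong (>= 1) edge otherwise (making it a candidate).

All randomness flows from the single ``seed`` through per-output
sub-streams, so regenerating with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio

__all__ = [
    "SimulationConfig", "PlantedTruth", "SyntheticDataset", "PackingError",
    "simulate_annotation", "plant_truth", "simulate_gwas", "simulate_eqtl",
    "simulate_labels_and_network", "simulate_dataset", "write_dataset",
]


class PackingError(ValueError):
    """The requested genes cannot be placed disjointly on the genome."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study; defaults are the reference
    planted-signal condition used throughout the test suite."""

    n_genes: int = 2000
    n_causal: int = 400
    genome_length: int = 30_000_000
    n_chromosomes: int = 2
    gene_length_range: tuple[int, int] = (1000, 5000)
    snps_per_gene_range: tuple[int, int] = (3, 15)
    causal_beta_a: float = 0.1          # Beta(a, 1) enrichment; a=1 is the null
    eqtl_signal_prob: float = 0.8       # P(top GWAS SNP of a causal gene is an eQTL)
    eqtl_null_pair_prob: float = 0.3    # P(any other SNP emitted as a null pair)
    top_k: int = 5                      # SNPs per gene considered "top"
    frac_causal_labeled: float = 0.8    # causal genes listed in the disease table
    negative_link_fraction: float = 0.5  # non-causal genes given a weak (<1) edge
    network_density: float = 0.001      # extra noise edges among non-positives
    n_intergenic_snps: int = 0          # null SNPs outside any gene body
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_genes:
            raise ValueError("n_causal must be <= n_genes")
        if not (0 < self.causal_beta_a <= 1):
            raise ValueError("causal_beta_a must lie in (0, 1]")
        for name in ("eqtl_signal_prob", "eqtl_null_pair_prob",
                     "frac_causal_labeled", "negative_link_fraction",
                     "network_density"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("gene_length_range must satisfy 0 < min <= max")
        lo, hi = self.snps_per_gene_range
        if not (0 <= lo <= hi):
            raise ValueError("snps_per_gene_range must satisfy 0 <= min <= max")
        if self.genome_length <= 0 or self.n_chromosomes <= 0:
            raise ValueError("genome_length and n_chromosomes must be positive")

    def _streams(self) -> dict[str, np.random.Generator]:
        """Deterministic, independent sub-streams, one per output."""
        names = ["annotation", "truth", "gwas", "eqtl", "labels"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class PlantedTruth:
    """Ground truth of the simulation: which genes are causal, which of those
    the gene–disease table will list, and each SNP's host gene and p-values."""

    causal_genes: frozenset[str]
    labeled_causal: frozenset[str]
    # one row per simulated SNP: variant_id, gene_id (host, "" if intergenic),
    # gwas_pvalue; eqtl_pvalue is NaN where no pair was emitted
    snp_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "causal_genes": sorted(self.causal_genes),
            "labeled_causal": sorted(self.labeled_causal),
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    annotation: pd.DataFrame
    gwas: pd.DataFrame
    eqtl: pd.DataFrame
    gene_disease: pd.DataFrame
    network: pd.DataFrame
    truth: PlantedTruth


def _chrom_lengths(config: SimulationConfig) -> dict[str, int]:
    per = config.genome_length // config.n_chromosomes
    return {f"chr{i + 1}": per for i in range(config.n_chromosomes)}


def simulate_annotation(config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Place ``n_genes`` genes on the synthetic genome.

    Genes are distributed round-robin over chromosomes; within each
    chromosome the inter-gene gaps are drawn uniformly from the free space,
    which keeps intervals disjoint unless ``allow_overlap`` is set.

    Raises
    ------
    PackingError
        If the genes cannot fit disjointly in the genome.
    """
    rng = rng if rng is not None else config._streams()["annotation"]
    if config.n_genes == 0:
        return pd.DataFrame(columns=pio.ANNOTATION_COLUMNS)

    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    chroms = list(_chrom_lengths(config).items())
    per_chrom: list[list[int]] = [[] for _ in chroms]
    for i in range(config.n_genes):
        per_chrom[i % len(chroms)].append(i)

    rows = []
    for (chrom, clen), idx in zip(chroms, per_chrom):
        if not idx:
            continue
        if config.allow_overlap:
            starts = np.sort(rng.integers(0, max(1, clen - hi), size=len(idx)))
        else:
            total = int(lengths[idx].sum())
            free = clen - total
            if free < 0:
                raise PackingError(
                    f"cannot place {len(idx)} genes totalling {total} bp on "
                    f"{chrom} of length {clen} bp without overlap")
            # gaps: differences of sorted uniform draws over the free space
            cuts = np.sort(rng.integers(0, free + 1, size=len(idx)))
            starts = cuts + np.concatenate(([0], np.cumsum(lengths[idx])[:-1]))
        for j, i in enumerate(idx):
            gid = f"G{i:05d}"
            rows.append((gid, gid, chrom, int(starts[j]),
                         int(starts[j] + lengths[i])))
    df = pd.DataFrame(rows, columns=pio.ANNOTATION_COLUMNS)
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def plant_truth(config: SimulationConfig, annotation: pd.DataFrame,
                rng: np.random.Generator | None = None) -> PlantedTruth:
    """Pick the causal genes and the subset listed in the disease table."""
    rng = rng if rng is not None else config._streams()["truth"]
    gene_ids = annotation["gene_id"].to_numpy()
    causal = rng.choice(gene_ids, size=config.n_causal, replace=False)
    n_labeled = int(round(config.frac_causal_labeled * config.n_causal))
    labeled = rng.choice(np.sort(causal), size=n_labeled, replace=False)
    return PlantedTruth(causal_genes=frozenset(causal.tolist()),
                        labeled_causal=frozenset(labeled.tolist()))


def simulate_gwas(config: SimulationConfig, annotation: pd.DataFrame,
                  truth: PlantedTruth,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-SNP GWAS p-values: Uniform(0,1) null, Beta(a,1) in causal genes.

    Also fills ``truth.snp_table`` with each SNP's host gene, which downstream
    stages must rediscover from coordinates alone.
    """
    if annotation.empty:
        raise ValueError("annotation is empty; nothing to simulate")
    rng = rng if rng is not None else config._streams()["gwas"]
    lo, hi = config.snps_per_gene_range
    recs, hosts = [], []
    counter = 0
    for g in annotation.itertuples(index=False):
        n = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
        if n == 0:
            continue
        pos = np.sort(rng.integers(g.start, g.end, size=n))
        if g.gene_id in truth.causal_genes:
            p = rng.beta(config.causal_beta_a, 1.0, size=n)
        else:
            p = rng.uniform(0.0, 1.0, size=n)
        p = np.maximum(p, np.nextafter(0.0, 1.0))
        for j in range(n):
            recs.append((f"snp{counter:07d}", g.chrom, int(pos[j]), float(p[j])))
            hosts.append(g.gene_id)
            counter += 1
    if config.n_intergenic_snps:
        # uniform null SNPs anywhere on the genome, host gene left blank
        clens = _chrom_lengths(config)
        names = list(clens)
        ci = rng.integers(0, len(names), size=config.n_intergenic_snps)
        for j in range(config.n_intergenic_snps):
            chrom = names[int(ci[j])]
            recs.append((f"snp{counter:07d}", chrom,
                         int(rng.integers(0, clens[chrom])),
                         float(rng.uniform())))
            hosts.append("")
            counter += 1
    gwas = pd.DataFrame(recs, columns=pio.GWAS_COLUMNS)
    truth.snp_table = pd.DataFrame({
        "variant_id": gwas["variant_id"],
        "gene_id": hosts,
        "gwas_pvalue": gwas["pvalue"],
    })
    return gwas


def simulate_eqtl(config: SimulationConfig, annotation: pd.DataFrame,
                  truth: PlantedTruth, gwas: pd.DataFrame,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Emit variant–gene eQTL pairs consistent with the planted truth.

    Causal genes' top GWAS SNPs carry enriched pairs with probability
    ``eqtl_signal_prob``; all other SNP–host pairs are null with probability
    ``eqtl_null_pair_prob``.
    """
    if truth.snp_table.empty:
        raise ValueError("simulate_gwas must run first (truth.snp_table empty)")
    rng = rng if rng is not None else config._streams()["eqtl"]
    snp = truth.snp_table[truth.snp_table["gene_id"] != ""]
    rows = []
    for gid, grp in snp.groupby("gene_id", sort=True):
        grp = grp.sort_values(["gwas_pvalue", "variant_id"], kind="stable")
        is_causal = gid in truth.causal_genes
        top = set(grp["variant_id"].head(config.top_k)) if is_causal else set()
        for r in grp.itertuples(index=False):
            # a top SNP that misses its signal draw stays eligible for a null
            # pair, so under a=1 / signal_prob=0 causal and non-causal genes
            # are exchangeable in the eQTL layer too
            if r.variant_id in top and rng.uniform() < config.eqtl_signal_prob:
                p = float(rng.beta(config.causal_beta_a, 1.0))
                rows.append((r.variant_id, gid, max(p, np.nextafter(0, 1))))
            elif rng.uniform() < config.eqtl_null_pair_prob:
                rows.append((r.variant_id, gid, float(rng.uniform())))
    eqtl = pd.DataFrame(rows, columns=pio.EQTL_COLUMNS)
    eqtl = eqtl.sort_values(["gene_id", "variant_id"],
                            kind="stable").reset_index(drop=True)
    merged = truth.snp_table.merge(
        eqtl.rename(columns={"pvalue": "eqtl_pvalue"}),
        on=["variant_id", "gene_id"], how="left")
    truth.snp_table = merged
    return eqtl


def simulate_labels_and_network(config: SimulationConfig, truth: PlantedTruth,
                                annotation: pd.DataFrame,
                                rng: np.random.Generator | None = None,
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit the gene–disease table and the network edge list.

    The disease table lists the labeled causal genes.  Every other annotated
    gene receives one edge to a random listed gene: weak (score in [0, 1))
    with probability ``negative_link_fraction`` — except held-out causal
    genes, which always get a strong (score in [1, 2)) edge so they surface
    as candidates.  ``network_density`` adds uninformative noise edges
    between non-positive genes.
    """
    rng = rng if rng is not None else config._streams()["labels"]
    positives = sorted(truth.labeled_causal)
    gene_disease = pd.DataFrame({
        "gene_id": positives,
        "score": np.round(rng.uniform(0.1, 1.0, size=len(positives)), 6),
    })
    others = [g for g in annotation["gene_id"] if g not in truth.labeled_causal]
    edges = []
    for g in others:
        anchor = positives[int(rng.integers(0, len(positives)))] if positives else None
        if anchor is None:
            continue
        held_out_causal = g in truth.causal_genes
        if not held_out_causal and rng.uniform() < config.negative_link_fraction:
            score = rng.uniform(0.0, 1.0)       # weak: becomes a negative
        else:
            score = rng.uniform(1.0, 2.0)       # strong: becomes a candidate
        edges.append((g, anchor, round(float(score), 6)))
    if config.network_density > 0 and len(others) > 1:
        n_noise = rng.binomial(len(others) * (len(others) - 1) // 2,
                               config.network_density)
        for _ in range(int(n_noise)):
            a, b = rng.choice(others, size=2, replace=False)
            edges.append((a, b, round(float(rng.uniform(0.0, 2.0)), 6)))
    network = pd.DataFrame(edges, columns=pio.NETWORK_COLUMNS)
    return gene_disease, network


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run all generators in order under the config's seed."""
    streams = config._streams()
    annotation = simulate_annotation(config, streams["annotation"])
    truth = plant_truth(config, annotation, streams["truth"])
    gwas = simulate_gwas(config, annotation, truth, streams["gwas"])
    eqtl = simulate_eqtl(config, annotation, truth, gwas, streams["eqtl"])
    gene_disease, network = simulate_labels_and_network(
        config, truth, annotation, streams["labels"])
    return SyntheticDataset(config=config, annotation=annotation, gwas=gwas,
                            eqtl=eqtl, gene_disease=gene_disease,
                            network=network, truth=truth)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the five tables plus the truth JSON; returns the file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": outdir / "genes.bed",
        "gwas": outdir / "gwas.tsv",
        "eqtl": outdir / "eqtl.tsv",
        "gene_disease": outdir / "gene_disease.tsv",
        "network": outdir / "network.tsv",
        "truth": outdir / "truth.json",
        "config": outdir / "config.json",
    }
    pio.write_annotation(ds.annotation, paths["annotation"], fmt="bed")
    pio.write_gwas(ds.gwas, paths["gwas"])
    pio.write_eqtl(ds.eqtl, paths["eqtl"])
    pio.write_gene_disease(ds.gene_disease, paths["gene_disease"])
    pio.write_network(ds.network, paths["network"])
    ds.truth.to_json(paths["truth"])
    paths["config"].write_text(
        json.dumps(dataclasses.asdict(ds.config), indent=1, default=list) + "\n")
    return paths
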