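import numpy as np
import pandas as pd
import pytest

from priogene.simulate import SimulationConfig, simulate_dataset

SMALL_CONFIG = SimulationConfig(n_genes=60, n_causal=15,
                                genome_length=2_000_000, n_chromosomes=2,
                                seed=11)


@pytest.fixture(scope="session")
def small_config():
    return SMALL_CONFIG


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-gene synthetic study shared by read-only tests."""
    return simulate_dataset(SMALL_CONFIG)


def random_tables(rng, n_genes=4, n_snps=30, chroms=("chr1", "chr2"),
                  gene_len=200, genome_len=2000, eqtl_frac=0.5):
    """An unstructured random (annotation, gwas, eqtl) triple for oracle tests.

    Built directly with numpy, independently of the simulator, so oracle
    comparisons do not inherit the generator's structure.
    """
    genes = []
    for i in range(n_genes):
        start = int(rng.integers(0, genome_len - gene_len))
        genes.append((f"g{i}", f"g{i}", chroms[i % len(chroms)],
                      start, start + int(rng.integers(50, gene_len))))
    annotation = pd.DataFrame(
        genes, columns=["gene_id", "symbol", "chrom", "start", "end"])
    gwas = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(n_snps)],
        "chrom": rng.choice(chroms, size=n_snps),
        "pos": rng.integers(0, genome_len, size=n_snps),
        "pvalue": rng.uniform(np.finfo(float).tiny, 1.0, size=n_snps),
    })
    n_pairs = int(eqtl_frac * n_snps)
    eqtl = pd.DataFrame({
        "variant_id": rng.choice(gwas["variant_id"], size=n_pairs, replace=False)
        if n_pairs <= n_snps else [],
        "gene_id": rng.choice(annotation["gene_id"], size=n_pairs),
        "pvalue": rng.uniform(np.finfo(float).tiny, 1.0, size=n_pairs),
    })
    return annotation, gwas, eqtl
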