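"""Feature extraction: mapping, top-k selection, padding, oracle equivalence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from priogene.features import (build_feature_matrix, eqtl_features,
                               gwas_features, map_snps_to_genes)

from conftest import random_tables


# ---------------------------------------------------------------------------
# Independent brute-force oracles (pure python, no package code)
# ---------------------------------------------------------------------------

def oracle_map(gwas, annotation, flank=0):
    out = {g.gene_id: [] for g in annotation.itertuples(index=False)}
    for s in gwas.itertuples(index=False):
        for g in annotation.itertuples(index=False):
            if (s.chrom == g.chrom
                    and max(0, g.start - flank) <= s.pos < g.end + flank):
                out[g.gene_id].append((s.variant_id, int(s.pos), float(s.pvalue)))
    return out


def oracle_gwas_part(snps, k=5):
    ordered = sorted(snps, key=lambda t: (t[2], t[1], t[0]))[:k]
    return ([p for _, _, p in ordered] + [1.0] * k)[:k], [v for v, _, _ in ordered]


def oracle_eqtl_part(gene_id, selected, eqtl, k=5):
    part = []
    for v in selected:
        hits = [r.pvalue for r in eqtl.itertuples(index=False)
                if r.variant_id == v and r.gene_id == gene_id]
        part.append(min(hits) if hits else 1.0)
    return part + [1.0] * (k - len(part))


# ---------------------------------------------------------------------------
# SNP -> gene mapping
# ---------------------------------------------------------------------------

class TestSnpGeneMapping:
    @pytest.fixture
    def one_gene(self):
        return pd.DataFrame([("g1", "g1", "chr1", 100, 200)],
                            columns=["gene_id", "symbol", "chrom", "start", "end"])

    @pytest.mark.parametrize("pos,mapped", [
        (150, True),    # inside
        (100, True),    # left edge included
        (200, False),   # right edge excluded (half-open)
        (99, False),
    ])
    def test_half_open_containment(self, one_gene, pos, mapped):
        gwas = pd.DataFrame([("v1", "chr1", pos, 0.5)],
                            columns=["variant_id", "chrom", "pos", "pvalue"])
        m = map_snps_to_genes(gwas, one_gene, flank=0)
        assert bool(m["g1"]) is mapped

    def test_flank_extends_the_window(self, one_gene):
        gwas = pd.DataFrame([("v1", "chr1", 90, 0.5)],
                            columns=["variant_id", "chrom", "pos", "pvalue"])
        assert not map_snps_to_genes(gwas, one_gene, flank=0)["g1"]
        assert map_snps_to_genes(gwas, one_gene, flank=20)["g1"]

    def test_overlapping_genes_each_receive_the_snp(self):
        ann = pd.DataFrame([("a", "a", "chr1", 0, 300),
                            ("b", "b", "chr1", 100, 400)],
                           columns=["gene_id", "symbol", "chrom", "start", "end"])
        gwas = pd.DataFrame([("v1", "chr1", 150, 0.5)],
                            columns=["variant_id", "chrom", "pos", "pvalue"])
        m = map_snps_to_genes(gwas, ann, flank=0)
        assert m["a"] and m["b"]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        ann, gwas, _ = random_tables(rng, n_genes=5, n_snps=50)
        got = map_snps_to_genes(gwas, ann, flank=0)
        expect = oracle_map(gwas, ann, flank=0)
        assert {g: sorted(v) for g, v in got.items()} == \
               {g: sorted(v) for g, v in expect.items()}


# ---------------------------------------------------------------------------
# Per-gene feature parts
# ---------------------------------------------------------------------------

class TestGwasFeatures:
    def test_top_five_ascending(self):
        ps = [0.9, 0.2, 0.5, 0.01, 0.3, 0.7, 0.04]
        snp_map = {"g": [(f"v{i}", i, p) for i, p in enumerate(ps)]}
        part, sel = gwas_features("g", snp_map)
        np.testing.assert_allclose(part, [0.01, 0.04, 0.2, 0.3, 0.5])
        assert len(sel) == 5

    def test_fewer_than_five_snps_padded_with_one(self):
        snp_map = {"g": [("a", 1, 0.001), ("b", 2, 0.01), ("c", 3, 0.2)]}
        part, sel = gwas_features("g", snp_map)
        np.testing.assert_array_equal(part, [0.001, 0.01, 0.2, 1.0, 1.0])
        assert sel == ["a", "b", "c"]

    def test_zero_snps_is_all_ones(self):
        part, sel = gwas_features("g", {"g": []})
        assert (part == 1.0).all() and sel == []

    def test_absent_gene_is_a_lookup_error(self):
        with pytest.raises(KeyError):
            gwas_features("missing", {"g": []})

    def test_ties_broken_by_position_then_id(self):
        snp_map = {"g": [("vB", 10, 0.5), ("vA", 10, 0.5), ("vC", 5, 0.5),
                         ("vD", 1, 0.1)]}
        _, sel = gwas_features("g", snp_map, k=3)
        assert sel == ["vD", "vC", "vA"]

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), max_size=12))
    def test_sorted_prefix_padded_property(self, pvals):
        snp_map = {"g": [(f"v{i}", i, p) for i, p in enumerate(pvals)]}
        part, _ = gwas_features("g", snp_map)
        expect, _ = oracle_gwas_part(snp_map["g"])
        np.testing.assert_allclose(part, expect)
        assert (np.diff(part) >= 0).all()
        assert (part[min(len(pvals), 5):] == 1.0).all()

    def test_adding_a_smaller_snp_never_raises_order_statistics(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ps = rng.uniform(size=rng.integers(1, 10)).tolist()
            snps = [(f"v{i}", i, p) for i, p in enumerate(ps)]
            before, _ = gwas_features("g", {"g": snps})
            extra = snps + [("vz", 99, float(min(ps) / 2))]
            after, _ = gwas_features("g", {"g": extra})
            assert (after <= before + 1e-15).all()


class TestEqtlFeatures:
    def test_direct_lookup(self):
        sel = [f"v{i}" for i in range(5)]
        eqtl = pd.DataFrame({"variant_id": sel, "gene_id": "g",
                             "pvalue": [.01, .02, .03, .04, .05]})
        np.testing.assert_allclose(eqtl_features("g", sel, eqtl),
                                   [.01, .02, .03, .04, .05])

    def test_no_records_is_full_padding(self):
        eqtl = pd.DataFrame(columns=["variant_id", "gene_id", "pvalue"])
        assert (eqtl_features("g", ["v1", "v2"], eqtl) == 1.0).all()

    def test_match_mode_pair_vs_snp_any_gene(self):
        eqtl = pd.DataFrame({"variant_id": ["v1"], "gene_id": ["other"],
                             "pvalue": [0.03]})
        pair = eqtl_features("g", ["v1"], eqtl, match_mode="pair")
        loose = eqtl_features("g", ["v1"], eqtl, match_mode="snp_any_gene")
        assert pair[0] == 1.0
        assert loose[0] == 0.03

    def test_alignment_preserved_with_gaps(self):
        eqtl = pd.DataFrame({"variant_id": ["v3"], "gene_id": ["g"],
                             "pvalue": [0.07]})
        part = eqtl_features("g", ["v1", "v2", "v3"], eqtl)
        np.testing.assert_array_equal(part, [1.0, 1.0, 0.07, 1.0, 1.0])


# ---------------------------------------------------------------------------
# Full matrix
# ---------------------------------------------------------------------------

class TestFeatureMatrix:
    def test_vectors_are_10d_and_in_unit_interval(self, small_dataset):
        ds = small_dataset
        feats, _ = build_feature_matrix(ds.annotation, ds.gwas, ds.eqtl)
        vals = feats[[c for c in feats.columns if c.startswith("P_")]]
        assert vals.shape[1] == 10
        assert ((vals > 0) & (vals <= 1)).all().all()

    def test_genes_without_snps_are_excluded_and_counted(self):
        rng = np.random.default_rng(1)
        ann, gwas, eqtl = random_tables(rng, n_genes=6, n_snps=8,
                                        genome_len=50_000)
        feats, excluded = build_feature_matrix(ann, gwas, eqtl)
        assert len(feats) + len(excluded) == 6
        mapped = oracle_map(gwas, ann)
        assert sorted(excluded) == sorted(g for g, v in mapped.items() if not v)

    def test_no_mapped_snp_anywhere_is_an_error(self):
        ann = pd.DataFrame([("g", "g", "chr9", 0, 10)],
                           columns=["gene_id", "symbol", "chrom", "start", "end"])
        gwas = pd.DataFrame([("v", "chr1", 5, 0.5)],
                            columns=["variant_id", "chrom", "pos", "pvalue"])
        eqtl = pd.DataFrame(columns=["variant_id", "gene_id", "pvalue"])
        with pytest.raises(ValueError, match="no gene"):
            build_feature_matrix(ann, gwas, eqtl)

    def test_row_order_permutation_invariance(self):
        rng = np.random.default_rng(3)
        ann, gwas, eqtl = random_tables(rng, n_genes=5, n_snps=40)
        base, _ = build_feature_matrix(ann, gwas, eqtl)
        shuf, _ = build_feature_matrix(
            ann, gwas.sample(frac=1, random_state=7).reset_index(drop=True),
            eqtl.sample(frac=1, random_state=8).reset_index(drop=True))
        pd.testing.assert_frame_equal(base, shuf)

    @pytest.mark.parametrize("seed", range(10))
    def test_matrix_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        ann, gwas, eqtl = random_tables(rng, n_genes=6, n_snps=60)
        try:
            feats, _ = build_feature_matrix(ann, gwas, eqtl)
        except ValueError:
            return  # no gene admitted in this draw
        mapped = oracle_map(gwas, ann)
        for gid in feats.index:
            gpart, sel = oracle_gwas_part(mapped[gid])
            tpart = oracle_eqtl_part(gid, sel, eqtl)
            np.testing.assert_allclose(
                feats.loc[gid, [f"P_p{i}" for i in range(1, 6)]].astype(float),
                gpart)
            np.testing.assert_allclose(
                feats.loc[gid, [f"P_T{i}" for i in range(1, 6)]].astype(float),
                tpart)

    def test_neglog10_scale_pads_with_zero(self, small_dataset):
        ds = small_dataset
        feats, _ = build_feature_matrix(ds.annotation, ds.gwas, ds.eqtl,
                                        scale="neglog10")
        vals = feats[[c for c in feats.columns if c.startswith("P_")]]
        assert (vals >= 0).all().all()
        raw, _ = build_feature_matrix(ds.annotation, ds.gwas, ds.eqtl)
        np.testing.assert_allclose(
            vals.to_numpy(dtype=float),
            -np.log10(raw[vals.columns].to_numpy(dtype=float)))
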