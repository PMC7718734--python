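import numpy as np
import pytest

import omniblup as ob


class TestSimulateGenotypes:
    def test_dosages_are_homozygous(self):
        G = ob.simulate_genotypes(n_lines=50, p_variants=200, seed=1)
        assert set(np.unique(G.dosages)) <= {0.0, 2.0}

    def test_no_ld_when_block_size_one(self):
        G = ob.simulate_genotypes(n_lines=300, p_variants=1001, ld_block_size=1, seed=2)
        D = G.dosages
        rs = []
        for j in range(1000):
            a, b = D[:, j], D[:, j + 1]
            if a.std() > 0 and b.std() > 0:
                rs.append(np.corrcoef(a, b)[0, 1])
        assert abs(np.mean(rs)) < 0.05

    def test_ld_blocks_induce_adjacent_correlation(self):
        G = ob.simulate_genotypes(
            n_lines=300, p_variants=400, ld_block_size=20, ld_copy_prob=0.9, seed=3
        )
        D = G.dosages
        within = [
            np.corrcoef(D[:, j], D[:, j + 1])[0, 1]
            for j in range(399)
            if (j % 20) != 19 and D[:, j].std() > 0 and D[:, j + 1].std() > 0
        ]
        assert np.mean(within) > 0.5

    def test_fixed_maf_half_hits_binomial_expectation(self):
        G = ob.simulate_genotypes(
            n_lines=400, p_variants=50, maf_range=(0.5, 0.5), ld_block_size=1, seed=4
        )
        maf = G.maf()
        se = np.sqrt(0.25 / 400)
        assert np.all(np.abs(maf - 0.5) < 5 * se)

    def test_deterministic_in_seed(self):
        a = ob.simulate_genotypes(n_lines=20, p_variants=30, seed=7)
        b = ob.simulate_genotypes(n_lines=20, p_variants=30, seed=7)
        np.testing.assert_array_equal(a.dosages, b.dosages)


class TestSimulateExpression:
    @pytest.fixture(scope="class")
    def geno(self):
        return ob.simulate_genotypes(n_lines=200, p_variants=300, seed=5)

    def test_zero_genetic_fraction_independent_of_genotypes(self, geno):
        E, truth = ob.simulate_expression(geno, n_genes=50, genetic_fraction=0.0, seed=6)
        cors = []
        for g, eqtls in truth.eqtl.items():
            j = E.gene_ids.index(g)
            for vid, _ in eqtls:
                k = geno.variant_ids.index(vid)
                cors.append(abs(np.corrcoef(E.abundances[:, j], geno.dosages[:, k])[0, 1]))
        assert np.mean(cors) < 0.1
        assert np.all(truth.realized_fractions == 0.0)

    def test_full_genetic_control_is_exact_linear_function(self, geno):
        E, truth = ob.simulate_expression(geno, n_genes=20, genetic_fraction=1.0, seed=7)
        g = E.gene_ids[0]
        j = 0
        recon = np.zeros(geno.n_lines)
        for vid, eff in truth.eqtl[g]:
            k = geno.variant_ids.index(vid)
            d = geno.dosages[:, k]
            recon += (d - d.mean()) * eff
        col = E.abundances[:, j] - E.abundances[:, j].mean()
        if recon.std() > 0:
            recon *= col.std(ddof=1) / recon.std(ddof=1)
        np.testing.assert_allclose(col, recon, atol=1e-8)

    def test_realized_fraction_matches_target(self, geno):
        E, truth = ob.simulate_expression(geno, n_genes=500, genetic_fraction=0.5, seed=8)
        nonzero = truth.realized_fractions[truth.realized_fractions > 0]
        assert abs(np.mean(nonzero) - 0.5) < 0.05
        assert np.max(np.abs(nonzero - 0.5)) < 1e-8  # exact by construction

    def test_too_many_eqtls_rejected(self, geno):
        with pytest.raises(ValueError, match="eqtl_per_gene"):
            ob.simulate_expression(geno, n_genes=5, eqtl_per_gene=10_000, seed=0)


class TestSimulatePhenotype:
    @pytest.fixture(scope="class")
    def layers(self):
        G = ob.simulate_genotypes(n_lines=150, p_variants=200, seed=9)
        E, truth = ob.simulate_expression(G, n_genes=100, genetic_fraction=0.5, seed=10)
        return G, E, truth

    def test_realized_h2_exact(self, layers):
        G, E, etruth = layers
        for h2 in (0.2, 0.5, 0.8):
            _, truth = ob.simulate_phenotype(
                G, E, "transcript_mediated", h2, ob.CausalSpec(n_causal_genes=20), seed=11
            )
            assert truth.realized_fractions["signal"] == pytest.approx(h2, abs=1e-10)

    def test_zero_h2_is_pure_noise(self, layers):
        G, E, _ = layers
        pheno, truth = ob.simulate_phenotype(
            G, E, "transcript_mediated", 0.0, ob.CausalSpec(n_causal_genes=20), seed=12
        )
        assert truth.realized_fractions["signal"] == 0.0
        assert np.var(pheno.trait_values("trait"), ddof=1) == pytest.approx(1.0)

    def test_gxt_requires_expression(self, layers):
        G, _, _ = layers
        with pytest.raises(ValueError, match="requires an expression layer"):
            ob.simulate_phenotype(G, None, "gxt", 0.5, seed=13)

    def test_causal_genes_restricted_to_go_pool(self, layers):
        G, E, _ = layers
        pool = E.gene_ids[:30]
        _, truth = ob.simulate_phenotype(
            G, E, "transcript_mediated", 0.5,
            ob.CausalSpec(n_causal_genes=10, causal_go_genes=pool), seed=14,
        )
        assert set(truth.causal_genes) <= set(pool)

    def test_mixed_with_shared_eqtls_uses_pool(self, layers):
        G, E, etruth = layers
        _, truth = ob.simulate_phenotype(
            G, E, "mixed", 0.6,
            ob.CausalSpec(n_causal_genes=10, n_causal_variants=20),
            seed=15, expression_truth=etruth,
        )
        eqtls = {v for g in truth.causal_genes for v, _ in etruth.eqtl[g]}
        assert set(truth.causal_variants) <= eqtls


class TestSimulateAnnotation:
    def test_exact_term_sizes(self):
        ann = ob.simulate_annotation([f"g{i}" for i in range(50)], n_terms=6,
                                     size_range=(5, 5), seed=16)
        for genes in ann.term_to_genes().values():
            assert len(genes) == 5

    def test_causal_term_contains_exactly_its_genes(self):
        gene_ids = [f"g{i}" for i in range(40)]
        causal = {"term_id": "GO:0000042", "gene_ids": gene_ids[:7]}
        ann = ob.simulate_annotation(gene_ids, n_terms=5, size_range=(5, 10),
                                     causal_term=causal, seed=17)
        assert ann.term_to_genes()["GO:0000042"] == set(gene_ids[:7])

    def test_unknown_causal_genes_rejected(self):
        with pytest.raises(ValueError, match="not in the universe"):
            ob.simulate_annotation(["g0"], n_terms=1, size_range=(1, 1),
                                   causal_term={"term_id": "GO:0000001",
                                                "gene_ids": ["nope"]}, seed=0)

    def test_spans_cover_a_toy_chromosome(self):
        ann = ob.simulate_annotation([f"g{i}" for i in range(10)], n_terms=2,
                                     size_range=(2, 4), seed=18, region_bp=10_000)
        for chrom, start, end in ann.gene_spans.values():
            assert chrom == "2L"
            assert 1 <= start <= end <= 10_400


class TestBundle:
    def test_bundle_is_pure_function_of_seed(self):
        cfg = ob.SimConfig(n_lines=30, p_variants=60, n_genes=30, n_terms=4,
                           term_size_range=(5, 8), causal_term_size=8,
                           causal=ob.CausalSpec(n_causal_genes=5, n_causal_variants=10))
        a = ob.simulate_bundle(cfg, seed=19)
        b = ob.simulate_bundle(cfg, seed=19)
        np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
        np.testing.assert_array_equal(a.expression.abundances, b.expression.abundances)
        np.testing.assert_array_equal(
            a.phenotypes.trait_values("trait"), b.phenotypes.trait_values("trait")
        )
        assert a.truth.causal_genes == b.truth.causal_genes

    def test_default_bundle_kernel_fidelity(self, tiny_bundle):
        panel = tiny_bundle.panel()
        ids = panel.line_ids
        W = ob.standardize_columns(panel.genotypes.dosages, panel.genotypes.variant_ids, ids)
        Z = ob.standardize_columns(panel.expression.abundances, panel.expression.gene_ids, ids)
        for F in (W, Z):
            K = ob.linear_kernel(F)
            off = K.values[~np.eye(len(ids), dtype=bool)]
            assert abs(off.mean()) < 0.05
            assert np.mean(np.diag(K.values)) == pytest.approx(1.0, abs=1e-10)

    def test_write_bundle_round_trip(self, tiny_bundle, tmp_path):
        paths = ob.write_bundle(tiny_bundle, tmp_path / "b")
        G = ob.read_genotypes(paths["genotypes"], format="dosage_tsv",
                              variants_path=paths["variants"])
        np.testing.assert_array_equal(G.dosages, tiny_bundle.genotypes.dosages)
        assert G.variants["pos"].tolist() == tiny_bundle.genotypes.variants["pos"].tolist()
        E = ob.read_matrix_table(paths["expression"], kind="expression")
        np.testing.assert_allclose(E.abundances, tiny_bundle.expression.abundances)
        ann = ob.read_annotation(paths["gene2go"], paths["spans"])
        assert ann.gene_to_terms == tiny_bundle.annotation.gene_to_terms
        assert ann.gene_spans == tiny_bundle.annotation.gene_spans

    def test_vcf_round_trip(self, tmp_path):
        G = ob.simulate_genotypes(n_lines=12, p_variants=25, seed=20)
        from omniblup.synthetic_data import _write_vcf

        path = _write_vcf(G, tmp_path / "g.vcf")
        back = ob.read_genotypes(path, format="vcf")
        np.testing.assert_array_equal(back.dosages, G.dosages)
        assert back.line_ids == G.line_ids
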