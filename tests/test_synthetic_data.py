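import numpy as np
import pytest
from scipy import stats

from exprweight.expr_weights import collapse_gene_burden, crude_weight, normalize_weights
from exprweight.io_formats import (
    _annotate_frequencies,
    read_expression,
    read_gene_annotation,
    read_phenotype,
    read_vcf_genotypes,
)
from exprweight.relatedness import estimate_kinship
from exprweight.synthetic_data import (
    SimulationConfig,
    _gene_drop,
    generate_dataset,
    read_truth,
    simulate_expression_and_phenotype,
    simulate_genotypes,
    simulate_pedigrees,
)


class TestSimulationConfig:
    def test_defaults_valid(self):
        SimulationConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"variants_per_gene": (1, 10)},
            {"variants_per_gene": (2, 50)},
            {"maf_range": (0.0, 0.005)},
            {"maf_range": (0.005, 0.02)},
            {"sd_phenotype": -1.0},
            {"frac_causal_chain": 0.8, "frac_reactive": 0.3},
            {"n_families": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestPedigrees:
    def test_trio_expected_matrix(self):
        cfg = SimulationConfig(n_families=1, n_children=1)
        ped, expected = simulate_pedigrees(cfg)
        assert len(ped) == 3
        # parent-parent 0, parent-child 0.5, diagonal 1
        assert expected[0, 1] == 0.0
        assert expected[0, 2] == 0.5
        assert expected[1, 2] == 0.5
        np.testing.assert_array_equal(np.diag(expected), 1.0)

    def test_block_diagonal_structure(self):
        cfg = SimulationConfig(n_families=50, n_children=2)
        ped, expected = simulate_pedigrees(cfg)
        assert expected.shape == (200, 200)
        # cross-family entries all zero
        assert expected[:4, 4:].max() == 0.0
        # sibs 0.5 within family
        assert expected[2, 3] == 0.5

    def test_invalid_family(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_families=0)


class TestGenotypes:
    def test_mendelian_consistency(self, small_family_data):
        """Each child's per-variant count lies within the bounds its parents'
        genotypes allow (exact check over all children and variants)."""
        d = small_family_data
        ped, rare = d["ped"], d["rare"]
        idx = {iid: i for i, iid in enumerate(ped["iid"])}
        counts = rare.counts
        for row in ped.itertuples(index=False):
            if row.father == "0":
                continue
            c = counts[idx[row.iid]]
            f = counts[idx[row.father]]
            m = counts[idx[row.mother]]
            lower = (f == 2).astype(int) + (m == 2).astype(int)
            upper = (f > 0).astype(int) + (m > 0).astype(int)
            assert (c >= lower).all() and (c <= upper).all()

    def test_zero_maf_columns_flagged_monomorphic(self, small_family_data):
        rng = np.random.default_rng(0)
        ped = small_family_data["ped"]
        counts = _gene_drop(ped, np.zeros(5), rng)
        assert counts.sum() == 0.0
        import pandas as pd

        from exprweight.io_formats import GenotypeMatrix

        g = GenotypeMatrix(
            ped["iid"].tolist(),
            counts,
            pd.DataFrame(
                {"chrom": "1", "pos": np.arange(1, 6), "ref": "A", "alt": "T"}
            ),
        )
        _annotate_frequencies(g)
        assert g.variants["monomorphic"].all()

    def test_founder_frequency_matches_target(self):
        """Realized founder allele frequency within the binomial interval."""
        cfg = SimulationConfig(n_families=5000, n_children=0)
        ped, _ = simulate_pedigrees(cfg)
        rng = np.random.default_rng(123)
        maf = 0.005
        counts = _gene_drop(ped, np.full(200, maf), rng)
        n_alleles = 2 * len(ped) * 200
        realized = counts.sum() / n_alleles
        se = np.sqrt(maf * (1 - maf) / n_alleles)
        assert abs(realized - maf) < 4 * se

    def test_gene_table_matches_variant_layout(self, small_family_data):
        d = small_family_data
        genes, rare = d["genes"], d["rare"]
        seen = []
        for gid, e in genes.entries.items():
            seen.extend(e.variant_indices)
            pos0 = rare.variants["pos"].iloc[e.variant_indices] - 1
            assert ((pos0 >= e.start) & (pos0 < e.end)).all()
        assert seen == list(range(rare.n_variants))

    def test_estimated_kinship_close_to_pedigree_expectation(self, small_family_data):
        d = small_family_data
        kin = estimate_kinship(d["common"], maf_min=0.05)
        err = np.abs(kin.sigma - d["expected_kinship"])
        off = err[~np.eye(err.shape[0], dtype=bool)]
        assert off.mean() < 0.05


class TestExpressionPhenotype:
    def test_truth_labels_partition_genes(self, small_family_data):
        d = small_family_data
        truth = d["truth"]
        assert sorted(truth.table["gene"]) == sorted(d["genes"].entries)
        assert set(truth.table["model"]) <= {"null", "causal_chain", "reactive", "direct"}

    def test_null_config_independent_of_genotype(self):
        cfg = SimulationConfig(
            n_families=40,
            n_genes=30,
            variants_per_gene=(2, 10),
            frac_causal_chain=0.0,
            frac_reactive=0.0,
            frac_direct=0.0,
            measurements=("SBP",),
            seed=77,
        )
        ped, ek = simulate_pedigrees(cfg)
        rare, genes, _ = simulate_genotypes(ped, cfg)
        expr, pheno, truth = simulate_expression_and_phenotype(rare, genes, cfg, ek)
        assert (truth.table["model"] == "null").all()
        # burden-phenotype correlations should be null-scale
        from exprweight.io_formats import average_visits

        y = average_visits(pheno, "SBP").loc[rare.samples].to_numpy()
        counts = rare.analysis_counts()
        cors = []
        for gid, e in genes.entries.items():
            g = counts[:, e.variant_indices].sum(axis=1)
            if g.std() > 0:
                cors.append(abs(np.corrcoef(g, y)[0, 1]))
        # mean |r| under the null is ~ sqrt(2/pi)/sqrt(n) ~ 0.063 at n=160
        assert np.mean(cors) < 0.12

    def test_chain_genes_rank_above_null_in_crude_weight(self):
        cfg = SimulationConfig(
            n_families=65,
            n_genes=40,
            n_probes=15,
            variants_per_gene=(2, 20),
            frac_causal_chain=0.25,
            frac_reactive=0.0,
            frac_direct=0.0,
            measurements=("SBP",),
            seed=31,
        )
        ped, ek = simulate_pedigrees(cfg)
        rare, genes, _ = simulate_genotypes(ped, cfg)
        expr, pheno, truth = simulate_expression_and_phenotype(rare, genes, cfg, ek)
        from exprweight.io_formats import average_visits

        y = average_visits(pheno, "SBP").loc[rare.samples].to_numpy()
        counts = rare.analysis_counts()
        crude = {}
        for gid, e in genes.entries.items():
            burden = collapse_gene_burden(counts[:, e.variant_indices], gene=gid)
            crude[gid], _, _ = crude_weight(burden, expr, y)
        chain = [crude[g] for g in truth.genes_with_model("causal_chain")]
        null = [crude[g] for g in truth.genes_with_model("null")]
        assert len(chain) >= 2
        p = stats.mannwhitneyu(chain, null, alternative="greater").pvalue
        assert p < 0.05

    def test_polygenic_effect_correlates_sibs(self):
        cfg = SimulationConfig(
            n_families=200,
            n_genes=5,
            variants_per_gene=(2, 5),
            frac_causal_chain=0.0,
            frac_reactive=0.0,
            frac_direct=0.0,
            polygenic_sd=1.5,
            sd_phenotype=0.5,
            measurements=("SBP",),
            n_visits=1,
            seed=55,
        )
        ped, ek = simulate_pedigrees(cfg)
        rare, genes, _ = simulate_genotypes(ped, cfg)
        _, pheno, _ = simulate_expression_and_phenotype(rare, genes, cfg, ek)
        from exprweight.io_formats import average_visits

        y = average_visits(pheno, "SBP").loc[rare.samples].to_numpy()
        fam = 2 + cfg.n_children
        sib1 = y[np.arange(cfg.n_families) * fam + 2]
        sib2 = y[np.arange(cfg.n_families) * fam + 3]
        unrel1 = y[np.arange(0, cfg.n_families - 1) * fam]  # parent of family i
        unrel2 = y[np.arange(1, cfg.n_families) * fam]  # parent of family i+1
        r_sib = np.corrcoef(sib1, sib2)[0, 1]
        r_unrel = np.corrcoef(unrel1, unrel2)[0, 1]
        assert r_sib > r_unrel + 0.15


class TestBundle:
    def test_round_trip_and_determinism(self, tmp_path):
        cfg = SimulationConfig(
            n_families=20,
            n_genes=10,
            n_probes=6,
            variants_per_gene=(2, 8),
            measurements=("SBP",),
            seed=99,
        )
        d1, d2 = tmp_path / "a", tmp_path / "b"
        paths1 = generate_dataset(cfg, str(d1))
        paths2 = generate_dataset(cfg, str(d2))
        for key in paths1:
            assert open(paths1[key], "rb").read() == open(paths2[key], "rb").read()

        geno = read_vcf_genotypes(paths1["vcf"])
        ped, ek = simulate_pedigrees(cfg)
        rare, genes, common = simulate_genotypes(ped, cfg)
        # the VCF interleaves rare (chrom 1) and common (chrom 2) panels
        assert geno.n_variants == rare.n_variants + common.n_variants
        rare_cols = geno.variants["chrom"] == "1"
        np.testing.assert_array_equal(
            geno.counts[:, rare_cols.to_numpy()], rare.counts
        )
        table = read_gene_annotation(paths1["bed"], geno)
        assert sorted(table.entries) == sorted(genes.entries)

        expr = read_expression(paths1["expression"])
        expr0, pheno0, truth0 = simulate_expression_and_phenotype(rare, genes, cfg, ek)
        np.testing.assert_allclose(expr.values, expr0.values, atol=1e-8)
        pheno = read_phenotype(paths1["phenotype"])
        assert sorted(pheno.measurements) == ["SBP"]
        truth = read_truth(paths1["truth"])
        assert truth.table["model"].tolist() == truth0.table["model"].tolist()

    def test_smoke_default_config_pipeline_ready(self, tmp_path):
        cfg = SimulationConfig(
            n_families=15, n_genes=6, variants_per_gene=(2, 6), seed=1
        )
        paths = generate_dataset(cfg, str(tmp_path / "bundle"))
        geno = read_vcf_genotypes(paths["vcf"])
        assert geno.n_samples == 60
        assert set(read_phenotype(paths["phenotype"]).measurements) == {"SBP", "DBP"}
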