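import numpy as np
import pytest

from exprweight.synthetic_data import (
    SimulationConfig,
    simulate_expression_and_phenotype,
    simulate_genotypes,
    simulate_pedigrees,
)

VCF_FIXTURE = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/0
1\t150\t.\tG\tC\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0\t0/0
1\t201\t.\tC\tA\t.\tPASS\t.\tGT\t./.\t0/1\t0/0\t0/1
"""

# hand-transcribed oracle for the fixture above (NaN = missing call)
VCF_ORACLE = np.array(
    [
        [0.0, 0.0, np.nan],
        [1.0, 0.0, 1.0],
        [2.0, 0.0, 0.0],
        [0.0, 0.0, 1.0],
    ]
)


@pytest.fixture
def vcf_path(tmp_path):
    p = tmp_path / "fixture.vcf"
    p.write_text(VCF_FIXTURE)
    return str(p)


@pytest.fixture(scope="session")
def small_family_data():
    """One small family dataset shared by read-only tests: genotypes,
    expected kinship, gene table, common panel, expression, phenotype, truth."""
    cfg = SimulationConfig(
        n_families=40,
        n_genes=40,
        n_probes=12,
        variants_per_gene=(2, 20),
        measurements=("SBP",),
        seed=20,
    )
    ped, expected = simulate_pedigrees(cfg)
    rare, genes, common = simulate_genotypes(ped, cfg)
    expr, pheno, truth = simulate_expression_and_phenotype(rare, genes, cfg, expected)
    return {
        "config": cfg,
        "ped": ped,
        "expected_kinship": expected,
        "rare": rare,
        "genes": genes,
        "common": common,
        "expression": expr,
        "phenotype": pheno,
        "truth": truth,
    }
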