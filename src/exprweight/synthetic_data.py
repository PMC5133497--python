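"""Family-structured synthetic genotype / expression / phenotype generator.

Emulates the features of a family sequencing study with paired expression:
nuclear families with known kinship, genes carrying a handful of rare
variants (MAF < 0.01), expression probes partly driven by gene burden, and a
quantitative phenotype receiving genetic effects either through expression
(the causative chain SNP -> E -> P), directly (SNP -> P), or with expression
reacting to the phenotype (SNP -> P -> E).  A separate common-variant panel
(MAF 0.05-0.5) is emitted for kinship estimation, mirroring the use of a
genome-wide marker panel for the relationship matrix.

Structural equations are linear-Gaussian; the shared family effect is drawn
MVN(0, sigma_A^2 * R) with R the pedigree-expected relationship matrix.
Founder haplotypes are Bernoulli(MAF) per variant and offspring genotypes
are produced by Mendelian gene-dropping (no linkage: variants segregate
independently, which is adequate because no analysis step here models LD).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from exprweight.io_formats import ExpressionMatrix, GeneEntry, GeneTable, GenotypeMatrix, PhenotypeTable, _annotate_frequencies

MODEL_LABELS = ("null", "causal_chain", "reactive", "direct")

_GENE_SPACING = 100_000  # bp between gene starts on the rare-variant chromosome
_VARIANT_SPACING = 10


@dataclass
class SimulationConfig:
    """Study-design knobs for the generator.

    Defaults emulate the family study the pipeline targets: 65 nuclear
    families of two parents and two children (260 individuals), genes with
    2-49 rare variants of MAF below 0.01, and a genome-wide common panel
    for relatedness.  Effect sizes are on the scale of the unit-variance
    expression/phenotype noise.
    """

    n_families: int = 65
    n_children: int = 2
    n_genes: int = 200
    variants_per_gene: tuple[int, int] = (2, 49)
    maf_range: tuple[float, float] = (0.002, 0.009)
    n_probes: int = 30
    n_common_markers: int = 5000
    common_maf_range: tuple[float, float] = (0.05, 0.5)
    b_gE: float = 2.5  # burden -> expression, per rare allele
    b_EP: float = 1.0  # expression -> phenotype
    b_gP: float = 1.0  # direct burden -> phenotype
    sd_expression: float = 1.0
    sd_phenotype: float = 1.0
    sd_visit: float = 0.5
    polygenic_sd: float = 0.7
    frac_causal_chain: float = 0.05
    frac_reactive: float = 0.025
    frac_direct: float = 0.025
    n_visits: int = 3
    measurements: tuple[str, ...] = ("SBP", "DBP")
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.variants_per_gene
        if not (2 <= lo <= hi <= 49):
            raise ValueError("variants_per_gene must lie within [2, 49]")
        mlo, mhi = self.maf_range
        if not (0.0 < mlo <= mhi < 0.01):
            raise ValueError("rare-variant MAF range must lie within (0, 0.01)")
        if min(self.sd_expression, self.sd_phenotype, self.sd_visit, self.polygenic_sd) < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.n_families < 1 or self.n_children < 0:
            raise ValueError("need at least one family; children must be >= 0")
        frac = self.frac_causal_chain + self.frac_reactive + self.frac_direct
        if frac > 1.0:
            raise ValueError("causal fractions sum above 1")


@dataclass
class SyntheticTruth:
    """Per-gene causal model labels, realized effect sizes and causal probes."""

    table: pd.DataFrame  # columns: gene, model, causal_probe, b_gE, b_EP, b_gP

    def __post_init__(self) -> None:
        bad = set(self.table["model"]) - set(MODEL_LABELS)
        if bad:
            raise ValueError(f"unknown model labels: {bad}")
        if self.table["gene"].duplicated().any():
            raise ValueError("model labels must partition the gene set")

    def genes_with_model(self, model: str) -> list[str]:
        return self.table.loc[self.table["model"] == model, "gene"].tolist()


def simulate_pedigrees(config: SimulationConfig, seed: int | None = None):
    """Nuclear-family pedigree and its expected relationship matrix.

    Founders are unrelated; on the relationship (GRM-diagonal-1) scale
    parent-child and full-sib entries are 0.5 and spouse entries 0.
    """
    if config.n_families < 1:
        raise ValueError("need at least one family")
    fam_size = 2 + config.n_children
    rows = []
    n = config.n_families * fam_size
    expected = np.zeros((n, n))
    for f in range(config.n_families):
        fid = f"F{f:03d}"
        base = f * fam_size
        father, mother = f"{fid}_P1", f"{fid}_P2"
        rows.append((fid, father, "0", "0", 1))
        rows.append((fid, mother, "0", "0", 2))
        for c in range(config.n_children):
            rows.append((fid, f"{fid}_C{c + 1}", father, mother, 1 + c % 2))
        block = np.full((fam_size, fam_size), 0.5)
        block[0, 1] = block[1, 0] = 0.0  # spouses unrelated
        np.fill_diagonal(block, 1.0)
        expected[base : base + fam_size, base : base + fam_size] = block
    ped = pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex"])
    return ped, expected


def _gene_drop(ped: pd.DataFrame, mafs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Founder Bernoulli haplotypes + Mendelian gene-dropping; returns counts."""
    n, m = len(ped), mafs.size
    idx = {iid: i for i, iid in enumerate(ped["iid"])}
    haps = np.zeros((n, 2, m), dtype=np.int8)
    founders = (ped["father"] == "0").to_numpy()
    haps[founders] = rng.random((int(founders.sum()), 2, m)) < mafs
    for i, row in enumerate(ped.itertuples(index=False)):
        if row.father == "0":
            continue
        for h, parent in enumerate((row.father, row.mother)):
            p = idx[parent]
            pick = rng.integers(0, 2, size=m)
            haps[i, h] = haps[p, pick, np.arange(m)]
    return haps.sum(axis=1).astype(float)


def simulate_genotypes(
    ped: pd.DataFrame, config: SimulationConfig, seed: int | None = None
) -> tuple[GenotypeMatrix, GeneTable, GenotypeMatrix]:
    """Rare gene variants plus a common marker panel by gene-dropping.

    Returns (rare genotypes, gene table joined to them, common panel).
    Rare variants sit on chromosome "1" in per-gene intervals; the common
    kinship panel sits on chromosome "2" so no gene contains it.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.variants_per_gene
    k_per_gene = rng.integers(lo, hi + 1, size=config.n_genes)
    mafs = rng.uniform(*config.maf_range, size=int(k_per_gene.sum()))
    counts = _gene_drop(ped, mafs, rng)

    entries: dict[str, GeneEntry] = {}
    meta = []
    col = 0
    for gi, k in enumerate(k_per_gene):
        start = gi * _GENE_SPACING
        end = start + int(k) * _VARIANT_SPACING + _VARIANT_SPACING
        idx = list(range(col, col + int(k)))
        for j in range(int(k)):
            meta.append(("1", start + _VARIANT_SPACING * j + 1, "A", "T"))
        entries[f"GENE{gi:04d}"] = GeneEntry("1", start, end, idx)
        col += int(k)
    rare = GenotypeMatrix(ped["iid"].tolist(), counts, pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt"]))
    _annotate_frequencies(rare)

    common_mafs = rng.uniform(*config.common_maf_range, size=config.n_common_markers)
    common_counts = _gene_drop(ped, common_mafs, rng)
    common_meta = pd.DataFrame(
        {
            "chrom": "2",
            "pos": np.arange(1, config.n_common_markers + 1) * 1000,
            "ref": "A",
            "alt": "T",
        }
    )
    common = GenotypeMatrix(ped["iid"].tolist(), common_counts, common_meta)
    _annotate_frequencies(common)
    return rare, GeneTable(entries), common


def simulate_expression_and_phenotype(
    rare: GenotypeMatrix,
    genes: GeneTable,
    config: SimulationConfig,
    expected_kinship: np.ndarray,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, PhenotypeTable, SyntheticTruth]:
    """Linear-Gaussian structural equations with known per-gene truth.

    causal_chain:  E_j = b_gE * g + e1;  P += b_EP * E_j
    direct:        P += b_gP * g, expression independent
    reactive:      P += b_gP * g;  E_j = b_EP * P + e1  (expression reacts)
    null:          expression and phenotype independent of g
    P additionally receives a polygenic family effect MVN(0, sd_A^2 R) and
    iid noise; visit-level records are P plus visit noise.  The second and
    later measurements share the genetic architecture but draw their own
    polygenic and noise terms; reactive probes track the first measurement.
    """
    rng = np.random.default_rng((config.seed + 1) if seed is None else seed)
    n = rare.n_samples
    counts = rare.analysis_counts()

    gene_ids = list(genes.entries)
    n_chain = round(config.frac_causal_chain * len(gene_ids))
    n_react = round(config.frac_reactive * len(gene_ids))
    n_direct = round(config.frac_direct * len(gene_ids))
    n_probe_needed = n_chain + n_react
    if n_probe_needed > config.n_probes:
        raise ValueError(
            f"{n_probe_needed} causal probes needed but only {config.n_probes} probes configured"
        )
    order = rng.permutation(len(gene_ids))
    labels = {}
    for r, gi in enumerate(order):
        if r < n_chain:
            labels[gene_ids[gi]] = "causal_chain"
        elif r < n_chain + n_react:
            labels[gene_ids[gi]] = "reactive"
        elif r < n_chain + n_react + n_direct:
            labels[gene_ids[gi]] = "direct"
        else:
            labels[gene_ids[gi]] = "null"

    probes = [f"probe_{j:03d}" for j in range(config.n_probes)]
    E = rng.normal(0.0, config.sd_expression, size=(n, config.n_probes))
    burdens = {gid: counts[:, genes.entries[gid].variant_indices].sum(axis=1) for gid in gene_ids}

    probe_cursor = 0
    truth_rows = []
    chain_terms = np.zeros(n)
    direct_terms = np.zeros(n)
    reactive_assignments = []  # (probe index, gene)
    for gid in gene_ids:
        model = labels[gid]
        probe_id, b_ge, b_ep, b_gp = "", 0.0, 0.0, 0.0
        if model == "causal_chain":
            j = probe_cursor
            probe_cursor += 1
            b_ge, b_ep = config.b_gE, config.b_EP
            E[:, j] += b_ge * burdens[gid]
            chain_terms += b_ep * E[:, j]
            probe_id = probes[j]
        elif model == "reactive":
            j = probe_cursor
            probe_cursor += 1
            b_gp, b_ep = config.b_gP, config.b_EP
            direct_terms += b_gp * burdens[gid]
            reactive_assignments.append((j, gid))
            probe_id = probes[j]
        elif model == "direct":
            b_gp = config.b_gP
            direct_terms += b_gp * burdens[gid]
        truth_rows.append((gid, model, probe_id, b_ge, b_ep, b_gp))

    # polygenic effect shares the pedigree covariance
    chol = np.linalg.cholesky(expected_kinship + 1e-8 * np.eye(n))

    records = []
    first_P = None
    for measurement in config.measurements:
        polygenic = config.polygenic_sd * (chol @ rng.normal(size=n))
        P = chain_terms + direct_terms + polygenic + rng.normal(0.0, config.sd_phenotype, size=n)
        if first_P is None:
            first_P = P
        for visit in range(1, config.n_visits + 1):
            vals = P + rng.normal(0.0, config.sd_visit, size=n)
            for iid, v in zip(rare.samples, vals):
                records.append((iid, visit, measurement, v))
    for j, _gid in reactive_assignments:
        E[:, j] = config.b_EP * first_P + rng.normal(0.0, config.sd_expression, size=n)

    expr = ExpressionMatrix(list(rare.samples), probes, E)
    pheno = PhenotypeTable(pd.DataFrame(records, columns=["individual", "visit", "measurement", "value"]))
    truth = SyntheticTruth(
        pd.DataFrame(truth_rows, columns=["gene", "model", "causal_probe", "b_gE", "b_EP", "b_gP"])
    )
    return expr, pheno, truth


# ---------------------------------------------------------------------------
# on-disk bundle
# ---------------------------------------------------------------------------


def _write_vcf(path: str, genos: list[GenotypeMatrix]) -> None:
    samples = genos[0].samples
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted({c for g in genos for c in g.variants["chrom"].unique()}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        rows = []
        for g in genos:
            for j, var in enumerate(g.variants.itertuples(index=False)):
                rows.append((str(var.chrom), int(var.pos), var.ref, var.alt, g.counts[:, j]))
        rows.sort(key=lambda r: (r[0], r[1]))
        for chrom, pos, ref, alt, col in rows:
            gts = "\t".join(gt_map.get(c, "./.") for c in col)
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def generate_dataset(config: SimulationConfig, out_dir: str) -> dict[str, str]:
    """Write a complete synthetic bundle readable by the io layer.

    Produces genotypes.vcf (rare + common panel), genes.bed, expression.tsv,
    phenotype.tsv, truth.tsv and pedigree.fam under ``out_dir``; the bundle
    is byte-identical for a fixed config (seed included).
    """
    os.makedirs(out_dir, exist_ok=True)
    ped, expected = simulate_pedigrees(config)
    rare, genes, common = simulate_genotypes(ped, config)
    expr, pheno, truth = simulate_expression_and_phenotype(rare, genes, config, expected)

    paths = {k: os.path.join(out_dir, v) for k, v in {
        "vcf": "genotypes.vcf",
        "bed": "genes.bed",
        "expression": "expression.tsv",
        "phenotype": "phenotype.tsv",
        "truth": "truth.tsv",
        "pedigree": "pedigree.fam",
    }.items()}

    _write_vcf(paths["vcf"], [rare, common])
    with open(paths["bed"], "w") as fh:
        for gid, e in genes.entries.items():
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{gid}\n")
    expr_df = pd.DataFrame(expr.values, columns=expr.probes)
    expr_df.insert(0, "sample", expr.samples)
    expr_df.to_csv(paths["expression"], sep="\t", index=False, float_format="%.10g")
    pheno.records.to_csv(paths["phenotype"], sep="\t", index=False, float_format="%.10g")
    truth.table.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    ped.assign(pheno=-9)[["fid", "iid", "father", "mother", "sex", "pheno"]].to_csv(
        paths["pedigree"], sep="\t", index=False, header=False
    )
    return paths


def read_truth(path: str) -> SyntheticTruth:
    """Read back a truth TSV; 'null' is a model label, not a missing value."""
    df = pd.read_csv(
        path,
        sep="\t",
        keep_default_na=False,
        dtype={"gene": str, "model": str, "causal_probe": str},
    )
    return SyntheticTruth(df)
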