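"""End-to-end orchestration: filter genes, test, weight, adjust, report.

Per phenotype the pipeline decorrelates and residualizes the averaged
measurement once, runs the sequential sum test for every eligible gene
(2-49 rare variants after MAF filtering), builds expression weights,
normalizes them to mean one within the phenotype's tested gene set, and
writes weight-adjusted p-values with two report flags per gene: a small raw
p-value or a small adjusted p-value each warrant follow-up, since variants
can act on the phenotype without altering expression.

Analysis is complete-case: only individuals present in genotypes,
expression and phenotype (with at least one visit per measurement) enter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from exprweight import expr_weights, io_formats, relatedness, rv_test
from exprweight.io_formats import GeneEntry, GeneTable, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str
    bed: str
    expression: str
    phenotype: str
    pheno_names: tuple[str, ...] = ("SBP", "DBP")
    maf_threshold: float = 0.01
    min_variants: int = 2
    max_variants: int = 49
    B: int = 500
    n_pcs: int = 3
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "results"
    kinship_maf: float = 0.05
    eigen_floor: float = 1e-6
    passes: int = 1
    display_3dp: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.maf_threshold <= 0.5:
            raise ValueError("maf_threshold must lie in (0, 0.5]")
        if self.min_variants < 2:
            raise ValueError("min_variants must be >= 2")
        if self.max_variants > 49:
            raise ValueError("max_variants must be <= 49")
        if not self.pheno_names:
            raise ValueError("need at least one phenotype")


def filter_genes(genes: GeneTable, geno: GenotypeMatrix, cfg: PipelineConfig) -> GeneTable:
    """Keep polymorphic rare variants (0 < MAF < threshold) and genes whose
    rare-variant count lies in [min_variants, max_variants]."""
    maf = geno.variants["maf"].to_numpy()
    rare = (maf > 0.0) & (maf < cfg.maf_threshold)
    kept: dict[str, GeneEntry] = {}
    for gid, e in genes.entries.items():
        idx = [i for i in e.variant_indices if rare[i]]
        if cfg.min_variants <= len(idx) <= cfg.max_variants:
            kept[gid] = GeneEntry(e.chrom, e.start, e.end, idx)
    logger.info(
        "gene filter: kept %d of %d genes (%d rare variants of %d total)",
        len(kept), len(genes), int(rare.sum()), geno.n_variants,
    )
    return GeneTable(kept)


def _align_samples(geno, expr, pheno_means: dict[str, pd.Series]):
    """Complete-case intersection, ordered as in the genotype matrix."""
    common = set(geno.samples) & set(expr.samples)
    for series in pheno_means.values():
        common &= set(series.index)
    ordered = [s for s in geno.samples if s in common]
    if len(ordered) < 10:
        raise ValueError(
            f"only {len(ordered)} samples shared across genotype, expression and "
            "phenotype inputs; check sample ids"
        )
    return ordered


def run_pipeline(cfg: PipelineConfig) -> pd.DataFrame:
    """Run the full analysis; returns the results table and writes TSVs."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    geno = io_formats.read_vcf_genotypes(cfg.vcf)
    genes = io_formats.read_gene_annotation(cfg.bed, geno)
    expr = io_formats.read_expression(cfg.expression)
    pheno = io_formats.read_phenotype(cfg.phenotype)

    pheno_means = {m: io_formats.average_visits(pheno, m) for m in cfg.pheno_names}
    samples = _align_samples(geno, expr, pheno_means)
    geno = geno.subset_samples(samples)
    expr = expr.subset_samples(samples)
    logger.info("analyzing %d complete-case individuals", len(samples))

    kin = relatedness.estimate_kinship(geno, maf_min=cfg.kinship_maf, eigen_floor=cfg.eigen_floor)
    axes = relatedness.compute_stratification_axes(geno, K=cfg.n_pcs)

    eligible = filter_genes(genes, geno, cfg)
    if len(eligible) == 0:
        raise ValueError("no genes eligible after rare-variant filtering")
    counts = geno.analysis_counts()

    per_pheno: dict[str, dict] = {}
    for measurement in cfg.pheno_names:
        y_raw = pheno_means[measurement].loc[samples].to_numpy(dtype=float)
        yt = relatedness.transform_phenotype(y_raw, kin, measurement=measurement)
        y = relatedness.residualize(yt, axes)

        raw_p, crude, decs = [], [], []
        for gid, e in eligible.entries.items():
            G_gene = counts[:, e.variant_indices]
            res = rv_test.seq_asum_vs(
                G_gene, y, B=cfg.B, seed=cfg.seed, gene_id=gid, passes=cfg.passes
            )
            burden = expr_weights.collapse_gene_burden(G_gene, gene=gid)
            w, _probe, dec = expr_weights.crude_weight(burden, expr, y)
            raw_p.append(res.p_value)
            crude.append(w)
            decs.append(dec)
        raw_p = np.asarray(raw_p)
        w_star = expr_weights.normalize_weights(np.asarray(crude))
        adj = expr_weights.adjust_pvalues(raw_p, w_star)
        per_pheno[measurement] = {
            "raw_p": raw_p, "w_star": w_star, "adjusted_p": adj, "decomp": decs,
        }

    results = []
    gene_ids = list(eligible.entries)
    for i, gid in enumerate(gene_ids):
        e = eligible.entries[gid]
        per = {}
        for m in cfg.pheno_names:
            d = per_pheno[m]
            per[m] = {
                "raw_p": float(d["raw_p"][i]),
                "weight": float(d["w_star"][i]),
                "adjusted_p": float(d["adjusted_p"][i]),
                "flag_raw_p": bool(d["raw_p"][i] <= cfg.alpha),
                "flag_adjusted_p": bool(d["adjusted_p"][i] <= cfg.alpha),
            }
        results.append(expr_weights.GeneResult(gid, e.chrom, len(e.variant_indices), per))

    # sort by the smallest adjusted p across phenotypes
    results.sort(key=lambda r: min(v["adjusted_p"] for v in r.per_phenotype.values()))
    io_formats.write_results(results, str(out / "results.tsv"), display_3dp=cfg.display_3dp)

    audit_rows = []
    for m in cfg.pheno_names:
        for dec in per_pheno[m]["decomp"]:
            for probe, wge, wep in zip(dec.probes, dec.w_gE, dec.w_EP):
                audit_rows.append((m, dec.gene, probe, wge, wep, wge * wep))
    pd.DataFrame(
        audit_rows, columns=["phenotype", "gene", "probe", "w_gE", "w_EP", "product"]
    ).to_csv(out / "weight_decomposition.tsv", sep="\t", index=False, float_format="%.6g")

    df = io_formats.read_results(str(out / "results.tsv"))
    flag_rows = []
    for r in results:
        row = {"gene": r.gene}
        for m, v in r.per_phenotype.items():
            row[f"{m}_flag_raw_p"] = v["flag_raw_p"]
            row[f"{m}_flag_adjusted_p"] = v["flag_adjusted_p"]
        flag_rows.append(row)
    df = df.merge(pd.DataFrame(flag_rows), on="gene")
    df.to_csv(out / "results_flagged.tsv", sep="\t", index=False, float_format="%.6g")

    n_sig = {
        m: int((per_pheno[m]["adjusted_p"] <= cfg.alpha).sum()) for m in cfg.pheno_names
    }
    logger.info("significant genes at alpha=%g (adjusted): %s", cfg.alpha, n_sig)
    return df
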