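"""Reusable simulation experiments: calibration, FWER and power studies.

These drive both the test suite and the reproduction script.  Problem sizes
are scaled for a single CPU: the type-I study uses 500 unrelated null genes,
the FWER study re-draws phenotype and expression over a fixed family
genotype panel (the relatedness structure and its decorrelation transform
depend only on genotypes, so re-simulating them per replicate would only
add Monte-Carlo noise, not information), and the power study re-simulates
complete family studies per replicate.
"""

from __future__ import annotations

import numpy as np

from exprweight.expr_weights import (
    bonferroni_threshold,
    collapse_gene_burden,
    crude_weight,
    normalize_weights,
    weighted_rejections,
)
from exprweight.io_formats import average_visits
from exprweight.pipeline import PipelineConfig, filter_genes
from exprweight.relatedness import (
    compute_stratification_axes,
    estimate_kinship,
    residualize,
    transform_phenotype,
)
from exprweight.rv_test import seq_asum_vs
from exprweight.synthetic_data import (
    SimulationConfig,
    simulate_expression_and_phenotype,
    simulate_genotypes,
    simulate_pedigrees,
)

_FILTER_CFG = dict(vcf="", bed="", expression="", phenotype="")


def type_one_error_study(
    n_genes: int = 500,
    n: int = 300,
    B: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate of the sequential sum test over independent null genes.

    Genes carry 2-49 rare variants (MAF 0.002-0.009) in unrelated
    individuals; the phenotype is standard normal noise.
    """
    rng = np.random.default_rng(seed)
    ps = []
    for g in range(n_genes):
        k = int(rng.integers(2, 50))
        mafs = rng.uniform(0.002, 0.009, size=k)
        G = rng.binomial(2, mafs, size=(n, k)).astype(float)
        y = rng.normal(size=n)
        ps.append(
            seq_asum_vs(G, y, B=B, seed=seed, gene_id=f"null{g}").p_value
        )
    ps = np.asarray(ps)
    return {
        "p_values": ps,
        "rejection_rate": float((ps <= alpha).mean()),
        "n_genes": n_genes,
    }


def _decorrelated_phenotype(pheno, measurement, kin, axes, samples):
    y_raw = average_visits(pheno, measurement).loc[samples].to_numpy(dtype=float)
    return residualize(transform_phenotype(y_raw, kin, measurement), axes)


def fwer_study(
    n_replicates: int = 200,
    n_genes: int = 200,
    B: int = 99,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Family-wise error of the end-to-end weighted-Bonferroni pipeline
    under a global null.

    One family genotype panel (65 families, 260 individuals) is simulated
    once; each replicate draws a fresh null phenotype and expression matrix,
    decorrelates, tests every eligible gene, builds normalized expression
    weights and applies the weighted Bonferroni rule at ``alpha``.  Returns
    the fraction of replicates with at least one rejection.
    """
    cfg = SimulationConfig(
        n_genes=n_genes,
        n_probes=20,
        variants_per_gene=(2, 20),
        frac_causal_chain=0.0,
        frac_reactive=0.0,
        frac_direct=0.0,
        measurements=("SBP",),
        n_visits=1,
        seed=seed,
    )
    ped, expected = simulate_pedigrees(cfg)
    rare, genes, common = simulate_genotypes(ped, cfg)
    kin = estimate_kinship(common, maf_min=0.05)
    axes = compute_stratification_axes(common, K=3)
    eligible = filter_genes(genes, rare, PipelineConfig(**_FILTER_CFG))
    counts = rare.analysis_counts()
    m = len(eligible)
    thr = bonferroni_threshold(alpha, m)

    n_any = 0
    for rep in range(n_replicates):
        expr, pheno, _ = simulate_expression_and_phenotype(
            rare, genes, cfg, expected, seed=seed + 10_000 + rep
        )
        y = _decorrelated_phenotype(pheno, "SBP", kin, axes, rare.samples)
        ps, crude = [], []
        for gid, e in eligible.entries.items():
            G = counts[:, e.variant_indices]
            ps.append(
                seq_asum_vs(G, y, B=B, seed=seed + rep, gene_id=gid).p_value
            )
            burden = collapse_gene_burden(G, gene=gid)
            w, _, _ = crude_weight(burden, expr, y)
            crude.append(w)
        w_star = normalize_weights(np.asarray(crude))
        if weighted_rejections(np.asarray(ps), w_star, thr).any():
            n_any += 1
    return {
        "fwer": n_any / n_replicates,
        "n_replicates": n_replicates,
        "n_genes_tested": m,
        "alpha": alpha,
    }


def power_study(
    n_replicates: int = 200,
    n_genes: int = 20,
    B: int = 499,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Weighted vs unweighted Bonferroni power under the causal chain.

    Each replicate simulates a complete family study (fresh pedigree
    genotypes, expression and phenotype) with 20% of genes following the
    SNP -> E -> P chain at the generator's default effect sizes, then counts
    causal-gene rejections under p <= alpha/m (unweighted) and
    p/w* <= alpha/m (weighted).
    """
    w_succ = u_succ = n_causal = n_w_only = n_u_only = 0
    for rep in range(n_replicates):
        cfg = SimulationConfig(
            n_genes=n_genes,
            n_probes=10,
            frac_causal_chain=0.2,
            frac_reactive=0.0,
            frac_direct=0.0,
            measurements=("SBP",),
            n_visits=1,
            seed=seed + 20_000 + rep,
        )
        ped, expected = simulate_pedigrees(cfg)
        rare, genes, common = simulate_genotypes(ped, cfg)
        kin = estimate_kinship(common, maf_min=0.05)
        axes = compute_stratification_axes(common, K=3)
        eligible = filter_genes(genes, rare, PipelineConfig(**_FILTER_CFG))
        counts = rare.analysis_counts()
        expr, pheno, truth = simulate_expression_and_phenotype(
            rare, genes, cfg, expected
        )
        y = _decorrelated_phenotype(pheno, "SBP", kin, axes, rare.samples)
        gids, ps, crude = [], [], []
        for gid, e in eligible.entries.items():
            G = counts[:, e.variant_indices]
            ps.append(
                seq_asum_vs(G, y, B=B, seed=seed + rep, gene_id=gid).p_value
            )
            burden = collapse_gene_burden(G, gene=gid)
            w, _, _ = crude_weight(burden, expr, y)
            crude.append(w)
            gids.append(gid)
        ps = np.asarray(ps)
        w_star = normalize_weights(np.asarray(crude))
        thr = bonferroni_threshold(alpha, len(gids))
        wrej = weighted_rejections(ps, w_star, thr)
        urej = ps <= thr
        chain = set(truth.genes_with_model("causal_chain"))
        for i, gid in enumerate(gids):
            if gid in chain:
                n_causal += 1
                w_succ += int(wrej[i])
                u_succ += int(urej[i])
                n_w_only += int(wrej[i] and not urej[i])
                n_u_only += int(urej[i] and not wrej[i])
    return {
        "power_weighted": w_succ / n_causal if n_causal else float("nan"),
        "power_unweighted": u_succ / n_causal if n_causal else float("nan"),
        "n_causal_genes": n_causal,
        "weighted_only": n_w_only,
        "unweighted_only": n_u_only,
    }
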