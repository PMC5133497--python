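"""Expression-informed gene weights and weighted-Bonferroni p-value adjustment.

Each gene i receives a weight built from two ordinary-least-squares
regressions per expression probe j:

  E_j = b0 + b_gE * g_i + c * P + e      ->  w_gE = (b_gE / SE(b_gE))^2
  P   = b0 + b_EP * E_j + c * g_i + e    ->  w_EP = (b_EP / SE(b_EP))^2

where g_i is the per-individual rare-allele burden of the gene (row sums of
its allele-count submatrix) and P the decorrelated, residualized phenotype.
The crude weight is the maximum over probes of w_gE * w_EP -- the product
is zero as soon as either link is absent, and amplified when the gene drives
phenotype-associated expression (the SNP -> E -> P chain).  Crude weights
are divided by their mean over the tested gene set so the normalized
weights average exactly one, which is the condition under which rejecting
p_i / w_i <= alpha preserves family-wise error control.  Adjusted p-values
are min(1, p / w*).

Degenerate regressions (constant regressor, perfect collinearity) yield a
weight of zero rather than an error: zero weight means "no usable
expression evidence".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from exprweight.io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

_COND_MAX = 1e12


@dataclass
class GeneBurden:
    """Per-individual total rare-allele count across a gene's variants."""

    gene: str
    g: np.ndarray

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        if self.g.ndim != 1:
            raise ValueError("burden must be a vector over individuals")
        if (self.g < 0).any():
            raise ValueError("burden counts must be non-negative")


@dataclass
class WeightDecomposition:
    """Per-probe (w_gE, w_EP) pairs behind a gene's crude weight."""

    gene: str
    probes: list[str]
    w_gE: np.ndarray
    w_EP: np.ndarray
    crude: float = 0.0
    argmax_probe: str = ""
    normalized: float = float("nan")

    @property
    def products(self) -> np.ndarray:
        return self.w_gE * self.w_EP


@dataclass
class GeneResult:
    """Per-gene, per-phenotype raw p, weight, adjusted p and report flags."""

    gene: str
    chrom: str
    k: int
    per_phenotype: dict = field(default_factory=dict)


def collapse_gene_burden(G_gene: np.ndarray, gene: str = "gene") -> GeneBurden:
    """Row sums of the gene's allele-count submatrix."""
    G = np.asarray(G_gene, dtype=float)
    if G.ndim != 2 or G.shape[1] < 1:
        raise ValueError("gene genotype matrix must be n x k with k >= 1")
    return GeneBurden(gene, G.sum(axis=1))


def wald_squared(beta_hat: float, se: float) -> float:
    """Squared Wald statistic (beta/SE)^2; 0 when the coefficient is inestimable."""
    if se < 0:
        raise ValueError("standard error must be non-negative")
    if se == 0 or not np.isfinite(se):
        return 0.0
    return float((beta_hat / se) ** 2)


def _ols_wald(X: np.ndarray, y: np.ndarray, coef: int) -> float:
    """Wald^2 for one coefficient of an OLS fit; 0 for degenerate designs.

    Uses the unbiased residual variance estimator (n - p degrees of freedom).
    """
    mask = np.isfinite(y) & np.isfinite(X).all(axis=1)
    X, y = X[mask], y[mask]
    n, p = X.shape
    if n <= p:
        return 0.0
    xtx = X.T @ X
    if np.linalg.cond(xtx) > _COND_MAX:
        logger.warning("degenerate regression design; weight set to 0")
        return 0.0
    xtxi = np.linalg.inv(xtx)
    beta = xtxi @ (X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - p)
    se = float(np.sqrt(max(sigma2, 0.0) * xtxi[coef, coef]))
    return wald_squared(float(beta[coef]), se)


def weight_gene_expression(g: GeneBurden, E_j: np.ndarray, P: np.ndarray) -> float:
    """w_gE: squared Wald statistic of the burden coefficient in E_j ~ 1 + g + P."""
    E_j = np.asarray(E_j, dtype=float)
    P = np.asarray(P, dtype=float)
    if not (len(g.g) == E_j.size == P.size):
        raise ValueError("burden, expression and phenotype lengths differ")
    X = np.column_stack([np.ones_like(P), g.g, P])
    return _ols_wald(X, E_j, coef=1)


def weight_expression_phenotype(E_j: np.ndarray, P: np.ndarray, g: GeneBurden) -> float:
    """w_EP: squared Wald statistic of the expression coefficient in P ~ 1 + E_j + g."""
    E_j = np.asarray(E_j, dtype=float)
    P = np.asarray(P, dtype=float)
    if not (len(g.g) == E_j.size == P.size):
        raise ValueError("burden, expression and phenotype lengths differ")
    X = np.column_stack([np.ones_like(E_j), E_j, g.g])
    return _ols_wald(X, P, coef=1)


def _batched_weights(g: np.ndarray, E: np.ndarray, P: np.ndarray):
    """Vectorised (w_gE_j, w_EP_j) over all probes for one gene.

    The burden-to-expression fits share a single design [1, g, P] and are
    solved in one shot; the expression-to-phenotype fits differ per probe and
    are solved as a stacked batch of 3x3 systems.  Falls back to per-probe
    loops when expression has missing values.
    """
    n, J = E.shape
    if np.isnan(E).any() or np.isnan(P).any() or np.isnan(g).any():
        gb = GeneBurden("g", g)
        w_ge = np.array([weight_gene_expression(gb, E[:, j], P) for j in range(J)])
        w_ep = np.array([weight_expression_phenotype(E[:, j], P, gb) for j in range(J)])
        return w_ge, w_ep

    dof = n - 3
    if dof <= 0:
        return np.zeros(J), np.zeros(J)

    # Eq: E_j ~ 1 + g + P (shared design)
    X = np.column_stack([np.ones(n), g, P])
    xtx = X.T @ X
    if np.linalg.cond(xtx) > _COND_MAX:
        w_ge = np.zeros(J)
    else:
        xtxi = np.linalg.inv(xtx)
        beta = xtxi @ (X.T @ E)  # 3 x J
        resid = E - X @ beta
        sigma2 = (resid * resid).sum(axis=0) / dof
        se2 = sigma2 * xtxi[1, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            w_ge = np.where(se2 > 0, beta[1] ** 2 / np.where(se2 > 0, se2, 1.0), 0.0)

    # Eq: P ~ 1 + E_j + g (per-probe design, batched 3x3 solves)
    sE = E.sum(axis=0)
    sEE = (E * E).sum(axis=0)
    sg = g.sum()
    sgg = float(g @ g)
    sEg = E.T @ g
    sP = P.sum()
    sPP = float(P @ P)
    sEP = E.T @ P
    sgP = float(g @ P)
    XtX = np.empty((J, 3, 3))
    XtX[:, 0, 0] = n
    XtX[:, 0, 1] = XtX[:, 1, 0] = sE
    XtX[:, 0, 2] = XtX[:, 2, 0] = sg
    XtX[:, 1, 1] = sEE
    XtX[:, 1, 2] = XtX[:, 2, 1] = sEg
    XtX[:, 2, 2] = sgg
    XtY = np.column_stack([np.full(J, sP), sEP, np.full(J, sgP)])
    w_ep = np.zeros(J)
    det_scale = np.abs(XtX).max(axis=(1, 2))
    ok = np.abs(np.linalg.det(XtX)) > (det_scale**3) / _COND_MAX
    if ok.any():
        XtXi = np.linalg.inv(XtX[ok])
        beta = np.einsum("jab,jb->ja", XtXi, XtY[ok])
        rss = sPP - np.einsum("ja,ja->j", beta, XtY[ok])
        sigma2 = np.maximum(rss, 0.0) / dof
        se2 = sigma2 * XtXi[:, 1, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(se2 > 0, beta[:, 1] ** 2 / np.where(se2 > 0, se2, 1.0), 0.0)
        w_ep[ok] = w
    return w_ge, w_ep


def crude_weight(
    g: GeneBurden, E: ExpressionMatrix, P: np.ndarray
) -> tuple[float, str, WeightDecomposition]:
    """Crude weight: max over probes of w_gE * w_EP, with its decomposition."""
    if len(E.probes) == 0:
        raise ValueError("expression matrix has no probes")
    P = np.asarray(P, dtype=float)
    if E.values.shape[0] != P.size or len(g.g) != P.size:
        raise ValueError("sample counts of burden, expression and phenotype differ")
    w_ge, w_ep = _batched_weights(g.g, E.values, P)
    products = w_ge * w_ep
    j = int(np.argmax(products))
    crude = float(products[j])
    dec = WeightDecomposition(
        gene=g.gene,
        probes=list(E.probes),
        w_gE=w_ge,
        w_EP=w_ep,
        crude=crude,
        argmax_probe=E.probes[j],
    )
    return crude, E.probes[j], dec


def normalize_weights(crude: np.ndarray) -> np.ndarray:
    """Divide crude weights by their mean so the normalized mean is exactly 1."""
    crude = np.asarray(crude, dtype=float)
    if crude.size == 0:
        raise ValueError("no genes to normalize over")
    if (crude < 0).any():
        raise ValueError("crude weights must be non-negative")
    mean = crude.mean()
    if mean <= 0:
        raise ValueError("all crude weights are zero; normalization undefined")
    return crude / mean


def adjust_pvalues(raw_p: np.ndarray, w_star: np.ndarray) -> np.ndarray:
    """Weight-adjusted p-values min(1, p / w*), capped at 1."""
    raw_p = np.asarray(raw_p, dtype=float)
    w_star = np.asarray(w_star, dtype=float)
    if raw_p.shape != w_star.shape:
        raise ValueError("p-values and weights have different shapes")
    if ((raw_p <= 0) | (raw_p > 1)).any():
        raise ValueError("raw p-values must lie in (0, 1]")
    if (w_star <= 0).any():
        raise ValueError("weights must be positive; zero-weight genes cannot be adjusted")
    return np.minimum(1.0, raw_p / w_star)


def weighted_rejections(raw_p: np.ndarray, w_star: np.ndarray, alpha: float) -> np.ndarray:
    """Reject gene i when p_i / w*_i <= alpha (weighted thresholding)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    raw_p = np.asarray(raw_p, dtype=float)
    w_star = np.asarray(w_star, dtype=float)
    if (w_star <= 0).any():
        raise ValueError("weights must be positive")
    return raw_p / w_star <= alpha


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m over m tested genes."""
    if m < 1:
        raise ValueError("need at least one gene")
    return alpha / m
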