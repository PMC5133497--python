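"""Sequential sum test with variable selection (Seq-aSum-VS) for gene regions.

For a gene with k rare variants the pooled regressor is
x = sum_i gamma_i * SNP_i with gamma_i = v_i * s_i and s_i in {+1, -1, 0}
(positive effect, negative effect, excluded).  The per-variant signs are
chosen by a greedy sequential pass that maximizes the score statistic of the
pooled regressor against the decorrelated, residualized phenotype;
significance comes from permutations in which the *whole selection* is
re-run on the permuted phenotype, so the optimism of the data-adaptive
selection is reflected in the null distribution.

The score statistic for a simple linear association reduces to n * r^2
(Pearson correlation r) under the MLE variance estimate; because a
permutation of y preserves its variance, permuted and observed statistics
can be compared on the unnormalised U^2 / (s' A s) scale.

Reproducibility: each gene draws its permutations from an independent RNG
stream derived from the root seed and a stable hash of the gene id, so
results do not depend on gene iteration order.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np

_CANDIDATES = (1.0, -1.0, 0.0)  # tie preference order: +1 > -1 > 0


@dataclass
class SignVector:
    """Per-variant sign selection s in {+1,-1,0}^k with weights v (default 1)."""

    s: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.s.shape != self.v.shape or self.s.ndim != 1:
            raise ValueError("s and v must be 1-d vectors of equal length")
        if not np.isin(self.s, (-1.0, 0.0, 1.0)).all():
            raise ValueError("sign entries must be in {+1, -1, 0}")
        if (self.v <= 0).any():
            raise ValueError("variant weights v must be positive")

    @property
    def gamma(self) -> np.ndarray:
        return self.s * self.v


@dataclass
class GeneTestResult:
    gene: str
    k: int
    statistic: float
    p_value: float
    selected: SignVector
    B: int
    seed: int

    def __post_init__(self) -> None:
        b = round(self.p_value * (self.B + 1) - 1)
        if not (0 <= b <= self.B):
            raise ValueError("p_value inconsistent with (b+1)/(B+1) for 0 <= b <= B")


def gene_rng(seed: int, gene_id: str) -> np.random.Generator:
    """Per-gene RNG stream: root seed + CRC32 of the gene id."""
    tag = zlib.crc32(str(gene_id).encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def score_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Score statistic U^2 / V for the slope of y on x.

    U = sum (x - xbar)(y - ybar), V = sigma2_MLE(y) * sum (x - xbar)^2,
    which simplifies to n * r^2.  Returns 0 for a constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx <= 0.0 or syy <= 0.0:
        return 0.0
    u = float(xc @ yc)
    return n * u * u / (sxx * syy)


def permutation_pvalue(b: int, B: int) -> float:
    """(b+1)/(B+1): valid permutation p-value, never zero."""
    if not 0 <= b <= B:
        raise ValueError(f"exceedance count b={b} outside [0, B={B}]")
    return (b + 1) / (B + 1)


def _greedy_select(A: np.ndarray, C: np.ndarray, mono: np.ndarray, s_init: np.ndarray | None = None):
    """Vectorized greedy sign selection across permutation columns.

    A is the k x k Gram matrix of centered genotype columns; C is k x R with
    column r holding Gc' y_r for the r-th (permuted) centered phenotype.
    Returns (stats, signs): the unnormalised statistic U^2 / (s' A s) and
    the selected sign matrix (k x R).  Statistic 0 where s' A s == 0.

    One forward pass in genomic order, initialized all +1; at each position
    the sign in {+1, -1, 0} maximizing the statistic (others held fixed) is
    kept, ties broken by preference +1 > -1 > 0 -- except an exact +1/-1 tie,
    which the squared statistic cannot distinguish, resolves to the sign of
    the pooled covariance so a lone negatively-associated variant is coded
    -1.  Monomorphic variants are forced to 0.
    """
    k, R = C.shape
    s = np.ones((k, R)) if s_init is None else s_init.copy()
    s[mono, :] = 0.0
    As = A @ s  # k x R
    cs = np.einsum("kr,kr->r", s, C)
    sAs = np.einsum("kr,kr->r", s, As)

    def stat(cs_, sAs_):
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(sAs_ > 0, cs_ * cs_ / np.where(sAs_ > 0, sAs_, 1.0), 0.0)
        return out

    for i in range(k):
        if mono[i]:
            continue
        cur = s[i].copy()
        cand_stats = np.empty((len(_CANDIDATES), R))
        for c_idx, v in enumerate(_CANDIDATES):
            d = v - cur
            cand_stats[c_idx] = stat(cs + d * C[i], sAs + d * (2.0 * As[i] + d * A[i, i]))
        choice = np.argmax(cand_stats, axis=0)  # first max wins -> preference order
        # an exact +1 / -1 tie (e.g. k = 1: the statistic is sign-free) resolves
        # to the sign giving a non-negative pooled covariance with y
        cs_plus = cs + (1.0 - cur) * C[i]
        tie = (cand_stats[0] == cand_stats[1]) & (choice == 0) & (cs_plus < 0)
        choice = np.where(tie, 1, choice)
        vals = np.asarray(_CANDIDATES)[choice]
        d = vals - cur
        cs = cs + d * C[i]
        sAs = sAs + d * (2.0 * As[i] + d * A[i, i])
        As = As + np.outer(A[:, i], d)
        s[i] = vals
    return stat(cs, sAs), s


def select_variant_signs(
    G_gene: np.ndarray, y: np.ndarray, v: np.ndarray | None = None, passes: int = 1
) -> SignVector:
    """Greedy data-adaptive sign/exclusion selection for one gene.

    ``passes`` repeats the forward sweep (default a single pass).
    """
    G = np.asarray(G_gene, dtype=float)
    if G.ndim != 2 or G.shape[1] < 1:
        raise ValueError("gene genotype matrix must be n x k with k >= 1")
    y = np.asarray(y, dtype=float)
    if y.shape != (G.shape[0],):
        raise ValueError("phenotype length does not match genotype rows")
    if v is None:
        v = np.ones(G.shape[1])
    v = np.asarray(v, dtype=float)
    Gv = G * v
    Gc = Gv - Gv.mean(axis=0)
    A = Gc.T @ Gc
    mono = np.isclose(np.diag(A), 0.0)
    yc = (y - y.mean())[:, None]
    C = Gc.T @ yc
    s = None
    for _ in range(max(1, passes)):
        _, s = _greedy_select(A, C, mono, s_init=s)
    return SignVector(s[:, 0], v)


def seq_asum_vs(
    G_gene: np.ndarray,
    y: np.ndarray,
    B: int = 500,
    seed: int = 0,
    gene_id: str = "gene",
    v: np.ndarray | None = None,
    passes: int = 1,
    reselect: bool = True,
) -> GeneTestResult:
    """Gene-level sequential sum test with permutation p-value.

    The observed statistic is computed after sign selection; each of the B
    permutations of y re-runs the selection (``reselect=True``, the valid
    default -- freezing the observed signs ignores selection optimism and
    inflates type-I error).  p = (b+1)/(B+1) with b the number of permuted
    statistics >= observed.
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    G = np.asarray(G_gene, dtype=float)
    y = np.asarray(y, dtype=float)
    if G.ndim != 2 or G.shape[1] < 1:
        raise ValueError("gene genotype matrix must be n x k with k >= 1")
    n, k = G.shape
    if y.shape != (n,):
        raise ValueError("phenotype length does not match genotype rows")
    if not np.isfinite(y).all():
        raise ValueError("phenotype contains non-finite values")
    if n < 10:
        warnings.warn(f"n={n} < 10: permutation p-values will be unstable", stacklevel=2)

    if v is None:
        v = np.ones(k)
    v = np.asarray(v, dtype=float)
    rng = gene_rng(seed, gene_id)
    yc = y - y.mean()
    perm = np.argsort(rng.random((B, n)), axis=1)
    Y = np.empty((n, B + 1))
    Y[:, 0] = yc
    Y[:, 1:] = yc[perm].T  # permutations preserve Syy, so no per-column scaling

    Gv = G * v
    Gc = Gv - Gv.mean(axis=0)
    A = Gc.T @ Gc
    mono = np.isclose(np.diag(A), 0.0)
    C = Gc.T @ Y
    if reselect:
        stats, signs = _greedy_select(A, C, mono)
        for _ in range(max(1, passes) - 1):
            stats, signs = _greedy_select(A, C, mono, s_init=signs)
    else:
        # signs frozen from the observed phenotype (diagnostic mode only)
        _, signs0 = _greedy_select(A, C[:, :1], mono)
        s0 = signs0[:, 0]
        sAs = float(s0 @ A @ s0)
        cs = s0 @ C
        stats = cs * cs / sAs if sAs > 0 else np.zeros(B + 1)
        signs = np.repeat(s0[:, None], B + 1, axis=1)

    b = int(np.sum(stats[1:] >= stats[0]))
    p = permutation_pvalue(b, B)

    syy = float(yc @ yc)
    statistic = n * stats[0] / syy if syy > 0 else 0.0
    return GeneTestResult(
        gene=str(gene_id),
        k=k,
        statistic=float(statistic),
        p_value=p,
        selected=SignVector(signs[:, 0], v),
        B=B,
        seed=int(seed),
    )
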