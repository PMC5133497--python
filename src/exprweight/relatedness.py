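"""Relatedness estimation and phenotype decorrelation for family data.

The phenotype of related individuals is modelled as Y ~ MVN(mu, Sigma) with
Sigma a SNP-estimated genetic relationship matrix (GRM).  Premultiplying by
Sigma^(-1/2) yields transformed values that are exchangeable across
individuals, which is what justifies permutation inference downstream.
Population stratification is adjusted by regressing the transformed
phenotype on the leading multidimensional-scaling axes of the standardized
genotype matrix (identical to principal-component scores).

Scaling note: the GRM here is on the "relationship" scale (self ~ 1,
parent-child ~ 0.5), i.e. twice the kinship coefficient.  A global rescaling
of Sigma rescales Y* uniformly and cancels in permutation inference; the
``scale`` argument of :func:`estimate_kinship` exposes it anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from exprweight.io_formats import GenotypeMatrix

_SYM_TOL = 1e-8


@dataclass
class KinshipMatrix:
    """Symmetric relatedness matrix over individuals.

    ``eigen_floor`` is the lower bound applied to eigenvalues before
    inversion; empirical GRMs are frequently near-singular.
    """

    sigma: np.ndarray
    samples: list[str]
    eigen_floor: float = 1e-6

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = len(self.samples)
        if self.sigma.shape != (n, n):
            raise ValueError("kinship matrix shape does not match sample count")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("kinship matrix not symmetric within 1e-10")
        if self.eigen_floor <= 0:
            raise ValueError("eigen_floor must be positive")


@dataclass
class TransformedPhenotype:
    """Decorrelated phenotype Y* = Sigma^(-1/2) Y."""

    values: np.ndarray
    measurement: str = ""
    covariate_residualized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("transformed phenotype contains non-finite values")


@dataclass
class StratificationAxes:
    """Leading MDS/PCA axes of the standardized genotype matrix (n x K)."""

    axes: np.ndarray
    eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.axes = np.asarray(self.axes, dtype=float)
        if self.axes.ndim != 2:
            raise ValueError("axes must be a 2-d matrix")


def estimate_kinship(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    scale: float = 1.0,
    eigen_floor: float = 1e-6,
) -> KinshipMatrix:
    """Estimate the GRM from SNP allele counts.

    Sigma_kl = (1/M) sum_m (g_km - 2 p_m)(g_lm - 2 p_m) / (2 p_m (1 - p_m))
    over the M variants with MAF >= ``maf_min`` (Astle-Balding / VanRaden
    form).  Missing genotypes enter mean-imputed.
    """
    if geno.n_samples < 2:
        raise ValueError("kinship estimation requires at least 2 individuals")
    counts = geno.analysis_counts()
    p = counts.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = (maf >= maf_min) & (maf > 0.0)
    if not keep.any():
        raise ValueError(f"no polymorphic variants with MAF >= {maf_min}")
    g = counts[:, keep]
    p = p[keep]
    z = (g - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    sigma = scale * (z @ z.T) / z.shape[1]
    sigma = (sigma + sigma.T) / 2.0
    return KinshipMatrix(sigma, list(geno.samples), eigen_floor=eigen_floor)


def inverse_sqrt(kin: KinshipMatrix) -> np.ndarray:
    """Symmetric inverse square root of Sigma via eigendecomposition.

    Eigenvalues are floored at ``kin.eigen_floor`` before taking
    lambda^(-1/2), so the result is defined for near-singular GRMs.
    """
    sigma = kin.sigma
    if not np.allclose(sigma, sigma.T, atol=_SYM_TOL):
        raise ValueError("matrix not symmetric within tolerance")
    vals, vecs = np.linalg.eigh(sigma)
    vals = np.maximum(vals, kin.eigen_floor)
    return (vecs * (1.0 / np.sqrt(vals))) @ vecs.T


def transform_phenotype(
    y: np.ndarray, kin: KinshipMatrix, measurement: str = ""
) -> TransformedPhenotype:
    """Decorrelate a phenotype vector: Y* = Sigma^(-1/2) y."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size != len(kin.samples):
        raise ValueError(
            f"phenotype length {y.size} does not match kinship dimension {len(kin.samples)}"
        )
    if not np.isfinite(y).all():
        raise ValueError("phenotype contains missing values; drop and realign upstream")
    ystar = inverse_sqrt(kin) @ y
    return TransformedPhenotype(ystar, measurement=measurement)


def compute_stratification_axes(geno: GenotypeMatrix, K: int = 3) -> StratificationAxes:
    """Top-K classical MDS axes of the standardized genotype matrix.

    Torgerson scaling on the Gram matrix of column-standardized counts,
    which equals the top-K PCA score matrix.  Deterministic: each column's
    sign is fixed so its largest-magnitude entry is positive.
    """
    n, m = geno.n_samples, geno.n_variants
    counts = geno.analysis_counts()
    sd = counts.std(axis=0)
    usable = sd > 0
    if K >= min(n, int(usable.sum()) + 1):
        raise ValueError(f"K={K} must be smaller than min(n, usable variants)")
    z = (counts[:, usable] - counts[:, usable].mean(axis=0)) / sd[usable]
    gram = z @ z.T  # rows already centered since columns are
    vals, vecs = np.linalg.eigh(gram)
    order = np.argsort(vals)[::-1][:K]
    lam = np.maximum(vals[order], 0.0)
    axes = vecs[:, order] * np.sqrt(lam)
    for j in range(K):
        i = int(np.argmax(np.abs(axes[:, j])))
        if axes[i, j] < 0:
            axes[:, j] = -axes[:, j]
    return StratificationAxes(axes, eigenvalues=lam)


def residualize(yt: TransformedPhenotype, axes: StratificationAxes) -> np.ndarray:
    """OLS residuals of Y* on an intercept plus the stratification axes.

    The residual vector is exactly orthogonal to each axis and to the
    intercept (mean zero); collinear or all-zero axis columns are rejected
    with the offending column named.
    """
    y = yt.values
    A = axes.axes
    if A.shape[0] != y.size:
        raise ValueError("axes and phenotype have different sample counts")
    norms = np.linalg.norm(A, axis=0)
    zero = np.nonzero(norms == 0)[0]
    if zero.size:
        raise ValueError(f"stratification axis column {int(zero[0])} is all zero")
    X = np.column_stack([np.ones_like(y), A])
    # column-pivot-free QR: a tiny diagonal element names the collinear column
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    bad = np.nonzero(diag < 1e-10 * max(diag.max(), 1.0))[0]
    if bad.size:
        raise ValueError(f"stratification axis column {int(bad[0]) - 1} is collinear")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta
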