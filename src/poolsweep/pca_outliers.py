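"""PCA-based SNP outlier scan on pooled allele frequencies.

Pipeline: build a SNP x population frequency matrix (alternate allele
relative to the global major allele), compute K principal components over
pools, regress every SNP's frequency profile on the component scores to get
a K-vector of z-scores, then flag outliers by Mahalanobis distance with
chi-squared(K) p-values and Benjamini-Hochberg q-values.

With few pools the scan is weakly powered; a warning is raised when the
number of populations is not at least K + 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diversity import SubsampleStatus
from .io import SyncMatrix

__all__ = [
    "FreqMatrix",
    "build_freq_matrix",
    "pca_zscores",
    "mahalanobis_pvalues",
    "fdr_correct",
    "scan",
]


@dataclass
class FreqMatrix:
    """Per-SNP alternate-allele frequencies across populations."""

    chroms: np.ndarray
    pos: np.ndarray
    freqs: np.ndarray        # (n_snps, n_populations) in [0, 1]
    major: np.ndarray        # global major allele index per SNP
    alt: np.ndarray          # global alternate (second) allele index per SNP

    def __post_init__(self) -> None:
        if ((self.freqs < 0) | (self.freqs > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def n_snps(self) -> int:
        return self.freqs.shape[0]

    @property
    def n_populations(self) -> int:
        return self.freqs.shape[1]


def build_freq_matrix(
    mat: SyncMatrix,
    counts: np.ndarray | None = None,
    status: np.ndarray | None = None,
    min_count: int = 2,
) -> FreqMatrix:
    """Alternate-allele frequency matrix from (subsampled) pooled counts.

    ``counts`` is ``(n_sites, n_pops, 4)`` (defaults to the raw sync
    counts); ``status`` is an optional per-site, per-population
    :class:`SubsampleStatus` array -- rows where any population is not OK
    are excluded, as are sites monomorphic across all pools after
    ``min_count`` filtering. Multi-allelic sites are reduced to the two
    globally most frequent alleles and frequencies renormalised over them.
    """
    if counts is None:
        counts = mat.counts[:, :, :4]
    counts = np.asarray(counts)
    keep = np.ones(counts.shape[0], dtype=bool)
    if status is not None:
        keep &= (np.asarray(status) == SubsampleStatus.OK).all(axis=1)

    filt = counts.copy()
    total = filt.sum(axis=1)                      # (L, 4) summed over pools
    total[total < min_count] = 0
    order = np.argsort(total, axis=1, kind="stable")
    major = order[:, 3]
    alt = order[:, 2]
    li = np.arange(counts.shape[0])
    keep &= total[li, alt] > 0                    # polymorphic across pools
    # gather per-pop counts of the two global alleles
    maj_counts = np.take_along_axis(counts, major[:, None, None], axis=2)[:, :, 0]
    alt_counts = np.take_along_axis(counts, alt[:, None, None], axis=2)[:, :, 0]
    denom = maj_counts + alt_counts
    keep &= (denom > 0).all(axis=1)               # no missing population
    with np.errstate(divide="ignore", invalid="ignore"):
        freqs = np.where(denom > 0, alt_counts / np.maximum(denom, 1), np.nan)
    return FreqMatrix(
        chroms=mat.chroms[keep],
        pos=mat.pos[keep],
        freqs=freqs[keep],
        major=major[keep],
        alt=alt[keep],
    )


def pca_zscores(
    freq: FreqMatrix | np.ndarray, K: int = 2, scale: bool = True,
) -> np.ndarray:
    """Z-scores from regressing each SNP's frequency profile on K components.

    The principal components are the left singular vectors of the
    (column-centred, optionally column-scaled) pools x SNPs matrix. For each
    SNP, the standardized coefficients of the orthonormal regression on the
    K component score vectors are returned (shape ``(n_snps, K)``).
    """
    F = freq.freqs if isinstance(freq, FreqMatrix) else np.asarray(freq, dtype=float)
    L, P = F.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if P < K + 2:
        warnings.warn(
            f"{P} populations with K={K}: outlier scan is weakly powered",
            stacklevel=2,
        )
    X = F.T.astype(float)                       # pools x SNPs
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = X / sd
    if not np.any(X):
        raise ValueError("zero-variance frequency matrix: PCA undefined")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    Uk = U[:, :K]                               # (P, K), orthonormal scores
    beta = Uk.T @ X                             # (K, L)
    resid = X - Uk @ beta
    df = P - 1 - K                              # centring consumes one df
    if df <= 0:
        # saturated regression (e.g. 3 pools, K=2): no residual variance to
        # standardise by; fall back to raw coefficients, ranked by Mahalanobis
        warnings.warn(
            f"{P} populations saturate a K={K} regression; "
            "using unstandardised coefficients as z-scores",
            stacklevel=2,
        )
        return beta.T
    sigma = np.sqrt((resid**2).sum(axis=0) / df)
    sigma[sigma == 0] = np.finfo(float).tiny
    t = (beta / sigma).T                        # (L, K)
    # the standardised coefficient is exactly t(df)-distributed under the
    # null; map it to a normal score so the downstream chi-squared tail is
    # calibrated (chi2 p-values on raw t-ratios are anti-conservative in the
    # extreme tail, which is where FDR control lives)
    with np.errstate(divide="ignore"):
        z = np.sign(t) * stats.norm.isf(stats.t.sf(np.abs(t), df))
    return np.clip(z, -40, 40)


def mahalanobis_pvalues(
    zscores: np.ndarray, K: int | None = None,
    robust: bool = False, gif: bool = False,
) -> pd.DataFrame:
    """Mahalanobis distances of z-vectors and chi-squared(K) p-values.

    The covariance of z is estimated from all SNPs (sample covariance by
    default; with ``robust`` a median/MAD diagonal estimate). ``gif``
    additionally rescales distances by the genomic inflation factor
    (median d2 over the chi-squared median); off by default.
    """
    z = np.asarray(zscores, dtype=float)
    if z.ndim != 2:
        raise ValueError("zscores must be (n_snps, K)")
    if not np.isfinite(z).all():
        raise ValueError("z-scores contain non-finite values")
    if K is None:
        K = z.shape[1]
    if K != z.shape[1]:
        raise ValueError("K does not match z-score dimensionality")
    if robust:
        center = np.median(z, axis=0)
        mad = stats.median_abs_deviation(z, axis=0, scale="normal")
        if (mad == 0).any():
            raise ValueError("degenerate (zero-MAD) z-score component")
        cov = np.diag(mad**2)
    else:
        center = z.mean(axis=0)
        cov = np.cov(z.T, ddof=1).reshape(K, K)
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"singular z-score covariance (rank deficient): {exc}"
        ) from exc
    d = z - center
    d2 = np.einsum("ij,jk,ik->i", d, prec, d)
    if gif:
        lam = np.median(d2) / stats.chi2.median(df=K)
        if lam > 0:
            d2 = d2 / lam
    p = stats.chi2.sf(d2, df=K)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({"d2": d2, "p_value": p})


def fdr_correct(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def scan(
    mat: SyncMatrix,
    counts: np.ndarray | None = None,
    status: np.ndarray | None = None,
    K: int = 2,
    min_count: int = 2,
    scale: bool = True,
    robust: bool = False,
    gif: bool = False,
) -> pd.DataFrame:
    """Full outlier scan: frequencies -> z-scores -> d2 -> p -> q."""
    freq = build_freq_matrix(mat, counts=counts, status=status, min_count=min_count)
    z = pca_zscores(freq, K=K, scale=scale)
    res = mahalanobis_pvalues(z, K=K, robust=robust, gif=gif)
    res.insert(0, "chrom", freq.chroms)
    res.insert(1, "pos", freq.pos)
    res["q_value"] = fdr_correct(res["p_value"].to_numpy())
    return res
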