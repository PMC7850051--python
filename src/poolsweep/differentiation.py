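"""Pairwise FST for pooled allele counts under two estimators.

Two estimators are computed side by side and reported raw (negative values
included; a clamp-to-zero option exists for summaries):

* ``classical`` -- the heterozygosity ratio ``(pi_total - pi_within) /
  pi_total`` computed from read counts, with ``pi_within`` the mean of the
  two per-pool site diversities and ``pi_total`` the diversity of the summed
  count vector.
* ``anova`` -- a moment estimator built on identity probabilities with a
  two-level sampling correction: reads are drawn with replacement from the
  ``2n`` chromosomes of a pool, chromosomes are drawn from the population.
  The within-pool read identity is debiased to chromosome-level identity via
  ``Q1 = (2n * q_reads - 1) / (2n - 1)``; between-pool identity needs no
  correction. ``FST = (Q1 - Q2) / (1 - Q2)``.

Multilocus values are ratios of summed numerators over summed denominators,
never means of per-SNP ratios.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import site_pi
from .io import SyncMatrix

__all__ = [
    "PoolSpec",
    "fst_classical",
    "fst_anova",
    "anova_components",
    "pairwise_fst_table",
    "multilocus_fst",
    "fst_outliers",
    "fst_excluding",
]


@dataclass
class PoolSpec:
    """One sequenced pool: label and number of diploid individuals."""

    label: str
    n_individuals: int

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("pool size must be >= 1")

    @property
    def haploid_size(self) -> int:
        return 2 * self.n_individuals


# ---------------------------------------------------------------------------
# per-site estimators
# ---------------------------------------------------------------------------

def fst_classical(counts_a, counts_b, min_count: int = 1) -> float:
    """Heterozygosity-ratio FST from two pooled count vectors.

    Returns NaN when the combined site is monomorphic (``pi_total == 0``)
    or either pool has fewer than 2 reads.
    """
    a = np.asarray(counts_a, dtype=np.int64)[:4]
    b = np.asarray(counts_b, dtype=np.int64)[:4]
    pi_a = site_pi(a, min_count=min_count)
    pi_b = site_pi(b, min_count=min_count)
    pi_t = site_pi(a + b, min_count=min_count)
    if np.isnan(pi_a) or np.isnan(pi_b) or np.isnan(pi_t):
        return float("nan")
    if pi_t == 0.0:
        return float("nan")
    pi_w = 0.5 * (pi_a + pi_b)
    return float((pi_t - pi_w) / pi_t)


def anova_components(counts_a, counts_b, pool_a: PoolSpec, pool_b: PoolSpec):
    """Numerator and denominator of the identity-probability estimator.

    Returns ``(Q1 - Q2, 1 - Q2)`` or ``(nan, nan)`` when either pool has
    coverage below 2.
    """
    a = np.asarray(counts_a, dtype=np.float64)[:4]
    b = np.asarray(counts_b, dtype=np.float64)[:4]
    ca, cb = a.sum(), b.sum()
    if ca < 2 or cb < 2:
        return float("nan"), float("nan")
    q_reads_a = (a * (a - 1)).sum() / (ca * (ca - 1))
    q_reads_b = (b * (b - 1)).sum() / (cb * (cb - 1))
    na, nb = pool_a.haploid_size, pool_b.haploid_size
    q1_a = (na * q_reads_a - 1.0) / (na - 1.0)
    q1_b = (nb * q_reads_b - 1.0) / (nb - 1.0)
    q1 = 0.5 * (q1_a + q1_b)
    q2 = float(np.dot(a / ca, b / cb))
    return q1 - q2, 1.0 - q2


def fst_anova(counts_a, counts_b, pool_a: PoolSpec, pool_b: PoolSpec) -> float:
    """Per-site ANOVA (identity-probability) FST; NaN when undefined."""
    num, den = anova_components(counts_a, counts_b, pool_a, pool_b)
    if not np.isfinite(num) or den == 0.0:
        return float("nan")
    return float(num / den)


# ---------------------------------------------------------------------------
# vectorised tables
# ---------------------------------------------------------------------------

def _pi_vec(counts: np.ndarray) -> np.ndarray:
    """site_pi without min_count filtering, vectorised over (L, 4) counts."""
    c = counts.sum(axis=1)
    out = np.full(len(counts), np.nan)
    ok = c >= 2
    f = counts[ok] / c[ok, None]
    out[ok] = c[ok] / (c[ok] - 1.0) * (1.0 - (f * f).sum(axis=1))
    return out


def _anova_vec(a: np.ndarray, b: np.ndarray, na: int, nb: int):
    ca = a.sum(axis=1)
    cb = b.sum(axis=1)
    num = np.full(len(a), np.nan)
    den = np.full(len(a), np.nan)
    ok = (ca >= 2) & (cb >= 2)
    af, bf = a[ok].astype(float), b[ok].astype(float)
    caf, cbf = ca[ok].astype(float), cb[ok].astype(float)
    qa = (af * (af - 1)).sum(axis=1) / (caf * (caf - 1))
    qb = (bf * (bf - 1)).sum(axis=1) / (cbf * (cbf - 1))
    q1 = 0.5 * ((na * qa - 1) / (na - 1) + (nb * qb - 1) / (nb - 1))
    q2 = ((af / caf[:, None]) * (bf / cbf[:, None])).sum(axis=1)
    num[ok] = q1 - q2
    den[ok] = 1.0 - q2
    return num, den


def pairwise_fst_table(
    mat: SyncMatrix, pools: list[PoolSpec],
    counts: np.ndarray | None = None,
    snp_only: bool = True,
) -> pd.DataFrame:
    """Per-site FST under both estimators for every population pair.

    ``counts`` defaults to the raw sync counts; pass subsampled counts of
    shape ``(n_sites, n_pops, 4)`` to work at uniform coverage. With
    ``snp_only`` sites monomorphic across both pools of a pair (classical
    FST undefined) are dropped.
    """
    if counts is None:
        counts = mat.counts[:, :, :4]
    if len(pools) != counts.shape[1]:
        raise ValueError("need one PoolSpec per population")
    frames = []
    for i, j in itertools.combinations(range(len(pools)), 2):
        a, b = counts[:, i, :], counts[:, j, :]
        pi_t = _pi_vec(a + b)
        pi_w = 0.5 * (_pi_vec(a) + _pi_vec(b))
        with np.errstate(divide="ignore", invalid="ignore"):
            classical = np.where(pi_t > 0, (pi_t - pi_w) / pi_t, np.nan)
        num, den = _anova_vec(a, b, pools[i].haploid_size, pools[j].haploid_size)
        with np.errstate(divide="ignore", invalid="ignore"):
            anova = num / den
        df = pd.DataFrame({
            "chrom": mat.chroms,
            "pos": mat.pos,
            "pop_pair": f"{pools[i].label}:{pools[j].label}",
            "fst_classical": classical,
            "fst_anova": anova,
            "anova_num": num,
            "anova_den": den,
            "pi_t": pi_t,
            "pi_w": pi_w,
        })
        if snp_only:
            df = df[np.isfinite(pi_t) & (pi_t > 0)]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def multilocus_fst(records: pd.DataFrame, clamp_zero: bool = False) -> pd.DataFrame:
    """Genome-wide FST per pair: ratio of summed numerators over denominators.

    Classical uses ``sum(pi_t - pi_w) / sum(pi_t)``; ANOVA uses the summed
    identity components. Invariant to SNP ordering by construction.
    """
    rows = []
    for pair, grp in records.groupby("pop_pair", sort=True):
        pi_t = grp["pi_t"].to_numpy(dtype=float)
        pi_w = grp["pi_w"].to_numpy(dtype=float)
        fin = np.isfinite(pi_t) & np.isfinite(pi_w)
        classical = (
            float((pi_t[fin] - pi_w[fin]).sum() / pi_t[fin].sum())
            if fin.any() and pi_t[fin].sum() > 0 else float("nan")
        )
        num = grp["anova_num"].to_numpy(dtype=float)
        den = grp["anova_den"].to_numpy(dtype=float)
        fin = np.isfinite(num) & np.isfinite(den)
        anova = (
            float(num[fin].sum() / den[fin].sum())
            if fin.any() and den[fin].sum() != 0 else float("nan")
        )
        if clamp_zero:
            classical = max(classical, 0.0) if np.isfinite(classical) else classical
            anova = max(anova, 0.0) if np.isfinite(anova) else anova
        rows.append({
            "pop_pair": pair, "fst_classical": classical, "fst_anova": anova,
            "n_snps": int(fin.sum()),
        })
    return pd.DataFrame(rows)


def fst_outliers(
    records: pd.DataFrame, q: float = 0.01, column: str = "fst_anova",
) -> tuple[pd.DataFrame, float, bool]:
    """SNPs at or above the empirical ``1 - q`` quantile of FST.

    Returns ``(outlier_rows, cutoff, degenerate)``; ``degenerate`` is set
    when all finite values are equal (every SNP is returned).
    """
    vals = records[column].to_numpy(dtype=float)
    fin = np.isfinite(vals)
    if not fin.any():
        raise ValueError("no finite FST values")
    cutoff = float(np.quantile(vals[fin], 1.0 - q))
    degenerate = bool(np.nanmin(vals[fin]) == np.nanmax(vals[fin]))
    out = records[fin & (vals >= cutoff)]
    return out, cutoff, degenerate


def fst_excluding(
    records: pd.DataFrame, region: tuple[str, int, int], clamp_zero: bool = False,
) -> pd.DataFrame:
    """Multilocus FST recomputed over the complement of ``region``.

    ``region`` is ``(chrom, start, end)`` with 1-based inclusive bounds.
    Raises if the region removes every SNP.
    """
    chrom, start, end = region
    if end < start:
        raise ValueError("region end < start")
    inside = (
        (records["chrom"].astype(str) == str(chrom))
        & (records["pos"] >= start) & (records["pos"] <= end)
    )
    rest = records[~inside]
    if len(rest) == 0:
        raise ValueError("region covers every SNP; nothing left to estimate from")
    return multilocus_fst(rest, clamp_zero=clamp_zero)
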