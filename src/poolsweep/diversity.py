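"""Coverage subsampling and diversity statistics (pi, Watterson's theta, Tajima's D).

Sites are first subsampled to a uniform target coverage (multivariate
hypergeometric draw without replacement); sites below the target are dropped
as insufficiently covered and sites above the maximum are excluded outright
(suspected copy-number artifacts). Statistics are then computed per site,
aggregated over nonoverlapping windows, and recomputed per gene over CDS
intervals.

Window pi is normalised by the number of covered positions, not by raw
window length; ``covered_frac`` is reported so either convention can be
reconstructed. Tajima's D uses the classic constants with sample size equal
to the subsampled coverage -- a deliberate simplification: after subsampling
to uniform coverage the classic formula is well defined for the read sample.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io import GeneModel, SyncMatrix

__all__ = [
    "SubsampleParams",
    "SubsampleStatus",
    "WindowStats",
    "GenePi",
    "tajima_constants",
    "subsample_site",
    "subsample_population",
    "site_pi",
    "windowed_diversity",
    "gene_pi",
]


class SubsampleStatus(enum.IntEnum):
    OK = 0
    INSUFFICIENT = 1   # coverage below target
    EXCLUDED = 2       # coverage above max (copy-number suspicion)


@dataclass
class SubsampleParams:
    """Uniform-coverage subsampling and allele-calling parameters."""

    target_coverage: int = 50
    max_coverage: int = 100
    min_count: int = 2
    min_covered_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_coverage <= self.max_coverage:
            raise ValueError("need 0 < target_coverage <= max_coverage")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if not 0 < self.min_covered_fraction <= 1:
            raise ValueError("min_covered_fraction must be in (0, 1]")


@dataclass
class WindowStats:
    chrom: str
    start: int
    end: int
    pi: float
    thetaW: float
    tajd: float            # NaN when undefined (S = 0)
    n_snps: int
    covered_fraction: float
    valid: bool

    @property
    def snps(self) -> int:  # report-schema alias
        return self.n_snps

    @property
    def covered_frac(self) -> float:
        return self.covered_fraction


@dataclass
class GenePi:
    gene_id: str
    pi: float
    n_snps: int
    mean_coverage: float
    usable: bool


class TajimaConstants(NamedTuple):
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """Standard Tajima's D normalisation constants for sample size ``n``."""
    if n < 2:
        raise ValueError("sample size must be >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(a1, a2, b1, b2, c1, c2, e1, e2)


# ---------------------------------------------------------------------------
# subsampling
# ---------------------------------------------------------------------------

def subsample_site(counts, params: SubsampleParams, rng: np.random.Generator | None = None):
    """Subsample one site of one population to exactly the target coverage.

    ``counts`` is a length-4 (A,T,C,G) or length-6 (A,T,C,G,N,del) vector.
    Returns ``(SubsampleStatus, counts4 | None)``; N/del are discarded.
    """
    counts = np.asarray(counts, dtype=np.int64)[:4]
    cov = int(counts.sum())
    if cov < params.target_coverage:
        return SubsampleStatus.INSUFFICIENT, None
    if cov > params.max_coverage:
        return SubsampleStatus.EXCLUDED, None
    if cov == params.target_coverage:
        return SubsampleStatus.OK, counts.copy()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    out = rng.multivariate_hypergeometric(counts, params.target_coverage)
    return SubsampleStatus.OK, np.asarray(out, dtype=np.int64)


def subsample_population(
    mat: SyncMatrix, population: int, params: SubsampleParams,
    rng: np.random.Generator | None = None,
):
    """Vectorised subsampling of every site of one population.

    Returns ``(sub_counts, status)`` where ``sub_counts`` is ``(n_sites, 4)``
    (zero rows where status != OK) and ``status`` is a
    :class:`SubsampleStatus`-valued int array.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    counts = mat.counts[:, population, :4]
    cov = counts.sum(axis=1)
    status = np.full(mat.n_sites, SubsampleStatus.OK, dtype=np.int8)
    status[cov < params.target_coverage] = SubsampleStatus.INSUFFICIENT
    status[cov > params.max_coverage] = SubsampleStatus.EXCLUDED

    sub = np.zeros_like(counts)
    ok = status == SubsampleStatus.OK
    exact = ok & (cov == params.target_coverage)
    sub[exact] = counts[exact]

    todo = np.flatnonzero(ok & (cov > params.target_coverage))
    if todo.size:
        c = counts[todo]
        remaining = c.sum(axis=1)
        draw = np.full(todo.size, params.target_coverage, dtype=np.int64)
        out = np.zeros_like(c)
        for a in range(3):  # sequential conditional hypergeometric over A,T,C; G gets the rest
            remaining = remaining - c[:, a]
            k = rng.hypergeometric(c[:, a], remaining, draw)
            out[:, a] = k
            draw -= k
        out[:, 3] = draw
        sub[todo] = out
    return sub, status


# ---------------------------------------------------------------------------
# per-site pi
# ---------------------------------------------------------------------------

def site_pi(counts, min_count: int = 2) -> float:
    """Average pairwise difference among the reads at one site.

    Alleles supported by fewer than ``min_count`` reads are zeroed and the
    coverage recomputed. Returns NaN when fewer than 2 reads remain.
    Equals ``(c/(c-1)) * (1 - sum_a f_a^2)``, the mean pairwise difference
    among the ``c`` sampled reads.
    """
    counts = np.asarray(counts, dtype=np.int64)[:4].copy()
    counts[counts < min_count] = 0
    c = counts.sum()
    if c < 2:
        return float("nan")
    f = counts / c
    return float(c / (c - 1.0) * (1.0 - np.sum(f * f)))


def _site_arrays(sub: np.ndarray, min_count: int):
    """Vectorised per-site pi and segregating flags from subsampled counts."""
    filt = sub.copy()
    filt[filt < min_count] = 0
    c = filt.sum(axis=1)
    pi = np.zeros(len(filt))
    okc = c >= 2
    if okc.any():
        f = filt[okc] / c[okc, None]
        pi[okc] = c[okc] / (c[okc] - 1.0) * (1.0 - (f * f).sum(axis=1))
    segregating = (filt > 0).sum(axis=1) >= 2
    return pi, segregating


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def windowed_diversity(
    mat: SyncMatrix, population: int, params: SubsampleParams,
    window: int = 5000,
    sub: np.ndarray | None = None, status: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-window diversity statistics for one population.

    Windows tile ``[1, max_pos]`` as ``[k*window+1, (k+1)*window]``. Pass
    precomputed ``sub``/``status`` from :func:`subsample_population` to avoid
    resampling. Returns a DataFrame with one row per window (including
    windows with no covered site, flagged invalid).
    """
    if mat.n_sites == 0:
        return pd.DataFrame(columns=[
            "chrom", "start", "end", "pi", "thetaW", "tajd", "snps",
            "covered_frac", "valid"])
    if len(np.unique(mat.chroms)) > 1:
        raise ValueError("windowed_diversity expects a single chromosome")
    if sub is None or status is None:
        sub, status = subsample_population(mat, population, params)
    pi_site, seg = _site_arrays(sub, params.min_count)
    ok = status == SubsampleStatus.OK
    win = (mat.pos - 1) // window
    n_win = int(win.max()) + 1

    n_cov = np.bincount(win[ok], minlength=n_win)
    pi_sum = np.bincount(win[ok], weights=pi_site[ok], minlength=n_win)
    s_count = np.bincount(win[ok & seg], minlength=n_win).astype(np.int64)

    k = tajima_constants(params.target_coverage)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(n_cov > 0, pi_sum / np.maximum(n_cov, 1), 0.0)
        thetaw = np.where(n_cov > 0, s_count / (k.a1 * np.maximum(n_cov, 1)), 0.0)
        var = k.e1 * s_count + k.e2 * s_count * (s_count - 1.0)
        tajd = np.where(s_count > 0, (pi_sum - s_count / k.a1) / np.sqrt(var), np.nan)

    covered_frac = n_cov / window
    chrom = str(mat.chroms[0])
    out = pd.DataFrame({
        "chrom": chrom,
        "start": np.arange(n_win, dtype=np.int64) * window + 1,
        "end": (np.arange(n_win, dtype=np.int64) + 1) * window,
        "pi": pi,
        "thetaW": thetaw,
        "tajd": tajd,
        "snps": s_count,
        "covered_frac": covered_frac,
    })
    out["valid"] = out["covered_frac"] >= params.min_covered_fraction
    return out


def window_stats(
    positions: Sequence[int], sub_counts: np.ndarray, status: np.ndarray,
    chrom: str, start: int, end: int, params: SubsampleParams,
) -> WindowStats:
    """Statistics for one explicit window from per-site subsampled counts."""
    positions = np.asarray(positions)
    mask = (positions >= start) & (positions <= end)
    sub = np.asarray(sub_counts)[mask]
    st = np.asarray(status)[mask]
    ok = st == SubsampleStatus.OK
    pi_site, seg = _site_arrays(sub, params.min_count)
    n_cov = int(ok.sum())
    s = int((seg & ok).sum())
    pi_sum = float(pi_site[ok].sum())
    length = end - start + 1
    covered = n_cov / length
    if n_cov == 0:
        return WindowStats(chrom, start, end, 0.0, 0.0, float("nan"), 0,
                           covered, False)
    k = tajima_constants(params.target_coverage)
    pi = pi_sum / n_cov
    thetaw = s / (k.a1 * n_cov)
    if s == 0:
        tajd = float("nan")
    else:
        tajd = (pi_sum - s / k.a1) / math.sqrt(k.e1 * s + k.e2 * s * (s - 1.0))
    return WindowStats(chrom, start, end, pi, thetaw, tajd, s, covered,
                       covered >= params.min_covered_fraction)


# ---------------------------------------------------------------------------
# genes
# ---------------------------------------------------------------------------

def gene_pi(
    mat: SyncMatrix, population: int, gene: GeneModel, params: SubsampleParams,
    min_cov: float = 50.0,
    sub: np.ndarray | None = None, status: np.ndarray | None = None,
) -> GenePi:
    """Nucleotide diversity over the CDS intervals of one gene.

    ``usable`` requires mean raw coverage strictly above ``min_cov`` and at
    least one covered position.
    """
    if sub is None or status is None:
        sub, status = subsample_population(mat, population, params)
    in_cds = np.zeros(mat.n_sites, dtype=bool)
    on_chrom = mat.chroms == gene.chrom
    for s, e in gene.cds_intervals:
        in_cds |= on_chrom & (mat.pos >= s) & (mat.pos <= e)
    if not in_cds.any():
        return GenePi(gene.gene_id, 0.0, 0, 0.0, False)
    raw_cov = mat.counts[in_cds, population, :4].sum(axis=1)
    mean_cov = float(raw_cov.mean())
    ok = (status == SubsampleStatus.OK) & in_cds
    n_cov = int(ok.sum())
    pi_site, seg = _site_arrays(sub[ok], params.min_count)
    pi = float(pi_site.sum() / n_cov) if n_cov else 0.0
    usable = n_cov > 0 and mean_cov > min_cov
    return GenePi(gene.gene_id, pi, int(seg.sum()), mean_cov, usable)
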