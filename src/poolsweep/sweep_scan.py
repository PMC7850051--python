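"""Delineation of low-diversity sweep regions and Tajima's D summaries.

Works on the per-window tables produced by :mod:`poolsweep.diversity`:
maximal runs of low-pi windows (with a configurable tolerance for interior
noisy windows), bootstrap confidence intervals of the mean, empirical 1%
tails of Tajima's D, and interval algebra to split a multi-population sweep
into a shared core plus per-population extensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneModel

__all__ = [
    "SweepRegion",
    "TajimaSummary",
    "bootstrap_ci",
    "tajima_tails",
    "delineate_sweeps",
    "intersect_regions",
]


@dataclass
class SweepRegion:
    """A maximal run of low-diversity windows."""

    chrom: str
    start: int
    end: int
    populations: tuple[str, ...]
    min_pi: float
    mean_pi: float
    n_windows: int
    genes_contained: list[str] = field(default_factory=list)
    flank_pi_left: float = float("nan")
    flank_pi_right: float = float("nan")

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("region end < start")

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass
class TajimaSummary:
    genome_mean: float
    ci_low: float
    ci_high: float
    lower_tail_cutoff: float
    upper_tail_cutoff: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.genome_mean <= self.ci_high):
            raise ValueError("bootstrap CI does not bracket the mean")


def bootstrap_ci(
    values, reps: int = 10_000, level: float = 0.90, seed: int = 0,
    chunk: int = 500,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean (sampling with replacement)."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("bootstrap_ci: no finite values")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = values.size
    means = np.empty(reps)
    done = 0
    while done < reps:
        b = min(chunk, reps - done)
        idx = rng.integers(0, n, size=(b, n))
        means[done:done + b] = values[idx].mean(axis=1)
        done += b
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def tajima_tails(
    windows: pd.DataFrame, q: float = 0.01,
    reps: int = 10_000, level: float = 0.90, seed: int = 0,
):
    """Empirical tail cutoffs and bootstrap mean CI of windowed Tajima's D.

    Uses windows with a finite ``tajd`` (and ``valid`` flag when present).
    Windows exactly at a cutoff are included in the tail. Returns
    ``(TajimaSummary, lower_tail_df, upper_tail_df)``.
    """
    w = windows
    if "valid" in w.columns:
        w = w[w["valid"].astype(bool)]
    w = w[np.isfinite(w["tajd"].to_numpy(dtype=float))]
    if len(w) == 0:
        raise ValueError("no valid Tajima's D values")
    if len(w) < 100:
        warnings.warn(
            f"only {len(w)} valid windows; {q:.0%} tail quantiles are noisy",
            stacklevel=2,
        )
    vals = w["tajd"].to_numpy(dtype=float)
    lo_cut, hi_cut = np.quantile(vals, [q, 1.0 - q])  # type-7 interpolation
    ci_low, ci_high = bootstrap_ci(vals, reps=reps, level=level, seed=seed)
    summary = TajimaSummary(
        genome_mean=float(vals.mean()),
        ci_low=ci_low, ci_high=ci_high,
        lower_tail_cutoff=float(lo_cut),
        upper_tail_cutoff=float(hi_cut),
        degenerate=bool(lo_cut == hi_cut),
    )
    lower = w[w["tajd"] <= lo_cut]
    upper = w[w["tajd"] >= hi_cut]
    return summary, lower, upper


def _flank_mean(pi: np.ndarray, lo: int, hi: int, n_flank: int, side: str) -> float:
    if side == "left":
        sel = pi[max(0, lo - n_flank):lo]
    else:
        sel = pi[hi + 1:hi + 1 + n_flank]
    return float(np.mean(sel)) if sel.size else float("nan")


def delineate_sweeps(
    windows: pd.DataFrame,
    pi_threshold: float = 0.002,
    max_gap_windows: int = 1,
    population: str = "pop",
    genes: list[GeneModel] | None = None,
    n_flank: int = 10,
) -> list[SweepRegion]:
    """Find maximal runs of valid windows with pi below the threshold.

    Up to ``max_gap_windows`` consecutive interior windows at or above the
    threshold are tolerated inside a run. Invalid windows are ignored: they
    neither extend nor break a run. Each region reports the mean pi of the
    ``n_flank`` valid windows on each side as a flanking contrast.
    """
    w = windows
    if "valid" in w.columns:
        w = w[w["valid"].astype(bool)]
    w = w.sort_values("start").reset_index(drop=True)
    if len(w) == 0:
        return []
    pi = w["pi"].to_numpy(dtype=float)
    low = pi < pi_threshold
    regions: list[SweepRegion] = []
    runs: list[tuple[int, int]] = []  # index ranges into w, inclusive
    i = 0
    n = len(w)
    while i < n:
        if not low[i]:
            i += 1
            continue
        j = i
        while True:
            # extend through the run of low windows
            while j + 1 < n and low[j + 1]:
                j += 1
            # bridge an interior gap of at most max_gap_windows high windows
            g = j + 1
            while g < n and not low[g]:
                g += 1
            gap = g - (j + 1)
            if g < n and low[g] and gap <= max_gap_windows:
                j = g
                continue
            break
        runs.append((i, j))
        i = j + 1
    for lo, hi in runs:
        seg = w.iloc[lo:hi + 1]
        chrom = str(seg["chrom"].iloc[0])
        contained: list[str] = []
        start, end = int(seg["start"].iloc[0]), int(seg["end"].iloc[-1])
        if genes:
            for g in genes:
                gs, ge = g.span
                if g.chrom == chrom and gs >= start and ge <= end:
                    contained.append(g.gene_id)
        regions.append(SweepRegion(
            chrom=chrom, start=start, end=end,
            populations=(population,),
            min_pi=float(seg["pi"].min()),
            mean_pi=float(seg["pi"].mean()),
            n_windows=len(seg),
            genes_contained=contained,
            flank_pi_left=_flank_mean(pi, lo, hi, n_flank, "left"),
            flank_pi_right=_flank_mean(pi, lo, hi, n_flank, "right"),
        ))
    return regions


# ---------------------------------------------------------------------------
# interval algebra across populations
# ---------------------------------------------------------------------------

def _as_intervals(regions) -> list[tuple[int, int]]:
    ivs = sorted(
        (r.interval if isinstance(r, SweepRegion) else (int(r[0]), int(r[1])))
        for r in regions
    )
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _intersect_sets(a: list[tuple[int, int]], b: list[tuple[int, int]]):
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            s, e = max(s1, s2), min(e1, e2)
            if s <= e:
                out.append((s, e))
    return _as_intervals(out)


def _subtract_sets(a: list[tuple[int, int]], b: list[tuple[int, int]]):
    out = []
    for s, e in a:
        pieces = [(s, e)]
        for bs, be in b:
            nxt = []
            for ps, pe in pieces:
                if be < ps or bs > pe:
                    nxt.append((ps, pe))
                    continue
                if ps < bs:
                    nxt.append((ps, bs - 1))
                if be < pe:
                    nxt.append((be + 1, pe))
            pieces = nxt
        out.extend(pieces)
    return _as_intervals(out)


def intersect_regions(
    regions_by_population: dict[str, list[SweepRegion]],
) -> tuple[list[tuple[int, int]], dict[str, list[tuple[int, int]]]]:
    """Split per-population sweep regions into a shared core and extensions.

    The core is the coordinate intersection present in every population; each
    population's extension is its coverage minus the core. All regions must
    be on one chromosome. Returns ``(core_intervals, {pop: extensions})``.
    """
    chroms = {r.chrom for regs in regions_by_population.values() for r in regs}
    if len(chroms) > 1:
        raise ValueError(f"regions span multiple chromosomes: {sorted(chroms)}")
    sets = {p: _as_intervals(regs) for p, regs in regions_by_population.items()}
    core: list[tuple[int, int]] | None = None
    for ivs in sets.values():
        core = ivs if core is None else _intersect_sets(core, ivs)
    core = core or []
    extensions = {p: _subtract_sets(ivs, core) for p, ivs in sets.items()}
    return core, extensions
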