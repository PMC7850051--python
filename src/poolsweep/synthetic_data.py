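"""Synthetic pooled-sequencing data with a planted selective sweep.

Generates sync + GFF3 + FASTA + truth tables with the statistical structure
the downstream analysis assumes: neutral-SFS background polymorphism, a
shared low-diversity core region, a population-specific sweep extension, a
fixed nonsynonymous "kdr-like" SNP inside a generated gene, and configurable
highly differentiated outlier SNPs.

The generative model is a stand-in: the study this emulates is empirical and
specifies no simulator, so every distributional choice here (neutral SFS
frequencies, Beta drift perturbation, Poisson depth, binomial read sampling,
uniform miscall error) is a documented modelling convenience, not a claim
about the source data. Pools are modelled as ``2n`` exchangeable chromosomes;
haplotypes and linkage are not tracked.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as psio

__all__ = [
    "SimConfig",
    "TruthTable",
    "neutral_sfs_frequency",
    "simulate_counts",
    "simulate_pools",
]

#  sync column order
_BASES = np.array(["A", "T", "C", "G"])
# for each base index, the indices of the three other bases (miscall targets)
_OTHER = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])


@dataclass
class SimConfig:
    """Parameters of the pooled-sequencing simulation."""

    n_populations: int = 3
    pool_individuals: int = 100          # diploid individuals per pool (2n chromosomes)
    genome_length: int = 200_000
    window: int = 5000
    theta: float = 0.01                  # per-site polymorphism probability
    depth_mean: float = 80.0             # Poisson mean raw depth; ~50x usable after subsampling
    error_rate: float = 0.001            # per-base miscall probability
    sweep_core: tuple[int, int] | None = None
    sweep_extension: tuple[int, int, int] | None = None  # (start, end, population)
    diversity_reduction: float = 0.0     # epsilon: retained polymorphism fraction in sweeps
    fixed_snp_pos: int | None = None
    fixed_snp_freqs: tuple[float, ...] | None = None     # default: 1.0 everywhere
    outlier_snps: list[tuple[int, tuple[float, ...]]] = field(default_factory=list)
    drift_concentration: float = 500.0   # Beta concentration around the ancestral frequency
    n_genes: int = 6
    gene_length: int = 300               # CDS length per generated gene (multiple of 3)
    chrom: str = "scaffold_1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        if self.pool_individuals < 1:
            raise ValueError("pool_individuals must be >= 1")
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must be in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if not 0.0 <= self.diversity_reduction <= 1.0:
            raise ValueError("diversity_reduction must be in [0, 1]")
        if self.gene_length % 3 != 0 or self.gene_length < 3:
            raise ValueError("gene_length must be a positive multiple of 3")
        if self.drift_concentration <= 0:
            raise ValueError("drift_concentration must be > 0 (use inf for no drift)")
        for region in (self.sweep_core, self.sweep_extension):
            if region is not None:
                s, e = region[0], region[1]
                if not (1 <= s <= e <= self.genome_length):
                    raise ValueError(f"region {region} outside genome")
        if self.sweep_extension is not None:
            pop = self.sweep_extension[2]
            if not 0 <= pop < self.n_populations:
                raise ValueError("sweep_extension population index out of range")
            if self.sweep_core is not None:
                cs, ce = self.sweep_core
                es, ee = self.sweep_extension[:2]
                if es <= ce and cs <= ee:
                    raise ValueError(
                        "sweep_extension overlaps sweep_core; regions must be disjoint"
                    )
        if self.fixed_snp_pos is not None:
            if not 1 <= self.fixed_snp_pos <= self.genome_length:
                raise ValueError("fixed_snp_pos outside genome")
            if self.fixed_snp_freqs is not None:
                self._check_freqs(self.fixed_snp_freqs)
        for pos, freqs in self.outlier_snps:
            if not 1 <= pos <= self.genome_length:
                raise ValueError(f"outlier SNP position {pos} outside genome")
            self._check_freqs(freqs)

    def _check_freqs(self, freqs) -> None:
        if len(freqs) != self.n_populations:
            raise ValueError("per-population frequency vector has wrong length")
        if any(not 0.0 <= f <= 1.0 for f in freqs):
            raise ValueError("frequencies must be in [0, 1]")

    @property
    def two_n(self) -> int:
        return 2 * self.pool_individuals


@dataclass
class TruthTable:
    """Ground truth written alongside the simulated data."""

    sweep_core: tuple[int, int] | None
    sweep_extension: tuple[int, int, int] | None
    snps: pd.DataFrame          # pos, kind, ref, alt, freq_<pop>...
    polymorphic_positions: np.ndarray

    def __post_init__(self) -> None:
        special = self.snps.loc[self.snps["kind"] != "neutral", "pos"]
        if special.duplicated().any():
            raise ValueError("fixed/outlier SNP positions must be unique")


def neutral_sfs_frequency(two_n: int, rng: np.random.Generator, size=None):
    """Draw derived-allele counts i in [1, 2N-1] with P(i) proportional to 1/i."""
    if two_n < 2:
        raise ValueError("two_n must be >= 2")
    i = np.arange(1, two_n)
    w = 1.0 / i
    w /= w.sum()
    return rng.choice(i, p=w, size=size)


def _place_genes(config: SimConfig) -> list[psio.GeneModel]:
    """Lay out single-CDS genes; the kdr-like gene is aligned on the fixed SNP."""
    genes: list[psio.GeneModel] = []
    glen = config.gene_length
    kdr_span = None
    if config.fixed_snp_pos is not None:
        # CDS start chosen so the fixed SNP lands on the first base of a codon
        offset = 3 * (glen // 6)
        start = max(1, config.fixed_snp_pos - offset)
        start += (config.fixed_snp_pos - start) % 3
        end = start + glen - 1
        if end > config.genome_length:
            raise ValueError("fixed SNP gene does not fit in the genome")
        genes.append(
            psio.GeneModel(
                gene_id="gene_kdr", chrom=config.chrom, strand="+",
                cds_intervals=[(start, end)], name="sodium-channel-like",
            )
        )
        kdr_span = (start, end)
    spacing = config.genome_length // (config.n_genes + 1)
    made = 0
    k = 1
    while made < config.n_genes and k <= 5 * (config.n_genes + 1):
        start = k * spacing + 1
        end = start + glen - 1
        k += 1
        if end > config.genome_length:
            break
        if kdr_span is not None and start <= kdr_span[1] and kdr_span[0] <= end:
            continue
        strand = "-" if made % 3 == 2 else "+"
        genes.append(
            psio.GeneModel(
                gene_id=f"gene_{made + 1:03d}", chrom=config.chrom, strand=strand,
                cds_intervals=[(start, end)], name=f"synthetic gene {made + 1}",
            )
        )
        made += 1
    genes.sort(key=lambda g: g.span)
    return genes


def _region_mask(length: int, region) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    if region is not None:
        s, e = region[0], region[1]
        mask[s - 1:e] = True
    return mask


def simulate_counts(config: SimConfig):
    """Run the simulation in memory.

    Returns ``(SyncMatrix, genes, reference_sequence, TruthTable)``.
    """
    rng = np.random.default_rng(config.seed)
    L, P, two_n = config.genome_length, config.n_populations, config.two_n

    ref_idx = rng.integers(0, 4, size=L)

    genes = _place_genes(config)
    # codon context for the fixed SNP: CTT (Leu); the T alternate gives TTT (Phe)
    if config.fixed_snp_pos is not None:
        p0 = config.fixed_snp_pos - 1
        ctx = np.array([np.flatnonzero(_BASES == b)[0] for b in "CTT"])
        ref_idx[p0:p0 + 3] = ctx[: L - p0]

    # --- choose polymorphic sites -------------------------------------------
    poly = rng.random(L) < config.theta
    eps = config.diversity_reduction
    core_mask = _region_mask(L, config.sweep_core)
    ext_mask = _region_mask(L, config.sweep_extension)
    # shared core: thin polymorphism for everyone
    thin = poly & core_mask
    poly[thin] &= rng.random(int(thin.sum())) < eps

    forced_pos = []
    if config.fixed_snp_pos is not None:
        forced_pos.append(config.fixed_snp_pos)
    forced_pos += [p for p, _ in config.outlier_snps]
    if len(set(forced_pos)) != len(forced_pos):
        raise ValueError("fixed/outlier SNP positions must be distinct")
    if forced_pos:
        poly[np.array(forced_pos, dtype=int) - 1] = True

    poly_idx = np.flatnonzero(poly)
    n_poly = poly_idx.size

    # --- per-population allele frequencies ----------------------------------
    anc = neutral_sfs_frequency(two_n, rng, size=n_poly) / two_n
    if np.isfinite(config.drift_concentration):
        c = config.drift_concentration
        freqs = rng.beta(anc[:, None] * c, (1.0 - anc[:, None]) * c, size=(n_poly, P))
    else:
        freqs = np.broadcast_to(anc[:, None], (n_poly, P)).copy()

    # population-specific extension: the designated population is swept back
    in_ext = ext_mask[poly_idx]
    if config.sweep_extension is not None and in_ext.any():
        pop = config.sweep_extension[2]
        keep = rng.random(int(in_ext.sum())) < eps
        swept = np.flatnonzero(in_ext)[~keep]
        freqs[swept, pop] = 0.0

    # forced SNPs override the drawn frequencies
    kinds = np.full(n_poly, "neutral", dtype=object)
    pos_to_row = {int(p): r for r, p in enumerate(poly_idx + 1)}
    if config.fixed_snp_pos is not None:
        row = pos_to_row[config.fixed_snp_pos]
        f = config.fixed_snp_freqs or tuple([1.0] * P)
        freqs[row] = np.asarray(f, dtype=float)
        kinds[row] = "fixed"
    for p, f in config.outlier_snps:
        row = pos_to_row[p]
        freqs[row] = np.asarray(f, dtype=float)
        kinds[row] = "outlier"

    # --- alternate allele identity ------------------------------------------
    alt_idx = (ref_idx[poly_idx] + rng.integers(1, 4, size=n_poly)) % 4
    if config.fixed_snp_pos is not None:
        # C -> T on the first codon position: Leu -> Phe
        alt_idx[pos_to_row[config.fixed_snp_pos]] = 1

    # --- sequencing ----------------------------------------------------------
    depth = rng.poisson(config.depth_mean, size=(L, P))
    counts = np.zeros((L, P, 6), dtype=np.int64)

    pool_alt = rng.binomial(two_n, freqs)                     # chromosomes in the pool
    alt_reads = rng.binomial(depth[poly_idx], pool_alt / two_n)
    ref_reads = depth.copy()
    ref_reads[poly_idx] -= alt_reads

    site_ax = np.arange(L)[:, None]
    pop_ax = np.arange(P)[None, :]
    np.add.at(counts, (site_ax, pop_ax, ref_idx[:, None]), ref_reads)
    np.add.at(counts, (poly_idx[:, None], pop_ax, alt_idx[:, None]), alt_reads)

    if config.error_rate > 0:
        e = config.error_rate
        third = np.array([1 / 3, 1 / 3, 1 / 3])
        err_ref = rng.binomial(ref_reads, e)
        np.add.at(counts, (site_ax, pop_ax, ref_idx[:, None]), -err_ref)
        spread = rng.multinomial(err_ref, third)               # (L, P, 3)
        np.add.at(counts, (site_ax[:, :, None], pop_ax[:, :, None],
                           _OTHER[ref_idx][:, None, :]), spread)
        err_alt = rng.binomial(alt_reads, e)
        np.add.at(counts, (poly_idx[:, None], pop_ax, alt_idx[:, None]), -err_alt)
        spread = rng.multinomial(err_alt, third)
        np.add.at(counts, (poly_idx[:, None, None], pop_ax[:, :, None],
                           _OTHER[alt_idx][:, None, :]), spread)

    ref_chars = _BASES[ref_idx]
    mat = psio.SyncMatrix(
        chroms=np.full(L, config.chrom, dtype=object),
        pos=np.arange(1, L + 1, dtype=np.int64),
        ref=ref_chars.astype(object),
        counts=counts,
    )

    snps = pd.DataFrame({
        "pos": poly_idx + 1,
        "kind": kinds,
        "ref": ref_chars[poly_idx],
        "alt": _BASES[alt_idx],
    })
    for p in range(P):
        snps[f"freq_{p}"] = freqs[:, p]
    for p in range(P):
        snps[f"pool_count_{p}"] = pool_alt[:, p]   # alt chromosomes among 2n
    truth = TruthTable(
        sweep_core=config.sweep_core,
        sweep_extension=config.sweep_extension,
        snps=snps,
        polymorphic_positions=poly_idx + 1,
    )
    return mat, genes, "".join(ref_chars), truth


def simulate_pools(config: SimConfig, outdir: str | os.PathLike) -> dict[str, str]:
    """Run :func:`simulate_counts` and write all artifacts to ``outdir``.

    Returns a dict of output names to paths. Identical config and seed
    produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat, genes, ref_seq, truth = simulate_counts(config)

    paths = {
        "sync": outdir / "pools.sync",
        "gff": outdir / "genes.gff3",
        "fasta": outdir / "reference.fasta",
        "truth_snps": outdir / "truth_snps.tsv",
        "truth_regions": outdir / "truth_regions.tsv",
    }
    psio.write_sync_matrix(mat, paths["sync"])
    psio.write_gff(genes, paths["gff"])
    psio.write_fasta({config.chrom: ref_seq}, paths["fasta"])

    snps = truth.snps.copy()
    for col in snps.columns:
        if col.startswith("freq_"):
            snps[col] = snps[col].map("{:.6f}".format)
    snps.to_csv(paths["truth_snps"], sep="\t", index=False)

    with open(paths["truth_regions"], "w") as fh:
        fh.write("kind\tstart\tend\tpopulation\n")
        if truth.sweep_core is not None:
            fh.write(f"sweep_core\t{truth.sweep_core[0]}\t{truth.sweep_core[1]}\tall\n")
        if truth.sweep_extension is not None:
            s, e, p = truth.sweep_extension
            fh.write(f"sweep_extension\t{s}\t{e}\t{p}\n")
    return {k: str(v) for k, v in paths.items()}
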