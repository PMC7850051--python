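"""Coding-consequence screen for segregating variants in a genomic region.

Classifies SNPs against gene models (synonymous / nonsynonymous / noncoding),
labels amino-acid changes in ``RefAA<codon#>AltAA`` form with 1-based codon
numbering from the annotated CDS start, computes per-population alternate
read fractions, and flags substitutions as conservative when their BLOSUM62
score is non-negative (threshold and matrix configurable -- the source
analysis gives no explicit criterion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io import BASE_INDEX, GeneModel, SyncMatrix

__all__ = [
    "VariantCall",
    "classify_snp",
    "is_conservative",
    "alt_read_fraction",
    "screen_region",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


class ReferenceMismatchError(ValueError):
    """The stated reference allele disagrees with the FASTA sequence."""


@dataclass
class VariantCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str                    # "intergenic" when outside every model
    consequence: str                # synonymous | nonsynonymous | noncoding
    aa_change: str | None           # present iff nonsynonymous
    conservative: bool | None       # defined for nonsynonymous changes only
    fractions: tuple[float, ...]    # per-population alternate read fraction

    def __post_init__(self) -> None:
        if (self.consequence == "nonsynonymous") != (self.aa_change is not None):
            raise ValueError("aa_change must be present iff nonsynonymous")
        for f in self.fractions:
            if np.isfinite(f) and not 0.0 <= f <= 1.0:
                raise ValueError("alt fraction outside [0, 1]")


def is_conservative(ref_aa: str, alt_aa: str, threshold: float = 0.0) -> bool:
    """BLOSUM62-based conservativeness: score >= threshold."""
    try:
        score = _BLOSUM62[ref_aa, alt_aa]
    except (KeyError, IndexError):
        return False
    return float(score) >= threshold


def _cds_sequence(seq: str, gene: GeneModel) -> str:
    parts = [seq[s - 1:e] for s, e in gene.cds_intervals]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def _cds_offset(gene: GeneModel, pos: int) -> int | None:
    """Offset of a genomic position within the spliced CDS (strand-aware)."""
    upstream = 0
    genomic = None
    for s, e in gene.cds_intervals:
        if s <= pos <= e:
            genomic = upstream + (pos - s)
            break
        upstream += e - s + 1
    if genomic is None:
        return None
    if gene.strand == "+":
        return genomic
    return gene.cds_length - 1 - genomic


def classify_snp(
    seq: str, gene: GeneModel, pos: int, ref: str, alt: str,
    conservative_threshold: float = 0.0,
) -> tuple[str, str | None, bool | None]:
    """Consequence of substituting ``ref -> alt`` at ``pos`` within ``gene``.

    ``seq`` is the full chromosome sequence. Returns ``(consequence,
    aa_change, conservative)``. Positions outside the CDS are "noncoding";
    a reference base of N is excluded from consequence calling (also
    "noncoding"); a non-N mismatch with the FASTA raises.
    """
    base = seq[pos - 1].upper()
    ref, alt = ref.upper(), alt.upper()
    if base == "N" or ref == "N":
        return "noncoding", None, None
    if base != ref:
        raise ReferenceMismatchError(
            f"{gene.chrom}:{pos}: reference allele {ref!r} does not match "
            f"FASTA base {base!r}"
        )
    off = _cds_offset(gene, pos)
    if off is None:
        return "noncoding", None, None
    cds = _cds_sequence(seq, gene)
    codon_i = off // 3
    within = off % 3
    codon = cds[3 * codon_i:3 * codon_i + 3]
    if len(codon) < 3:
        return "noncoding", None, None
    alt_base = alt if gene.strand == "+" else str(Seq(alt).complement())
    alt_codon = codon[:within] + alt_base + codon[within + 1:]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return "synonymous", None, None
    label = f"{ref_aa}{codon_i + 1}{alt_aa}"
    return "nonsynonymous", label, is_conservative(
        ref_aa, alt_aa, conservative_threshold
    )


def alt_read_fraction(counts, alt: str) -> float:
    """Alternate reads over A+T+C+G coverage for one population; NaN at 0x."""
    counts = np.asarray(counts, dtype=np.int64)[:4]
    cov = counts.sum()
    if cov == 0:
        return float("nan")
    return float(counts[BASE_INDEX[alt]] / cov)


def screen_region(
    region: tuple[str, int, int],
    mat: SyncMatrix,
    genes: list[GeneModel],
    sequences: dict[str, str],
    min_count: int = 2,
    conservative_threshold: float = 0.0,
) -> list[VariantCall]:
    """Annotate every segregating variant in ``region``.

    A non-reference allele is reported when its summed count across pools
    reaches ``min_count``. Sites overlapping multiple gene models yield one
    call per model. Results are sorted by position (then gene id).
    """
    chrom, start, end = region
    if end < start:
        raise ValueError("region end < start")
    sel = (
        (mat.chroms.astype(str) == str(chrom))
        & (mat.pos >= start) & (mat.pos <= end)
    )
    idx = np.flatnonzero(sel)
    seq = sequences.get(str(chrom))
    calls: list[VariantCall] = []
    region_genes = [
        g for g in genes
        if g.chrom == str(chrom) and g.span[0] <= end and start <= g.span[1]
    ]
    for i in idx:
        ref = str(mat.ref[i]).upper()
        counts = mat.counts[i, :, :4]
        totals = counts.sum(axis=0)
        for b, bi in BASE_INDEX.items():
            if b == ref or totals[bi] < min_count:
                continue
            fracs = tuple(alt_read_fraction(counts[p], b)
                          for p in range(mat.n_populations))
            pos = int(mat.pos[i])
            hits = [g for g in region_genes if g.contains(pos)]
            if not hits:
                calls.append(VariantCall(
                    chrom=str(chrom), pos=pos, ref=ref, alt=b,
                    gene_id="intergenic", consequence="noncoding",
                    aa_change=None, conservative=None, fractions=fracs,
                ))
                continue
            for g in hits:
                if seq is None:
                    raise KeyError(f"no sequence for chromosome {chrom!r}")
                cons, aa, conserv = classify_snp(
                    seq, g, pos, ref, b,
                    conservative_threshold=conservative_threshold,
                )
                calls.append(VariantCall(
                    chrom=str(chrom), pos=pos, ref=ref, alt=b,
                    gene_id=g.gene_id, consequence=cons,
                    aa_change=aa, conservative=conserv, fractions=fracs,
                ))
    calls.sort(key=lambda c: (c.pos, c.gene_id, c.alt))
    return calls


def calls_to_frame(calls: list[VariantCall]) -> pd.DataFrame:
    """Tabular view of :func:`screen_region` output."""
    return pd.DataFrame([
        {
            "chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
            "gene_id": c.gene_id, "consequence": c.consequence,
            "aa_change": c.aa_change if c.aa_change else "NA",
            "conservative": c.conservative,
            "fractions": ",".join(
                "NA" if not np.isfinite(f) else f"{f:.4f}" for f in c.fractions
            ),
        }
        for c in calls
    ])
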